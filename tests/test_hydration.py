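"""RDF normalisation, coordination numbers, hydrogen-bond detection and
occupancy statistics."""

import math

import numpy as np
import pytest

import deutbind as db
from deutbind.core import Atom, Structure, Trajectory, covalent_hydrogen_pairs
from deutbind.hydration import (
    BoxDomain,
    HBondCriteria,
    SphereDomain,
    TopologyError,
    compute_rdf,
    coordination_number,
    detect_hbonds,
    direct_coordination,
    occupancy_stats,
)
from deutbind.simgen import SolvationSpec, TrajectorySpec, resolve_site


def _gas_fixture(n_targets, box=40.0, margin=8.0, n_centers=300, n_frames=20,
                 seed=0):
    """Uniform ideal-gas fixture: targets uniform in the box, centers
    uniform in the interior (so analytic shells stay inside)."""
    rng = np.random.default_rng(seed)
    atoms = [Atom("C", f"C{i}", "GAS", 1) for i in range(n_centers)]
    atoms += [Atom("Ar", f"AR{i}", "GAS", 2) for i in range(n_targets)]
    frames = np.empty((n_frames, n_centers + n_targets, 3))
    for f in range(n_frames):
        frames[f, :n_centers] = rng.uniform(margin, box - margin,
                                            size=(n_centers, 3))
        frames[f, n_centers:] = rng.uniform(0, box, size=(n_targets, 3))
    topo = Structure(atoms, frames[0])
    traj = Trajectory(topo, frames)
    centers = list(range(n_centers))
    targets = list(range(n_centers, n_centers + n_targets))
    domain = BoxDomain((0, 0, 0), (box, box, box))
    return traj, centers, targets, domain


def test_rdf_ideal_gas_limit():
    traj, centers, targets, domain = _gas_fixture(n_targets=1700)
    prof = compute_rdf(traj, centers, targets, r_max=8.0, dr=0.25, domain=domain)
    sel = (prof.bin_centers >= 2.0) & (prof.bin_centers <= 8.0)
    g = prof.g[sel]
    assert np.abs(g - 1.0).max() < 0.08     # per-bin sampling error
    assert np.mean(g) == pytest.approx(1.0, abs=0.02)
    # per-bin Poisson bound: |g-1| < 5 sigma everywhere
    sigma = 1.0 / np.sqrt(np.maximum(prof.counts[sel], 1))
    assert np.all(np.abs(g - 1.0) < 5.0 * sigma + 1e-12)


def test_coordination_closed_form():
    # density 0.01 per cubic Å: N(5) = 4/3 π 125 ρ = 5.236
    traj, centers, targets, domain = _gas_fixture(n_targets=640)
    prof = compute_rdf(traj, centers, targets, r_max=8.0, dr=0.25, domain=domain)
    expected = 4.0 / 3.0 * math.pi * 125.0 * (640 / 40.0**3)
    assert coordination_number(prof, 5.0) == pytest.approx(expected, rel=0.05)
    assert coordination_number(prof, 0.0) == 0.0


def test_coordination_matches_direct_counting():
    traj, centers, targets, domain = _gas_fixture(n_targets=1700, n_frames=10)
    prof = compute_rdf(traj, centers, targets, r_max=8.0, dr=0.1, domain=domain)
    for r_cut in (4.0, 6.0):
        direct = direct_coordination(traj, centers, targets, r_cut)
        assert coordination_number(prof, r_cut) == pytest.approx(direct, rel=0.02)


def test_rdf_droplet_peak_at_contact(histamine_trans):
    """A pinned contact at 2.8 Å over a fluctuating bulk shows up as the
    RDF peak bin.  Bulk placements are redrawn each frame (a static bulk
    has no configurational average and every occupied bin spikes)."""
    spec = SolvationSpec(n_water=10, geometry="sphere", radius=6.0,
                         placed_contacts=[("N2", 2.8)])
    frames = [db.solvate(histamine_trans, spec, seed=f).coords
              for f in range(30)]
    sol = db.solvate(histamine_trans, spec, seed=0)
    traj = Trajectory(sol, np.stack(frames))
    n2 = sol.index_of("N2")
    water_o = [i for i, a in enumerate(sol.atoms)
               if a.res_name == "HOH" and a.element == "O"]
    domain = SphereDomain(tuple(histamine_trans.centroid()), 6.0)
    prof = compute_rdf(traj, [n2], water_o, r_max=5.0, dr=0.1, domain=domain,
                       seed=1)
    peak_r = prof.bin_centers[int(np.argmax(prof.g))]
    assert peak_r == pytest.approx(2.8, abs=0.1 + 1e-9)


def test_rdf_single_contact_coordination(histamine_trans):
    sol = db.solvate(
        histamine_trans,
        SolvationSpec(n_water=1, geometry="sphere", radius=6.0,
                      placed_contacts=[("N2", 2.8)]),
        seed=3,
    )
    traj = db.synth_trajectory(sol, TrajectorySpec(n_frames=10, seed=4))
    n2 = sol.index_of("N2")
    o = resolve_site(sol, "HOH@N2")
    domain = SphereDomain(tuple(histamine_trans.centroid()), 6.0)
    prof = compute_rdf(traj, [n2], [o], r_max=4.5, dr=0.05, domain=domain,
                       seed=1, mc_samples=200_000)
    assert coordination_number(prof, 3.2) == pytest.approx(1.0, abs=0.05)


def test_rdf_errors(histamine_trans):
    traj = db.synth_trajectory(histamine_trans, TrajectorySpec(n_frames=2, seed=0))
    domain = SphereDomain((0, 0, 0), 5.0)
    with pytest.raises(ValueError):
        compute_rdf(traj, [], [1], domain=domain)
    with pytest.raises(ValueError):
        compute_rdf(Trajectory(histamine_trans,
                               np.empty((0, histamine_trans.n_atoms, 3))),
                    [0], [1], domain=domain)


# ---------------------------------------------------------------------------
# hydrogen-bond detection


def _oho(d_oo, angle_deg):
    """O-H···O geometry with given O···O distance and D-H···A angle
    (closed-form: law of cosines at the hydrogen)."""
    r = 0.97
    o1 = np.array([0.0, 0.0, 0.0])
    h = np.array([r, 0.0, 0.0])
    theta = math.radians(angle_deg)
    # |H-A| solving |O1-A| = d with the requested angle at H
    ell = r * math.cos(theta) + math.sqrt(
        d_oo**2 - (r * math.sin(theta)) ** 2
    )
    # direction of H->A making angle theta with H->O1 (= -x)
    u = np.array([-math.cos(theta), math.sin(theta), 0.0])
    a = h + ell * u
    atoms = [Atom("O", "O1", "MOL", 1), Atom("H", "H1", "MOL", 1),
             Atom("O", "O2", "MOL", 2)]
    return Structure(atoms, np.vstack([o1, h, a]))


@pytest.mark.parametrize(
    "d,ang,detected",
    [
        (2.8, 180.0, True),
        (4.0, 180.0, False),     # beyond the distance cutoff
        (3.5, 135.0, True),      # inclusive boundary in both criteria
        (3.0, 120.0, False),     # too bent
    ],
)
def test_detect_hbond_geometries(d, ang, detected):
    s = _oho(d, ang)
    events = detect_hbonds(s, [(0, 1)], [2])
    assert bool(events) is detected
    if detected:
        assert events[0].d_da == pytest.approx(d, abs=1e-6)
        assert events[0].dha_angle == pytest.approx(ang, abs=1e-6)


def test_detect_topology_error():
    s = _oho(2.8, 180.0)
    s.coords[1] = s.coords[0] + np.array([2.0, 0, 0])  # detached hydrogen
    with pytest.raises(TopologyError):
        detect_hbonds(s, [(0, 1)], [2])


def test_detect_duplicate_inputs_single_event():
    s = _oho(2.8, 180.0)
    events = detect_hbonds(s, [(0, 1), (0, 1)], [2, 2])
    assert len(events) == 1


def test_detect_rigid_motion_invariant():
    from scipy.spatial.transform import Rotation

    s = _oho(3.2, 160.0)
    rot = Rotation.random(rng=np.random.default_rng(12))
    moved = Structure(list(s.atoms), rot.apply(s.coords) + np.array([5, -3, 2.0]))
    e1 = detect_hbonds(s, [(0, 1)], [2])
    e2 = detect_hbonds(moved, [(0, 1)], [2])
    assert len(e1) == len(e2) == 1
    assert e1[0].d_da == pytest.approx(e2[0].d_da, abs=1e-9)
    assert e1[0].dha_angle == pytest.approx(e2[0].dha_angle, abs=1e-9)


# ---------------------------------------------------------------------------
# occupancy


def test_occupancy_recovery(histamine_trans):
    sol = db.solvate(
        histamine_trans,
        SolvationSpec(n_water=1, geometry="sphere", radius=6.0,
                      placed_contacts=[("N2", 2.8)]),
        seed=2,
    )
    traj = db.synth_trajectory(
        sol, TrajectorySpec(n_frames=800,
                            hbond_occupancy={("N2", "HOH@N2"): 0.92}, seed=6)
    )
    n2 = sol.index_of("N2")
    o = resolve_site(sol, "HOH@N2")
    donors = [(x, h) for x, h in covalent_hydrogen_pairs(sol) if x == n2]
    stats = occupancy_stats(traj, donors, [o])
    drawn = traj.metadata["generator_log"]["occupancy"][("N2", "HOH@N2")].mean()
    occ = stats.pair_occupancy[(n2, o)]
    assert occ == pytest.approx(drawn, abs=0.01)
    assert 0.0 <= occ <= 1.0
    assert stats.pair_mean_distance[(n2, o)] <= 3.5
    assert stats.pair_mean_distance[(n2, o)] == pytest.approx(2.8, abs=0.05)


def test_three_permanent_waters_mean_count(histamine_trans):
    sol = db.solvate(
        histamine_trans,
        SolvationSpec(n_water=3, geometry="sphere", radius=6.0,
                      placed_contacts=[("N2", 2.8)] * 3),
        seed=7,
    )
    traj = db.synth_trajectory(sol, TrajectorySpec(n_frames=30, seed=8))
    n2 = sol.index_of("N2")
    donors = [(x, h) for x, h in covalent_hydrogen_pairs(sol) if x == n2]
    water_o = [i for i, a in enumerate(sol.atoms)
               if a.res_name == "HOH" and a.element == "O"]
    stats = occupancy_stats(traj, donors, water_o)
    assert stats.donor_mean_count[n2] == pytest.approx(3.0)


def test_mixed_count_mean_two_point_two(histamine_trans):
    """Per-frame ammonium contact count 2 w.p. 0.8 and 3 w.p. 0.2, realised
    as two permanent contacts plus one at 20% occupancy."""
    sol = db.solvate(
        histamine_trans,
        SolvationSpec(n_water=3, geometry="sphere", radius=6.0,
                      placed_contacts=[("N2", 2.8)] * 3),
        seed=5,
    )
    traj = db.synth_trajectory(
        sol,
        TrajectorySpec(
            n_frames=1500,
            hbond_occupancy={
                ("N2", "HOH@N2:1"): 1.0,
                ("N2", "HOH@N2:2"): 1.0,
                ("N2", "HOH@N2:3"): 0.2,
            },
            seed=7,
        ),
    )
    n2 = sol.index_of("N2")
    donors = [(x, h) for x, h in covalent_hydrogen_pairs(sol) if x == n2]
    water_o = [i for i, a in enumerate(sol.atoms)
               if a.res_name == "HOH" and a.element == "O"]
    stats = occupancy_stats(traj, donors, water_o)
    assert stats.donor_mean_count[n2] == pytest.approx(2.2, abs=0.05)


def test_occupancy_empty_trajectory_errors(histamine_trans):
    empty = Trajectory(histamine_trans,
                       np.empty((0, histamine_trans.n_atoms, 3)))
    with pytest.raises(ValueError):
        occupancy_stats(empty, [(0, 1)], [2])
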