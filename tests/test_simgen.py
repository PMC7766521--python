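"""Generator ground-truth checks: template geometry, water packing,
trajectory statistics, the toy pocket, and the surrogate score."""

import numpy as np
import pytest

import deutbind as db
from deutbind.core import Atom, Structure, covalent_hydrogen_pairs, measure
from deutbind.deuteron import apply_deuteration, find_exchangeable
from deutbind.simgen import (
    PackingError,
    SolvationSpec,
    TrajectorySpec,
    resolve_site,
)
from conftest import make_water, merge


@pytest.mark.parametrize("torsion", [158.8, 62.1, -120.0, 180.0, 1.0])
def test_build_torsion_exact(torsion):
    h = db.build_histamine(side_torsion=torsion)
    quad = [h.index_of(n) for n in ("C5", "CB", "CA", "N2")]
    assert measure(h, "dihedral", quad) == pytest.approx(torsion, abs=1e-6)


def test_conformer_regime_distances(histamine_trans, histamine_gauche):
    def d(s):
        return measure(s, "distance", [s.index_of("N1"), s.index_of("N2")])

    assert d(histamine_trans) > 4.0     # extended trans
    assert d(histamine_gauche) < 3.6    # folded gauche


def test_monocation_has_four_nh_bonds(histamine_trans):
    pairs = covalent_hydrogen_pairs(histamine_trans)
    nh = [(x, h) for x, h in pairs if histamine_trans.atoms[x].element == "N"]
    assert len(nh) == 4
    by_site = {}
    for x, h in nh:
        by_site.setdefault(histamine_trans.atoms[x].name, []).append(h)
    assert len(by_site["N2"]) == 3
    assert len(by_site["N3"]) == 1


def test_neutral_and_pi_tautomer_variants():
    neutral = db.build_histamine(protonated=False)
    nh = [
        (x, h)
        for x, h in covalent_hydrogen_pairs(neutral)
        if neutral.atoms[x].element == "N"
    ]
    assert len(nh) == 3
    pi = db.build_histamine(tau_tautomer="Npi")
    names = {a.name for a in pi.atoms}
    assert "HN1" in names and "HN3" not in names


# ---------------------------------------------------------------------------
# solvate


def test_solvate_sphere_bounds(histamine_trans):
    spec = SolvationSpec(n_water=36, geometry="sphere", radius=6.0)
    sol = db.solvate(histamine_trans, spec, seed=4)
    o_idx = [i for i, a in enumerate(sol.atoms)
             if a.res_name == "HOH" and a.element == "O"]
    assert len(o_idx) == 36
    d = np.linalg.norm(sol.coords[o_idx] - histamine_trans.centroid(), axis=1)
    assert d.max() <= 6.0 + 1e-9


def test_solvate_placed_contact(solvated):
    n2 = solvated.index_of("N2")
    o_idx = [i for i, a in enumerate(solvated.atoms)
             if a.res_name == "HOH" and a.element == "O"]
    d = np.linalg.norm(solvated.coords[o_idx] - solvated.coords[n2], axis=1)
    assert np.any(np.abs(d - 2.8) <= 0.05)


def test_solvate_zero_waters_is_identity(histamine_trans):
    spec = SolvationSpec(n_water=0, geometry="sphere", radius=5.0)
    sol = db.solvate(histamine_trans, spec, seed=0)
    assert sol.n_atoms == histamine_trans.n_atoms
    assert np.array_equal(sol.coords, histamine_trans.coords)


def test_solvate_no_heavy_clashes(histamine_trans):
    spec = SolvationSpec(n_water=30, geometry="box", box_edge=12.0)
    sol = db.solvate(histamine_trans, spec, seed=5)
    heavy = sol.coords[sol.heavy_indices()]
    d = np.linalg.norm(heavy[:, None] - heavy[None, :], axis=2)
    # intra-solute and intra-water bonded pairs sit below the cut; check
    # water O against everything that is not its own molecule
    o_idx = [k for k, i in enumerate(sol.heavy_indices())
             if sol.atoms[i].res_name == "HOH"]
    for k in o_idx:
        row = np.delete(d[k], k)
        assert row.min() >= 2.4 - 1e-9


def test_solvate_reproducible(histamine_trans):
    spec = SolvationSpec(n_water=12, geometry="sphere", radius=6.0)
    a = db.solvate(histamine_trans, spec, seed=9)
    b = db.solvate(histamine_trans, spec, seed=9)
    assert np.array_equal(a.coords, b.coords)


def test_solvate_packing_error(histamine_trans):
    spec = SolvationSpec(n_water=60, geometry="sphere", radius=3.0)
    with pytest.raises(PackingError):
        db.solvate(histamine_trans, spec, seed=0)


def test_spec_validation():
    with pytest.raises(ValueError):
        SolvationSpec(n_water=2, geometry="sphere", radius=5.0,
                      placed_contacts=[("N2", 2.8)] * 3)
    with pytest.raises(ValueError):
        TrajectorySpec(n_frames=10, state_populations={"trans": 0.5})
    with pytest.raises(ValueError):
        TrajectorySpec(n_frames=0)
    with pytest.raises(ValueError):
        TrajectorySpec(n_frames=5, hbond_occupancy={("a", "b"): 1.5})


# ---------------------------------------------------------------------------
# synth_trajectory


def test_all_gauche_population(histamine_trans):
    traj = db.synth_trajectory(
        histamine_trans,
        TrajectorySpec(n_frames=50, state_populations={"gauche": 1.0}, seed=3),
    )
    series = db.conformer_series(traj)
    assert all(series.labels == "gauche")


def test_trajectory_bit_reproducible(histamine_trans):
    spec = TrajectorySpec(
        n_frames=20, state_populations={"trans": 0.73, "gauche": 0.27}, seed=11
    )
    a = db.synth_trajectory(histamine_trans, spec)
    b = db.synth_trajectory(histamine_trans, spec)
    assert np.array_equal(a.frames, b.frames)


def test_drawn_states_match_spec_marginals(histamine_trans):
    spec = TrajectorySpec(
        n_frames=4000, state_populations={"trans": 0.73, "gauche": 0.27}, seed=1
    )
    traj = db.synth_trajectory(histamine_trans, spec)
    drawn = traj.metadata["generator_log"]["states"]
    # 99% binomial band around the requested fraction
    half = 2.576 * np.sqrt(0.73 * 0.27 / 4000)
    assert abs(np.mean(drawn == "trans") - 0.73) < half


def test_occupancy_schedule_realised(histamine_trans):
    sol = db.solvate(
        histamine_trans,
        SolvationSpec(n_water=1, geometry="sphere", radius=6.0,
                      placed_contacts=[("N2", 2.8)]),
        seed=2,
    )
    spec = TrajectorySpec(
        n_frames=400, hbond_occupancy={("N2", "HOH@N2"): 0.92}, seed=6
    )
    traj = db.synth_trajectory(sol, spec)
    log = traj.metadata["generator_log"]["occupancy"][("N2", "HOH@N2")]
    n2 = sol.index_of("N2")
    o = resolve_site(sol, "HOH@N2")
    d = np.linalg.norm(traj.frames[:, o] - traj.frames[:, n2], axis=1)
    # bonded frames sit at 2.8, broken at 5.0 (up to jitter)
    assert np.all(np.abs(d[log] - 2.8) < 0.3)
    assert np.all(np.abs(d[~log] - 5.0) < 0.3)


def test_unknown_site_errors(histamine_trans):
    spec = TrajectorySpec(
        n_frames=5, hbond_occupancy={("N9", "HOH@N2"): 0.5}, seed=0
    )
    with pytest.raises(KeyError):
        db.synth_trajectory(histamine_trans, spec)


# ---------------------------------------------------------------------------
# pocket and surrogate


def test_pocket_has_sixteen_residues(pocket):
    receptor = {
        (a.res_number, a.res_name) for a in pocket.atoms if a.chain == "R"
    }
    assert len(receptor) == 16
    assert (98, "ASP") in receptor and (254, "PHE") in receptor


def test_pocket_asp98_anchor_distance(pocket):
    n2 = pocket.index_of("N2")
    od1 = resolve_site(pocket, "Asp98:OD1")
    d = np.linalg.norm(pocket.coords[od1] - pocket.coords[n2])
    assert d == pytest.approx(2.8, abs=0.1)


def test_pocket_tyr250_donates_to_asp98(pocket):
    pairs = covalent_hydrogen_pairs(pocket)
    oh = resolve_site(pocket, "Tyr250:OH")
    donors = [(x, h) for x, h in pairs if x == oh]
    od2 = resolve_site(pocket, "Asp98:OD2")
    events = db.detect_hbonds(pocket, donors, [od2])
    assert len(events) == 1


def test_surrogate_zero_without_hbonds():
    lone = Structure([Atom("O", "O", "HOH", 1)], np.zeros((1, 3)))
    assert db.surrogate_energy(lone) == 0.0


def test_surrogate_ideal_well_depth():
    # single bent O-H···O bond with through-hydrogen path exactly 2.9 Å
    import math

    o1 = np.array([0.0, 0.0, 0.0])
    h = np.array([0.97, 0.0, 0.0])
    theta = math.radians(180.0 - 150.0)
    rest = 2.9 - 0.97
    o2 = h + rest * np.array([math.cos(theta), math.sin(theta), 0.0])
    s = Structure(
        [Atom("O", "O1", "MOL", 1), Atom("H", "H1", "MOL", 1),
         Atom("O", "O2", "MOL", 2)],
        np.vstack([o1, h, o2]),
    )
    assert db.surrogate_energy(s) == pytest.approx(-5.0, abs=1e-9)
    # contracting the donor bond changes the path length, hence the score
    deut = apply_deuteration(s, find_exchangeable(s))
    assert db.surrogate_energy(deut.structure) != pytest.approx(-5.0, abs=1e-6)


def test_surrogate_sensitive_to_deuteration(pocket):
    e_h = db.surrogate_energy(pocket)
    deut = apply_deuteration(pocket, find_exchangeable(pocket))
    e_d = db.surrogate_energy(deut.structure)
    assert e_h < 0
    assert e_d != e_h
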