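"""Synthetic-data generators for the deuteration-binding pipeline.

Nothing here runs molecular dynamics or quantum chemistry.  The generators
emulate the *statistical* structure of such outputs at fixture scale — a
histamine-like monocation with a settable side-chain torsion, droplets and
boxes of rigid 3-site waters, a toy 16-residue binding pocket with an
anionic anchor, and trajectories with prescribed conformer populations,
positional jitter and hydrogen-bond occupancy schedules — so that every
analysis stage can be exercised and validated against known ground truth.

All generators are deterministic given (spec, seed): a single
``numpy.random.default_rng(seed)`` drives every stochastic draw.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    Atom,
    GeometryError,
    Structure,
    Trajectory,
    covalent_hydrogen_pairs,
    dihedral,
    place_atom,
)
from .hydration import HBondCriteria, detect_hbonds


class PackingError(RuntimeError):
    """Could not place the requested number of waters without clashes."""


# ---------------------------------------------------------------------------
# specs

#: Torsion window (degrees, absolute value) sampled for gauche frames;
#: straddles the representative gauche torsion of 62.1°.
GAUCHE_RANGE = (40.0, 90.0)
#: Torsion window sampled for trans frames; straddles 158.8°.
TRANS_RANGE = (140.0, 180.0)

#: Rigid 3-site water geometry (standard TIP3P-style): O-H bond length and
#: H-O-H angle.
WATER_OH = 0.9572
WATER_HOH = 104.52

#: Minimum heavy-atom separation accepted when packing waters.
CLASH_DISTANCE = 2.4


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for a synthetic trajectory.

    state_populations maps conformer labels ("gauche"/"trans") to fractions
    summing to 1.  hbond_occupancy maps (donor site, partner site) token
    pairs to the marginal fraction of frames in which the contact is in its
    bonded geometry (see :func:`resolve_site` for the token grammar).
    jitter_sigma is an isotropic Gaussian displacement applied to every
    atom, in Å.
    """

    n_frames: int
    state_populations: Mapping[str, float] = field(default_factory=dict)
    jitter_sigma: float = 0.02
    hbond_occupancy: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.state_populations:
            bad = set(self.state_populations) - {"gauche", "trans"}
            if bad:
                raise ValueError(f"unknown conformer labels {sorted(bad)}")
            total = float(sum(self.state_populations.values()))
            if any(not 0.0 <= v <= 1.0 for v in self.state_populations.values()):
                raise ValueError("state populations must lie in [0, 1]")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"state populations sum to {total}, not 1")
        for pair, frac in self.hbond_occupancy.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"occupancy for {pair} outside [0, 1]")


@dataclass(frozen=True)
class SolvationSpec:
    """Recipe for a water shell or box around a solute.

    ``geometry`` is "sphere" (droplet of given ``radius`` around the solute
    centroid) or "box" (cube of edge ``box_edge`` centred on the solute
    centroid).  ``placed_contacts`` pins selected water oxygens at a target
    distance from named solute sites; the rest are placed uniformly with a
    hard heavy-atom clash exclusion.
    """

    n_water: int
    geometry: str = "sphere"
    radius: float | None = None
    box_edge: float | None = None
    bulk_density: float | None = None
    placed_contacts: Sequence[tuple[str, float]] = ()

    def __post_init__(self) -> None:
        if self.n_water < 0:
            raise ValueError("n_water must be >= 0")
        if self.geometry not in {"sphere", "box"}:
            raise ValueError("geometry must be 'sphere' or 'box'")
        if self.geometry == "sphere" and self.radius is None:
            raise ValueError("sphere geometry needs a radius")
        if self.geometry == "box" and self.box_edge is None:
            raise ValueError("box geometry needs a box_edge")
        if self.bulk_density is not None and self.bulk_density <= 0:
            raise ValueError("bulk_density must be > 0")
        if len(self.placed_contacts) > self.n_water:
            raise ValueError("more placed_contacts than waters")

    def volume(self) -> float:
        if self.geometry == "sphere":
            return 4.0 / 3.0 * math.pi * float(self.radius) ** 3
        return float(self.box_edge) ** 3

    def density(self) -> float:
        if self.bulk_density is not None:
            return self.bulk_density
        return self.n_water / self.volume()


# ---------------------------------------------------------------------------
# site token grammar

_RES_SITE = re.compile(r"^([A-Za-z]{2,4}?)(\d+):(\S+)$")
_WATER_SITE = re.compile(r"^(HOH|WAT)@(\S+?)(?::(\d+))?$")


def resolve_site(structure: Structure, token: str) -> int:
    """Resolve a site token to a 0-based atom index.

    Grammar:
      - ``"N2"``            unique atom name anywhere in the structure;
      - ``"Thr190:OG1"``    atom OG1 of residue THR 190;
      - ``"HOH@N2"``        O atom of the water whose O is nearest to site
        N2 (``HOH@N2:2`` the second nearest, and so on).
    """
    m = _WATER_SITE.match(token)
    if m is not None:
        anchor = resolve_site(structure, m.group(2))
        rank = int(m.group(3) or 1)
        waters = [
            i
            for i, a in enumerate(structure.atoms)
            if a.res_name in {"HOH", "WAT"} and a.element == "O"
        ]
        if len(waters) < rank:
            raise KeyError(f"site {token!r}: only {len(waters)} waters present")
        d = np.linalg.norm(
            structure.coords[waters] - structure.coords[anchor], axis=1
        )
        order = np.lexsort((np.asarray(waters), d))
        return int(np.asarray(waters)[order][rank - 1])
    m = _RES_SITE.match(token)
    if m is not None:
        res_name, res_number, atom_name = m.groups()
        hits = [
            i
            for i, a in enumerate(structure.atoms)
            if a.res_number == int(res_number)
            and a.res_name.upper() == res_name.upper()
            and a.name == atom_name
        ]
        if len(hits) != 1:
            raise KeyError(f"site {token!r} resolved to {len(hits)} atoms")
        return hits[0]
    return structure.index_of(token)


def _residue_indices_of(structure: Structure, atom_index: int) -> np.ndarray:
    a = structure.atoms[atom_index]
    return np.array(
        [
            i
            for i, b in enumerate(structure.atoms)
            if b.res_number == a.res_number and b.res_name == a.res_name
            and b.chain == a.chain
        ],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# histamine template

#: Fixed template dihedral N1-C5-CB-CA (degrees): orientation of the ethyl
#: linker relative to the imidazole plane.  20° places the gauche/trans
#: N1-N2 distances in the regimes seen in solution (≈3.1 / ≈4.4 Å).
_RING_SIDE_DIHEDRAL = 20.0

_RING_BOND = 1.37
_C_H = 1.08
_N_H_RING = 1.01
_N_H_AMINE = 1.03
_C_C = 1.53
_C_N = 1.49
_C_RING_CB = 1.50


def build_histamine(
    tau_tautomer: str = "Ntau",
    protonated: bool = True,
    side_torsion: float = 158.8,
) -> Structure:
    """Idealized-geometry histamine with a settable side-chain torsion.

    Atom naming follows the convention used for this ligand: N1 is the ring
    imino nitrogen adjacent to the side chain (hydrogen-bond acceptor in
    the gauche conformer), N2 the aliphatic amine, and N3 the ring amino
    nitrogen.  ``tau_tautomer`` picks which ring nitrogen carries the
    hydrogen ("Ntau": N3-H, the dominant form in water; "Npi": N1-H).  The
    protonated monocation carries three hydrogens on N2 (18 atoms,
    C5H10N3+); the neutral amine carries two.

    The measured C5-CB-CA-N2 torsion of the returned structure equals
    ``side_torsion`` exactly (construction by internal coordinates).
    """
    if tau_tautomer not in {"Ntau", "Npi"}:
        raise ValueError("tau_tautomer must be 'Ntau' or 'Npi'")
    if not -180.0 < side_torsion <= 180.0:
        raise ValueError("side_torsion must lie in (-180, 180]")

    radius = _RING_BOND / (2.0 * math.sin(math.radians(36.0)))
    ring_order = ["C5", "N1", "C2", "N3", "C4"]
    pos: dict[str, np.ndarray] = {}
    for k, nm in enumerate(ring_order):
        th = math.radians(90.0 + 72.0 * k)
        pos[nm] = np.array([radius * math.cos(th), radius * math.sin(th), 0.0])

    def radial(nm: str, bond: float) -> np.ndarray:
        p = pos[nm]
        return p + bond * p / np.linalg.norm(p)

    pos["H2"] = radial("C2", _C_H)
    pos["H4"] = radial("C4", _C_H)
    ring_nh = "N3" if tau_tautomer == "Ntau" else "N1"
    pos["H" + ring_nh] = radial(ring_nh, _N_H_RING)

    pos["CB"] = radial("C5", _C_RING_CB)
    pos["CA"] = place_atom(
        pos["N1"], pos["C5"], pos["CB"], _C_C, 111.0, _RING_SIDE_DIHEDRAL
    )
    pos["N2"] = place_atom(pos["C5"], pos["CB"], pos["CA"], _C_N, 111.0, side_torsion)
    pos["HB1"] = place_atom(
        pos["N1"], pos["C5"], pos["CB"], 1.09, 109.5, _RING_SIDE_DIHEDRAL + 120.0
    )
    pos["HB2"] = place_atom(
        pos["N1"], pos["C5"], pos["CB"], 1.09, 109.5, _RING_SIDE_DIHEDRAL - 120.0
    )
    pos["HA1"] = place_atom(
        pos["C5"], pos["CB"], pos["CA"], 1.09, 109.5, side_torsion + 120.0
    )
    pos["HA2"] = place_atom(
        pos["C5"], pos["CB"], pos["CA"], 1.09, 109.5, side_torsion - 120.0
    )
    amine_dihedrals = (60.0, 180.0, -60.0) if protonated else (60.0, -60.0)
    for i, dih in enumerate(amine_dihedrals, start=1):
        pos[f"HN2{i}"] = place_atom(
            pos["CB"], pos["CA"], pos["N2"], _N_H_AMINE, 109.5, dih
        )

    order = ["N1", "C2", "N3", "C4", "C5", "CB", "CA", "N2", "H2", "H4",
             "H" + ring_nh, "HB1", "HB2", "HA1", "HA2"]
    order += [f"HN2{i}" for i in range(1, len(amine_dihedrals) + 1)]
    atoms = [
        Atom(
            element="N" if nm.startswith("N") and not nm.startswith("H") else
            ("H" if nm.startswith("H") else "C"),
            name=nm,
            res_name="HSM",
            res_number=1,
            chain="A",
        )
        for nm in order
    ]
    return Structure(atoms, np.array([pos[nm] for nm in order]))


# ---------------------------------------------------------------------------
# water packing


def _water_coords(o_pos: np.ndarray, bisector: np.ndarray, spin: float) -> np.ndarray:
    """Rigid 3-site water with its H-H bisector along ``bisector`` and an
    arbitrary spin (radians) about it."""
    half = math.radians(WATER_HOH / 2.0)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [WATER_OH * math.cos(half), WATER_OH * math.sin(half), 0.0],
            [WATER_OH * math.cos(half), -WATER_OH * math.sin(half), 0.0],
        ]
    )
    b = bisector / np.linalg.norm(bisector)
    rot_align, _ = Rotation.align_vectors([b], [[1.0, 0.0, 0.0]])
    rot_spin = Rotation.from_rotvec(spin * b)
    return o_pos + rot_spin.apply(rot_align.apply(local))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def solvate(solute: Structure, spec: SolvationSpec, seed: int = 0) -> Structure:
    """Surround a solute with rigid 3-site waters.

    Placed contacts put a water oxygen at the requested distance from the
    named solute site, along one of the site's X-H bond directions when the
    site carries hydrogens (so a donated hydrogen bond is near-linear) and
    radially outward otherwise, satisfied to well under 0.05 Å.  Remaining
    waters are placed uniformly in the droplet/box with a hard heavy-atom
    clash exclusion of 2.4 Å.  Raises PackingError when the density cannot
    be met after bounded retries.
    """
    if spec.n_water == 0:
        return solute.copy()
    rng = np.random.default_rng(seed)
    center = solute.centroid()
    heavy = list(solute.coords[solute.heavy_indices()])
    hpairs = covalent_hydrogen_pairs(solute)

    water_blocks: list[np.ndarray] = []
    next_res = int(max((a.res_number for a in solute.atoms), default=0)) + 1

    def accept(o_pos: np.ndarray, relax: float = 1.0) -> bool:
        pts = np.asarray(heavy)
        return bool(
            np.all(np.linalg.norm(pts - o_pos, axis=1) >= CLASH_DISTANCE * relax)
        )

    # pinned contacts first
    for site_token, target in spec.placed_contacts:
        site = resolve_site(solute, site_token)
        site_pos = solute.coords[site]
        h_dirs = [
            (solute.coords[h] - site_pos) / np.linalg.norm(solute.coords[h] - site_pos)
            for x, h in hpairs
            if x == site
        ]
        # prefer the site's X-H bond directions (near-linear donated bond),
        # cycling through them as contacts accumulate; fall back on random
        # directions for acceptor-only sites or when all bond axes clash
        start = len(water_blocks) % len(h_dirs) if h_dirs else 0
        candidates = h_dirs[start:] + h_dirs[:start]
        candidates += [_random_unit(rng) for _ in range(200)]
        placed = False
        for direction in candidates:
            o_pos = site_pos + target * direction
            # the pinned O may sit closer than the generic clash cut to its
            # own site, but not to anything else
            others = [p for p in heavy if np.linalg.norm(p - site_pos) > 1e-9]
            ok = all(
                np.linalg.norm(p - o_pos) >= min(CLASH_DISTANCE, target - 0.05)
                for p in others
            ) and all(
                np.linalg.norm(w[0] - o_pos) >= CLASH_DISTANCE
                for w in water_blocks
            )
            if ok:
                bisector = direction  # hydrogens point away from the site
                water_blocks.append(
                    _water_coords(o_pos, bisector, rng.uniform(0, 2 * math.pi))
                )
                heavy.append(o_pos)
                placed = True
                break
        if not placed:
            raise PackingError(f"cannot satisfy placed contact at {site_token!r}")

    # bulk waters
    n_bulk = spec.n_water - len(spec.placed_contacts)
    attempts = 0
    max_attempts = 4000 * max(n_bulk, 1)
    while len(water_blocks) < spec.n_water:
        if attempts > max_attempts:
            raise PackingError(
                f"placed {len(water_blocks)}/{spec.n_water} waters after "
                f"{attempts} attempts"
            )
        attempts += 1
        if spec.geometry == "sphere":
            r = float(spec.radius) * rng.random() ** (1.0 / 3.0)
            o_pos = center + r * _random_unit(rng)
        else:
            o_pos = center + float(spec.box_edge) * (rng.random(3) - 0.5)
        if not accept(o_pos):
            continue
        if any(np.linalg.norm(w[0] - o_pos) < CLASH_DISTANCE for w in water_blocks):
            continue
        water_blocks.append(
            _water_coords(o_pos, _random_unit(rng), rng.uniform(0, 2 * math.pi))
        )
        heavy.append(o_pos)

    atoms = list(solute.atoms)
    coords = [solute.coords]
    for k, block in enumerate(water_blocks):
        for nm, el in (("O", "O"), ("H1", "H"), ("H2", "H")):
            atoms.append(
                Atom(element=el, name=nm, res_name="HOH",
                     res_number=next_res + k, chain="W")
            )
        coords.append(block)
    return Structure(atoms, np.vstack(coords))


# ---------------------------------------------------------------------------
# trajectory synthesis

#: Heavy-atom distance (Å) realised for an occupied (bonded) contact, at
#: the solution-phase hydrogen-bond peak, and for a broken one, well past
#: the detection cutoff.
BONDED_DISTANCE = 2.8
BROKEN_DISTANCE = 5.0


def synth_trajectory(base: Structure, spec: TrajectorySpec) -> Trajectory:
    """Draw an i.i.d. synthetic trajectory from a base structure.

    Each frame samples a conformer state from ``spec.state_populations``
    (gauche torsions uniform in ±[40°, 90°], trans in ±[140°, 180°]) by
    rotating the aminoethyl group about the CB-CA bond, realises each
    hydrogen-bond occupancy schedule by toggling the partner residue
    between its bonded (2.8 Å) and broken (5.0 Å) positions along the
    donor-partner axis, and finally applies isotropic Gaussian jitter to
    every atom.  The drawn ground truth (states, torsions, per-pair bonded
    flags) is stored in ``Trajectory.metadata["generator_log"]`` so that
    estimators can be validated against the generator's own schedule.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    coords0 = base.coords.copy()

    # conformer machinery (only when populations are requested)
    if spec.state_populations:
        try:
            quad = [base.index_of(nm) for nm in ("C5", "CB", "CA", "N2")]
        except KeyError as exc:
            raise KeyError(f"base structure lacks a torsion site: {exc}") from exc
        phi0 = dihedral(coords0, *quad)
        ca, cb = quad[2], quad[1]
        rotating = _downstream_atoms(base, pivot=ca, exclude=cb)
        labels = sorted(spec.state_populations)
        probs = np.array([spec.state_populations[l] for l in labels])
        states = rng.choice(len(labels), size=n, p=probs)
        state_names = np.array(labels, dtype=object)[states]
        lo = np.where(state_names == "gauche", GAUCHE_RANGE[0], TRANS_RANGE[0])
        hi = np.where(state_names == "gauche", GAUCHE_RANGE[1], TRANS_RANGE[1])
        signs = rng.choice([-1.0, 1.0], size=n)
        torsions = signs * rng.uniform(lo, hi)
    else:
        state_names = np.array(["base"] * n, dtype=object)
        torsions = None

    # occupancy machinery: each toggled partner lives on the axis of one of
    # the donor's X-H bonds (the one best aligned with the base geometry),
    # so the bonded position forms a near-linear, detectable hydrogen bond
    base_hpairs = covalent_hydrogen_pairs(base)
    claimed_axes: dict[int, set[int]] = {}
    pair_info = []
    for (donor_tok, partner_tok), frac in spec.hbond_occupancy.items():
        donor = resolve_site(base, donor_tok)
        partner = resolve_site(base, partner_tok)
        group = _residue_indices_of(base, partner)
        u = coords0[partner] - coords0[donor]
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            raise GeometryError(f"coincident sites in pair {(donor_tok, partner_tok)}")
        u = u / norm
        free_h = [
            h for x, h in base_hpairs
            if x == donor and h not in claimed_axes.get(donor, set())
        ]
        if free_h:
            dirs = [
                (coords0[h] - coords0[donor])
                / np.linalg.norm(coords0[h] - coords0[donor])
                for h in free_h
            ]
            best = int(np.argmax([float(np.dot(d, u)) for d in dirs]))
            claimed_axes.setdefault(donor, set()).add(free_h[best])
            axis_h = free_h[best]
        else:
            axis_h = None
        bonded = rng.random(n) < frac
        pair_info.append(
            ((donor_tok, partner_tok), donor, partner, group, u, axis_h, bonded)
        )

    jitter = rng.normal(0.0, spec.jitter_sigma, size=(n, base.n_atoms, 3)) \
        if spec.jitter_sigma > 0 else np.zeros((n, base.n_atoms, 3))

    frames = np.empty((n, base.n_atoms, 3))
    for f in range(n):
        c = coords0.copy()
        if torsions is not None:
            dphi = math.radians(torsions[f] - phi0)
            axis = c[ca] - c[cb]
            axis = axis / np.linalg.norm(axis)
            rot = Rotation.from_rotvec(dphi * axis)
            c[rotating] = rot.apply(c[rotating] - c[ca]) + c[ca]
        for _, donor, partner, group, u, axis_h, bonded in pair_info:
            if axis_h is not None:
                axis = c[axis_h] - c[donor]
                axis = axis / np.linalg.norm(axis)
            else:
                axis = u
            target = BONDED_DISTANCE if bonded[f] else BROKEN_DISTANCE
            shift = (c[donor] + target * axis) - c[partner]
            c[group] = c[group] + shift
        frames[f] = c + jitter[f]

    log = {
        "states": state_names,
        "torsions": torsions,
        "occupancy": {
            pair: bonded for pair, _, _, _, _, _, bonded in pair_info
        },
    }
    return Trajectory(base.copy(), frames, metadata={"generator_log": log,
                                                     "spec": spec})


def _downstream_atoms(s: Structure, pivot: int, exclude: int) -> np.ndarray:
    """Atom indices on the far side of the exclude->pivot bond (the pivot's
    substituents and everything bonded beyond them), pivot itself excluded.
    Bonds are perceived by distance (<1.8 Å heavy-heavy, <1.2 Å X-H)."""
    n = s.n_atoms
    d = np.linalg.norm(s.coords[:, None, :] - s.coords[None, :, :], axis=2)
    is_h = s.elements == "H"
    cut = np.where(is_h[:, None] | is_h[None, :], 1.2, 1.8)
    adj = (d > 1e-9) & (d <= cut)
    seen = {pivot, exclude}
    stack = [j for j in np.flatnonzero(adj[pivot]) if j not in seen]
    out = []
    while stack:
        j = stack.pop()
        if j in seen:
            continue
        seen.add(j)
        out.append(j)
        stack.extend(k for k in np.flatnonzero(adj[j]) if k not in seen)
    return np.asarray(sorted(out), dtype=int)


# ---------------------------------------------------------------------------
# toy binding pocket

POCKET_RESIDUES = [
    (98, "ASP"), (99, "VAL"), (100, "MET"), (101, "LEU"), (102, "CYS"),
    (103, "THR"), (186, "ASP"), (187, "GLY"), (188, "LEU"), (189, "VAL"),
    (190, "THR"), (250, "TYR"), (251, "PHE"), (252, "THR"), (253, "ALA"),
    (254, "PHE"),
]


def make_pocket_complex(ligand: Structure, seed: int = 0) -> Structure:
    """Toy 16-residue binding-pocket complex around a histamine-like ligand.

    Idealized side-chain stubs arranged so that: the Asp98 carboxylate OD1
    accepts a near-linear hydrogen bond from the ligand ammonium (OD1 2.8 Å
    from N2 along an N2-H direction); the Tyr250 hydroxyl donates to the
    other carboxylate oxygen OD2; the Thr103 hydroxyl oxygen accepts the
    ring N3-H; and the Thr190 hydroxyl donates to a backbone-like carbonyl
    oxygen on Asp186 at 2.76 Å.  Remaining residues are Cα stubs (plus the
    exchangeable -OH/-SH groups on Thr252 and Cys102) scattered on a shell
    around the ligand with clash avoidance.
    """
    rng = np.random.default_rng(seed)
    lig_centroid = ligand.centroid()
    hpairs = covalent_hydrogen_pairs(ligand)
    n2 = ligand.index_of("N2")
    n3 = ligand.index_of("N3")
    n2_h = [h for x, h in hpairs if x == n2]
    n3_h = [h for x, h in hpairs if x == n3]
    if not n2_h or not n3_h:
        raise ValueError("ligand must carry N2-H and N3-H hydrogens")

    def unit(v):
        return v / np.linalg.norm(v)

    residues: dict[tuple[int, str], list[tuple[str, str, np.ndarray]]] = {}

    def add(resnum, resname, entries):
        residues[(resnum, resname)] = entries

    # --- Asp98: carboxylate anchored on the ligand ammonium -------------
    # hydrogen bonds are built slightly bent (D-H···A around 170°, well
    # inside the detection window) as in real geometries; an exactly
    # linear bond would make the surrogate score blind to donor-H shifts
    u1 = unit(ligand.coords[n2_h[0]] - ligand.coords[n2])
    perp = unit(np.cross(u1, unit(ligand.coords[n2] - lig_centroid) + 0.3))
    od1 = ligand.coords[n2] + 2.8 * unit(u1 + 0.18 * perp)
    cg = od1 + 1.25 * (math.cos(math.radians(30)) * u1
                       + math.sin(math.radians(30)) * perp)
    od2 = place_atom(ligand.coords[n2], od1, cg, 1.25, 126.0, 10.0)
    cb98 = place_atom(od2, od1, cg, 1.53, 117.0, 150.0)
    ca98 = place_atom(od1, cg, cb98, 1.53, 111.0, 180.0)
    add(98, "ASP", [("CA", "C", ca98), ("CB", "C", cb98), ("CG", "C", cg),
                    ("OD1", "O", od1), ("OD2", "O", od2)])

    # --- Tyr250: hydroxyl donating to Asp98 OD2 (bent, not collinear) ----
    v = unit(od2 - cg)
    tilt = unit(v + 0.35 * perp)
    oh = od2 + 2.8 * tilt
    hh = oh + 0.97 * unit(unit(od2 - oh) + 0.15 * perp)
    cz = place_atom(cg, od2, oh, 1.36, 112.0, 60.0)
    ca250 = cz + 2.0 * unit(cz - od2)
    add(250, "TYR", [("CA", "C", ca250), ("CZ", "C", cz),
                     ("OH", "O", oh), ("HH", "H", hh)])

    # --- Thr103: hydroxyl oxygen accepting the ring N3-H -----------------
    w = unit(ligand.coords[n3_h[0]] - ligand.coords[n3])
    wtilt = unit(np.cross(w, perp))
    og103 = ligand.coords[n3] + 2.9 * unit(w + 0.15 * wtilt)
    wperp = unit(np.cross(w, perp))
    hg103 = og103 + 0.96 * unit(w + 1.4 * wperp)
    cb103 = og103 + 1.43 * unit(w - 0.8 * wperp)
    ca103 = cb103 + 1.53 * unit(w)
    add(103, "THR", [("CA", "C", ca103), ("CB", "C", cb103),
                     ("OG1", "O", og103), ("HG1", "H", hg103)])

    # --- Asp186 backbone carbonyl + Thr190 hydroxyl pair ------------------
    e = unit(-u1 - 0.5 * w)
    o186 = lig_centroid + 6.5 * e
    c186 = o186 + 1.23 * unit(e + 0.4 * perp)
    ca186 = c186 + 1.52 * unit(e - 0.4 * perp)
    add(186, "ASP", [("CA", "C", ca186), ("C", "C", c186), ("O", "O", o186)])
    h = unit(np.cross(e, perp) + 0.3 * e)
    og190 = o186 + 2.76 * h
    hg190 = og190 + 0.96 * unit(unit(o186 - og190) + 0.15 * perp)
    cb190 = og190 + 1.43 * unit(h + 0.5 * perp)
    ca190 = cb190 + 1.53 * h
    add(190, "THR", [("CA", "C", ca190), ("CB", "C", cb190),
                     ("OG1", "O", og190), ("HG1", "H", hg190)])

    # --- remaining stub residues on a shell -------------------------------
    taken = [ligand.coords[i] for i in ligand.heavy_indices()]
    for entries in residues.values():
        taken.extend(p for _, el, p in entries if el != "H")

    def place_stub(extra_entries):
        for _ in range(2000):
            pos = lig_centroid + rng.uniform(6.0, 8.5) * _random_unit(rng)
            pts = np.asarray(taken)
            if np.all(np.linalg.norm(pts - pos, axis=1) >= 3.0):
                out = unit(pos - lig_centroid)
                entries = [("CA", "C", pos)]
                cursor = pos
                for nm, el, bond in extra_entries:
                    cursor = cursor + bond * out
                    entries.append((nm, el, cursor))
                for _, el, p in entries:
                    if el != "H":
                        taken.append(p)
                return entries
        raise PackingError("cannot place pocket stub without clashes")

    plain = {99: "VAL", 100: "MET", 101: "LEU", 187: "GLY", 188: "LEU",
             189: "VAL", 251: "PHE", 253: "ALA", 254: "PHE"}
    for num, name in sorted(plain.items()):
        add(num, name, place_stub([]))
    add(102, "CYS", place_stub([("CB", "C", 1.53), ("SG", "S", 1.81),
                                ("HG", "H", 1.34)]))
    add(252, "THR", place_stub([("CB", "C", 1.53), ("OG1", "O", 1.43),
                                ("HG1", "H", 0.96)]))

    atoms = list(ligand.atoms)
    coords = [ligand.coords]
    for (num, name) in sorted(residues):
        for atom_name, el, pos in residues[(num, name)]:
            atoms.append(Atom(element=el, name=atom_name, res_name=name,
                              res_number=num, chain="R"))
            coords.append(pos[None, :])
    return Structure(atoms, np.vstack(coords))


# ---------------------------------------------------------------------------
# surrogate energy


def surrogate_energy(s: Structure, criteria: HBondCriteria | None = None) -> float:
    """Deterministic hydrogen-bond network score in kcal/mol.

    Sum over detected hydrogen bonds of a Gaussian well
    -5·exp(-((d - 2.9)/0.3)²) where d is the through-hydrogen path length
    |D-H| + |H···A| (equal to the donor-acceptor separation for a perfectly
    linear bond).  Using the path length makes the score sensitive to the
    donor-hydrogen displacement applied by the deuteration transform.

    This is a synthetic scoring device for exercising the thermodynamic
    cycle end-to-end; it is not a quantum-chemical or force-field energy.
    """
    criteria = criteria or HBondCriteria()
    hpairs = covalent_hydrogen_pairs(s)
    donors = [(x, h) for x, h in hpairs if s.atoms[x].element in {"N", "O", "S"}]
    acceptors = [
        i for i in range(s.n_atoms) if s.atoms[i].element in {"N", "O", "S"}
    ]
    if not donors or not acceptors:
        return 0.0
    events = detect_hbonds(s, donors, acceptors, criteria)
    total = 0.0
    for ev in events:
        path = (
            np.linalg.norm(s.coords[ev.hydrogen] - s.coords[ev.donor])
            + np.linalg.norm(s.coords[ev.acceptor] - s.coords[ev.hydrogen])
        )
        total += -5.0 * math.exp(-(((path - 2.9) / 0.3) ** 2))
    return float(total)
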