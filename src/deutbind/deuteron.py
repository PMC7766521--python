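"""Exchangeable-site identification, the empirical deuteration geometry
transform, and binding-site cluster / water-shell extraction.

Deuteration is mimicked geometrically (the Ubbelohde effect): every acidic
X-H bond (X = N, O, S by default — hydrogens on these heteroatoms exchange
with solvent deuterium in D2O) is contracted by a fixed fraction, 2.3% by
default, along the X→H direction with the heavy atom frozen.  The
transformed bonds are emitted as a generic constraint list (atom pair +
target length) for downstream engines that re-optimise the remaining
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, GeometryError, Structure, WATER_NAMES

#: Default fractional X-H bond contraction mimicking H→D substitution.
DEFAULT_FRACTION = 0.023


@dataclass(frozen=True)
class ExchangeRule:
    """Which hydrogens count as exchangeable: those within ``max_bond`` Å
    of a heavy atom whose element is in ``donor_elements``."""

    donor_elements: frozenset = frozenset({"N", "O", "S"})
    max_bond: float = 1.4

    def __post_init__(self) -> None:
        if not self.donor_elements:
            raise ValueError("donor element set must be non-empty")


def find_exchangeable(
    s: Structure, rule: ExchangeRule | None = None
) -> list[tuple[int, int]]:
    """(X index, H index) pairs for every exchangeable hydrogen.

    Each hydrogen within the rule's bond length of an N/O/S atom is paired
    with its nearest such heavy atom; each hydrogen appears at most once.
    Output sorted by (X index, H index).  A hydrogen equidistant (within
    1e-6 Å) to two candidates indicates a malformed structure and raises.
    """
    rule = rule or ExchangeRule()
    elements = s.elements
    h_idx = np.flatnonzero(elements == "H")
    x_idx = np.flatnonzero(np.isin(elements, sorted(rule.donor_elements)))
    pairs: list[tuple[int, int]] = []
    if h_idx.size == 0 or x_idx.size == 0:
        return pairs
    d = np.linalg.norm(
        s.coords[h_idx][:, None, :] - s.coords[x_idx][None, :, :], axis=2
    )
    for row, h in enumerate(h_idx):
        within = np.flatnonzero(d[row] <= rule.max_bond)
        if within.size == 0:
            continue
        dists = d[row][within]
        best = np.argmin(dists)
        tie = np.flatnonzero(np.abs(dists - dists[best]) < 1e-6)
        if tie.size > 1:
            raise ValueError(
                f"hydrogen {int(h)} equidistant to multiple donor candidates"
            )
        pairs.append((int(x_idx[within[best]]), int(h)))
    return sorted(pairs)


@dataclass
class DeuterationResult:
    """Transformed structure plus the constraint list for downstream
    engines.  Each constrained bond length equals (1 - fraction) times the
    original; heavy-atom positions are untouched."""

    structure: Structure
    constrained_bonds: list[tuple[int, int, float]]
    fraction: float

    def constraints_dataframe(self) -> pd.DataFrame:
        """Engine-agnostic constraint table with 1-based atom serials."""
        return pd.DataFrame(
            [
                {"serial1": x + 1, "serial2": h + 1, "length_A": round(l, 6)}
                for x, h, l in self.constrained_bonds
            ]
        )

    def write_constraints(self, path: str | Path) -> None:
        self.constraints_dataframe().to_csv(path, sep="\t", index=False)


def apply_deuteration(
    s: Structure,
    bonds: Sequence[tuple[int, int]],
    fraction: float = DEFAULT_FRACTION,
) -> DeuterationResult:
    """Contract each X-H bond by ``fraction`` along the X→H direction.

    The hydrogen is moved so that |X-H|_new = (1 - fraction)·|X-H|_old;
    all other atoms, and in particular every heavy atom, are bit-identical
    to the input.  Applying fractions f1 then f2 composes to a single
    application of 1 - (1-f1)(1-f2).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    out = s.copy()
    constrained: list[tuple[int, int, float]] = []
    for x, h in bonds:
        v = s.coords[h] - s.coords[x]
        length = float(np.linalg.norm(v))
        if length < 1e-9:
            raise GeometryError(f"zero-length bond between atoms {x} and {h}")
        new_len = (1.0 - fraction) * length
        out.coords[h] = s.coords[x] + (1.0 - fraction) * v
        constrained.append((int(x), int(h), new_len))
    return DeuterationResult(out, constrained, fraction)


# ---------------------------------------------------------------------------
# cluster / shell extraction


def _ligand_residue_keys(s: Structure) -> set[tuple[int, str, str]]:
    """Residues that are neither standard amino acids nor waters."""
    return {
        (a.res_number, a.res_name, a.chain)
        for a in s.atoms
        if a.res_name not in AMINO_ACIDS and a.res_name not in WATER_NAMES
    }


def extract_cluster(
    complex_structure: Structure, ranges: Sequence[tuple[int, int]]
) -> Structure:
    """Retain the residues whose numbers fall in any (first, last) range,
    plus any ligand residue (a residue that is neither a standard amino
    acid nor a water).  Coordinates and atom order are preserved; the
    operation is idempotent for fixed ranges."""
    if not ranges:
        raise ValueError("at least one residue range is required")
    ligand_keys = _ligand_residue_keys(complex_structure)
    keep = []
    kept_receptor = False
    for i, a in enumerate(complex_structure.atoms):
        key = (a.res_number, a.res_name, a.chain)
        if key in ligand_keys:
            keep.append(i)
            continue
        if any(lo <= a.res_number <= hi for lo, hi in ranges):
            keep.append(i)
            kept_receptor = True
    if not kept_receptor:
        raise ValueError(f"no residues fall in ranges {list(ranges)}")
    return complex_structure.subset(keep)


@dataclass(frozen=True)
class ShellSelectionSpec:
    """Water-shell selection: keep the nearest ``n_waters`` whole water
    molecules whose oxygen lies within ``cutoff`` Å of a solute heavy
    atom."""

    n_waters: int = 36
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.n_waters < 0:
            raise ValueError("n_waters must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ShellResult:
    structure: Structure
    water_res_numbers: list[int]
    water_distances: list[float]
    truncated: bool  # fewer waters within the cutoff than requested


def select_water_shell(
    s: Structure,
    spec: ShellSelectionSpec | None = None,
    solute_indices: Sequence[int] | None = None,
) -> ShellResult:
    """Nearest-n water-shell extraction around a solute.

    Waters (residue name HOH/WAT/...) are ranked by the minimum distance
    from their oxygen to any solute heavy atom; ties at the n-th rank keep
    the lower residue number.  The returned structure contains the solute
    plus the selected waters as whole molecules, original coordinates and
    order preserved.  When fewer than n waters lie within the cutoff, all
    available ones are returned with ``truncated=True`` and a warning.
    """
    spec = spec or ShellSelectionSpec()
    water_atoms = [
        i for i, a in enumerate(s.atoms) if a.res_name in WATER_NAMES
    ]
    if not water_atoms:
        raise ValueError("structure contains no water residues")
    water_keys = sorted(
        {(s.atoms[i].res_number, s.atoms[i].chain) for i in water_atoms}
    )
    if solute_indices is None:
        solute_indices = [
            i for i in range(s.n_atoms) if s.atoms[i].res_name not in WATER_NAMES
        ]
    solute_heavy = [
        i for i in solute_indices if s.atoms[i].element != "H"
    ]
    if not solute_heavy:
        raise ValueError("solute selection has no heavy atoms")
    solute_pts = s.coords[solute_heavy]

    ranked: list[tuple[float, int, tuple[int, str]]] = []
    for num, chain in water_keys:
        o_idx = [
            i
            for i in water_atoms
            if s.atoms[i].res_number == num
            and s.atoms[i].chain == chain
            and s.atoms[i].element == "O"
        ]
        if not o_idx:
            continue
        dmin = min(
            float(np.min(np.linalg.norm(solute_pts - s.coords[o], axis=1)))
            for o in o_idx
        )
        ranked.append((dmin, num, (num, chain)))
    ranked.sort(key=lambda t: (t[0], t[1]))
    in_cut = [r for r in ranked if r[0] <= spec.cutoff]
    selected = in_cut[: spec.n_waters]
    truncated = len(selected) < spec.n_waters
    if truncated:
        warnings.warn(
            f"only {len(selected)} waters within {spec.cutoff} Å "
            f"(requested {spec.n_waters})",
            stacklevel=2,
        )
    selected_keys = {key for _, _, key in selected}
    keep = [
        i
        for i in range(s.n_atoms)
        if (s.atoms[i].res_name not in WATER_NAMES and i in set(solute_indices))
        or (s.atoms[i].res_name in WATER_NAMES
            and (s.atoms[i].res_number, s.atoms[i].chain) in selected_keys)
    ]
    return ShellResult(
        structure=s.subset(keep),
        water_res_numbers=[num for _, num, _ in selected],
        water_distances=[d for d, _, _ in selected],
        truncated=truncated,
    )
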