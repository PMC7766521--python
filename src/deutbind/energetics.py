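"""Thermodynamic bookkeeping for the H/D binding cycle, affinity-unit
conversions, protonation speciation, and per-residue free-energy
decomposition filtering.

The cycle separates the deuteration-induced affinity change into a
hydration term (cost of leaving the solvent) and a receptor-interaction
term (gain on entering the binding site):

    ΔE_BIND = ΔE_INTER − ΔE_HYDR            (per isotope state)
    ΔΔE_X   = ΔE_X(D) − ΔE_X(H)             (D-minus-H differences)
    ΔΔE_BIND = ΔΔE_INTER − ΔΔE_HYDR         (algebraic identity)

A negative ΔΔE_BIND means the deuterated ligand binds more strongly.
Energies are carried at full precision and rounded only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Relative permittivity conventions for the three environments.
DIELECTRIC = {"aqueous": 78.4, "receptor": 4.0, "gas": 1.0}


@dataclass(frozen=True)
class AffinityParams:
    """Temperature and gas constant for free-energy conversions.
    Defaults give RT·ln10 = 1.3643 kcal/mol per log unit at 298.15 K."""

    temperature: float = 298.15          # K
    gas_constant: float = 1.98720425e-3  # kcal/(mol·K)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_ln10(self) -> float:
        return self.gas_constant * self.temperature * math.log(10.0)


@dataclass(frozen=True)
class EnergyRecord:
    """A component electronic energy from an external engine."""

    species: str
    environment: str  # aqueous | receptor | gas
    isotope: str      # H | D
    energy: float     # kcal/mol

    def __post_init__(self) -> None:
        if self.environment not in DIELECTRIC:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.isotope not in {"H", "D"}:
            raise ValueError("isotope must be 'H' or 'D'")
        if not math.isfinite(self.energy):
            raise ValueError("energy must be finite")

    @property
    def dielectric(self) -> float:
        return DIELECTRIC[self.environment]


def complexation_energy(e_complex: float, e_part_a: float, e_part_b: float) -> float:
    """Supermolecule association energy E(AB) − E(A) − E(B), kcal/mol.

    Both cycle legs are instances: hydration is ligand + water cluster →
    hydrated complex; interaction is ligand + binding-site cluster →
    bound complex.
    """
    for v in (e_complex, e_part_a, e_part_b):
        if not math.isfinite(v):
            raise ValueError("energies must be finite")
    return e_complex - e_part_a - e_part_b


@dataclass(frozen=True)
class CycleResult:
    """All legs and differences of the H/D binding cycle (kcal/mol)."""

    dE_hydr_H: float
    dE_hydr_D: float
    dE_inter_H: float
    dE_inter_D: float
    dE_bind_H: float
    dE_bind_D: float
    ddE_hydr: float
    ddE_inter: float
    ddE_bind: float

    def to_dataframe(self) -> pd.DataFrame:
        """One-row report mirroring the cycle table column order."""
        return pd.DataFrame(
            [
                {
                    "dE_hydr_H": round(self.dE_hydr_H, 2),
                    "dE_inter_H": round(self.dE_inter_H, 2),
                    "dE_bind_H": round(self.dE_bind_H, 2),
                    "dE_hydr_D": round(self.dE_hydr_D, 2),
                    "dE_inter_D": round(self.dE_inter_D, 2),
                    "dE_bind_D": round(self.dE_bind_D, 2),
                    "ddE_bind": round(self.ddE_bind, 2),
                }
            ]
        )


def assemble_cycle(
    hydration: dict[str, float], interaction: dict[str, float]
) -> CycleResult:
    """Build the full cycle from the four component energies.

    ``hydration`` and ``interaction`` map isotope state ("H"/"D") to
    ΔE_HYDR and ΔE_INTER in kcal/mol.  A missing component raises an error
    naming it.  Differences are D-minus-H, so a negative ddE_bind means
    deuteration strengthens binding.
    """
    for name, d in (("hydration", hydration), ("interaction", interaction)):
        for iso in ("H", "D"):
            if iso not in d:
                raise ValueError(f"missing {name} energy for isotope {iso!r}")
    bind = {iso: interaction[iso] - hydration[iso] for iso in ("H", "D")}
    return CycleResult(
        dE_hydr_H=hydration["H"],
        dE_hydr_D=hydration["D"],
        dE_inter_H=interaction["H"],
        dE_inter_D=interaction["D"],
        dE_bind_H=bind["H"],
        dE_bind_D=bind["D"],
        ddE_hydr=hydration["D"] - hydration["H"],
        ddE_inter=interaction["D"] - interaction["H"],
        ddE_bind=bind["D"] - bind["H"],
    )


def dg_from_pki(pki: float, params: AffinityParams | None = None) -> float:
    """Binding free energy from a pKi: ΔG = −RT·ln(10)·pKi, kcal/mol."""
    params = params or AffinityParams()
    return -params.rt_ln10 * pki


def ddg_from_pic50(
    pic50_control: float, pic50_treated: float, params: AffinityParams | None = None
) -> float:
    """Relative binding free-energy change from a pIC50 shift.

    The relative form of the Cheng-Prusoff relation:
    ΔΔG = −RT·ln(10)·(p2 − p1), so an affinity increase (p2 > p1) gives a
    negative ΔΔG.
    """
    params = params or AffinityParams()
    return -params.rt_ln10 * (pic50_treated - pic50_control)


def monocation_fraction(ph: float, pka_ring: float, pka_amine: float) -> float:
    """Fraction of the monocation (amine protonated, ring neutral) under an
    independent-site protonation model:

        f = 1/(1 + 10^(pH − pKa_amine)) · 1/(1 + 10^(pKa_ring − pH))

    For a histamine-like diamine with pKa 6.0 (ring) and 9.7 (amine) this
    gives 0.957 at physiological pH 7.4.
    """
    amine_protonated = 1.0 / (1.0 + 10.0 ** (ph - pka_amine))
    ring_neutral = 1.0 / (1.0 + 10.0 ** (pka_ring - ph))
    return amine_protonated * ring_neutral


# ---------------------------------------------------------------------------
# per-residue decomposition


@dataclass
class DecompositionTable:
    """Per-residue free-energy contributions plus the total binding free
    energy.  Thresholds default to the reporting convention of listing
    favorable contributions at or below −0.06 kcal/mol and unfavorable
    ones at or above +0.02 kcal/mol."""

    table: pd.DataFrame  # columns: residue, contribution
    total: float         # ΔG_BIND, kcal/mol
    favorable_threshold: float = -0.06
    unfavorable_threshold: float = 0.02

    def __post_init__(self) -> None:
        if not (self.favorable_threshold < 0.0 < self.unfavorable_threshold):
            raise ValueError("thresholds must straddle zero")
        missing = {"residue", "contribution"} - set(self.table.columns)
        if missing:
            raise ValueError(f"decomposition table lacks columns {missing}")


@dataclass
class DecompositionFilterResult:
    favorable: pd.DataFrame    # residue, contribution, percent_of_total
    unfavorable: pd.DataFrame
    n_favorable: int
    n_unfavorable: int


def decompose_filter(t: DecompositionTable) -> DecompositionFilterResult:
    """Partition residues by contribution sign and magnitude.

    Favorable rows have contribution ≤ favorable_threshold; unfavorable
    rows have contribution ≥ unfavorable_threshold (both inclusive — the
    thresholds themselves appear in real tables).  Percentages are
    100·contribution/total and require a non-zero total.  Rows are sorted
    by contribution (most favorable first within the favorable set).
    """
    df = t.table.copy()
    if len(df) and t.total == 0:
        raise ValueError("total binding energy is zero; percentages undefined")
    if len(df):
        df["percent_of_total"] = 100.0 * df["contribution"] / t.total
    else:
        df["percent_of_total"] = pd.Series(dtype=float)
    fav = df[df["contribution"] <= t.favorable_threshold].sort_values(
        "contribution", kind="stable"
    ).reset_index(drop=True)
    unfav = df[df["contribution"] >= t.unfavorable_threshold].sort_values(
        "contribution", kind="stable"
    ).reset_index(drop=True)
    return DecompositionFilterResult(fav, unfav, len(fav), len(unfav))


# ---------------------------------------------------------------------------
# delimited-text loaders (bundled reference tables)


def _data_path(name: str) -> Path:
    return Path(resources.files("deutbind").joinpath("data", name))


def load_decomposition(path: str | Path | None = None) -> DecompositionTable:
    """Read a per-residue decomposition TSV (columns residue,
    contribution_kcal_mol; a ``# total_dg_bind_kcal_mol=`` comment carries
    the total).  With no path, the bundled published-table mirror is
    loaded."""
    p = Path(path) if path is not None else _data_path("table1_decomposition.tsv")
    total = None
    for line in p.read_text().splitlines():
        if line.startswith("#") and "total_dg_bind_kcal_mol" in line:
            total = float(line.split("=")[1])
    if total is None:
        raise ValueError(f"{p}: no '# total_dg_bind_kcal_mol=' header")
    df = pd.read_csv(p, sep="\t", comment="#")
    df = df.rename(columns={"contribution_kcal_mol": "contribution"})
    return DecompositionTable(df[["residue", "contribution"]], total)


def load_cycle_components(
    path: str | Path | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Read cycle component energies (columns quantity, isotope,
    energy_kcal_mol; quantity ∈ {hydration, interaction}) and return the
    (hydration, interaction) isotope maps."""
    p = Path(path) if path is not None else _data_path("table2_components.tsv")
    df = pd.read_csv(p, sep="\t", comment="#")
    hydration: dict[str, float] = {}
    interaction: dict[str, float] = {}
    for _, row in df.iterrows():
        q = str(row["quantity"]).strip().lower()
        iso = str(row["isotope"]).strip()
        if q == "hydration":
            hydration[iso] = float(row["energy_kcal_mol"])
        elif q == "interaction":
            interaction[iso] = float(row["energy_kcal_mol"])
        else:
            raise ValueError(f"unknown quantity {q!r} in {p}")
    return hydration, interaction
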