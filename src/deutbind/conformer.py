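"""Per-frame gauche/trans conformer classification, state-population
estimation with Wilson intervals, and k-medoids clustering of the
(|torsion|, N1-N2 distance) feature plane.

The two conformers of a histamine-like monocation are told apart by the
side-chain torsion: gauche (folded, |φ| near 60°, permitting the
intramolecular N2-H···N1 contact) versus trans (extended, |φ| near 180°).
Classification uses |φ| only — it is a pure function of internal
coordinates — with an explicit intermediate band between the two
thresholds rather than a forced binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import circstd
from statsmodels.stats.proportion import proportion_confint

from .core import Structure, Trajectory, dihedral, distance, covalent_hydrogen_pairs
from .hydration import HBondCriteria

LABELS = ("gauche", "intermediate", "trans")


@dataclass(frozen=True)
class ConformerThresholds:
    """|torsion| bands: gauche at or below ``gauche_max_abs_torsion``,
    trans at or above ``trans_min_abs_torsion``, intermediate between.
    ``hbond_flag_distance`` is the N1-N2 cutoff for flagging a possible
    intramolecular hydrogen bond."""

    gauche_max_abs_torsion: float = 90.0
    trans_min_abs_torsion: float = 120.0
    hbond_flag_distance: float = 3.5

    def __post_init__(self) -> None:
        if not self.gauche_max_abs_torsion < self.trans_min_abs_torsion:
            raise ValueError("gauche_max must be below trans_min")


def classify_conformer(
    d_n1n2: float, torsion: float, thresholds: ConformerThresholds | None = None
) -> str:
    """Label a single geometry as gauche / trans / intermediate.

    A pure function of the N1-N2 distance (Å, must be positive) and the
    side-chain torsion (degrees, sign ignored).
    """
    t = thresholds or ConformerThresholds()
    if d_n1n2 <= 0:
        raise ValueError("N1-N2 distance must be positive")
    a = abs(torsion)
    if a <= t.gauche_max_abs_torsion:
        return "gauche"
    if a >= t.trans_min_abs_torsion:
        return "trans"
    return "intermediate"


@dataclass
class ConformerSeries:
    """Per-frame conformer record over a trajectory."""

    labels: np.ndarray          # object array of LABELS entries
    abs_torsion: np.ndarray     # degrees
    distance: np.ndarray        # N1-N2, Å
    hbond_flag: np.ndarray      # bool: plausible intramolecular N2-H···N1

    def __len__(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.labels)),
                "label": self.labels,
                "abs_torsion_deg": self.abs_torsion,
                "d_n1n2_A": self.distance,
                "intramolecular_hbond": self.hbond_flag,
            }
        )


def conformer_series(
    traj: Trajectory,
    n1: int | str = "N1",
    n2: int | str = "N2",
    torsion_atoms: tuple = ("C5", "CB", "CA", "N2"),
    thresholds: ConformerThresholds | None = None,
    hbond_criteria: HBondCriteria | None = None,
) -> ConformerSeries:
    """Classify every frame of a trajectory.

    Sites may be atom names (resolved on the topology) or indices.  The
    intramolecular-hydrogen-bond flag is true iff d(N1,N2) is at most the
    flag distance and some N2-H points at N1 within the hydrogen-bond
    angular criterion.
    """
    t = thresholds or ConformerThresholds()
    crit = hbond_criteria or HBondCriteria()
    topo = traj.topology

    def _resolve(x) -> int:
        return topo.index_of(x) if isinstance(x, str) else int(x)

    i_n1, i_n2 = _resolve(n1), _resolve(n2)
    quad = [_resolve(a) for a in torsion_atoms]
    n2_h = [h for x, h in covalent_hydrogen_pairs(topo) if x == i_n2]

    n = traj.n_frames
    labels = np.empty(n, dtype=object)
    tors = np.empty(n)
    dists = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    for f in range(n):
        c = traj.frames[f]
        phi = dihedral(c, *quad)
        d = distance(c, i_n1, i_n2)
        tors[f] = abs(phi)
        dists[f] = d
        labels[f] = classify_conformer(d, phi, t)
        if d <= t.hbond_flag_distance and n2_h:
            for h in n2_h:
                v1 = c[i_n2] - c[h]
                v2 = c[i_n1] - c[h]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom < 1e-12:
                    continue
                ang = math.degrees(
                    math.acos(float(np.clip(np.dot(v1, v2) / denom, -1, 1)))
                )
                if ang >= crit.min_dha_angle:
                    flags[f] = True
                    break
    return ConformerSeries(labels, tors, dists, flags)


@dataclass
class PopulationEstimate:
    """Label fractions with 95% Wilson confidence half-widths."""

    fractions: dict[str, float]
    ci_halfwidth: dict[str, float]
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.fractions),
                "fraction": list(self.fractions.values()),
                "ci95_halfwidth": [self.ci_halfwidth[l] for l in self.fractions],
            }
        )


def estimate_populations(series: ConformerSeries) -> PopulationEstimate:
    """Fractions (count/n) per label with Wilson 95% intervals.

    The Wilson interval is bounded in [0, 1] and behaves at the extremes,
    which matters for near-unanimous trajectories.
    """
    n = len(series)
    if n == 0:
        raise ValueError("empty conformer series")
    fractions, half = {}, {}
    for label in LABELS:
        k = int(np.sum(series.labels == label))
        fractions[label] = k / n
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        half[label] = (hi - lo) / 2.0
    return PopulationEstimate(fractions, half, n)


# ---------------------------------------------------------------------------
# k-medoids clustering


@dataclass
class ClusterResult:
    labels: np.ndarray
    medoid_indices: list[int]
    populations: list[float]


def _feature_distances(abs_torsion: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Pairwise distances on standardised (torsion-on-the-circle, d) pairs.

    Torsion separations use the angular metric (period 360°) scaled by the
    circular standard deviation of the sample; distances are z-scored.
    """
    phi = np.asarray(abs_torsion, dtype=float)
    d = np.asarray(dist, dtype=float)
    s_phi = float(circstd(np.radians(phi))) * 180.0 / math.pi
    s_d = float(np.std(d))
    s_phi = s_phi if s_phi > 1e-12 else 1.0
    s_d = s_d if s_d > 1e-12 else 1.0
    dphi = np.abs(phi[:, None] - phi[None, :])
    dphi = np.minimum(dphi, 360.0 - dphi) / s_phi
    dd = (d[:, None] - d[None, :]) / s_d
    return np.hypot(dphi, dd)


def cluster_conformers(
    abs_torsion: np.ndarray,
    dist: np.ndarray,
    k: int,
    seed: int = 0,
) -> ClusterResult:
    """k-medoids (PAM BUILD initialisation + Voronoi iteration) on the
    (|torsion|, d) feature plane.

    Medoids are actual frames (the frame minimising the summed in-cluster
    distance), which makes cluster representatives directly inspectable;
    ties are broken by the lowest frame index.  The procedure is
    deterministic: BUILD is greedy, so ``seed`` only labels the run.
    """
    phi = np.asarray(abs_torsion, dtype=float)
    d = np.asarray(dist, dtype=float)
    n = len(phi)
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= n_frames")
    distinct = len(set(zip(phi.tolist(), d.tolist())))
    if k > distinct:
        raise ValueError(f"k={k} exceeds the {distinct} distinct feature points")

    dm = _feature_distances(phi, d)
    # BUILD: first medoid minimises the total distance; later medoids
    # greedily maximise the decrease in assignment cost
    medoids = [int(np.argmin(dm.sum(axis=1)))]
    while len(medoids) < k:
        cur = dm[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - dm, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    for _ in range(100):
        assign = np.argmin(dm[:, medoids], axis=1)
        new_medoids = []
        for ci in range(k):
            members = np.flatnonzero(assign == ci)
            if members.size == 0:
                new_medoids.append(medoids[ci])
                continue
            costs = dm[np.ix_(members, members)].sum(axis=0)
            best = members[np.lexsort((members, costs))[0]]
            new_medoids.append(int(best))
        if new_medoids == medoids:
            break
        medoids = new_medoids

    assign = np.argmin(dm[:, medoids], axis=1)
    order = np.argsort(medoids)  # stable label order by frame index
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(a)] for a in assign])
    medoids_sorted = [medoids[i] for i in order]
    pops = [float(np.mean(labels == ci)) for ci in range(k)]
    return ClusterResult(labels, medoids_sorted, pops)
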