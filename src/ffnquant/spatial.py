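"""Spatial hotspot analysis across fields of view.

A sparsely innervated slice shows strikingly variable evoked transients
across ~50 x 50 um fields of view (FOVs), with occasional "hotspots" whose
AUC rivals densely innervated tissue. This module asks whether the
high-releasing FOVs cluster in space: FOVs are ranked by AUC into quartiles
and the pairwise-distance distribution of top-quartile pairs is compared to
that of all pairs, with a permutation test making the comparison assertable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FieldOfViewRecord",
    "SliceSession",
    "QuartilePairResult",
    "pairwise_distances",
    "quartile_pair_analysis",
    "hotspot_dispersion_test",
]


@dataclass
class FieldOfViewRecord:
    """Per-FOV summary row.

    Position is in micrometres along the slice-plane axes (the long and short
    axes of the imaged nucleus); depth is ignored since each FOV is a single
    imaging plane.
    """

    fov_id: str
    slice_id: str
    x_um: float
    y_um: float
    auc: float
    canny_sum: int | None = None
    initial_f: float | None = None
    region: str = "GPe"
    drug: str = "none"
    calcium_mM: float = 2.4
    frequency_hz: float = 10.0
    hemisphere: str = "left"
    is_hotspot: bool | None = None  # ground-truth label when simulated


@dataclass
class SliceSession:
    """All fields of view imaged within one slice."""

    slice_id: str
    region: str
    fovs: list[FieldOfViewRecord]
    extent_um: tuple[float, float] = (1000.0, 600.0)

    def __post_init__(self) -> None:
        if len(self.fovs) < 1:
            raise ValueError("a session needs at least one field of view")
        ids = [f.fov_id for f in self.fovs]
        if len(set(ids)) != len(ids):
            raise ValueError("fov_ids within a session must be unique")

    def positions(self) -> np.ndarray:
        return np.array([[f.x_um, f.y_um] for f in self.fovs], dtype=float)

    def aucs(self) -> np.ndarray:
        return np.array([f.auc for f in self.fovs], dtype=float)

    def __len__(self) -> int:
        return len(self.fovs)


@dataclass
class QuartilePairResult:
    """Pair-distance distributions split by AUC quartile membership.

    ``quartile[i]`` is 0 (bottom) .. 3 (top) for the i-th FOV in session
    order. ``top_pair_distances`` holds distances between pairs whose members
    are both in the top quartile; similarly for the bottom quartile;
    ``all_pair_distances`` holds every unordered pair.
    """

    session: SliceSession
    quartile: np.ndarray
    top_pair_distances: np.ndarray
    bottom_pair_distances: np.ndarray
    all_pair_distances: np.ndarray


def pairwise_distances(session: SliceSession) -> list[tuple[str, str, float]]:
    """Euclidean distance for every unordered FOV pair, n*(n-1)/2 entries.

    Returns an empty list (with a warning) for a single-FOV session.
    """
    n = len(session)
    if n < 2:
        warnings.warn("fewer than 2 fields of view: no pairs", stacklevel=2)
        return []
    pos = session.positions()
    out = []
    d = squareform(pdist(pos))
    for i in range(n):
        for j in range(i + 1, n):
            out.append((session.fovs[i].fov_id, session.fovs[j].fov_id, float(d[i, j])))
    return out


def assign_quartiles(aucs: np.ndarray) -> np.ndarray:
    """Rank FOVs by AUC into four near-equal groups, 0 = bottom, 3 = top.

    Ties are broken by stable input order. When n is not divisible by 4 the
    larger groups are the lower quartiles.
    """
    aucs = np.asarray(aucs, dtype=float)
    n = aucs.size
    order = np.argsort(aucs, kind="stable")  # ascending; stable tiebreak
    base, rem = divmod(n, 4)
    sizes = [base + 1 if q < rem else base for q in range(4)]  # bottom first
    quartile = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes):
        quartile[order[start : start + size]] = q
        start += size
    return quartile


def quartile_pair_analysis(session: SliceSession) -> QuartilePairResult:
    """Split pairwise distances by shared top / bottom AUC quartile."""
    n = len(session)
    if n < 4:
        raise ValueError("quartile analysis needs at least 4 fields of view")
    quartile = assign_quartiles(session.aucs())
    d = squareform(pdist(session.positions()))
    iu = np.triu_indices(n, k=1)
    all_d = d[iu]
    top = quartile == 3
    bottom = quartile == 0
    top_d = d[iu][top[iu[0]] & top[iu[1]]]
    bottom_d = d[iu][bottom[iu[0]] & bottom[iu[1]]]
    return QuartilePairResult(session, quartile, top_d, bottom_d, all_d)


def hotspot_dispersion_test(
    result: QuartilePairResult,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for spatial clustering of high-AUC fields of view.

    The statistic is the median distance between top-quartile pairs. The null
    distribution is obtained by permuting AUC values across positions
    (equivalently, drawing the top-quartile set uniformly at random), and the
    one-sided p-value asks whether top-quartile FOVs are closer together than
    chance. Uses the add-one permutation p-value, so p >= 1/(B+1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if result.top_pair_distances.size < 1:
        raise ValueError("need at least one top-quartile pair")
    statistic = float(np.median(result.top_pair_distances))
    session = result.session
    n = len(session)
    k = int(np.count_nonzero(result.quartile == 3))
    d = squareform(pdist(session.positions()))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        sub = rng.choice(n, size=k, replace=False)
        dsub = d[np.ix_(sub, sub)]
        med = np.median(dsub[np.triu_indices(k, k=1)])
        if med <= statistic + 1e-12:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return statistic, float(p)
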