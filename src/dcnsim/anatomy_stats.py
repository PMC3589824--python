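"""Quantitative anatomy of medulla-axon patterns.

Operations mirror how DCN wiring is quantified from coordinate
profiles: distances between adjacent medulla axons along the D-V axis,
counts of abnormally close ("clustered") axon pairs, an agglomerative
division of the axon pattern into D-V regions with per-region
soma-per-axon ratios, soma-axon positional correlation, and
mean/SD/SEM summary blocks.  All operations accept measured or
simulated input alike; for simulated data the axon D-V position is the
winner soma's D-V coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from dcnsim.synthetic_cluster import SomaCloud

__all__ = [
    "AxonPattern",
    "RegionDivision",
    "interaxonal_distances",
    "detect_clustered_axons",
    "divide_into_regions",
    "soma_axon_ratio",
    "dv_correlation",
    "summarize",
    "SummaryBlock",
]


@dataclass(frozen=True)
class AxonPattern:
    """Sorted D-V positions (nad) of one cluster's medulla axons."""

    cluster_id: str
    dv_positions: np.ndarray
    source: str = "simulated"

    def __post_init__(self) -> None:
        dv = np.sort(np.asarray(self.dv_positions, dtype=float))
        if not np.all(np.isfinite(dv)):
            raise ValueError("axon positions must be finite")
        if self.source not in ("measured", "simulated"):
            raise ValueError(f"unknown source {self.source!r}")
        dv.setflags(write=False)
        object.__setattr__(self, "dv_positions", dv)

    @property
    def axon_count(self) -> int:
        return len(self.dv_positions)


@dataclass(frozen=True)
class RegionDivision:
    """D-V regions from agglomerative grouping of axon positions.

    ``boundaries`` are the ``n_regions - 1`` cut points between
    adjacent groups; region *j* spans ``(boundaries[j-1], boundaries[j]]``
    (a position exactly on a boundary belongs to the lower region).
    """

    n_regions: int
    boundaries: np.ndarray
    axon_counts: np.ndarray
    groups: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        boundaries = np.asarray(self.boundaries, dtype=float)
        if len(boundaries) != self.n_regions - 1:
            raise ValueError("need n_regions - 1 boundaries")
        if np.any(np.diff(boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        counts = np.asarray(self.axon_counts, dtype=int)
        if len(counts) != self.n_regions:
            raise ValueError("need one axon count per region")
        boundaries.setflags(write=False)
        counts.setflags(write=False)
        object.__setattr__(self, "boundaries", boundaries)
        object.__setattr__(self, "axon_counts", counts)

    def assign(self, positions: np.ndarray) -> np.ndarray:
        """Region index per position; boundary ties go to the lower region."""
        return np.searchsorted(self.boundaries, np.asarray(positions, float), side="left")


def interaxonal_distances(pattern: AxonPattern) -> np.ndarray:
    """Distances between consecutive (sorted) axon D-V positions."""
    if pattern.axon_count < 2:
        warnings.warn(
            f"pattern {pattern.cluster_id!r} has {pattern.axon_count} axon(s); "
            "no interaxonal distances",
            stacklevel=2,
        )
        return np.array([])
    return np.diff(pattern.dv_positions)


def detect_clustered_axons(pattern: AxonPattern, cluster_threshold: float) -> int:
    """Number of adjacent axon pairs closer than ``cluster_threshold``.

    Reduced pair distances are the clustered-axon phenotype seen under
    loss of Notch function.
    """
    if cluster_threshold <= 0:
        raise ValueError("cluster_threshold must be > 0")
    dists = interaxonal_distances(pattern) if pattern.axon_count >= 2 else np.array([])
    return int(np.sum(dists < cluster_threshold))


def _agglomerate_1d(positions: np.ndarray, n_groups: int) -> list[list[float]]:
    """Greedy contiguous centroid-linkage agglomeration on sorted 1-D data.

    Start from singletons in sorted order and repeatedly merge the pair
    of adjacent groups whose centroids are closest, until ``n_groups``
    remain.  For 1-D data the closest-centroid pair is always adjacent
    in sorted order, so restricting merges to contiguous groups loses
    nothing and keeps the brute-force oracle in the tests feasible.
    Ties on centroid distance merge the lowest (leftmost) pair.
    """
    groups: list[list[float]] = [[float(x)] for x in np.sort(positions)]
    while len(groups) > n_groups:
        centroids = [float(np.mean(g)) for g in groups]
        gaps = np.diff(centroids)
        j = int(np.argmin(gaps))  # argmin takes the first of tied gaps
        groups[j] = groups[j] + groups[j + 1]
        del groups[j + 1]
    return groups


def divide_into_regions(pattern: AxonPattern, n_regions: int = 10) -> RegionDivision:
    """Group axon D-V positions into ``n_regions`` contiguous regions.

    Agglomerative centroid-linkage clustering of the 1-D positions;
    region sizes adapt to the axonal pattern.  Boundaries are placed at
    the midpoints between adjacent groups' extreme members.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if pattern.axon_count < n_regions:
        raise ValueError(
            f"need >= {n_regions} axons to form {n_regions} regions, "
            f"got {pattern.axon_count}"
        )
    groups = _agglomerate_1d(pattern.dv_positions, n_regions)
    boundaries = np.array(
        [(max(groups[j]) + min(groups[j + 1])) / 2.0 for j in range(len(groups) - 1)]
    )
    counts = np.array([len(g) for g in groups], dtype=int)
    return RegionDivision(
        n_regions=n_regions,
        boundaries=boundaries,
        axon_counts=counts,
        groups=tuple(tuple(g) for g in groups),
    )


def soma_axon_ratio(
    division: RegionDivision,
    cloud: SomaCloud,
    tolerance: float = 0.25,
) -> np.ndarray:
    """Per-region soma-per-axon ratios.

    The axon-derived division is projected onto the soma cluster: each
    soma is assigned to a region by its D-V coordinate, and
    ``ratio_j = soma_count_j / axon_count_j``.  Regions without axons
    get ``nan`` (cannot happen for divisions built by
    :func:`divide_into_regions`, which has >= 1 axon per group).
    Soma must lie within the division's D-V range, up to ``tolerance``
    in nad, otherwise the two inputs are on different scales and a
    ``ValueError`` is raised.
    """
    dv = cloud.points[:, 1]
    lo = min(division.groups[0]) if division.groups else division.boundaries[0]
    hi = max(division.groups[-1]) if division.groups else division.boundaries[-1]
    if dv.min() < lo - tolerance or dv.max() > hi + tolerance:
        raise ValueError(
            "soma D-V coordinates far outside the axon division range; "
            "are both inputs on the same normalized scale?"
        )
    soma_regions = division.assign(dv)
    soma_counts = np.bincount(soma_regions, minlength=division.n_regions)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(
            division.axon_counts > 0,
            soma_counts / np.maximum(division.axon_counts, 1),
            np.nan,
        )
    return ratios


def dv_correlation(soma_dv, axon_dv) -> float:
    """Pearson correlation between paired soma and axon D-V positions."""
    x = np.asarray(soma_dv, dtype=float)
    y = np.asarray(axon_dv, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("soma_dv and axon_dv must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in one input")
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass(frozen=True)
class SummaryBlock:
    """Mean +/- SD +/- SEM block, with a normality flag."""

    mean: float
    sd: float
    sem: float
    n: int
    normal: bool

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "sem": self.sem,
            "n": self.n,
            "normal": self.normal,
        }


def summarize(values, alpha: float = 0.05) -> SummaryBlock:
    """Sample mean, SD (n-1 denominator), SEM and a normality flag.

    Normality is assessed with the Shapiro-Wilk test at level ``alpha``
    (degenerate constant samples are flagged non-normal).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D sample of >= 2 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        normal = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.shapiro(x)
        normal = bool(p > alpha)
    return SummaryBlock(
        mean=float(np.mean(x)),
        sd=sd,
        sem=sd / np.sqrt(len(x)),
        n=len(x),
        normal=normal,
    )
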