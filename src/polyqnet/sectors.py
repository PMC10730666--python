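"""Angular-gap sector clustering of embedded nodes.

Nodes of a hyperbolically embedded network are sorted by their angular
(similarity) coordinate; the circular sequence of consecutive-angle gaps is
cut wherever a gap exceeds a threshold g, and each maximal uncut run forms a
sector.  The wrap-around gap (last angle back to the first) is a cuttable
gap like any other — the circle has no privileged origin.  A tuner recovers
the g that maximizes the number of sectors subject to every sector reaching
a minimum size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import TWO_PI, HyperbolicPoint

__all__ = [
    "GapParams",
    "Sector",
    "SectorPartition",
    "circular_gaps",
    "angular_gap_clusters",
    "tune_gap_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class GapParams:
    """Gap threshold g (radians) and minimum sector membership."""

    g: float
    min_size: int = 5

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError(f"gap threshold must be > 0, got {self.g}")
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")


@dataclass
class Sector:
    """One circularly contiguous run of nodes.

    ``members`` and ``thetas`` are aligned and ordered by increasing angle
    along the run (the run may wrap through 2pi, in which case angles wrap
    too).  ``theta_start``/``theta_end`` delimit the angular span
    [theta_start, theta_end); for a partition with a single sector the span
    is the full circle.
    """

    sector_id: int
    members: list
    thetas: list
    theta_start: float
    theta_end: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SectorPartition:
    """Ordered circular partition of nodes into angular sectors."""

    sectors: list = field(default_factory=list)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    @property
    def assignments(self) -> dict:
        return {
            node: s.sector_id for s in self.sectors for node in s.members
        }

    def __iter__(self):
        return iter(self.sectors)


def _theta_of(value) -> float:
    return value.theta if isinstance(value, HyperbolicPoint) else float(value) % TWO_PI


def circular_gaps(thetas) -> np.ndarray:
    """Gaps between consecutive sorted angles, including the wrap gap.

    For sorted angles t_(1) <= ... <= t_(n), returns
    [t_(2)-t_(1), ..., t_(n)-t_(n-1), 2pi - t_(n) + t_(1)]; the gaps sum to
    2pi.
    """
    t = np.sort(np.asarray(list(thetas), dtype=float) % TWO_PI)
    if len(t) < 2:
        raise ValueError(f"need at least 2 angles, got {len(t)}")
    gaps = np.empty(len(t))
    gaps[:-1] = np.diff(t)
    gaps[-1] = TWO_PI - t[-1] + t[0]
    return gaps


def angular_gap_clusters(
    coords: dict,
    params: GapParams,
    small_sector_policy: str = "keep",
) -> SectorPartition:
    """Partition nodes into sectors by cutting angular gaps larger than g.

    ``coords`` maps node -> HyperbolicPoint (or bare angle).  Nodes are
    sorted by (theta, node id); every gap strictly greater than ``params.g``
    is cut, and each maximal uncut circular run becomes a sector.  Note that
    a single cut merely opens the circle: sector count equals the number of
    cuts when there is at least one, else 1.

    Sectors smaller than ``params.min_size`` are handled per
    ``small_sector_policy``: "keep" (default; a warning is emitted) or
    "merge" (repeatedly join the smallest undersized sector with its
    neighbour across the smaller adjacent gap until all sectors reach
    min_size or one sector remains).  Sector ids are numbered 1..k by
    increasing theta_start, starting just after the largest cut gap.
    """
    if small_sector_policy not in {"keep", "merge"}:
        raise ValueError(f"unknown small-sector policy {small_sector_policy!r}")
    if not coords:
        raise ValueError("coords is empty")

    items = sorted(((_theta_of(v), str(k), k) for k, v in coords.items()))
    nodes = [k for _, _, k in items]
    thetas = np.array([t for t, _, _ in items])
    n = len(nodes)
    if n == 1:
        only = Sector(1, [nodes[0]], [float(thetas[0])], float(thetas[0]),
                      float(thetas[0]) + TWO_PI)
        return SectorPartition([only])

    gaps = np.empty(n)
    gaps[:-1] = np.diff(thetas)
    gaps[-1] = TWO_PI - thetas[-1] + thetas[0]
    # gaps[i] follows position i (gap between sorted node i and i+1 mod n)

    cut = np.flatnonzero(gaps > params.g)
    if len(cut) == 0:
        runs = [list(range(n))]
        anchor_gap = int(np.argmax(gaps))
    else:
        # runs start right after each cut, walking the circle
        cut_set = set(cut.tolist())
        runs = []
        starts = (cut + 1) % n
        order = np.argsort(thetas[starts])  # increasing theta_start
        for s_idx in order:
            start = int(starts[s_idx])
            run = []
            j = start
            while True:
                run.append(j)
                if j in cut_set:
                    break
                j = (j + 1) % n
            runs.append(run)
        # rotate numbering so sector 1 starts just after the largest cut gap
        largest = int(cut[np.argmax(gaps[cut])])
        first_start = (largest + 1) % n
        for pos, run in enumerate(runs):
            if run[0] == first_start:
                runs = runs[pos:] + runs[:pos]
                break

    partition = _runs_to_partition(runs, nodes, thetas, gaps)

    if small_sector_policy == "merge":
        partition = _merge_small(partition, gaps_between(partition), params.min_size)
    else:
        small = [s.sector_id for s in partition.sectors if s.size < params.min_size]
        if small:
            logger.warning(
                "%d sector(s) below min_size=%d kept as-is: %s",
                len(small), params.min_size, small,
            )
    return partition


def _runs_to_partition(runs, nodes, thetas, gaps) -> SectorPartition:
    sectors = []
    n = len(nodes)
    for sid, run in enumerate(runs, start=1):
        members = [nodes[j] for j in run]
        ths = [float(thetas[j]) for j in run]
        start = float(thetas[run[0]])
        end_gap = gaps[run[-1]]
        end = float(thetas[run[-1]]) + float(end_gap) if len(runs) > 1 else start + TWO_PI
        sectors.append(Sector(sid, members, ths, start, end))
    assert sum(s.size for s in sectors) == n
    return SectorPartition(sectors)


def gaps_between(partition: SectorPartition) -> list:
    """Angular gap following each sector (to the next sector clockwise)."""
    out = []
    ss = partition.sectors
    for i, s in enumerate(ss):
        nxt = ss[(i + 1) % len(ss)]
        gap = (nxt.thetas[0] - s.thetas[-1]) % TWO_PI
        out.append(gap)
    return out


def _merge_small(partition: SectorPartition, boundary_gaps: list, min_size: int) -> SectorPartition:
    sectors = [
        [list(s.members), list(s.thetas)] for s in partition.sectors
    ]
    gaps = list(boundary_gaps)  # gaps[i] follows sector i
    while len(sectors) > 1:
        sizes = [len(m) for m, _ in sectors]
        under = [i for i, sz in enumerate(sizes) if sz < min_size]
        if not under:
            break
        i = min(under, key=lambda j: (sizes[j], j))
        k = len(sectors)
        prev_gap = gaps[(i - 1) % k]
        next_gap = gaps[i]
        if prev_gap <= next_gap:  # merge into the previous sector
            j = (i - 1) % k
            sectors[j][0].extend(sectors[i][0])
            sectors[j][1].extend(sectors[i][1])
            gaps[j] = gaps[i]
            del sectors[i], gaps[i]
        else:  # merge into the next sector
            j = (i + 1) % k
            sectors[i][0].extend(sectors[j][0])
            sectors[i][1].extend(sectors[j][1])
            gaps[i] = gaps[j]
            del sectors[j], gaps[j]
    out = []
    for sid, (members, ths) in enumerate(sectors, start=1):
        start = ths[0]
        end = start + TWO_PI if len(sectors) == 1 else ths[-1]
        out.append(Sector(sid, members, ths, start, end))
    return SectorPartition(out)


def tune_gap_threshold(coords: dict, min_size: int = 5) -> float:
    """Find the g maximizing sector count with every sector >= min_size.

    Candidate thresholds are the observed gap values and values just below
    each of them (the cut rule is strictly >, so cutting a gap requires g
    slightly below it); the partition uses the "keep" policy.  Ties are
    broken toward the larger g.  Worst case returns the largest observed
    gap, which yields a single sector.
    """
    if len(coords) < min_size:
        raise ValueError(
            f"need at least min_size={min_size} nodes, got {len(coords)}"
        )
    thetas = [_theta_of(v) for v in coords.values()]
    observed = np.unique(circular_gaps(thetas))
    candidates = set(float(d) for d in observed if d > 0)
    candidates.update(float(np.nextafter(d, 0.0)) for d in observed if d > 0)
    best_g = float(observed.max())
    best_count = -1
    level = logger.level
    logger.setLevel(logging.ERROR)  # silence undersized-sector warnings while scanning
    try:
        for g in sorted(candidates):
            part = angular_gap_clusters(coords, GapParams(g=g, min_size=min_size))
            if all(s.size >= min_size for s in part.sectors):
                count = part.n_sectors
                if count > best_count or (count == best_count and g > best_g):
                    best_count, best_g = count, g
    finally:
        logger.setLevel(level)
    return best_g
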