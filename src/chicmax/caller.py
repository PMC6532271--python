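"""Interaction calling on virtual 4C profiles.

For each bait (captured promoter fragment) the cis read counts of its
other-end fragments form a "virtual 4C" profile against genomic position.
Chromatin loops appear as peaks over the distance-decay background, so calls
are made as local maxima of the loess-smoothed profile within sliding windows
of a fixed number of covered restriction fragments.  Spurious weak maxima are
then removed by a bait-specific filter: a maximum is kept only if its
smoothed signal strictly exceeds the geometric mean of raw read counts in the
corresponding genomic-separation bin.

The four tunable parameters are the maximum-calling window ``w`` (in covered
fragments), the loess span ``s``, the cis window ``c`` (bp), and the
geometric-mean bin width ``b`` (bp).  Defaults: w=20, s=0.05, c=1.5 Mb,
b=30 kb; w=50 is the documented stricter alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import (
    CALL_COLUMNS,
    INTERACTION_COLUMNS,
    FragmentMap,
    InteractionTable,
    interval_gap,
)

logger = logging.getLogger("chicmax")


@dataclass(frozen=True)
class CallerParams:
    """Tuning parameters of the local-maxima caller.

    w : maximum-calling window, in covered fragments (>= 3).
    s : loess span fraction (0 < s <= 1).
    c : cis window in bp; other ends farther than this from the bait
        are ignored.
    b : width in bp of the genomic-separation bins used for the
        geometric-mean filter.
    collapse_plateaus : keep only the most central fragment of each
        contiguous run of tied maxima.
    """

    w: int = 20
    s: float = 0.05
    c: int = 1_500_000
    b: int = 30_000
    collapse_plateaus: bool = False

    def __post_init__(self) -> None:
        if self.w < 3:
            raise ValueError(f"window w must be >= 3, got {self.w}")
        if not (0 < self.s <= 1):
            raise ValueError(f"span s must be in (0, 1], got {self.s}")
        if self.c <= 0 or self.b <= 0:
            raise ValueError("cis window c and bin width b must be positive")


@dataclass
class Virtual4CProfile:
    """Per-bait profile of covered cis other-end fragments, sorted by position.

    Only covered fragments (>= 1 read) appear; ``positions`` are fragment
    midpoints in bp, ``distances`` the interval gap to the bait (adjacent
    fragments have distance 0).  ``smoothed`` is filled by the caller.
    """

    bait_id: int
    bait_chrom: str
    bait_start: int
    bait_end: int
    bait_name: str
    oe_ids: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    positions: np.ndarray
    raw_counts: np.ndarray
    distances: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.oe_ids)
        for name in ("starts", "ends", "positions", "raw_counts", "distances"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch in {name}")
        if n > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.oe_ids)

    @property
    def empty(self) -> bool:
        return len(self) == 0


def build_virtual_4c(
    table: InteractionTable,
    bait_id: int,
    bait_ids: set[int],
    params: CallerParams,
) -> Virtual4CProfile:
    """Extract the virtual 4C profile of one bait from an interaction table.

    Keeps cis, non-bait, covered fragments within distance ``params.c`` of
    the bait, sorted by genomic position.  Returns an empty profile when no
    fragment qualifies (the dataset-level caller skips such baits).
    """
    sub = table.for_bait(bait_id)
    if len(sub) == 0:
        raise KeyError(f"bait {bait_id} not present in table")
    first = sub.iloc[0]
    bait_chrom = first["chr_Bait"]
    bait_start = int(first["start_Bait"])
    bait_end = int(first["end_Bait"])
    keep = (sub["chr_OE"] == bait_chrom) & ~sub["ID_OE"].isin(bait_ids)
    sub = sub[keep]
    oe_start = sub["start_OE"].to_numpy(np.int64)
    oe_end = sub["end_OE"].to_numpy(np.int64)
    dist = np.maximum(
        0, np.maximum(oe_start - bait_end, bait_start - oe_end)
    )
    within = dist <= params.c
    sub = sub[within]
    dist = dist[within]
    pos = 0.5 * (sub["start_OE"].to_numpy(np.int64) + sub["end_OE"].to_numpy(np.int64))
    order = np.argsort(pos, kind="stable")
    return Virtual4CProfile(
        bait_id=bait_id,
        bait_chrom=bait_chrom,
        bait_start=bait_start,
        bait_end=bait_end,
        bait_name=str(first["Bait_name"]),
        oe_ids=sub["ID_OE"].to_numpy(np.int64)[order],
        starts=sub["start_OE"].to_numpy(np.int64)[order],
        ends=sub["end_OE"].to_numpy(np.int64)[order],
        positions=pos[order],
        raw_counts=sub["N"].to_numpy(np.float64)[order],
        distances=dist[order],
    )


def min_profile_points(s: float, n: int) -> int:
    """Minimum covered fragments needed to smooth a profile of size n."""
    return max(3, math.ceil(s * n))


def loess_smooth(
    positions: np.ndarray, raw_counts: np.ndarray, s: float
) -> np.ndarray:
    """Loess-smooth a count profile against genomic position.

    Degree-1 locally weighted regression (tricube weights, no robustness
    iterations) with span fraction ``s``, evaluated at every input position.
    """
    positions = np.asarray(positions, dtype=np.float64)
    raw_counts = np.asarray(raw_counts, dtype=np.float64)
    n = len(positions)
    if n < min_profile_points(s, n):
        raise ValueError(
            f"profile of {n} points is too small to smooth at span {s}"
        )
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    # the local regression needs at least 3 points in each window
    frac = max(s, min(1.0, 3.0 / n))
    return lowess(
        raw_counts, positions, frac=frac, it=0, return_sorted=False
    )


def find_local_maxima(smoothed: np.ndarray, w: int) -> np.ndarray:
    """Indices that attain the maximum of their centred covered-fragment window.

    The window spans ``floor(w/2)`` covered fragments on each side, truncated
    at the profile edges.  Plateaus return every tied index.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if len(smoothed) == 0:
        return np.empty(0, dtype=np.int64)
    half = w // 2
    rolling_max = maximum_filter1d(
        smoothed, size=2 * half + 1, mode="constant", cval=-np.inf
    )
    return np.flatnonzero(smoothed == rolling_max).astype(np.int64)


@dataclass
class DistanceBinTable:
    """Geometric means of raw counts, stratified by bait distance bins.

    Bin ``k`` covers distances in ``[k*b, (k+1)*b)``; only bins containing at
    least one covered fragment have a geometric mean.
    """

    bin_width: int
    geomeans: dict[int, float] = field(default_factory=dict)

    def geomean_at(self, distance: int | float) -> float:
        return self.geomeans[int(distance // self.bin_width)]


def distance_bin_geomeans(
    profile: Virtual4CProfile, b: int
) -> DistanceBinTable:
    """Per-bin geometric mean exp(mean(log count)) of a profile's raw counts."""
    if profile.empty:
        raise ValueError("empty profile has no distance bins")
    bins = (profile.distances // b).astype(np.int64)
    logs = np.log(profile.raw_counts)
    table = DistanceBinTable(bin_width=int(b))
    for k in np.unique(bins):
        table.geomeans[int(k)] = float(np.exp(logs[bins == k].mean()))
    return table


def _collapse_plateaus(indices: np.ndarray) -> np.ndarray:
    """Keep the most central index of each contiguous run of tied maxima."""
    if len(indices) == 0:
        return indices
    runs = np.split(indices, np.flatnonzero(np.diff(indices) > 1) + 1)
    return np.array([run[len(run) // 2] for run in runs], dtype=np.int64)


def call_bait(
    profile: Virtual4CProfile, params: CallerParams
) -> pd.DataFrame:
    """Run the full caller on one bait profile.

    Smooths the profile, finds windowed local maxima, and keeps those whose
    smoothed signal strictly exceeds the geometric mean of raw counts in
    their genomic-separation bin.  Returns a called-interaction frame
    (canonical columns plus smoothed_value / bin_geomean / distance_to_bait);
    empty when nothing passes or the profile is too small to smooth.
    """
    empty = pd.DataFrame(columns=INTERACTION_COLUMNS + CALL_COLUMNS)
    n = len(profile)
    if n < min_profile_points(params.s, n):
        logger.warning(
            "bait %s (%d): %d covered fragments, too few to smooth; skipped",
            profile.bait_name, profile.bait_id, n,
        )
        return empty
    smoothed = loess_smooth(profile.positions, profile.raw_counts, params.s)
    profile.smoothed = smoothed
    maxima = find_local_maxima(smoothed, params.w)
    if params.collapse_plateaus:
        maxima = _collapse_plateaus(maxima)
    bins = distance_bin_geomeans(profile, params.b)
    rows = []
    for i in maxima:
        gm = bins.geomean_at(profile.distances[i])
        # strictly greater, with a relative epsilon so exact ties (e.g. a
        # constant profile, where smoothed == geomean) never pass on
        # floating-point noise
        if smoothed[i] > gm * (1.0 + 1e-12):
            rows.append((
                profile.bait_id, profile.bait_chrom, profile.bait_start,
                profile.bait_end, profile.bait_name,
                int(profile.oe_ids[i]), profile.bait_chrom,
                int(profile.starts[i]), int(profile.ends[i]),
                int(profile.raw_counts[i]),
                float(smoothed[i]), float(gm), int(profile.distances[i]),
            ))
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=INTERACTION_COLUMNS + CALL_COLUMNS)


def call_dataset(
    table: InteractionTable,
    bait_ids: set[int],
    params: CallerParams | None = None,
) -> InteractionTable:
    """Call interactions for every bait of a dataset.

    Baits are processed independently (one profile at a time, so memory is
    flat in the number of baits) in ascending bait-id order.
    """
    params = params or CallerParams()
    frames = []
    for bait_id in sorted(set(table.df["ID_Bait"].unique()) & set(bait_ids)):
        profile = build_virtual_4c(table, int(bait_id), bait_ids, params)
        if profile.empty:
            logger.warning(
                "bait %d: no qualifying cis fragments; skipped", bait_id
            )
            continue
        calls = call_bait(profile, params)
        if len(calls):
            frames.append(calls)
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=INTERACTION_COLUMNS + CALL_COLUMNS)
    return InteractionTable(df, label=table.label, provenance="called")
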