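"""Epigenomic enrichment and inter-method comparison of called interactions.

Fold enrichment of promoter-interacting regions for a ChIP-seq feature is the
proportion of called other-end fragments overlapping a feature peak divided
by the proportion of all mappable, non-bait restriction fragments overlapping
a peak.  "Mappable" defaults to every non-bait fragment covered by at least
one read in the raw dataset; an explicit fragment list overrides this.
Overlap is any-bp interval intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import FragmentMap, InteractionTable

logger = logging.getLogger("chicmax")


class PeakSet:
    """Sorted, merged genomic intervals (e.g. ChIP-seq peaks) per chromosome."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], np.int64)

    @classmethod
    def from_bed(cls, path) -> "PeakSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        return cls(df.itertuples(index=False, name=None))

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (c, int(s), int(e))
            for c in self.chromosomes
            for s, e in zip(self._starts[c], self._ends[c])
        ]

    def total_bases(self) -> int:
        return int(sum((self._ends[c] - self._starts[c]).sum()
                       for c in self._starts))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any-bp intersection with a half-open query interval."""
        if chrom not in self._starts:
            return False
        ends = self._ends[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(ends) and self._starts[chrom][i] < end

    def overlaps_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized :meth:`overlaps` over query interval arrays."""
        if chrom not in self._starts:
            return np.zeros(len(starts), dtype=bool)
        pe = self._ends[chrom]
        ps = self._starts[chrom]
        i = np.searchsorted(pe, starts, side="right")
        ok = i < len(pe)
        out = np.zeros(len(starts), dtype=bool)
        out[ok] = ps[i[ok]] < ends[ok]
        return out


@dataclass
class EnrichmentResult:
    """Fold enrichment of a call set for one epigenomic feature."""

    feature: str
    n_interactions: int
    n_overlapping: int
    interaction_proportion: float
    background_proportion: float
    fold_enrichment: float


def _fragment_overlap_flags(
    frag_ids: Iterable[int], peaks: PeakSet, fmap: FragmentMap
) -> np.ndarray:
    frags = [fmap.by_id(i) for i in frag_ids]
    flags = np.zeros(len(frags), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for idx, f in enumerate(frags):
        by_chrom.setdefault(f.chrom, []).append(idx)
    for chrom, idxs in by_chrom.items():
        starts = np.array([frags[i].start for i in idxs], np.int64)
        ends = np.array([frags[i].end for i in idxs], np.int64)
        flags[np.array(idxs)] = peaks.overlaps_many(chrom, starts, ends)
    return flags


def fold_enrichment(
    calls: InteractionTable,
    peaks: PeakSet,
    fmap: FragmentMap,
    bait_ids: set[int],
    mappable_ids: set[int],
    feature: str = "feature",
    per_interaction: bool = False,
) -> EnrichmentResult:
    """Fold enrichment of called other-ends for a peak set over background.

    Background is the proportion of mappable non-bait fragments overlapping a
    peak.  By default each distinct other-end fragment in the call set is
    counted once even if it partners several baits; ``per_interaction``
    counts every call row instead.
    """
    background_ids = sorted(set(mappable_ids) - set(bait_ids))
    if not background_ids:
        raise ValueError("no mappable non-bait fragments for background")
    bg_flags = _fragment_overlap_flags(background_ids, peaks, fmap)
    bg_prop = float(bg_flags.mean())
    if bg_prop == 0:
        raise ValueError(
            "background proportion is zero; fold enrichment undefined"
        )
    if per_interaction:
        oe_ids = calls.df["ID_OE"].tolist()
    else:
        oe_ids = sorted(calls.df["ID_OE"].unique())
    if not oe_ids:
        raise ValueError("empty call set")
    call_flags = _fragment_overlap_flags(oe_ids, peaks, fmap)
    prop = float(call_flags.mean())
    return EnrichmentResult(
        feature=feature,
        n_interactions=len(oe_ids),
        n_overlapping=int(call_flags.sum()),
        interaction_proportion=prop,
        background_proportion=bg_prop,
        fold_enrichment=prop / bg_prop,
    )


def assign_enhancers(
    calls: InteractionTable, enhancers: PeakSet, fmap: FragmentMap
) -> tuple[float, float]:
    """Enhancer assignment bookkeeping for a call set.

    Returns ``(fraction of enhancers overlapping >= 1 called other-end,
    total calls / calls overlapping >= 1 enhancer)``; the ratio is ``inf``
    when no call touches an enhancer.
    """
    iv = enhancers.intervals()
    if not iv:
        raise ValueError("empty enhancer set")
    oe_ids = sorted(calls.df["ID_OE"].unique())
    oe_frags = [fmap.by_id(i) for i in oe_ids]
    call_peaks = PeakSet((f.chrom, f.start, f.end) for f in oe_frags)
    assigned = sum(
        1 for chrom, s, e in iv if call_peaks.overlaps(chrom, s, e)
    )
    fraction = assigned / len(iv)
    call_flags = _fragment_overlap_flags(oe_ids, enhancers, fmap)
    # ratio is over call rows, mapped through their other-end fragment
    flag_of = dict(zip(oe_ids, call_flags))
    n_calls = len(calls.df)
    n_with = int(sum(flag_of[i] for i in calls.df["ID_OE"]))
    ratio = float("inf") if n_with == 0 else n_calls / n_with
    return fraction, ratio


class CallSetPartition(NamedTuple):
    both_a: pd.DataFrame
    both_b: pd.DataFrame
    a_only: pd.DataFrame
    b_only: pd.DataFrame


def intersect_call_sets(
    set_a: InteractionTable,
    set_b: InteractionTable,
    mode: str = "overlap",
) -> CallSetPartition:
    """Partition two call sets into shared and method-specific interactions.

    ``exact`` matches on identical (Bait_name, ID_OE); ``overlap`` matches
    interactions of the same bait whose non-bait intervals intersect by any
    bp.  Returns the matched rows of each set and the unmatched remainders
    (counts are symmetric and suitable for Venn reporting).
    """
    a, b = set_a.df, set_b.df
    if mode == "exact":
        keys_b = set(zip(b["Bait_name"], b["ID_OE"]))
        keys_a = set(zip(a["Bait_name"], a["ID_OE"]))
        in_b = a.apply(lambda r: (r["Bait_name"], r["ID_OE"]) in keys_b, axis=1)
        in_a = b.apply(lambda r: (r["Bait_name"], r["ID_OE"]) in keys_a, axis=1)
    elif mode == "overlap":
        def matched(df_q, df_s):
            groups = {k: g for k, g in df_s.groupby("Bait_name")}
            flags = []
            for _, r in df_q.iterrows():
                g = groups.get(r["Bait_name"])
                if g is None:
                    flags.append(False)
                    continue
                hit = (
                    (g["start_OE"].to_numpy() < r["end_OE"])
                    & (g["end_OE"].to_numpy() > r["start_OE"])
                    & (g["chr_OE"].to_numpy() == r["chr_OE"])
                )
                flags.append(bool(hit.any()))
            return pd.Series(flags, index=df_q.index)

        in_b = matched(a, b)
        in_a = matched(b, a)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(a) == 0:
        in_b = pd.Series(dtype=bool, index=a.index)
    if len(b) == 0:
        in_a = pd.Series(dtype=bool, index=b.index)
    return CallSetPartition(
        both_a=a[in_b].reset_index(drop=True),
        both_b=b[in_a].reset_index(drop=True),
        a_only=a[~in_b].reset_index(drop=True),
        b_only=b[~in_a].reset_index(drop=True),
    )


def rank_score_test(
    scores_conserved: np.ndarray, scores_specific: np.ndarray
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum comparison of interaction score columns.

    Generic wrapper for comparing scores (from any caller) of interactions
    conserved vs not conserved with another method.  Returns (statistic, p).
    """
    res = stats.mannwhitneyu(
        scores_conserved, scores_specific, alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)


def mappable_from_table(table: InteractionTable) -> set[int]:
    """Default mappability: fragments covered (>=1 read) in the raw dataset."""
    return set(table.df["ID_OE"].unique())
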