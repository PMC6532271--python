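"""Replicate reproducibility analysis and distance-tolerant merging.

Capture Hi-C undersamples the space of ligation products, so the "same" loop
often lands on a nearby — not identical — restriction fragment in another
biological replicate.  Two operations deal with this at fragment resolution:

* :func:`closest_distances` — per-bait distributions of the genomic distance
  from each called interaction in a query set to the nearest called
  interaction of the same bait in a subject set (to pick a merge threshold);
* :func:`merge_replicates` — keep a reference replicate's call only if every
  other replicate called an interaction for the same bait within ``d`` bp
  (default d = 20 kb).

The distance between two other-end fragments is the interval gap: identical,
overlapping, or directly contiguous fragments count as zero separation.
A midpoint-distance metric is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import InteractionTable, sort_interactions

logger = logging.getLogger("chicmax")

DEFAULT_REPDIST = 20_000


def _gap_matrix(
    q_start: np.ndarray, q_end: np.ndarray,
    s_start: np.ndarray, s_end: np.ndarray,
    metric: str,
) -> np.ndarray:
    """All-pairs distance between query and subject intervals."""
    if metric == "gap":
        return np.maximum(
            0,
            np.maximum(
                s_start[None, :] - q_end[:, None],
                q_start[:, None] - s_end[None, :],
            ),
        )
    if metric == "midpoint":
        qm = 0.5 * (q_start + q_end)
        sm = 0.5 * (s_start + s_end)
        return np.abs(qm[:, None] - sm[None, :])
    raise ValueError(f"unknown distance metric {metric!r}")


@dataclass
class ClosestDistanceDistribution:
    """Per-interaction nearest-neighbour distances between two call sets.

    ``records`` has one row per query interaction: bait name/id, query
    other-end interval, nearest subject other-end interval (id + coords),
    and the gap in bp; queries whose bait is absent from the subject set get
    NaN gaps and are excluded from summaries.
    """

    records: pd.DataFrame

    @property
    def gaps(self) -> np.ndarray:
        g = self.records["gap"].to_numpy(np.float64)
        return g[~np.isnan(g)]


def closest_distances(
    query: InteractionTable,
    subject: InteractionTable,
    metric: str = "gap",
) -> ClosestDistanceDistribution:
    """Distance from each query interaction to the nearest subject interaction.

    Call sets are split by bait; for each non-bait fragment of the query, the
    minimal distance to any subject other-end of the same bait is recorded.
    """
    sub_by_bait = {b: g for b, g in subject.df.groupby("ID_Bait")}
    rows = []
    for _, q in query.df.iterrows():
        s = sub_by_bait.get(q["ID_Bait"])
        if s is None or len(s) == 0:
            gap, nearest = np.nan, None
        else:
            d = _gap_matrix(
                np.array([q["start_OE"]]), np.array([q["end_OE"]]),
                s["start_OE"].to_numpy(np.int64),
                s["end_OE"].to_numpy(np.int64),
                metric,
            )[0]
            j = int(np.argmin(d))
            gap, nearest = float(d[j]), s.iloc[j]
        rows.append({
            "ID_Bait": q["ID_Bait"],
            "Bait_name": q["Bait_name"],
            "ID_OE": q["ID_OE"],
            "start_OE": q["start_OE"],
            "end_OE": q["end_OE"],
            "nearest_ID_OE": None if nearest is None else nearest["ID_OE"],
            "nearest_start_OE": None if nearest is None else nearest["start_OE"],
            "nearest_end_OE": None if nearest is None else nearest["end_OE"],
            "gap": gap,
        })
    return ClosestDistanceDistribution(pd.DataFrame(rows))


def repdist_summary(
    dist: ClosestDistanceDistribution,
    thresholds: tuple[int, ...] = (5_000, 10_000, 20_000, 50_000),
    hist_bin: int = 5_000,
    hist_max: int = 200_000,
) -> dict:
    """Summarise a closest-distance distribution.

    Returns the fraction of query interactions at exactly 0 bp, the fraction
    within each threshold, deciles, and a histogram table for plotting.
    """
    gaps = dist.gaps
    if len(gaps) == 0:
        raise ValueError("no query interactions with a shared bait")
    edges = np.arange(0, hist_max + hist_bin, hist_bin)
    counts, _ = np.histogram(np.minimum(gaps, hist_max - 1), bins=edges)
    hist = pd.DataFrame({
        "gap_lo": edges[:-1], "gap_hi": edges[1:], "count": counts,
    })
    return {
        "n": int(len(gaps)),
        "fraction_at_0": float(np.mean(gaps == 0)),
        **{
            f"fraction_le_{t}": float(np.mean(gaps <= t)) for t in thresholds
        },
        "deciles": {
            int(10 * q): float(np.quantile(gaps, q / 10))
            for q in range(11)
        },
        "histogram": hist,
    }


def merge_replicates(
    calls: list[InteractionTable],
    d: int = DEFAULT_REPDIST,
    metric: str = "gap",
    min_replicates: int | None = None,
) -> InteractionTable:
    """Keep reference calls reproduced within ``d`` bp in the other replicates.

    The first table is the reference; one of its calls is retained iff every
    other replicate contains, for the same bait, an interaction whose
    other-end lies within ``d`` bp (interval gap).  The output keeps the
    reference's coordinates and diagnostics and adds one ``partners_<label>``
    column per other replicate listing the matched other-end ids.

    ``min_replicates`` relaxes the all-replicates rule to "matched in at
    least k of the other replicates" (default: all).
    """
    if len(calls) < 2:
        raise ValueError("need at least two call sets to merge")
    if d < 0:
        raise ValueError("distance threshold d must be >= 0")
    ref = calls[0]
    others = calls[1:]
    need = len(others) if min_replicates is None else min_replicates
    partner_labels = [
        f"partners_{t.label or i + 2}" for i, t in enumerate(others)
    ]
    by_bait = [
        {b: g for b, g in t.df.groupby("ID_Bait")} for t in others
    ]
    keep_rows = []
    for _, q in ref.df.iterrows():
        matched = 0
        partners: list[str] = []
        for groups in by_bait:
            s = groups.get(q["ID_Bait"])
            ids = ""
            if s is not None and len(s):
                dmat = _gap_matrix(
                    np.array([q["start_OE"]]), np.array([q["end_OE"]]),
                    s["start_OE"].to_numpy(np.int64),
                    s["end_OE"].to_numpy(np.int64),
                    metric,
                )[0]
                hit = dmat <= d
                if hit.any():
                    matched += 1
                    ids = ",".join(
                        str(x) for x in s["ID_OE"].to_numpy()[hit]
                    )
            partners.append(ids)
        if matched >= need:
            row = q.to_dict()
            row.update(dict(zip(partner_labels, partners)))
            keep_rows.append(row)
    if keep_rows:
        df = pd.DataFrame(keep_rows)
    else:
        df = pd.DataFrame(columns=list(ref.df.columns) + partner_labels)
    df = sort_interactions(df) if len(df) else df
    logger.info(
        "merge_replicates: %d of %d reference calls retained at d=%d",
        len(df), len(ref.df), d,
    )
    return InteractionTable(df, label=ref.label, provenance="merged")
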