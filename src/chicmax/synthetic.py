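"""Seeded generators for synthetic Capture Hi-C inputs with planted truth.

The generator emulates the statistical structure the caller assumes:

* a contiguous restriction digest (fixed or lognormal fragment lengths;
  the default 500-bp fragments emulate a 4-cutter HiCap-style digest);
* bait-centric cis profiles whose expected read count decays with genomic
  separation as a power law, ``E[count] = depth * eff_bait * (d + eps)**-alpha``
  (background contacts are dominated by genomic distance);
* per-bait capture-efficiency multipliers (lognormal);
* overdispersed counts (negative binomial; Poisson optional), with
  zero-count pairs omitted so only covered fragments appear — matching real
  CHi-C sparsity;
* planted interaction peaks: contiguous runs of fragments whose expected
  count is multiplied by an amplitude, registered in a truth table;
* biological replicates as independent resamplings sharing the planted
  truth, optionally with each replicate's peak centre jittered to a nearby
  fragment.

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .caller import CallerParams, build_virtual_4c
from .epigenomics import PeakSet
from .io import (
    INTERACTION_COLUMNS,
    FragmentMap,
    InteractionTable,
    RestrictionFragment,
)

logger = logging.getLogger("chicmax")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic CHi-C experiment.

    Defaults describe a 4-cutter-style digest (500-bp fragments) with 50
    baits, distance-decay exponent alpha = 1 with a 5-kb offset, negative
    binomial counts with dispersion 0.2, and a sequencing-depth scale that
    leaves on the order of a thousand covered cis fragments per bait within
    the 1.5-Mb cis window — deep proximal coverage decaying to sparse
    single-read distal coverage, as in real promoter CHi-C.
    """

    seed: int = 0
    chrom: str = "chrS"
    n_baits: int = 50
    frag_length: int = 1000
    frag_length_sigma: float = 0.0   # lognormal sigma in log-space; 0 = fixed
    bait_spacing: int = 2000         # fragments between consecutive baits
    flank: int = 1600                # fragments before first / after last bait
    alpha: float = 1.0
    eps: float = 5_000.0
    depth_scale: float = 250_000.0
    capture_eff_sigma: float = 0.25  # lognormal spread of per-bait efficiency
    noise: str = "nb"                # 'nb' | 'poisson'
    dispersion: float = 0.2
    cis_window: int = 1_500_000
    peak_shape: str = "tri"          # 'tri' (smeared loop) | 'box'
    peaks: tuple = ()                # (bait_id, target_frag_id, amplitude, width)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("decay exponent alpha must be > 0")
        if self.noise not in ("nb", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        for _, _, amp, _ in self.peaks:
            if amp <= 1:
                raise ValueError("planted amplitudes must be > 1")


def simulate_fragment_map(spec: SyntheticSpec) -> FragmentMap:
    """Contiguous non-overlapping digest of one synthetic chromosome."""
    rng = np.random.default_rng(spec.seed)
    n = spec.flank * 2 + (spec.n_baits - 1) * spec.bait_spacing + 1
    if spec.frag_length_sigma > 0:
        mu = math.log(spec.frag_length) - 0.5 * spec.frag_length_sigma**2
        lengths = np.maximum(
            50, rng.lognormal(mu, spec.frag_length_sigma, size=n).astype(np.int64)
        )
    else:
        lengths = np.full(n, spec.frag_length, dtype=np.int64)
    ends = np.cumsum(lengths)
    starts = ends - lengths
    return FragmentMap(
        RestrictionFragment(spec.chrom, int(s), int(e), i)
        for i, (s, e) in enumerate(zip(starts, ends))
    )


def bait_ids_of(spec: SyntheticSpec) -> list[int]:
    """Fragment ids of the baits implied by the spec's regular spacing."""
    return [
        spec.flank + k * spec.bait_spacing for k in range(spec.n_baits)
    ]


def plant_random_peaks(
    spec: SyntheticSpec,
    fmap: FragmentMap,
    n_per_bait: int = 3,
    amplitude: float = 10.0,
    width: int = 8,
    min_dist: int = 60_000,
    max_dist: int = 250_000,
    min_separation: int = 70_000,
    seed: int | None = None,
) -> SyntheticSpec:
    """Return a spec with random peaks planted around every bait.

    Peaks are placed at genomic separations in ``[min_dist, max_dist]`` on
    either side of the bait — the range where regulatory loops typically sit
    and where profile coverage gives the caller adequate power — at least
    ``min_separation`` bp apart within a bait (well beyond the calling
    window in covered fragments).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frag_bp = spec.frag_length
    peaks: list[tuple[int, int, float, int]] = []
    for bait in bait_ids_of(spec):
        placed: list[int] = []
        attempts = 0
        while len(placed) < n_per_bait and attempts < 1000:
            attempts += 1
            dist = rng.integers(min_dist, max_dist + 1)
            side = 1 if rng.random() < 0.5 else -1
            target = bait + side * int(round(dist / frag_bp))
            if target not in fmap:
                continue
            if any(abs(target - p) * frag_bp < min_separation for p in placed):
                continue
            placed.append(target)
            peaks.append((bait, target, float(amplitude), int(width)))
    return replace(spec, peaks=tuple(peaks))


def _expected_counts(
    spec: SyntheticSpec,
    distances: np.ndarray,
    eff: float,
    peak_multiplier: np.ndarray,
) -> np.ndarray:
    decay = (distances + spec.eps) ** (-spec.alpha)
    return spec.depth_scale * eff * decay * peak_multiplier


def _draw_counts(
    spec: SyntheticSpec, mu: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if spec.noise == "poisson":
        return rng.poisson(mu)
    phi = spec.dispersion
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_dataset(
    spec: SyntheticSpec,
    fmap: FragmentMap,
    rng: np.random.Generator | None = None,
    peaks: tuple | None = None,
) -> tuple[InteractionTable, pd.DataFrame]:
    """Draw one CHi-C dataset and its planted-truth registry.

    Counts are drawn per (bait, cis fragment) pair around the distance-decay
    curve, multiplied by the amplitude across each planted peak's width, and
    zero-count pairs are dropped.  The truth table records one row per
    planted peak (bait id, target fragment id/coords, amplitude, width).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    peaks = spec.peaks if peaks is None else peaks
    baits = bait_ids_of(spec)
    bait_set = set(baits)
    effs = np.exp(rng.normal(0.0, spec.capture_eff_sigma, size=len(baits)))
    peaks_by_bait: dict[int, list[tuple[int, float, int]]] = {}
    for bait, target, amp, width in peaks:
        peaks_by_bait.setdefault(bait, []).append((target, amp, width))

    all_frags = fmap.fragments(spec.chrom)
    all_starts = np.array([f.start for f in all_frags], np.int64)
    all_ends = np.array([f.end for f in all_frags], np.int64)
    all_ids = np.array([f.frag_id for f in all_frags], np.int64)
    is_bait = np.isin(all_ids, list(bait_set))

    rows: list[pd.DataFrame] = []
    for bait, eff in zip(baits, effs):
        bf = fmap.by_id(bait)
        # cis candidates within the window: start <= bait_end + c and
        # end >= bait_start - c (fragments are position-sorted)
        lo = int(np.searchsorted(all_ends, bf.start - spec.cis_window, "right"))
        hi = int(np.searchsorted(all_starts, bf.end + spec.cis_window, "right"))
        sel = slice(lo, hi)
        keep = ~is_bait[sel]
        starts = all_starts[sel][keep]
        ends = all_ends[sel][keep]
        ids = all_ids[sel][keep]
        dists = np.maximum(0, np.maximum(starts - bf.end, bf.start - ends))
        within = dists <= spec.cis_window
        starts, ends, ids, dists = (
            starts[within], ends[within], ids[within], dists[within]
        )
        mult = np.ones(len(ids))
        for target, amp, width in peaks_by_bait.get(bait, []):
            off = np.abs(ids - target)
            if spec.peak_shape == "tri":
                # signal smeared over contiguous fragments, apex at the target
                mult *= 1.0 + (amp - 1.0) * np.clip(1.0 - off / width, 0.0, 1.0)
            else:
                mult[off <= width // 2] *= amp
        mu = _expected_counts(spec, dists.astype(np.float64), float(eff), mult)
        counts = _draw_counts(spec, mu, rng)
        covered = counts >= 1
        rows.append(pd.DataFrame({
            "ID_Bait": bait, "chr_Bait": bf.chrom,
            "start_Bait": bf.start, "end_Bait": bf.end,
            "Bait_name": f"bait_{bait}",
            "ID_OE": ids[covered], "chr_OE": spec.chrom,
            "start_OE": starts[covered], "end_OE": ends[covered],
            "N": counts[covered].astype(np.int64),
        }))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=INTERACTION_COLUMNS
    )
    truth = pd.DataFrame(
        [
            {
                "ID_Bait": b, "target_ID_OE": t, "amplitude": a, "width": w,
                "target_start": fmap.by_id(t).start,
                "target_end": fmap.by_id(t).end,
            }
            for b, t, a, w in peaks
        ],
        columns=["ID_Bait", "target_ID_OE", "amplitude", "width",
                 "target_start", "target_end"],
    )
    return InteractionTable(df, label=f"sim_seed{spec.seed}"), truth


def simulate_replicates(
    spec: SyntheticSpec,
    fmap: FragmentMap,
    k: int = 2,
    jitter: int = 0,
    jitter_min: int = 0,
) -> tuple[list[InteractionTable], list[pd.DataFrame]]:
    """Draw ``k`` independent replicates sharing the planted truth.

    Replicates after the first optionally have every peak centre moved to a
    fragment whose interval gap from the original lies in
    ``[jitter_min, jitter]`` bp (emulating fragment-level irreproducibility
    of undersampled data).  Returns the tables and each replicate's
    (possibly jittered) truth registry.
    """
    if k < 2:
        raise ValueError("need k >= 2 replicates")
    rng = np.random.default_rng(spec.seed)
    tables: list[InteractionTable] = []
    truths: list[pd.DataFrame] = []
    bait_set = set(bait_ids_of(spec))
    for rep in range(k):
        peaks = spec.peaks
        if rep > 0 and jitter > 0:
            jittered = []
            for bait, target, amp, width in spec.peaks:
                # shift measured as the interval gap between old and new frag
                lo_frags = jitter_min // spec.frag_length + 1 if jitter_min else 1
                hi_frags = max(lo_frags, jitter // spec.frag_length)
                shift = int(rng.integers(lo_frags, hi_frags + 1))
                side = 1 if rng.random() < 0.5 else -1
                new = target + side * shift
                if new not in fmap or new in bait_set:
                    new = target - side * shift
                jittered.append((bait, new, amp, width))
            peaks = tuple(jittered)
        table, truth = simulate_dataset(spec, fmap, rng=rng, peaks=peaks)
        table.label = f"rep{rep + 1}"
        tables.append(table)
        truths.append(truth)
    return tables, truths


def simulate_peaks(
    fmap: FragmentMap, fraction_covered: float, seed: int,
    tile: int = 1_000,
) -> PeakSet:
    """Random merged intervals covering about ``fraction_covered`` of the map.

    Each ``tile``-bp tile of every chromosome is switched on independently
    with the requested probability, then adjacent tiles are merged.
    """
    if not (0 < fraction_covered <= 1):
        raise ValueError("fraction_covered must be in (0, 1]")
    rng = np.random.default_rng(seed)
    intervals: list[tuple[str, int, int]] = []
    for chrom in fmap.chromosomes:
        lo, hi = fmap.chrom_extent(chrom)
        if fraction_covered == 1:
            intervals.append((chrom, lo, hi))
            continue
        n_tiles = math.ceil((hi - lo) / tile)
        on = rng.random(n_tiles) < fraction_covered
        for i in np.flatnonzero(on):
            intervals.append(
                (chrom, lo + int(i) * tile, min(lo + (int(i) + 1) * tile, hi))
            )
    return PeakSet(intervals)


# ---------------------------------------------------------------------------
# Planted-truth evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(
    calls: InteractionTable,
    truth: pd.DataFrame,
    table: InteractionTable,
    bait_ids: set[int],
    params: CallerParams,
    fmap: FragmentMap,
    tol_fragments: int = 2,
    mask_edge_bins: bool = True,
) -> dict:
    """Recall / precision of a call set against a planted-peak registry.

    A planted interaction is *recovered* if some call for its bait lies
    within ``tol_fragments`` covered fragments of the planted enrichment
    region (target fragment +/- the planted width); a call is a true
    positive if it lies within the tolerance of some planted region.
    Distances are counted in covered-fragment index space of the bait's
    virtual 4C profile.

    With ``mask_edge_bins`` (default), calls in the first and last genomic-
    distance bin of the profile are excluded from the bookkeeping: the point
    of closest approach to the bait is the apex of any distance-decay
    profile (an expected background maximum, routinely masked around 4C/CHi-C
    viewpoints), and the truncation at the cis-window boundary makes maxima
    in the outermost bin equally ill-defined.  Planted peaks are never
    placed in either zone.
    """
    truth_by_bait = {b: g for b, g in truth.groupby("ID_Bait")}
    calls_by_bait = {b: g for b, g in calls.df.groupby("ID_Bait")}
    lo_mask = params.b
    hi_mask = params.c - params.b
    n_truth = n_recovered = n_calls = n_true_pos = 0
    for bait in sorted(set(truth_by_bait) | set(calls_by_bait)):
        profile = build_virtual_4c(table, int(bait), bait_ids, params)
        pos = profile.positions
        id_to_idx = {int(i): k for k, i in enumerate(profile.oe_ids)}

        regions: list[tuple[int, int]] = []
        t = truth_by_bait.get(bait)
        if t is not None:
            for _, row in t.iterrows():
                w = int(row["width"])
                lo = fmap.by_id(int(row["target_ID_OE"]) - w).mid
                hi = fmap.by_id(int(row["target_ID_OE"]) + w).mid
                regions.append((
                    int(np.searchsorted(pos, lo)), int(np.searchsorted(pos, hi))
                ))
        c_idx: list[int] = []
        c = calls_by_bait.get(bait)
        if c is not None:
            for _, row in c.iterrows():
                d = float(row["distance_to_bait"])
                if mask_edge_bins and not (lo_mask <= d < hi_mask):
                    continue
                c_idx.append(id_to_idx[int(row["ID_OE"])])
        n_truth += len(regions)
        n_calls += len(c_idx)
        for i0, i1 in regions:
            if any(i0 - tol_fragments <= ci <= i1 + tol_fragments for ci in c_idx):
                n_recovered += 1
        for ci in c_idx:
            if any(i0 - tol_fragments <= ci <= i1 + tol_fragments
                   for i0, i1 in regions):
                n_true_pos += 1
    return {
        "n_truth": n_truth,
        "n_calls": n_calls,
        "n_recovered": n_recovered,
        "n_true_positive": n_true_pos,
        "recall": n_recovered / n_truth if n_truth else float("nan"),
        "precision": n_true_pos / n_calls if n_calls else float("nan"),
    }
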