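"""Profile normalization and static multi-track rendering.

The browser-style view of Capture Hi-C data: virtual 4C profiles of one bait
across datasets, quantile-normalized so different sequencing depths are
visually comparable, smoothed by a running mean, and drawn above gene and
linear epigenomic signal tracks with called interactions highlighted.
Rendering is non-interactive and deterministic (a fixed Agg backend figure
written to PNG/SVG/PDF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import FancyArrow  # noqa: E402

from .io import INTERACTION_COLUMNS, InteractionTable

logger = logging.getLogger("chicmax")


# ---------------------------------------------------------------------------
# Normalization / smoothing
# ---------------------------------------------------------------------------

def quantile_normalize(
    wide: pd.DataFrame, count_columns: list[str] | None = None
) -> pd.DataFrame:
    """Classic quantile normalization of the count columns of a collated table.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; tied values receive the mean of the order statistics
    they span, so within-column rank order is preserved and the procedure is
    idempotent.  With a single count column the input is returned unchanged
    with a warning.
    """
    if count_columns is None:
        count_columns = [c for c in wide.columns if c not in INTERACTION_COLUMNS[:-1]]
    if not count_columns:
        raise ValueError("no count columns to normalize")
    out = wide.copy()
    if len(count_columns) < 2:
        logger.warning("quantile_normalize: single column, returning as is")
        return out
    mat = wide[count_columns].to_numpy(np.float64)
    ref = np.sort(mat, axis=0).mean(axis=1)
    for j, col in enumerate(count_columns):
        x = mat[:, j]
        order = np.argsort(x, kind="stable")
        vals = np.empty_like(ref)
        vals[order] = ref
        # ties: average the reference values spanned by each tied group
        s = pd.Series(vals).groupby(pd.Series(x)).transform("mean")
        out[col] = s.to_numpy()
    return out


def running_mean(values: np.ndarray, k: int) -> np.ndarray:
    """Centred moving average over ``k`` covered fragments, edge-truncated.

    ``k`` must be >= 1 and is bumped to the next odd number if even; windows
    shorten at the profile ends.
    """
    if k < 1:
        raise ValueError("window k must be >= 1")
    if k % 2 == 0:
        k += 1
        logger.warning("running_mean: even window adjusted to %d", k)
    values = np.asarray(values, dtype=np.float64)
    if len(values) == 0 or k == 1:
        return values.copy()
    return (
        pd.Series(values)
        .rolling(window=k, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass
class TrackSpec:
    """One display track.

    kind   : 'chic-profile' | 'gene' | 'signal' | 'interactions'
    source : a collated DataFrame column name (chic-profile), a BED/bedGraph
             path or DataFrame (gene/signal), or an InteractionTable.
    level  : positive integer; tracks sharing a level share one y-scale.
    """

    kind: str
    source: object
    level: int = 1
    color: str = "black"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("chic-profile", "gene", "signal", "interactions"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.level < 1:
            raise ValueError("plot level must be a positive integer")


def read_genes(path) -> pd.DataFrame:
    """Genes as modified BED: chrom / start / end / name / strand."""
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "strand"],
    )


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "value"],
    )


def _bait_profile(
    wide: pd.DataFrame, bait_name: str, column: str,
    window: tuple[int, int], smooth_k: int,
) -> tuple[np.ndarray, np.ndarray]:
    sub = wide[wide["Bait_name"] == bait_name]
    if len(sub) == 0:
        raise KeyError(f"bait {bait_name!r} not found in collated table")
    sub = sub.sort_values("start_OE", kind="mergesort")
    pos = 0.5 * (sub["start_OE"].to_numpy(np.float64) + sub["end_OE"].to_numpy(np.float64))
    vals = running_mean(sub[column].to_numpy(np.float64), smooth_k)
    keep = (pos >= window[0]) & (pos <= window[1])
    return pos[keep], vals[keep]


def render_region(
    wide: pd.DataFrame,
    bait_name: str,
    tracks: list[TrackSpec],
    out_path,
    flank: int = 500_000,
    smooth_k: int = 5,
    normalize: bool = True,
) -> None:
    """Render a bait-centred multi-track figure to ``out_path``.

    CHi-C profile tracks are taken from the collated wide table (quantile
    normalized across all datasets unless ``normalize=False``), smoothed by a
    ``smooth_k``-fragment running mean, and grouped by plot level with a
    shared y-scale per level.  Gene tracks draw strand arrows; signal tracks
    fill bedGraph values; interaction tracks shade the called other-end
    intervals of the displayed bait.  Identical inputs yield identical files.
    """
    bait_rows = wide[wide["Bait_name"] == bait_name]
    if len(bait_rows) == 0:
        raise KeyError(f"bait {bait_name!r} not found")
    b0 = bait_rows.iloc[0]
    chrom = b0["chr_Bait"]
    center = 0.5 * (b0["start_Bait"] + b0["end_Bait"])
    window = (int(center - flank), int(center + flank))

    profile_cols = [t.source for t in tracks if t.kind == "chic-profile"]
    if normalize and len(profile_cols) >= 2:
        wide = quantile_normalize(wide, count_columns=list(profile_cols))

    levels = sorted({t.level for t in tracks})
    fig, axes = plt.subplots(
        len(levels), 1, figsize=(10, 1.8 * len(levels)),
        sharex=True, squeeze=False,
    )
    axes = axes[:, 0]
    ax_of = dict(zip(levels, axes))

    # shared y-max per level over profile/signal tracks
    level_data: dict[int, list[tuple[TrackSpec, np.ndarray, np.ndarray]]] = {}
    for t in tracks:
        if t.kind == "chic-profile":
            x, y = _bait_profile(wide, bait_name, t.source, window, smooth_k)
        elif t.kind == "signal":
            bg = t.source if isinstance(t.source, pd.DataFrame) else read_bedgraph(t.source)
            bg = bg[(bg["chrom"] == chrom) & (bg["end"] > window[0]) & (bg["start"] < window[1])]
            x = 0.5 * (bg["start"].to_numpy(np.float64) + bg["end"].to_numpy(np.float64))
            y = bg["value"].to_numpy(np.float64)
        else:
            continue
        level_data.setdefault(t.level, []).append((t, x, y))

    for level, items in level_data.items():
        ax = ax_of[level]
        ymax = max((y.max() for _, _, y in items if len(y)), default=1.0)
        for t, x, y in items:
            if len(x) == 0:
                ax.annotate("no data in window", (0.5, 0.5),
                            xycoords="axes fraction", ha="center")
                continue
            if t.kind == "signal":
                ax.fill_between(x, y, color=t.color, label=t.label or None)
            else:
                ax.plot(x, y, color=t.color, lw=1.0, label=t.label or None)
        ax.set_ylim(0, 1.05 * ymax if ymax > 0 else 1.0)
        if any(t.label for t, _, _ in items):
            ax.legend(loc="upper right", fontsize=7, frameon=False)

    for t in tracks:
        if t.kind == "gene":
            genes = t.source if isinstance(t.source, pd.DataFrame) else read_genes(t.source)
            ax = ax_of[t.level]
            genes = genes[(genes["chrom"] == chrom)
                          & (genes["end"] > window[0]) & (genes["start"] < window[1])]
            ax.set_ylim(0, 1)
            for _, g in genes.iterrows():
                y = 0.3
                dx = (g["end"] - g["start"]) * (1 if g["strand"] == "+" else -1)
                x0 = g["start"] if g["strand"] == "+" else g["end"]
                ax.add_patch(FancyArrow(
                    x0, y, dx, 0, width=0.08, color=t.color or "blue",
                    length_includes_head=True,
                    head_width=0.25, head_length=0.05 * abs(dx),
                ))
                ax.annotate(str(g["name"]), (0.5 * (g["start"] + g["end"]), 0.65),
                            ha="center", fontsize=7)
        elif t.kind == "interactions":
            calls = t.source
            df = calls.df if isinstance(calls, InteractionTable) else calls
            df = df[df["Bait_name"] == bait_name]
            for ax in axes:
                for _, r in df.iterrows():
                    if r["end_OE"] > window[0] and r["start_OE"] < window[1]:
                        ax.axvspan(r["start_OE"], r["end_OE"],
                                   color=t.color or "red", alpha=0.3, lw=0)

    axes[0].axvline(center, color="gray", ls=":", lw=0.8)
    axes[-1].set_xlim(window)
    axes[-1].set_xlabel(f"{chrom} position (bp)")
    fig.suptitle(f"bait {bait_name}", fontsize=10)
    fig.savefig(out_path, dpi=120, metadata=_no_date_metadata(str(out_path)))
    plt.close(fig)


def _no_date_metadata(path: str) -> dict | None:
    """Strip volatile timestamps so identical inputs give identical bytes."""
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".pdf"):
        return {"CreationDate": None}
    return None  # PNG (Agg) embeds no timestamp
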