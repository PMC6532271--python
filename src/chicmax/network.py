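"""Chromatin contact networks and chromatin assortativity (ChAs).

Called interactions define an undirected network whose nodes are restriction
fragments and whose edges are bait <-> other-end contacts.  Each node carries
per-feature "fraction of presence" values: chromatin features binarized in
200-bp windows are averaged over the windows overlapping the fragment.

For a feature, *abundance* is its mean value over network nodes, and *ChAs*
is the Pearson correlation of the feature value across the endpoints of all
edges, each undirected edge contributing both orientations of its endpoint
pair (the standard numeric-assortativity convention).  High ChAs means
like-marked fragments preferentially contact each other.

Because some captured "other ends" overlap bait (promoter) fragments — i.e.
are themselves promoter-promoter contacts the capture design is not meant to
see — the promoter-other-end (P-O) restriction removes edges whose other end
overlaps any bait before computing ChAs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epigenomics import PeakSet
from .io import FragmentMap, InteractionTable, RestrictionFragment

logger = logging.getLogger("chicmax")

WINDOW_SIZE = 200  # bp; binarization grid for chromatin features


class FeatureWindows:
    """Genome-wide 0/1 presence calls of one feature on a fixed 200-bp grid."""

    def __init__(self, values: dict[str, np.ndarray], window_size: int = WINDOW_SIZE):
        self.window_size = int(window_size)
        self.values = {c: np.asarray(v, dtype=np.float64) for c, v in values.items()}
        for c, v in self.values.items():
            if np.any((v != 0) & (v != 1)):
                raise ValueError(f"{c}: window values must be 0/1")

    @classmethod
    def from_peaks(
        cls, peaks: PeakSet, chrom_extents: dict[str, tuple[int, int]],
        window_size: int = WINDOW_SIZE,
    ) -> "FeatureWindows":
        """Rasterize a peak set: a window is 1 on any-bp overlap with a peak."""
        values = {}
        for chrom, (lo, hi) in chrom_extents.items():
            n = math.ceil(hi / window_size)
            arr = np.zeros(n, dtype=np.float64)
            if chrom in peaks.chromosomes:
                for c, s, e in peaks.intervals():
                    if c != chrom:
                        continue
                    w0 = s // window_size
                    w1 = math.ceil(e / window_size)
                    arr[w0:min(w1, n)] = 1.0
            values[chrom] = arr
        return cls(values, window_size)

    @classmethod
    def from_bedgraph(
        cls, path, chrom_extents: dict[str, tuple[int, int]],
        window_size: int = WINDOW_SIZE,
    ) -> "FeatureWindows":
        """Read pre-binarized 200-bp windows from a bedGraph of 0/1 values."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        values = {}
        for chrom, (lo, hi) in chrom_extents.items():
            n = math.ceil(hi / window_size)
            arr = np.zeros(n, dtype=np.float64)
            sub = df[df["chrom"] == chrom]
            for _, r in sub.iterrows():
                w0 = int(r["start"]) // window_size
                w1 = math.ceil(int(r["end"]) / window_size)
                arr[w0:min(w1, n)] = float(r["value"])
            values[chrom] = arr
        return cls(values, window_size)


def feature_fraction(
    fragment: RestrictionFragment, windows: FeatureWindows
) -> float:
    """Fraction of presence of a feature in one fragment.

    The mean of the 0/1 values of all fixed-step windows overlapping the
    fragment interval; a fragment overlapping no window is a map/window
    mismatch and raises.
    """
    ws = windows.window_size
    arr = windows.values.get(fragment.chrom)
    if arr is None:
        raise ValueError(f"no windows for chromosome {fragment.chrom}")
    w0 = fragment.start // ws
    w1 = math.ceil(fragment.end / ws)
    if w0 >= len(arr) or w1 <= 0 or w1 <= w0:
        raise ValueError(
            f"fragment {fragment.frag_id} overlaps no feature window"
        )
    return float(arr[w0:min(w1, len(arr))].mean())


@dataclass
class ChromatinNetwork:
    """Fragments as nodes, called interactions as undirected edges.

    ``roles`` flags each node as bait / other-end / other-end-overlapping-a-
    bait; ``features`` maps feature label -> {node -> fraction of presence}.
    """

    nodes: list[int]
    edges: list[tuple[int, int]]
    roles: dict[int, set[str]]
    features: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def add_feature(
        self, label: str, windows: FeatureWindows, fmap: FragmentMap
    ) -> None:
        self.features[label] = {
            nid: feature_fraction(fmap.by_id(nid), windows)
            for nid in self.nodes
        }

    def feature_values(self, label: str) -> dict[int, float]:
        vals = self.features[label]
        missing = [n for n in self.nodes if n not in vals]
        if missing:
            raise ValueError(
                f"feature {label!r} missing for {len(missing)} nodes"
            )
        return vals


def build_network(
    calls: InteractionTable,
    fmap: FragmentMap,
    bait_ids: set[int],
    restrict_po: bool = False,
) -> ChromatinNetwork:
    """Build the contact network from a call set.

    Edges are deduplicated undirected (bait, other-end) pairs; self-loops are
    dropped.  With ``restrict_po`` every edge whose other-end fragment
    overlaps any bait fragment is removed (promoter-other-end subnetwork) and
    nodes left isolated are discarded.
    """
    bait_intervals = PeakSet(
        (f.chrom, f.start, f.end)
        for f in (fmap.by_id(b) for b in bait_ids)
    )
    edge_set: set[tuple[int, int]] = set()
    oe_overlapping: set[int] = set()
    for row in calls.df.itertuples(index=False):
        b, o = int(row.ID_Bait), int(row.ID_OE)
        if b == o:
            continue
        oe_frag = fmap.by_id(o)
        overlaps_bait = bait_intervals.overlaps(
            oe_frag.chrom, oe_frag.start, oe_frag.end
        )
        if overlaps_bait:
            oe_overlapping.add(o)
            if restrict_po:
                continue
        edge_set.add((min(b, o), max(b, o)))
    nodes = sorted({n for e in edge_set for n in e})
    roles: dict[int, set[str]] = {n: set() for n in nodes}
    for row in calls.df.itertuples(index=False):
        for n, role in ((int(row.ID_Bait), "bait"), (int(row.ID_OE), "other-end")):
            if n in roles:
                roles[n].add(role)
    for n in oe_overlapping:
        if n in roles:
            roles[n].add("other-end-overlapping-bait")
    return ChromatinNetwork(nodes=nodes, edges=sorted(edge_set), roles=roles)


def abundance(network: ChromatinNetwork, feature: str) -> float:
    """Mean feature value over all nodes of the network."""
    vals = network.feature_values(feature)
    return float(np.mean([vals[n] for n in network.nodes]))


def chas(
    network: ChromatinNetwork, feature: str, doubled: bool = True
) -> float:
    """Chromatin assortativity of one feature.

    Pearson correlation of the feature value across connected node pairs;
    with ``doubled`` (the standard assortativity convention) each undirected
    edge contributes both orientations (x_i, x_j) and (x_j, x_i).  Returns
    NaN (with a logged reason) when endpoint values have zero variance.
    """
    if network.n_edges < 2:
        raise ValueError("need at least two edges to compute ChAs")
    vals = network.feature_values(feature)
    x = np.array([vals[i] for i, j in network.edges], np.float64)
    y = np.array([vals[j] for i, j in network.edges], np.float64)
    if doubled:
        x, y = np.concatenate([x, y]), np.concatenate([y, x])
    if np.var(x) == 0 or np.var(y) == 0:
        logger.warning(
            "ChAs undefined for %r: zero variance over edge endpoints", feature
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class ChAsResult:
    feature: str
    abundance: float
    chas: float
    n_nodes: int
    n_edges: int


def chas_table(
    network: ChromatinNetwork, features: list[str] | None = None
) -> pd.DataFrame:
    """Abundance and ChAs for every feature attached to the network."""
    features = features or sorted(network.features)
    rows = [
        ChAsResult(
            feature=f,
            abundance=abundance(network, f),
            chas=chas(network, f),
            n_nodes=network.n_nodes,
            n_edges=network.n_edges,
        ).__dict__
        for f in features
    ]
    return pd.DataFrame(rows)
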