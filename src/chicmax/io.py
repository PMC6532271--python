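"""Domain types and file I/O for fragment-resolution Capture Hi-C data.

The coordinate backbone is the restriction digest: a :class:`FragmentMap` of
non-overlapping, per-chromosome-sorted intervals, each with a unique integer
fragment id.  Capture Hi-C read pairs are stored in fragment space as
bait <-> other-end records with a read count, read from and written to a
10-column tab-separated table (see :data:`INTERACTION_COLUMNS`).

All coordinates are 0-based half-open internally (BED convention).  Readers
accept 1-based closed input through an explicit ``one_based`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("chicmax")

#: Canonical interaction-table header.  ``Bait_name`` labels the captured
#: (promoter) fragment; ``ID_OE`` is the other-end fragment id; ``N`` is the
#: number of supporting read pairs.
INTERACTION_COLUMNS = [
    "ID_Bait", "chr_Bait", "start_Bait", "end_Bait", "Bait_name",
    "ID_OE", "chr_OE", "start_OE", "end_OE", "N",
]

#: Extra diagnostic columns carried by called-interaction tables.
CALL_COLUMNS = ["smoothed_value", "bin_geomean", "distance_to_bait"]


class ValidationError(ValueError):
    """Input data violates a structural invariant (names the offending line)."""


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment: a half-open genomic interval with an id."""

    chrom: str
    start: int
    end: int
    frag_id: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"fragment {self.frag_id}: start {self.start} >= end {self.end}"
            )

    @property
    def mid(self) -> float:
        return 0.5 * (self.start + self.end)


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Genomic gap between two half-open intervals.

    Overlapping, identical, or directly adjacent intervals have gap 0; this is
    the fragment-space notion of "no genomic separation".
    """
    return max(0, b_start - a_end, a_start - b_end)


class FragmentMap:
    """Ordered restriction digest with id and coordinate lookup.

    Per chromosome, fragments are sorted and non-overlapping; adjacent
    fragments may share a boundary (``end_i == start_{i+1}``).
    """

    def __init__(self, fragments: Iterable[RestrictionFragment]):
        frags = list(fragments)
        by_chrom: dict[str, list[RestrictionFragment]] = {}
        self._by_id: dict[int, RestrictionFragment] = {}
        for f in frags:
            if f.frag_id in self._by_id:
                raise ValidationError(f"duplicate frag_id {f.frag_id}")
            self._by_id[f.frag_id] = f
            by_chrom.setdefault(f.chrom, []).append(f)
        self._chroms: dict[str, list[RestrictionFragment]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, lst in by_chrom.items():
            lst.sort(key=lambda f: f.start)
            for a, b in zip(lst, lst[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"overlapping fragments on {chrom}: "
                        f"[{a.start},{a.end}) id={a.frag_id} and "
                        f"[{b.start},{b.end}) id={b.frag_id}"
                    )
            self._chroms[chrom] = lst
            self._starts[chrom] = np.array([f.start for f in lst], dtype=np.int64)
            self._ends[chrom] = np.array([f.end for f in lst], dtype=np.int64)

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, frag_id: int) -> bool:
        return frag_id in self._by_id

    def __iter__(self) -> Iterator[RestrictionFragment]:
        for chrom in self.chromosomes:
            yield from self._chroms[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    @property
    def frag_ids(self) -> list[int]:
        return list(self._by_id)

    def fragments(self, chrom: str) -> list[RestrictionFragment]:
        return list(self._chroms[chrom])

    def by_id(self, frag_id: int) -> RestrictionFragment:
        try:
            return self._by_id[frag_id]
        except KeyError:
            raise KeyError(f"unknown frag_id {frag_id}") from None

    def at(self, chrom: str, pos: int) -> RestrictionFragment | None:
        """Fragment containing base-pair ``pos`` on ``chrom``, or None."""
        if chrom not in self._chroms:
            return None
        starts = self._starts[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return None
        f = self._chroms[chrom][i]
        return f if f.start <= pos < f.end else None

    def chrom_extent(self, chrom: str) -> tuple[int, int]:
        return int(self._starts[chrom][0]), int(self._ends[chrom][-1])

    def to_frame(self) -> pd.DataFrame:
        rows = [(f.chrom, f.start, f.end, f.frag_id) for f in self]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "frag_id"])


@dataclass
class InteractionTable:
    """A set of bait <-> other-end records with read counts.

    ``df`` carries at least :data:`INTERACTION_COLUMNS`; called tables add
    :data:`CALL_COLUMNS`.  ``provenance`` is one of ``raw``, ``called``,
    ``merged``.
    """

    df: pd.DataFrame
    label: str = "dataset"
    provenance: str = "raw"

    def __post_init__(self) -> None:
        missing = [c for c in INTERACTION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        dup = self.df.duplicated(subset=["ID_Bait", "ID_OE"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            row = self.df.iloc[i]
            raise ValidationError(
                f"duplicate (bait, other-end) pair at row {i}: "
                f"({row['ID_Bait']}, {row['ID_OE']})"
            )
        if (self.df["N"] < 1).any():
            i = int(np.flatnonzero((self.df["N"] < 1).to_numpy())[0])
            raise ValidationError(f"read count < 1 at row {i}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def bait_ids(self) -> list[int]:
        return sorted(self.df["ID_Bait"].unique())

    def for_bait(self, bait_id: int) -> pd.DataFrame:
        return self.df[self.df["ID_Bait"] == bait_id]

    def validate_against(self, fmap: FragmentMap) -> None:
        """Check that every fragment id resolves and coordinates match the map."""
        for i, row in enumerate(self.df.itertuples(index=False)):
            for prefix, fid in (("Bait", row.ID_Bait), ("OE", row.ID_OE)):
                if fid not in fmap:
                    raise ValidationError(f"row {i}: unknown frag_id {fid}")
                f = fmap.by_id(fid)
                chrom = getattr(row, f"chr_{prefix}")
                start = getattr(row, f"start_{prefix}")
                end = getattr(row, f"end_{prefix}")
                if (f.chrom, f.start, f.end) != (chrom, start, end):
                    raise ValidationError(
                        f"row {i}: {prefix} coordinates ({chrom}:{start}-{end}) "
                        f"do not match fragment {fid} "
                        f"({f.chrom}:{f.start}-{f.end})"
                    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_fragment_map(path, one_based: bool = False) -> FragmentMap:
    """Read a restriction digest from a BED-like file (chrom/start/end/frag_id).

    Lines must be tab-separated with >= 4 columns; a header line starting with
    ``chrom`` or ``#`` is tolerated.  With ``one_based`` the input is taken as
    1-based closed and converted.
    """
    frags: list[RestrictionFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("chrom", "chr"):
                continue
            if len(parts) < 4:
                raise ValidationError(f"line {lineno}: expected >=4 columns")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                frag_id = int(parts[3])
            except ValueError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
            if one_based:
                start -= 1
            try:
                frags.append(RestrictionFragment(chrom, start, end, frag_id))
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
    return FragmentMap(frags)


def write_fragment_map(fmap: FragmentMap, path) -> None:
    fmap.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_interactions(
    path,
    fragment_map: FragmentMap | None = None,
    label: str | None = None,
    one_based: bool = False,
) -> InteractionTable:
    """Read a 10-column interaction TSV, optionally validating against a map."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if one_based:
        df["start_Bait"] = df["start_Bait"] - 1
        df["start_OE"] = df["start_OE"] - 1
    provenance = "called" if all(c in df.columns for c in CALL_COLUMNS) else "raw"
    table = InteractionTable(df, label=label or str(path), provenance=provenance)
    if fragment_map is not None:
        table.validate_against(fragment_map)
    return table


def sort_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic output order: bait name, then other-end position."""
    return df.sort_values(
        ["Bait_name", "chr_OE", "start_OE", "ID_OE"], kind="mergesort"
    ).reset_index(drop=True)


def write_interactions(table: InteractionTable | pd.DataFrame, path) -> None:
    """Write an interaction table as TSV with deterministic order.

    Called tables carry the diagnostic columns after the canonical ten.
    An empty table yields a header-only file.
    """
    df = table.df if isinstance(table, InteractionTable) else table
    extra = [c for c in df.columns if c not in INTERACTION_COLUMNS]
    cols = INTERACTION_COLUMNS + extra
    out = sort_interactions(df)[cols] if len(df) else df[cols]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Table operations
# ---------------------------------------------------------------------------

def filter_cis_nonbait(
    table: InteractionTable, bait_ids: set[int]
) -> InteractionTable:
    """Drop trans (inter-chromosomal) and bait-to-bait records.

    Bait-to-bait ligation products show up as artificial local maxima in a
    virtual 4C profile and are excluded from calling, as are trans pairs.
    """
    if not bait_ids:
        raise ValueError("bait_ids must be nonempty")
    df = table.df
    keep = (df["chr_OE"] == df["chr_Bait"]) & ~df["ID_OE"].isin(bait_ids)
    return InteractionTable(
        df[keep].reset_index(drop=True), label=table.label,
        provenance=table.provenance,
    )


def collate(tables: Sequence[InteractionTable]) -> pd.DataFrame:
    """Combine datasets into one wide table, one count column per dataset.

    Rows are the union of (bait, other-end) pairs over all datasets; a pair
    absent from a dataset gets count 0.  Shared pairs must agree on
    coordinates and names.
    """
    if not tables:
        raise ValueError("need at least one table")
    labels = [t.label for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"dataset labels must be unique: {labels}")
    key_cols = INTERACTION_COLUMNS[:-1]  # all but N
    merged: pd.DataFrame | None = None
    for t in tables:
        part = t.df[key_cols + ["N"]].rename(columns={"N": t.label})
        if merged is None:
            merged = part
        else:
            before = len(merged) + len(part)
            merged = merged.merge(part, on=key_cols, how="outer")
            # A coordinate conflict shows up as the same (bait, oe) ids landing
            # in two rows after the outer join on the full key.
            dup = merged.duplicated(subset=["ID_Bait", "ID_OE"])
            if dup.any():
                row = merged[dup].iloc[0]
                raise ValidationError(
                    "conflicting coordinates across datasets for pair "
                    f"({row['ID_Bait']}, {row['ID_OE']})"
                )
            del before
    assert merged is not None
    count_cols = [t.label for t in tables]
    merged[count_cols] = merged[count_cols].fillna(0).astype(np.int64)
    return sort_interactions(merged)


def uncollate(wide: pd.DataFrame, label: str) -> InteractionTable:
    """Extract one dataset (nonzero rows) back out of a collated wide table."""
    key_cols = INTERACTION_COLUMNS[:-1]
    df = wide[wide[label] > 0][key_cols + [label]].rename(columns={label: "N"})
    return InteractionTable(df.reset_index(drop=True), label=label)


def read_baits(path) -> set[int]:
    """Read a one-column list of bait fragment ids."""
    with open(path) as fh:
        return {int(line.strip()) for line in fh if line.strip()}
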