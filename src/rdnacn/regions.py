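"""Reference coordinate systems and single-copy background region selection.

The 45S rDNA reference used for depth profiling is a composite built from the
GenBank U13369.1 consensus: the promoter-proximal tail of the repeat unit
(source 41021-42999) is prepended to the transcribed head (source 1-14000),
yielding a ~16 kb sequence that contains the transcription start site, the
three mature components (18S, 5.8S, 28S) and the 3' ETS.

Background ("single-copy") regions are exons and introns on the rDNA-bearing
chromosomes (1, 13, 14, 15, 21, 22) that survive homology and repeat filters,
a 300 bp - 10 kb length filter, and a 50 nt trim at each end.  Their mean
depth, after aneuploidy correction, is the denominator (BRD) of every copy
number estimate.

All coordinates at this interface are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CHROM_GROUP_5S = ("chr1",)
CHROM_GROUP_45S = ("chr13", "chr14", "chr15", "chr21", "chr22")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval annotated with feature class and gene."""

    chrom: str
    start: int
    end: int
    feature_class: str = "exon"  # exon | intron
    gene_id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end in {self}")
        if self.feature_class not in ("exon", "intron"):
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared base on the same chromosome; strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class RegionSet:
    """Background intervals kept after filtering, plus removal provenance."""

    kept: list = field(default_factory=list)
    removed: list = field(default_factory=list)  # (GenomicInterval, reason)

    def __post_init__(self):
        self._check_disjoint()

    def _check_disjoint(self):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.kept:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda r: r.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end >= b.start:
                    raise ValueError(f"overlapping kept intervals: {a} / {b}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(chrom=iv.chrom, start=iv.start, end=iv.end,
                 feature_class=iv.feature_class, gene_id=iv.gene_id,
                 removed_reason="")
            for iv in self.kept
        ]
        rows += [
            dict(chrom=iv.chrom, start=iv.start, end=iv.end,
                 feature_class=iv.feature_class, gene_id=iv.gene_id,
                 removed_reason=reason)
            for iv, reason in self.removed
        ]
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "feature_class", "gene_id",
                     "removed_reason"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        kept, removed = [], []
        for row in df.itertuples(index=False):
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end),
                                 row.feature_class, row.gene_id)
            reason = getattr(row, "removed_reason", "") or ""
            if isinstance(reason, float):  # NaN from empty TSV cell
                reason = ""
            if reason:
                removed.append((iv, reason))
            else:
                kept.append(iv)
        return cls(kept=kept, removed=removed)


@dataclass(frozen=True)
class CompositeReference:
    """Composite 45S coordinate system: head range then tail range of the source.

    Composite position 1 maps to ``head_start`` on the source; after the head
    range is exhausted, positions continue at source position 1 through
    ``tail_end``.  The mapping is a bijection over the composite length.
    """

    source_name: str
    head_start: int
    head_end: int
    tail_end: int
    components: dict = field(default_factory=dict)  # name -> (start, end), composite coords

    @property
    def head_length(self) -> int:
        return self.head_end - self.head_start + 1

    @property
    def length(self) -> int:
        return self.head_length + self.tail_end

    def to_source(self, pos: int) -> int:
        """Map a composite position (1-based) to the source coordinate."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"composite position {pos} outside 1..{self.length}")
        if pos <= self.head_length:
            return self.head_start + pos - 1
        return pos - self.head_length

    def to_composite(self, source_pos: int) -> int:
        """Inverse of :meth:`to_source`; errors for unmapped source positions."""
        if self.head_start <= source_pos <= self.head_end:
            return source_pos - self.head_start + 1
        if 1 <= source_pos <= self.tail_end:
            return self.head_length + source_pos
        raise ValueError(f"source position {source_pos} is not on the composite")


def build_composite_45s(
    source_length: int = 42999,
    head_start: int = 41021,
    head_end: int = 42999,
    tail_end: int = 14000,
    components: dict | None = None,
) -> CompositeReference:
    """Build the composite 45S reference (default length 15979 = 1979 + 14000)."""
    if not (1 <= head_start <= head_end <= source_length):
        raise ValueError("head range out of bounds")
    if not (1 <= tail_end <= source_length):
        raise ValueError("tail range out of bounds")
    ref = CompositeReference(
        source_name="U13369.1",
        head_start=head_start,
        head_end=head_end,
        tail_end=tail_end,
        components=dict(components or {}),
    )
    for name, (s, e) in ref.components.items():
        if not (1 <= s <= e <= ref.length):
            raise ValueError(f"component {name} interval outside composite")
    return ref


def resolve_isoform_overlaps(exons, introns) -> list:
    """Collapse isoform redundancy before background filtering.

    Among mutually overlapping exons only the largest is kept (ties broken by
    leftmost start, then reported order); any intron overlapping any surviving
    or non-surviving exon is removed.
    """
    exons = list(exons)
    introns = list(introns)
    # sort so the keeper of each overlap cluster is decided deterministically
    order = sorted(
        range(len(exons)),
        key=lambda i: (-exons[i].length, exons[i].chrom, exons[i].start, i),
    )
    kept_exons: list[GenomicInterval] = []
    for i in order:
        cand = exons[i]
        if not any(cand.overlaps(k) for k in kept_exons):
            kept_exons.append(cand)
    kept_exons.sort(key=lambda iv: (iv.chrom, iv.start))
    kept_introns = [
        intr for intr in introns if not any(intr.overlaps(ex) for ex in exons)
    ]
    return kept_exons + kept_introns


def select_single_copy_regions(
    candidates,
    homology_hits=(),
    repeat_hits=(),
    min_len: int = 300,
    max_len: int = 10_000,
    trim: int = 50,
) -> RegionSet:
    """Apply the single-copy background filters in order.

    1. remove candidates overlapping any homology hit (multi-mapping risk);
    2. remove candidates overlapping any annotated repeat;
    3. remove candidates whose *pre-trim* length is < ``min_len`` or
       > ``max_len``;
    4. trim ``trim`` nt off each end of the survivors.

    Removal reasons are recorded per interval.
    """
    if 2 * trim >= min_len:
        raise ValueError("trim must be < min_len / 2")
    homology_hits = list(homology_hits)
    repeat_hits = list(repeat_hits)
    kept, removed = [], []
    for iv in candidates:
        if any(iv.overlaps(h) for h in homology_hits):
            removed.append((iv, "homology_hit"))
            continue
        if any(iv.overlaps(r) for r in repeat_hits):
            removed.append((iv, "repeat_hit"))
            continue
        if iv.length < min_len:
            removed.append((iv, "too_short"))
            continue
        if iv.length > max_len:
            removed.append((iv, "too_long"))
            continue
        kept.append(
            GenomicInterval(
                iv.chrom, iv.start + trim, iv.end - trim,
                iv.feature_class, iv.gene_id,
            )
        )
    return RegionSet(kept=kept, removed=removed)
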