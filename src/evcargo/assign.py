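"""Hierarchical biotype-prioritized read-to-feature assignment.

Small-RNA loci overlap heavily in the genome (a miRNA hairpin inside a
lncRNA intron, piRNAs over tRNAs, ...), so a read overlapping several
annotated features must be resolved by a fixed class hierarchy:

    miRNA > tRNA > rRNA > mRNA > pseudogene > snRNA > snoRNA > piRNA >
    lncRNA > miscRNA

Each read is assigned to exactly one feature: among same-strand overlapping
features, the one whose biotype ranks highest wins; ties at equal rank go to
the larger overlap, then to the lexicographically smallest feature id, which
makes assignment independent of catalog insertion order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .matrix import CountMatrix
from .simulate import BIOTYPES

#: Assignment priority, rank 1 (highest) .. 10 (lowest).
BIOTYPE_PRIORITY = {bt: rank for rank, bt in enumerate(BIOTYPES, start=1)}

UNASSIGNED = None


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read: 0-based half-open genomic interval."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.read_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    """An annotated RNA locus (0-based half-open)."""

    feature_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    source_db: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.feature_id}: end must exceed start")
        if self.biotype not in BIOTYPE_PRIORITY:
            raise ValueError(
                f"{self.feature_id}: unknown biotype {self.biotype!r}")


class FeatureCatalog:
    """Interval index over features, keyed by (chrom, strand)."""

    def __init__(self, features):
        self.features = list(features)
        self._trees: dict = {}
        for f in self.features:
            key = (f.chrom, f.strand)
            self._trees.setdefault(key, IntervalTree()).addi(f.start, f.end, f)

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(self, a: AlignmentRecord):
        """Same-strand features sharing >=1 base with the read.

        Unstranded reads (strand '.') match features on either strand;
        unstranded features match reads on either strand.
        """
        strands = ("+", "-", ".") if a.strand == "." else (a.strand, ".")
        hits = []
        for s in strands:
            tree = self._trees.get((a.chrom, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(a.start, a.end))
        return hits

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureCatalog":
        """Build from a frame with feature_id/biotype/chrom/start/end[/strand]."""
        feats = [
            Feature(r.feature_id, r.biotype, r.chrom, int(r.start),
                    int(r.end), getattr(r, "strand", "+"))
            for r in df.itertuples(index=False)
        ]
        return cls(feats)


def read_length_filter(alignments, min_len: int = 15):
    """Drop fragments shorter than ``min_len`` nt (default 15).

    The boundary is kept: a 15-nt read passes a 15-nt filter.
    """
    return [a for a in alignments if a.length >= min_len]


def assign_read(a: AlignmentRecord, catalog: FeatureCatalog):
    """Assign one read to a feature id, or ``None`` if nothing overlaps.

    Among overlapping same-strand features: highest biotype priority wins;
    ties by larger overlap length, then smallest feature_id.
    """
    hits = catalog.overlapping(a)
    if not hits:
        return UNASSIGNED
    best = min(
        hits,
        key=lambda f: (
            BIOTYPE_PRIORITY[f.biotype],
            -(min(a.end, f.end) - max(a.start, f.start)),
            f.feature_id,
        ),
    )
    return best.feature_id


def count_features(alignments, catalog: FeatureCatalog,
                   sample_id: str = "sample") -> CountMatrix:
    """Count reads per feature for one sample.

    Every read contributes at most one count to exactly one feature.  The
    recorded library size is the number of input reads, so it can exceed the
    column sum when reads fall outside the annotation.  Duplicate read ids
    (multi-mapped leftovers) are counted once, with a warning.
    """
    counts = {f.feature_id: 0 for f in catalog.features}
    seen: set = set()
    n_dup = 0
    n_total = 0
    for a in alignments:
        n_total += 1
        if a.read_id in seen:
            n_dup += 1
            continue
        seen.add(a.read_id)
        fid = assign_read(a, catalog)
        if fid is not None:
            counts[fid] += 1
    if n_dup:
        warnings.warn(f"{n_dup} duplicate read ids ignored", stacklevel=2)
    biotype = pd.Series({f.feature_id: f.biotype for f in catalog.features},
                        name="biotype")
    df = pd.DataFrame({sample_id: pd.Series(counts, dtype=np.int64)})
    df.index.name = "feature_id"
    lib = pd.Series({sample_id: n_total - n_dup})
    return CountMatrix(df.loc[biotype.index], biotype, lib)


def count_frame(bed: pd.DataFrame, catalog: FeatureCatalog,
                sample_id: str = "sample", min_len: int = 15) -> CountMatrix:
    """Length-filter and count a BED6-style alignment frame in one call."""
    alignments = [
        AlignmentRecord(r.read_id, r.chrom, int(r.start), int(r.end),
                        getattr(r, "strand", "."))
        for r in bed.itertuples(index=False)
    ]
    return count_features(read_length_filter(alignments, min_len), catalog,
                          sample_id)


def biotype_proportions(cm: CountMatrix, exclude: tuple = ()) -> pd.DataFrame:
    """Per-sample fraction of assigned reads in each biotype.

    Fractions are over assigned reads only and sum to 1 per sample.  Biotypes
    in ``exclude`` (e.g. rRNA for composition plots) are dropped before
    renormalization.  Raises on samples with no assigned reads.
    """
    keep = ~cm.biotype.isin(exclude)
    sub = cm.counts.loc[keep]
    by_bio = sub.groupby(cm.biotype.loc[keep], observed=True).sum()
    totals = by_bio.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"no assigned reads in samples {bad}")
    props = (by_bio / totals).T
    props.index.name = "sample_id"
    return props.reindex(columns=[b for b in BIOTYPES if b not in exclude],
                         fill_value=0.0)
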