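"""Gene-feature overlap reporting for sweep regions.

A gene is reported for a region when it is fully or partially contained in
it, i.e. overlaps it by at least 1 bp.  Intervals are closed and 1-based
internally; the GFF3 reader keeps its native 1-based coordinates and the BED
reader converts from 0-based half-open on load, so a single convention holds
everywhere downstream.  Functional enrichment of the reported genes is out of
scope — this module only does the interval plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .sweep_scan import SweepRegion


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on 1-based closed coordinates."""

    id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")


class FeatureIndex:
    """Chromosome-keyed interval index over gene features."""

    def __init__(self, features: Iterable[GeneFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            # interval trees are half-open; +1 makes the closed end inclusive
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end + 1, f)

    def query(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda f: (f.start, f.end, f.id))


def genes_in_region(
    features: Union[FeatureIndex, Sequence[GeneFeature]], region: SweepRegion
) -> list[GeneFeature]:
    """Features overlapping ``[region.start, region.end]`` by >= 1 bp."""
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    return index.query(region.chrom, region.start, region.end)


def overlap_bp(feature: GeneFeature, region: SweepRegion) -> int:
    """Length (bp, closed-interval) of the feature/region overlap."""
    return max(0, min(feature.end, region.end) - max(feature.start, region.start) + 1)


def read_gff3(path: str, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneFeature]:
    """Load features of the given types from a GFF3 file (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneFeature] = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            name = feat.attributes.get("Name", [feat.id])[0]
            out.append(
                GeneFeature(feat.id, name, feat.seqid, feat.start, feat.end,
                            feat.strand or ".")
            )
    return sorted(out, key=lambda f: (f.chrom, f.start, f.end, f.id))


def read_bed(path: str) -> list[GeneFeature]:
    """Load BED3+ features, converting 0-based half-open to 1-based closed."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if len(row) > 3 and isinstance(row[3], str) else f"feature{i}"
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        out.append(
            GeneFeature(name, name, str(row[0]), int(row[1]) + 1, int(row[2]), strand)
        )
    return sorted(out, key=lambda f: (f.chrom, f.start, f.end, f.id))


def annotation_report(
    regions: Sequence[SweepRegion],
    features: Union[FeatureIndex, Sequence[GeneFeature]],
) -> pd.DataFrame:
    """One row per (region, overlapping gene) with the overlap length in bp."""
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    rows = []
    for r in regions:
        hits = index.query(r.chrom, r.start, r.end)
        if not hits:
            rows.append(
                {"population": r.population, "chrom": r.chrom, "start": r.start,
                 "end": r.end, "gene_id": None, "gene_name": None, "overlap_bp": 0}
            )
        for f in hits:
            rows.append(
                {"population": r.population, "chrom": r.chrom, "start": r.start,
                 "end": r.end, "gene_id": f.id, "gene_name": f.name,
                 "overlap_bp": overlap_bp(f, r)}
            )
    return pd.DataFrame(rows)
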