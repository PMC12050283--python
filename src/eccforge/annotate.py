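"""Genomic-feature classification of unified eccDNA regions.

Every region gets exactly one location class with priority
gene > up2kb > down2kb > intergenic (the 2 kb windows are gene-orientation
aware), so location classes partition the catalog.  Track overlaps
(TE/ncRNA/NUMT/NUPT) are non-exclusive labels with a 1 bp threshold, and a
region that fully contains an annotated repeat unit is a full-length
ecRepeatUnit.  All interval arithmetic is 0-based half-open; a length-0
intersection is never a hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .sim.genome import GeneModel, TrackFeature

FLANK_DEFAULT = 2000

Region = tuple[str, str, int, int]  # (unified_id, chrom, start, end)


@dataclass(frozen=True)
class LocationClass:
    unified_id: str
    location: str  # gene | up2kb | down2kb | intergenic
    gene_id: str | None = None


@dataclass(frozen=True)
class GenePartLabel:
    unified_id: str
    parts: frozenset[str]  # subset of {"5UTR", "CDS", "3UTR"}
    full_length_gene: bool


@dataclass(frozen=True)
class EcTrackRecord:
    unified_id: str
    kind: str
    feature_id: str
    class1: str
    superfamily: str
    subfamily: str
    overlap_bp: int


@dataclass(frozen=True)
class FullLengthRepeatRecord:
    unified_id: str
    repeat_unit_id: str
    family: str
    subfamily: str


def _overlap(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def _flank_windows(gene: GeneModel, flank: int, stranded: bool):
    """(up_window, down_window) in genome coordinates, clipped at 0."""
    left = (max(0, gene.start - flank), gene.start)
    right = (gene.end, gene.end + flank)
    if not stranded or gene.strand == "+":
        return left, right
    return right, left


def classify_location(
    region: Region,
    genes: list[GeneModel],
    flank: int = FLANK_DEFAULT,
    stranded: bool = True,
) -> LocationClass:
    """Mutually exclusive location call for one region.

    Priority gene > up2kb > down2kb > intergenic; within the winning
    priority level the gene with the largest overlap is reported (ties to
    the smaller (chrom, start)).
    """
    uid, chrom, start, end = region
    best = {"gene": None, "up2kb": None, "down2kb": None}
    for gene in genes:
        if gene.chrom != chrom:
            continue
        key = (gene.chrom, gene.start, gene.gene_id)
        hit_gene = _overlap(start, end, gene.start, gene.end)
        up, down = _flank_windows(gene, flank, stranded)
        for level, ov in (("gene", hit_gene),
                          ("up2kb", _overlap(start, end, *up)),
                          ("down2kb", _overlap(start, end, *down))):
            if ov > 0:
                cur = best[level]
                if cur is None or (-ov, key) < (-cur[0], cur[1]):
                    best[level] = (ov, key, gene.gene_id)
    for level in ("gene", "up2kb", "down2kb"):
        if best[level] is not None:
            return LocationClass(uid, level, best[level][2])
    return LocationClass(uid, "intergenic", None)


def classify_gene_parts(region: Region, gene: GeneModel) -> GenePartLabel:
    """UTR/CDS composition of a region located on `gene`.

    A gene without annotated parts is treated as CDS over its whole body.
    `full_length_gene` is true when the region contains [start, end)
    (containment inclusive at both boundaries).
    """
    uid, chrom, start, end = region
    part_ivs = [("5UTR", gene.utr5), ("CDS", gene.cds_exons), ("3UTR", gene.utr3)]
    if not (gene.utr5 or gene.cds_exons or gene.utr3):
        part_ivs = [("CDS", [(gene.start, gene.end)])]
    parts = set()
    for name, ivs in part_ivs:
        if any(_overlap(start, end, s, e) > 0 for s, e in ivs):
            parts.add(name)
    full = chrom == gene.chrom and start <= gene.start and gene.end <= end
    return GenePartLabel(uid, frozenset(parts), full)


def overlap_track(
    regions: list[Region],
    features: list[TrackFeature],
    min_overlap_bp: int = 1,
) -> list[EcTrackRecord]:
    """All (region, feature) pairs intersecting by >= `min_overlap_bp`."""
    trees: dict[str, IntervalTree] = {}
    for i, f in enumerate(features):
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, i)
    records = []
    for uid, chrom, start, end in regions:
        tree = trees.get(chrom)
        if tree is None or start >= end:
            continue
        hits = []
        for iv in tree.overlap(start, end):
            f = features[iv.data]
            ov = _overlap(start, end, f.start, f.end)
            if ov >= min_overlap_bp:
                hits.append(EcTrackRecord(
                    uid, f.kind, f.feature_id, f.class1, f.superfamily,
                    f.subfamily, ov))
        hits.sort(key=lambda r: (r.feature_id,))
        records.extend(hits)
    return records


def full_length_repeat_units(
    regions: list[Region], repeat_track: list[TrackFeature]
) -> list[FullLengthRepeatRecord]:
    """Regions fully containing an annotated repeat unit (boundaries inclusive)."""
    trees: dict[str, IntervalTree] = {}
    for i, f in enumerate(repeat_track):
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, i)
    records = []
    for uid, chrom, start, end in regions:
        tree = trees.get(chrom)
        if tree is None or start >= end:
            continue
        hits = []
        for iv in tree.overlap(start, end):
            f = repeat_track[iv.data]
            if start <= f.start and f.end <= end:
                hits.append(FullLengthRepeatRecord(
                    uid, f.feature_id, f.superfamily, f.subfamily))
        hits.sort(key=lambda r: r.repeat_unit_id)
        records.extend(hits)
    return records


@dataclass
class AnnotationSummary:
    """Proportion tables derived from the classification outputs."""

    n_regions: int = 0
    location_pct: dict[str, float] = field(default_factory=dict)
    gene_part_pct: dict[str, float] = field(default_factory=dict)
    te_class1_ratio: dict[str, float] = field(default_factory=dict)
    te_superfamily_ratio: dict[str, float] = field(default_factory=dict)
    n_full_length_genes: int = 0
    n_full_length_repeat_units: int = 0


def _part_label(parts: frozenset[str]) -> str:
    order = [p for p in ("5UTR", "CDS", "3UTR") if p in parts]
    return "+".join(order) if order else "none"


def summarize(
    locations: list[LocationClass],
    gene_parts: list[GenePartLabel] | None = None,
    te_records: list[EcTrackRecord] | None = None,
    full_length_repeats: list[FullLengthRepeatRecord] | None = None,
) -> AnnotationSummary:
    """Aggregate proportions; safe on empty inputs (no division by zero)."""
    summary = AnnotationSummary(n_regions=len(locations))
    if locations:
        counts: dict[str, int] = {}
        for loc in locations:
            counts[loc.location] = counts.get(loc.location, 0) + 1
        summary.location_pct = {
            k: 100.0 * v / len(locations) for k, v in sorted(counts.items())}
    if gene_parts:
        labels: dict[str, int] = {}
        for gp in gene_parts:
            lbl = _part_label(gp.parts)
            labels[lbl] = labels.get(lbl, 0) + 1
        summary.gene_part_pct = {
            k: 100.0 * v / len(gene_parts) for k, v in sorted(labels.items())}
        summary.n_full_length_genes = sum(gp.full_length_gene for gp in gene_parts)
    if te_records:
        c1: dict[str, int] = {}
        sf: dict[str, int] = {}
        for r in te_records:
            c1[r.class1] = c1.get(r.class1, 0) + 1
            sf[r.superfamily] = sf.get(r.superfamily, 0) + 1
        summary.te_class1_ratio = {k: v / len(te_records) for k, v in sorted(c1.items())}
        summary.te_superfamily_ratio = {k: v / len(te_records) for k, v in sorted(sf.items())}
    if full_length_repeats:
        summary.n_full_length_repeat_units = len(full_length_repeats)
    return summary


def classify_catalog(
    regions: list[Region],
    genes: list[GeneModel],
    tracks: list[TrackFeature],
    flank: int = FLANK_DEFAULT,
    stranded: bool = True,
) -> tuple[pd.DataFrame, AnnotationSummary]:
    """Convenience: classify every region and summarize.

    Returns a per-region DataFrame (location, gene_id, parts, full-length
    flags, ecTE/ecNcRNA/NUMT-NUPT hit counts) plus the summary.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    locations = [classify_location(r, genes, flank, stranded) for r in regions]
    parts = []
    for region, loc in zip(regions, locations):
        if loc.location == "gene":
            parts.append(classify_gene_parts(region, gene_by_id[loc.gene_id]))
    te = overlap_track(regions, [t for t in tracks if t.kind == "TE"])
    nc = overlap_track(regions, [t for t in tracks if t.kind == "ncRNA"])
    org = overlap_track(regions, [t for t in tracks if t.kind in ("NUMT", "NUPT")])
    flr = full_length_repeat_units(
        regions, [t for t in tracks if t.kind == "repeat_unit"])
    summary = summarize(locations, parts, te, flr)

    def hit_count(records):
        counts: dict[str, int] = {}
        for r in records:
            counts[r.unified_id] = counts.get(r.unified_id, 0) + 1
        return counts

    te_n, nc_n, org_n = hit_count(te), hit_count(nc), hit_count(org)
    flr_n: dict[str, int] = {}
    for r in flr:
        flr_n[r.unified_id] = flr_n.get(r.unified_id, 0) + 1
    parts_by_id = {p.unified_id: p for p in parts}
    rows = []
    for (uid, chrom, start, end), loc in zip(regions, locations):
        p = parts_by_id.get(uid)
        rows.append({
            "unified_id": uid, "chrom": chrom, "start": start, "end": end,
            "location": loc.location, "gene_id": loc.gene_id or "",
            "gene_parts": _part_label(p.parts) if p else "",
            "full_length_gene": bool(p.full_length_gene) if p else False,
            "n_te_hits": te_n.get(uid, 0), "n_ncrna_hits": nc_n.get(uid, 0),
            "n_numt_nupt_hits": org_n.get(uid, 0),
            "n_full_length_repeat_units": flr_n.get(uid, 0),
        })
    return pd.DataFrame(rows), summary
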