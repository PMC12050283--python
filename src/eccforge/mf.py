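"""Multiple-fragment eccDNA detection.

A rolling-circle read of a circle built from several non-contiguous
genomic fragments aligns as a repeating cycle of segments.  The smallest
period of the segment-identity sequence gives Nfragment (fragments per
circle traversal); the number of complete cycles observed gives Nfullpass.
Reads passing minimum thresholds on both (default 1 and 1) are classified
single-fragment (Nfragment = 1) or multi-fragment (Nfragment >= 2);
multi-fragment reads are grouped by their core gene — the gene with the
largest summed overlap across cycle fragments — to reduce redundancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapper import AlignmentSegment, GenomeIndex, map_query, trim_read_overlaps
from .sim.genome import GeneModel, LTR_SUPERFAMILIES, TrackFeature

DEFAULT_COORD_TOL = 20


@dataclass(frozen=True)
class SegmentCycle:
    """One circle traversal: ordered genomic fragments."""

    fragments: tuple[tuple[str, int, int, str], ...]

    @property
    def period(self) -> int:
        return len(self.fragments)

    @property
    def total_monomer_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)


@dataclass
class MfEccRead:
    read_id: str
    n_fullpass: int
    n_fragment: int
    cycle: SegmentCycle
    core_gene_id: str | None = None

    @property
    def total_monomer_length(self) -> int:
        return self.cycle.total_monomer_length


def _merge_collinear(segments: list[AlignmentSegment],
                     max_gap: int = 150) -> list[AlignmentSegment]:
    """Merge read-consecutive segments that continue the same alignment.

    Indels inside a fragment can split its alignment into two diagonal
    bands; the pieces are collinear (the reference gap tracks the read
    gap), so they are rejoined before cycle detection.
    """
    from dataclasses import replace

    out: list[AlignmentSegment] = []
    for seg in segments:
        if out:
            a = out[-1]
            gap_read = seg.read_start - a.read_end
            if (seg.chrom == a.chrom and seg.strand == a.strand
                    and -20 <= gap_read <= max_gap):
                if a.strand == "+":
                    gap_ref = seg.ref_start - a.ref_end
                else:
                    gap_ref = a.ref_start - seg.ref_end
                if abs(gap_ref - gap_read) <= 50 and gap_ref >= -20:
                    out[-1] = replace(
                        a,
                        read_end=seg.read_end,
                        ref_start=min(a.ref_start, seg.ref_start),
                        ref_end=max(a.ref_end, seg.ref_end),
                        n_seed_bases=a.n_seed_bases + seg.n_seed_bases,
                    )
                    continue
        out.append(seg)
    return out


def order_segments(segments: list[AlignmentSegment]) -> list[AlignmentSegment]:
    """Segments of one read sorted by read coordinate, overlaps trimmed at
    midpoints, split alignments rejoined."""
    return _merge_collinear(trim_read_overlaps(segments))


def _same_locus(a: AlignmentSegment, b: AlignmentSegment, tol: int) -> bool:
    """Same genomic fragment: endpoints within `tol`, or (for fragments
    long relative to the alignment jitter) reciprocal overlap >= 0.9."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if abs(a.ref_start - b.ref_start) <= tol and abs(a.ref_end - b.ref_end) <= tol:
        return True
    inter = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if inter <= 0:
        return False
    return inter >= 0.9 * (a.ref_end - a.ref_start) and inter >= 0.9 * (b.ref_end - b.ref_start)


def _truncation_of(part: AlignmentSegment, whole: AlignmentSegment, tol: int) -> bool:
    """`part` is a clipped version of `whole`: contained, sharing one endpoint."""
    if part.chrom != whole.chrom or part.strand != whole.strand:
        return False
    contained = (part.ref_start >= whole.ref_start - tol
                 and part.ref_end <= whole.ref_end + tol)
    shares_end = (abs(part.ref_start - whole.ref_start) <= tol
                  or abs(part.ref_end - whole.ref_end) <= tol)
    return contained and shares_end


def detect_cycle(
    segments: list[AlignmentSegment], coord_tol: int = DEFAULT_COORD_TOL
) -> tuple[int, int, SegmentCycle] | None:
    """Find the smallest repeating period of the ordered segment sequence.

    Segments are "equal" when chromosome, strand and both reference
    endpoints agree within `coord_tol`.  A clipped first segment (read
    starts mid-fragment) or clipped last segment (read ends mid-fragment)
    is dropped before the period search.  Returns
    `(n_fullpass, n_fragment, cycle)` or None when no repetition is seen.
    """
    segs = list(segments)
    if len(segs) < 2:
        return None

    def drop_clipped(seq: list[AlignmentSegment], idx: int) -> bool:
        cand = seq[idx]
        others = seq[:idx] + seq[idx + 1:]
        if any(_same_locus(cand, o, coord_tol) for o in others):
            return False
        return any(_truncation_of(cand, o, coord_tol) for o in others)

    if len(segs) > 2 and drop_clipped(segs, 0):
        segs = segs[1:]
    if len(segs) > 2 and drop_clipped(segs, len(segs) - 1):
        segs = segs[:-1]

    m = len(segs)
    if m < 2:
        return None
    for p in range(1, m):
        checks = [_same_locus(segs[i], segs[i + p], coord_tol) for i in range(m - p)]
        # tolerate a minority of failed comparisons from residual
        # alignment jitter; clean reads still demand full agreement
        needed = max(1, int(np.ceil(0.75 * len(checks))))
        if sum(checks) >= needed and checks[0]:
            # representative fragment coordinates: lower-median per cycle slot
            frags = []
            for slot in range(p):
                occ = segs[slot::p]
                starts = sorted(s.ref_start for s in occ)
                ends = sorted(s.ref_end for s in occ)
                frags.append((
                    occ[0].chrom,
                    starts[(len(starts) - 1) // 2],
                    ends[(len(ends) - 1) // 2],
                    occ[0].strand,
                ))
            return m // p, p, SegmentCycle(tuple(frags))
    return None


def classify_read(n_fullpass: int, n_fragment: int, min_fullpass: int = 1,
                  min_fragment: int = 1) -> str:
    """'rejected', 'single' (Nfragment = 1) or 'multi' (Nfragment >= 2)."""
    if n_fullpass < min_fullpass or n_fragment < min_fragment:
        return "rejected"
    return "single" if n_fragment == 1 else "multi"


def assign_core_gene(mf: MfEccRead, genes: list[GeneModel]) -> str | None:
    """Gene with the largest summed overlap across cycle fragments.

    Ties break toward the smaller (chrom, start); None when no gene
    overlaps any fragment.
    """
    overlaps: dict[str, int] = {}
    keys: dict[str, tuple[str, int]] = {}
    for gene in genes:
        total = 0
        for chrom, s, e, _ in mf.cycle.fragments:
            if chrom == gene.chrom:
                total += max(0, min(e, gene.end) - max(s, gene.start))
        if total > 0:
            overlaps[gene.gene_id] = total
            keys[gene.gene_id] = (gene.chrom, gene.start)
    if not overlaps:
        return None
    return min(overlaps, key=lambda g: (-overlaps[g], keys[g]))


def is_ltr_flanked(cycle: SegmentCycle, tracks: list[TrackFeature]) -> bool:
    """True when every gap between genomically adjacent same-chromosome
    fragments contains LTR-superfamily TEs of one single subfamily."""
    frags = sorted(cycle.fragments, key=lambda f: (f[0], f[1]))
    gaps = []
    for a, b in zip(frags, frags[1:]):
        if a[0] == b[0] and b[1] > a[2]:
            gaps.append((a[0], a[2], b[1]))
    if not gaps:
        return False
    subfamilies = set()
    for chrom, s, e in gaps:
        here = [t for t in tracks
                if t.kind == "TE" and t.superfamily in LTR_SUPERFAMILIES
                and t.chrom == chrom and t.start < e and t.end > s]
        if not here:
            return False
        subfamilies.update(t.subfamily for t in here)
    return len(subfamilies) == 1


GROUP_COLUMNS = ["core_gene_id", "n_fragment", "read_count", "sample_id", "ltr_flanked"]


def group_mf(reads: list[MfEccRead], sample_id: str,
             tracks: list[TrackFeature] | None = None) -> pd.DataFrame:
    """One row per (core gene, Nfragment), read counts descending."""
    rows: dict[tuple, dict] = {}
    for r in reads:
        key = (r.core_gene_id, r.n_fragment)
        if key not in rows:
            rows[key] = {
                "core_gene_id": r.core_gene_id if r.core_gene_id is not None else "",
                "n_fragment": r.n_fragment,
                "read_count": 0,
                "sample_id": sample_id,
                "ltr_flanked": is_ltr_flanked(r.cycle, tracks) if tracks else False,
            }
        rows[key]["read_count"] += 1
    frame = pd.DataFrame(list(rows.values()), columns=GROUP_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            ["read_count", "core_gene_id", "n_fragment"],
            ascending=[False, True, True], kind="mergesort",
        ).reset_index(drop=True)
    return frame


def detect_mf_reads(
    reads: dict[str, str],
    index: GenomeIndex,
    genes: list[GeneModel] | None = None,
    coord_tol: int = DEFAULT_COORD_TOL,
    min_fullpass: int = 1,
    min_fragment: int = 1,
) -> tuple[dict[str, str], list[MfEccRead]]:
    """Map, order, cycle-detect and classify every read.

    Returns `(classes, mf_reads)`: a per-read class label and the MfEccRead
    records (both single- and multi-fragment accepted reads), with core
    genes assigned when gene models are given.
    """
    classes: dict[str, str] = {}
    records: list[MfEccRead] = []
    for read_id in sorted(reads):
        segs = order_segments(map_query(reads[read_id], index, read_id=read_id))
        found = detect_cycle(segs, coord_tol)
        if found is None:
            classes[read_id] = "rejected"
            continue
        nfp, nf, cycle = found
        label = classify_read(nfp, nf, min_fullpass, min_fragment)
        classes[read_id] = label
        if label != "rejected":
            rec = MfEccRead(read_id, nfp, nf, cycle)
            if genes is not None:
                rec.core_gene_id = assign_core_gene(rec, genes)
            records.append(rec)
    return classes, records
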