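"""Single-fragment eccDNA calling from rolling-circle concatemer reads.

The identification criteria mirror the long-read eccDNA detection
framework used in the field: a read is evidence for a circle only if it
self-decomposes into tandem repeat units at least 200 bp long, with at
least two units and no more than 25% divergence between adjacent units;
reads whose repeat structure already exists collinearly in the linear
genome (genomic tandem arrays) are excluded; and a locus is emitted only
when covered by at least three reads, each with a minimum of 80% of its
length aligning to the locus of origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import edlib
import numpy as np
import pandas as pd

from .mapper import AlignmentSegment, GenomeIndex, best_segment, map_query


class ReadTooShortError(ValueError):
    """Read shorter than two k-mers cannot be decomposed."""


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the identification criteria (defaults are the printed ones)."""

    min_unit_length: int = 200
    min_units: float = 2.0
    max_unit_divergence: float = 0.25
    min_locus_reads: int = 3
    min_read_aligned_fraction: float = 0.80
    kmer_size: int = 15
    cluster_reciprocal_overlap: float = 0.80

    def validate(self) -> None:
        for p in (self.max_unit_divergence, self.min_read_aligned_fraction,
                  self.cluster_reciprocal_overlap):
            if not 0.0 < p <= 1.0:
                raise ValueError("proportions must lie in (0, 1]")
        if self.min_unit_length < self.kmer_size:
            raise ValueError("min_unit_length must be >= kmer_size")


@dataclass
class TandemDecomposition:
    """Self-repeat structure of one read."""

    read_id: str
    unit_length: int
    n_units: float
    unit_divergence: float
    consensus: str
    repeat_span: tuple[int, int] = (0, 0)  # read interval explained by the repeat


@dataclass(frozen=True)
class EccLocus:
    locus_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    n_reads: int
    mean_aligned_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _smoothed_mode(dists: list[int], k: int) -> tuple[int, int] | None:
    """Dominant inter-occurrence distance and the half-window used."""
    arr = np.bincount(dists)
    if len(arr) <= k:
        return None
    best_d, best_score = None, 0
    cum = np.concatenate([[0], np.cumsum(arr)])
    for d in range(k, len(arr)):
        w = max(3, d // 50)  # jitter window grows with the period (indels)
        lo, hi = max(0, d - w), min(len(arr), d + w + 1)
        score = cum[hi] - cum[lo]
        if score > best_score:
            best_d, best_score = d, score
    if best_d is None:
        return None
    return best_d, max(3, best_d // 50)


def decompose_concatemer(
    read: str, params: CallerParams, read_id: str = "read"
) -> TandemDecomposition | None:
    """Detect the dominant tandem-repeat period of a read.

    The period is the mode of distances between consecutive occurrences of
    repeated k-mers; the repeat span is the read interval covered by the
    supporting k-mer pairs, and units are consecutive period-length slices
    of that span.  Divergence is the mean edit distance between adjacent
    units divided by the unit length.  Returns None when no period
    explains at least 2 x k of matched k-mer bases.
    """
    params.validate()
    k = params.kmer_size
    if len(read) < 2 * k:
        raise ReadTooShortError(f"read of {len(read)} bp is shorter than 2k = {2 * k}")

    occ: dict[str, list[int]] = {}
    for i in range(len(read) - k + 1):
        occ.setdefault(read[i : i + k], []).append(i)
    dists, pairs = [], []
    for positions in occ.values():
        for a, b in zip(positions, positions[1:]):
            if b - a >= k:
                dists.append(b - a)
                pairs.append((a, b))
    if not dists:
        return None

    mode = _smoothed_mode(dists, k)
    if mode is None:
        return None
    period0, w = mode
    support = [(a, b) for (a, b), d in zip(pairs, dists) if abs(d - period0) <= w]
    if not support:
        return None
    covered = []
    for a, b in support:
        covered.append((a, a + k))
        covered.append((b, b + k))
    covered.sort()
    total, last = 0, -1
    for s, e in covered:
        total += max(0, e - max(s, last))
        last = max(last, e)
    if total < 2 * k:
        return None

    period = int(np.median([b - a for a, b in support]))
    span_start = min(a for a, _ in support)
    span_end = max(b for _, b in support) + k
    span_len = span_end - span_start
    n_units = span_len / period

    n_full = span_len // period
    units = [read[span_start + j * period : span_start + (j + 1) * period]
             for j in range(n_full)]
    if len(units) >= 2:
        dv = [edlib.align(u, v, task="distance")["editDistance"] / period
              for u, v in zip(units, units[1:])]
        divergence = float(np.mean(dv))
    else:
        rem = read[span_start + period : span_end]
        if len(rem) >= k:
            divergence = (edlib.align(rem, units[0][: len(rem)], task="distance")
                          ["editDistance"] / len(rem))
        else:
            divergence = 0.0

    consensus = _consensus(units) if len(units) >= 2 else units[0]
    return TandemDecomposition(
        read_id, period, n_units, divergence, consensus,
        (span_start, span_end),
    )


def _consensus(units: list[str], max_units: int = 8) -> str:
    """Majority consensus: align every unit to the medoid, vote per column."""
    pool = units[:max_units]
    if len(pool) == 1:
        return pool[0]
    dist = np.zeros((len(pool), len(pool)))
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            d = edlib.align(pool[i], pool[j], task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d
    medoid = pool[int(np.argmin(dist.sum(axis=1)))]
    votes = [Counter() for _ in medoid]
    for u in pool:
        res = edlib.align(u, medoid, task="path")
        qpos = tpos = 0
        for length, op in _iter_cigar(res["cigar"]):
            if op == "=" or op == "X":
                for _ in range(length):
                    votes[tpos][u[qpos]] += 1
                    qpos += 1
                    tpos += 1
            elif op == "D":  # base in medoid absent from this unit
                for _ in range(length):
                    votes[tpos]["-"] += 1
                    tpos += 1
            else:  # 'I': extra base in unit, no medoid column
                qpos += length
    out = []
    for col in votes:
        base, _ = col.most_common(1)[0]
        if base != "-":
            out.append(base)
    return "".join(out)


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def passes_unit_filters(dec: TandemDecomposition, params: CallerParams) -> bool:
    """Unit-length / unit-count / divergence filters, applied independently.

    The divergence bound is inclusive: exactly 25% is retained, strictly
    greater is rejected.
    """
    return (
        dec.unit_length >= params.min_unit_length
        and dec.n_units >= params.min_units
        and dec.unit_divergence <= params.max_unit_divergence
    )


def map_consensus(consensus: str, index: GenomeIndex,
                  read_id: str = "consensus") -> list[AlignmentSegment]:
    """Map a repeat-unit consensus to the genome (or import PAF instead)."""
    return map_query(consensus, index, read_id=read_id)


def is_genomic_tandem(read: str, index: GenomeIndex, params: CallerParams,
                      raw_segments: list[AlignmentSegment] | None = None) -> bool:
    """True when the raw read aligns collinearly to one genomic window.

    A repeat structure that exists head-to-tail in the linear genome needs
    no circular interpretation; such reads (and plain linear reads) are
    excluded.  A single diagonal band covering at least
    `min_read_aligned_fraction` of the read is the criterion.
    """
    segs = raw_segments if raw_segments is not None else map_query(read, index, read_id="raw")
    if not segs:
        return False
    longest = max(s.read_span for s in segs)
    return longest >= params.min_read_aligned_fraction * len(read)


def aligned_fraction(read_len: int, raw_segments: list[AlignmentSegment],
                     locus: AlignmentSegment, margin: int) -> float:
    """Fraction of the read explained by alignments to the locus of origin.

    Each full (or partial) pass of the concatemer maps to the locus as its
    own segment; the union of their read intervals over `read_len` is the
    per-read aligned fraction.
    """
    intervals = []
    for s in raw_segments:
        if s.chrom != locus.chrom:
            continue
        if s.ref_end <= locus.ref_start - margin or s.ref_start >= locus.ref_end + margin:
            continue
        intervals.append((s.read_start, s.read_end))
    if not intervals:
        return 0.0
    intervals.sort()
    total, last = 0, -1
    for s, e in intervals:
        total += max(0, e - max(s, last))
        last = max(last, e)
    return total / read_len


@dataclass
class ReadCandidate:
    """Per-read evidence for a single-fragment circle locus."""

    read_id: str
    chrom: str
    start: int
    end: int
    aligned_fraction: float


AUDIT_COLUMNS = ["read_id", "status", "unit_length", "n_units",
                 "unit_divergence", "chrom", "start", "end", "aligned_fraction"]


def process_read(read_id: str, seq: str, index: GenomeIndex,
                 params: CallerParams) -> tuple[dict, ReadCandidate | None]:
    """Run one read through decomposition, filters and mapping.

    Returns an audit record and, for reads that survive the unit and
    linear-repeat filters, a locus candidate (kept even below the aligned
    fraction cutoff, flagged by status, so support counting can apply the
    cutoff explicitly).
    """
    audit = dict.fromkeys(AUDIT_COLUMNS)
    audit.update(read_id=read_id, status="", aligned_fraction=np.nan)
    if len(seq) < 2 * params.kmer_size:
        audit["status"] = "too_short"
        return audit, None
    dec = decompose_concatemer(seq, params, read_id=read_id)
    if dec is None:
        audit["status"] = "no_repeat"
        return audit, None
    audit.update(unit_length=dec.unit_length, n_units=round(dec.n_units, 2),
                 unit_divergence=round(dec.unit_divergence, 4))
    if not passes_unit_filters(dec, params):
        audit["status"] = "unit_filter"
        return audit, None
    raw_segs = map_query(seq, index, read_id=read_id)
    if is_genomic_tandem(seq, index, params, raw_segments=raw_segs):
        audit["status"] = "genomic_tandem"
        return audit, None
    cons_segs = map_consensus(dec.consensus, index, read_id=read_id)
    best = best_segment(cons_segs)
    if best is None:
        audit["status"] = "unmapped"
        return audit, None
    # the consensus is one rotation of the circular monomer, so it maps as
    # up to two wrap-around pieces lying side by side on the genome; the
    # locus is the hull of the pieces adjacent to the best one
    chrom, start, end = best.chrom, best.ref_start, best.ref_end
    for s in cons_segs:
        if (s.chrom == chrom
                and s.ref_start >= start - dec.unit_length
                and s.ref_end <= end + dec.unit_length):
            start, end = min(start, s.ref_start), max(end, s.ref_end)
    locus = AlignmentSegment(read_id, 0, len(dec.consensus), chrom, start, end,
                             best.strand, best.identity)
    af = aligned_fraction(len(seq), raw_segs, locus, margin=dec.unit_length)
    audit.update(chrom=chrom, start=start, end=end,
                 aligned_fraction=round(af, 4))
    low = af < params.min_read_aligned_fraction
    audit["status"] = "low_aligned_fraction" if low else "supporting"
    return audit, ReadCandidate(read_id, chrom, start, end, af)


def _reciprocal_overlap(a: ReadCandidate, b: ReadCandidate) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def _lower_median(values: list[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def call_loci(candidates: list[ReadCandidate], params: CallerParams,
              sample_id: str) -> list[EccLocus]:
    """Cluster per-read candidates into loci and apply the support filters.

    Reads below the aligned-fraction cutoff never count toward support.
    Clustering is single-linkage on reciprocal overlap; the emitted
    interval takes the member-median endpoints (lower median on ties), and
    loci with fewer than `min_locus_reads` supporting reads are dropped.
    """
    params.validate()
    members = [c for c in candidates
               if c.aligned_fraction >= params.min_read_aligned_fraction
               and c.end - c.start >= params.min_unit_length]
    if not members:
        return []
    members.sort(key=lambda c: (c.chrom, c.start, c.end, c.read_id))
    parent = list(range(len(members)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_chrom: dict[str, list[int]] = {}
    for idx, c in enumerate(members):
        by_chrom.setdefault(c.chrom, []).append(idx)
    for idxs in by_chrom.values():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if members[j].start >= members[i].end:
                    break
                if _reciprocal_overlap(members[i], members[j]) >= params.cluster_reciprocal_overlap:
                    union(i, j)

    clusters: dict[int, list[ReadCandidate]] = {}
    for idx in range(len(members)):
        clusters.setdefault(find(idx), []).append(members[idx])

    loci = []
    for group in clusters.values():
        if len(group) < params.min_locus_reads:
            continue
        chrom = group[0].chrom
        start = _lower_median([c.start for c in group])
        end = _lower_median([c.end for c in group])
        loci.append((chrom, start, end, len(group),
                     float(np.mean([c.aligned_fraction for c in group]))))
    loci.sort(key=lambda t: (t[0], t[1], t[2]))
    out = []
    for i, (chrom, start, end, n, maf) in enumerate(loci):
        out.append(EccLocus(f"{sample_id}_ecc{i + 1:05d}", sample_id, chrom,
                            start, end, n, maf))
    return out


def call_sample(reads: dict[str, str], index: GenomeIndex, params: CallerParams,
                sample_id: str) -> tuple[list[EccLocus], pd.DataFrame]:
    """Full per-sample pipeline: every read through `process_read`, then `call_loci`."""
    audits, candidates = [], []
    for read_id in sorted(reads):
        audit, cand = process_read(read_id, reads[read_id], index, params)
        audits.append(audit)
        if cand is not None:
            candidates.append(cand)
    loci = call_loci(candidates, params, sample_id)
    for locus in loci:
        assert locus.length >= params.min_unit_length
        assert locus.n_reads >= params.min_locus_reads
    return loci, pd.DataFrame(audits, columns=AUDIT_COLUMNS)
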