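"""Minimal exact-seed k-mer mapper.

Intentionally small: exact k-mer seeds grouped into diagonal bands per
(chromosome, strand), greedily chained, then extended outward while bases
match exactly.  Adequate for queries within ~5% divergence of the
reference, which is all the pipeline asks of it — real-data users can
import alignments from an external long-read aligner as PAF records
instead; every downstream stage operates on `AlignmentSegment`, not on
this mapper.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

from ._seq import revcomp


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned block between a read and the reference (PAF semantics).

    Coordinates are 0-based half-open.  `read_start`/`read_end` are on the
    original (forward) read; for strand '-' the reverse complement of
    `read[read_start:read_end]` aligns to `ref[ref_start:ref_end]`.
    """

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    n_seed_bases: int = 0

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


class GenomeIndex:
    """Exact k-mer index over the forward strand of every chromosome."""

    def __init__(self, seqs: dict[str, str], k: int = 15):
        self.k = k
        self.seqs = seqs
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in seqs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((chrom, i))
        self._index = index

    def lookup(self, kmer: str):
        return self._index.get(kmer, ())


_XDROP = 12
_MATCH, _MISMATCH = 1, -3


def _xdrop_right(q: str, ref: str, q1: int, r1: int) -> tuple[int, int]:
    """Gapless X-drop extension past substitutions; returns trimmed ends."""
    best, score, best_off, off = 0, 0, 0, 0
    nq, nr = len(q), len(ref)
    while q1 + off < nq and r1 + off < nr:
        score += _MATCH if q[q1 + off] == ref[r1 + off] else _MISMATCH
        off += 1
        if score > best:
            best, best_off = score, off
        elif best - score > _XDROP:
            break
    return q1 + best_off, r1 + best_off


def _xdrop_left(q: str, ref: str, q0: int, r0: int) -> tuple[int, int]:
    best, score, best_off, off = 0, 0, 0, 0
    while q0 - off > 0 and r0 - off > 0:
        score += _MATCH if q[q0 - off - 1] == ref[r0 - off - 1] else _MISMATCH
        off += 1
        if score > best:
            best, best_off = score, off
        elif best - score > _XDROP:
            break
    return q0 - best_off, r0 - best_off


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, last = 0, -1
    for s, e in sorted(intervals):
        if s > last:
            total += e - s
            last = e
        elif e > last:
            total += e - last
            last = e
    return total


def map_query(
    query: str,
    index: GenomeIndex,
    read_id: str = "query",
    band: int = 32,
    min_seed_bases: int | None = None,
    seed_step: int = 1,
) -> list[AlignmentSegment]:
    """Map `query` to the indexed genome; one segment per diagonal band.

    Bands group seeds whose diagonals (ref_pos - query_pos) lie within
    `band` of each other, so each full pass of a concatemer read over a
    genomic locus yields its own segment.  Segments with fewer than
    `min_seed_bases` (default 2k) covered query bases are dropped.
    """
    k = index.k
    if min_seed_bases is None:
        min_seed_bases = 2 * k
    if len(query) < k:
        return []

    segments: list[AlignmentSegment] = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        hits = []  # (chrom, diag, qpos, rpos)
        for i in range(0, len(q) - k + 1, seed_step):
            for chrom, rpos in index.lookup(q[i : i + k]):
                hits.append((chrom, rpos - i, i, rpos))
        if not hits:
            continue
        hits.sort()
        # split into diagonal bands per chromosome
        groups: list[list[tuple[str, int, int, int]]] = []
        for h in hits:
            if groups and h[0] == groups[-1][-1][0] and h[1] - groups[-1][-1][1] <= band:
                groups[-1].append(h)
            else:
                groups.append([h])
        for grp in groups:
            chrom = grp[0][0]
            grp.sort(key=lambda h: (h[2], h[3]))
            # greedy collinear chain
            chain = []
            last_q = last_r = -1
            for _, _, qpos, rpos in grp:
                if qpos >= last_q and rpos >= last_r:
                    chain.append((qpos, rpos))
                    last_q, last_r = qpos, rpos
            if not chain:
                continue
            q0, r0 = chain[0]
            q1 = chain[-1][0] + k
            r1 = chain[-1][1] + k
            seed_bases = _union_length([(qp, qp + k) for qp, _ in chain])
            if seed_bases < min_seed_bases:
                continue
            ref = index.seqs[chrom]
            q0, r0 = _xdrop_left(q, ref, q0, r0)
            q1, r1 = _xdrop_right(q, ref, q1, r1)
            aln = edlib.align(q[q0:q1], ref[r0:r1], task="distance")
            span = max(q1 - q0, r1 - r0)
            identity = 1.0 - aln["editDistance"] / span if span else 0.0
            if strand == "+":
                rs, re_ = q0, q1
            else:
                rs, re_ = len(query) - q1, len(query) - q0
            segments.append(AlignmentSegment(
                read_id, rs, re_, chrom, r0, r1, strand, identity, seed_bases))
    segments.sort(key=lambda s: (s.read_start, s.read_end, s.chrom, s.ref_start))
    return segments


def best_segment(segments: list[AlignmentSegment]) -> AlignmentSegment | None:
    """Segment with the most seed support (ties: longest, then position)."""
    if not segments:
        return None
    return max(
        segments,
        key=lambda s: (s.n_seed_bases, s.read_span, -s.ref_start),
    )


def read_paf(path) -> list[AlignmentSegment]:
    """Import precomputed alignments from a PAF file.

    Uses the 12 mandatory PAF columns; identity is residue matches over
    alignment block length.
    """
    segments = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            matches, blocklen = int(f[9]), int(f[10])
            segments.append(AlignmentSegment(
                read_id=f[0],
                read_start=int(f[2]), read_end=int(f[3]),
                chrom=f[5], ref_start=int(f[7]), ref_end=int(f[8]),
                strand=f[4],
                identity=matches / blocklen if blocklen else 0.0,
                n_seed_bases=matches,
            ))
    return segments


def write_paf(segments: list[AlignmentSegment], read_lengths: dict[str, int],
              ref_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            block = max(s.read_span, s.ref_span)
            matches = int(round(s.identity * block))
            fh.write("\t".join(map(str, [
                s.read_id, read_lengths.get(s.read_id, s.read_end),
                s.read_start, s.read_end, s.strand,
                s.chrom, ref_lengths.get(s.chrom, s.ref_end),
                s.ref_start, s.ref_end, matches, block, 60,
            ])) + "\n")


def trim_read_overlaps(segments: list[AlignmentSegment]) -> list[AlignmentSegment]:
    """Sort by read_start and trim read-interval overlaps at the midpoint.

    Reference coordinates are shrunk by the same amount on the
    corresponding side (strand-aware), keeping segment identity
    comparisons meaningful downstream.
    """
    segs = sorted(segments, key=lambda s: (s.read_start, s.read_end))
    out: list[AlignmentSegment] = []
    for seg in segs:
        if out and seg.read_start < out[-1].read_end:
            prev = out[-1]
            ov = prev.read_end - seg.read_start
            cut_prev = (ov + 1) // 2
            cut_cur = ov - cut_prev
            if prev.read_span > cut_prev and seg.read_span > cut_cur:
                if prev.strand == "+":
                    prev = replace(prev, read_end=prev.read_end - cut_prev,
                                   ref_end=prev.ref_end - cut_prev)
                else:
                    prev = replace(prev, read_end=prev.read_end - cut_prev,
                                   ref_start=prev.ref_start + cut_prev)
                if seg.strand == "+":
                    seg = replace(seg, read_start=seg.read_start + cut_cur,
                                  ref_start=seg.ref_start + cut_cur)
                else:
                    seg = replace(seg, read_start=seg.read_start + cut_cur,
                                  ref_end=seg.ref_end - cut_cur)
                out[-1] = prev
        out.append(seg)
    return out
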