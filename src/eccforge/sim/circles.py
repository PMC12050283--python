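"""Planting of circular DNA templates on the toy genome.

Single-fragment templates follow a truncated log-normal size law (median
500 bp, sigma 0.8, truncated to [200, 37000] bp), matching the size range
and central tendency reported for plant eccDNA detected from nanopore
concatemer reads.  Multi-fragment templates join 2-10 non-contiguous
genomic regions, optionally across chromosomes; a special `ltr_flanked_pair`
variant joins two fragments whose intervening genomic gap contains an
LTR-retrotransposon annotation of a single subfamily — the configuration a
homologous-recombination origin would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._seq import revcomp
from .genome import Genome, LTR_SUPERFAMILIES, SizingError

SIZE_MIN = 200
SIZE_MAX = 37_000


@dataclass(frozen=True)
class CircleTemplate:
    """A circular template: an ordered tuple of genomic fragments."""

    template_id: str
    fragments: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, strand)
    origin_tag: str  # single | multi | ltr_flanked_pair

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)


def monomer_sequence(genome: Genome, template: CircleTemplate) -> str:
    """One full traversal of the circle: fragments concatenated strand-aware."""
    parts = []
    for chrom, s, e, strand in template.fragments:
        seq = genome.fetch(chrom, s, e)
        parts.append(seq if strand == "+" else revcomp(seq))
    return "".join(parts)


def lognormal_size_law(rng: np.random.Generator) -> int:
    """Default circle size: log-normal, median 500 bp, sigma 0.8, truncated."""
    while True:
        size = int(round(rng.lognormal(np.log(500.0), 0.8)))
        if SIZE_MIN <= size <= SIZE_MAX:
            return size


def single_fragment_template(
    genome: Genome,
    length: int,
    rng: np.random.Generator,
    template_id: str = "circle",
    occupied: list[tuple[str, int, int]] | None = None,
    margin: int = 100,
) -> CircleTemplate:
    """Place one single-fragment template, avoiding `occupied` intervals."""
    chroms = genome.chrom_names
    for _ in range(500):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        limit = len(genome.seqs[chrom]) - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if occupied is not None:
            lo, hi = start - margin, start + length + margin
            if any(c == chrom and not (hi <= s or lo >= e) for c, s, e in occupied):
                continue
            occupied.append((chrom, start, start + length))
        strand = "+" if rng.random() < 0.5 else "-"
        return CircleTemplate(template_id, ((chrom, start, start + length, strand),), "single")
    raise SizingError(f"cannot place a {length} bp template without overlap")


def _array_intervals(genome: Genome, margin: int = 100):
    """Genomic tandem arrays, padded: templates must not be drawn from them
    (a repeat-borne fragment multi-maps and is not a unique locus)."""
    return [(t.chrom, t.start - margin, t.end + margin)
            for t in genome.tandem_arrays]


def _clear_of(blocked, chrom, start, end) -> bool:
    return all(c != chrom or end <= s or start >= e for c, s, e in blocked)


def _multi_template(genome, rng, template_id, n_fragments, cross_chrom, blocked):
    chroms = genome.chrom_names
    frags = []
    total = 0
    for j in range(n_fragments):
        length = int(np.clip(round(rng.lognormal(np.log(400.0), 0.5)), 150, 3000))
        if total + length > SIZE_MAX:
            length = 150
        for _ in range(200):
            if cross_chrom and len(chroms) > 1:
                chrom = chroms[j % len(chroms)]
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, len(genome.seqs[chrom]) - length))
            if _clear_of(blocked, chrom, start, start + length):
                break
        else:
            raise SizingError("cannot place a multi-template fragment")
        strand = "+" if rng.random() < 0.5 else "-"
        frags.append((chrom, start, start + length, strand))
        total += length
    return CircleTemplate(template_id, tuple(frags), "multi")


def ltr_flanked_pair_template(
    genome: Genome, rng: np.random.Generator, template_id: str = "ltrpair"
) -> CircleTemplate:
    """Two fragments flanking one LTR-superfamily TE annotation."""
    ltrs = [t for t in genome.track("TE") if t.superfamily in LTR_SUPERFAMILIES]
    if not ltrs:
        raise SizingError("genome has no LTR-superfamily TE to flank")
    te = ltrs[int(rng.integers(0, len(ltrs)))]
    chrom_len = len(genome.seqs[te.chrom])
    len1 = int(rng.integers(300, 1200))
    len2 = int(rng.integers(300, 1200))
    gap = int(rng.integers(10, 100))
    s1 = te.start - gap - len1
    e2 = te.end + gap + len2
    if s1 < 0 or e2 > chrom_len:
        raise SizingError("LTR feature too close to a chromosome end to flank")
    frags = (
        (te.chrom, s1, te.start - gap, "+"),
        (te.chrom, te.end + gap, e2, "+"),
    )
    return CircleTemplate(template_id, frags, "ltr_flanked_pair")


def plant_circles(
    genome: Genome,
    n_single: int,
    n_multi: int,
    size_law=None,
    seed: int = 0,
    n_ltr_flanked: int = 0,
    fragment_count: int | None = None,
    single_lengths: list[int] | None = None,
) -> list[CircleTemplate]:
    """Plant circular templates on the genome.

    `single_lengths` forces exact sizes for the single-fragment templates
    (boundary-condition studies); otherwise sizes follow `size_law`
    (default truncated log-normal).  Single templates are mutually
    non-overlapping so each circle defines a distinct locus.  When
    `n_multi >= 2` and the genome has >= 2 chromosomes, at least one multi
    template is cross-chromosomal.
    """
    rng = np.random.default_rng(seed)
    law = size_law or lognormal_size_law
    templates: list[CircleTemplate] = []
    occupied: list[tuple[str, int, int]] = list(_array_intervals(genome))

    if single_lengths is not None:
        lengths = list(single_lengths)
    else:
        lengths = [law(rng) for _ in range(n_single)]
    for i, length in enumerate(lengths):
        templates.append(single_fragment_template(
            genome, length, rng, f"circle{i + 1:04d}", occupied))

    blocked = _array_intervals(genome)
    for i in range(n_multi):
        nf = fragment_count if fragment_count is not None else int(rng.integers(2, 11))
        cross = (i == 0 and n_multi >= 2)
        templates.append(_multi_template(genome, rng, f"mcircle{i + 1:04d}", nf, cross, blocked))

    for i in range(n_ltr_flanked):
        templates.append(ltr_flanked_pair_template(genome, rng, f"ltrpair{i + 1:02d}"))

    return templates
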