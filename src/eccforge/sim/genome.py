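"""Toy annotated genome generator.

Produces random chromosome sequences plus the annotation tracks the
downstream pipeline classifies against: protein-coding gene models with
5'UTR/CDS/3'UTR structure, transposable elements with a
class/superfamily/subfamily hierarchy, repeat units, non-coding RNAs,
nuclear organellar insertions (NUMT/NUPT), and literal head-to-tail genomic
tandem arrays.  The tandem arrays are written into the sequence itself so
that reads drawn from them genuinely self-repeat — they are the negative
controls for the circular-DNA caller's linear-repeat exclusion rule.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import random_seq

#: class1 lookup for the TE superfamilies the simulator plants.
SUPERFAMILY_CLASS1: dict[str, str] = {
    "hAT": "DNA_transposon",
    "Tc1_Mariner": "DNA_transposon",
    "Mutator": "DNA_transposon",
    "Zator": "DNA_transposon",
    "Stowaway": "DNA_transposon",
    "Kiddo": "DNA_transposon",
    "CACTA": "DNA_transposon",
    "Gypsy": "Retrotransposon",
    "Copia": "Retrotransposon",
    "LINE": "Retrotransposon",
    "SINE": "Retrotransposon",
}

#: superfamilies treated as LTR retrotransposons (used for LTR-flanked circles).
LTR_SUPERFAMILIES = ("Gypsy", "Copia")

_REPEAT_FAMILIES = ("Stowaway", "Kiddo", "CentO", "TrsA")


class SizingError(ValueError):
    """Requested features do not fit on the requested chromosomes."""


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the toy genome.

    Defaults give a 2 x 100 kb genome with enough annotation density for
    every downstream classification to have non-trivial hits.
    """

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    gc_fraction: float = 0.44
    n_genes: int = 30
    n_tes: int = 40
    n_repeat_units: int = 30
    n_ncrnas: int = 10
    n_numt_nupt: int = 4
    n_genomic_tandem_arrays: int = 3
    seed: int = 0

    # longest feature the generator may plant (tandem array of 800 bp x 10)
    _MAX_FEATURE = 8_000

    def validate(self) -> None:
        counts = (
            self.n_genes, self.n_tes, self.n_repeat_units, self.n_ncrnas,
            self.n_numt_nupt, self.n_genomic_tandem_arrays, self.n_chromosomes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be non-negative")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.chrom_length < 10 * self._MAX_FEATURE:
            raise SizingError(
                f"chrom_length {self.chrom_length} < 10 x longest plantable "
                f"feature ({self._MAX_FEATURE} bp)"
            )


@dataclass
class GeneModel:
    """A gene whose 5'UTR, CDS exons and 3'UTR tile [start, end) contiguously."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    utr5: list[tuple[int, int]] = field(default_factory=list)
    cds_exons: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TrackFeature:
    """An annotated interval on one of the auxiliary tracks."""

    feature_id: str
    kind: str  # TE | repeat_unit | ncRNA | NUMT | NUPT | genomic_tandem
    chrom: str
    start: int
    end: int
    strand: str
    class1: str = "other"
    superfamily: str = ""
    subfamily: str = ""
    monomer_length: int | None = None  # genomic_tandem only

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """Sequences plus all annotation tracks."""

    spec: GenomeSpec
    seqs: dict[str, str]
    genes: list[GeneModel]
    tracks: list[TrackFeature]

    @property
    def chrom_names(self) -> list[str]:
        return list(self.seqs)

    def track(self, kind: str) -> list[TrackFeature]:
        return [t for t in self.tracks if t.kind == kind]

    @property
    def tandem_arrays(self) -> list[TrackFeature]:
        return self.track("genomic_tandem")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.seqs[chrom][start:end]


def _place_nonoverlapping(rng, occupied, chrom_len, length, margin=0, tries=200):
    """Sample a start so [start, start+length) avoids `occupied` intervals."""
    for _ in range(tries):
        start = int(rng.integers(0, chrom_len - length))
        lo, hi = start - margin, start + length + margin
        if all(hi <= s or lo >= e for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise SizingError("could not place feature without overlap; chromosome too crowded")


def _make_gene(rng, gene_id, chrom, start, length, strand) -> GeneModel:
    u5 = int(rng.integers(100, 301))
    u3 = int(rng.integers(100, 301))
    cds_len = length - u5 - u3
    n_exon = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exon - 1, replace=False)) if n_exon > 1 else []
    bounds = [0, *cuts, cds_len]
    # tile [start, end): utr5 | cds exons | utr3, in genomic order; for '-'
    # strand genes the 5'UTR sits at the right-hand (higher-coordinate) end.
    if strand == "+":
        utr5 = [(start, start + u5)]
        cds0 = start + u5
        utr3 = [(start + length - u3, start + length)]
    else:
        utr3 = [(start, start + u3)]
        cds0 = start + u3
        utr5 = [(start + length - u5, start + length)]
    cds = [(cds0 + a, cds0 + b) for a, b in zip(bounds[:-1], bounds[1:])]
    return GeneModel(gene_id, chrom, start, start + length, strand, utr5, cds, utr3)


def generate_genome(spec: GenomeSpec) -> Genome:
    """Generate sequences and annotation tracks for `spec` deterministically."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1:02d}" for i in range(spec.n_chromosomes)]
    seqs = {
        c: random_seq(spec.chrom_length, rng, spec.gc_fraction) for c in chroms
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    tracks: list[TrackFeature] = []

    def pick_chrom() -> str:
        return chroms[int(rng.integers(0, len(chroms)))]

    # genomic tandem arrays first: they rewrite the sequence
    for i in range(spec.n_genomic_tandem_arrays):
        chrom = pick_chrom()
        monomer_len = int(rng.integers(150, 801))
        copies = int(rng.integers(3, 11))
        total = monomer_len * copies
        start = _place_nonoverlapping(rng, occupied[chrom], spec.chrom_length, total, margin=50)
        monomer = random_seq(monomer_len, rng, spec.gc_fraction)
        s = seqs[chrom]
        seqs[chrom] = s[:start] + monomer * copies + s[start + total:]
        tracks.append(TrackFeature(
            f"tandem{i + 1:03d}", "genomic_tandem", chrom, start, start + total,
            "+", "other", "tandem_array", f"tandem{i + 1:03d}",
            monomer_length=monomer_len,
        ))

    # genes: non-overlapping with each other and with tandem arrays
    for i in range(spec.n_genes):
        chrom = pick_chrom()
        length = int(rng.integers(600, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        start = _place_nonoverlapping(rng, occupied[chrom], spec.chrom_length, length, margin=50)
        genes.append(_make_gene(rng, f"gene{i + 1:04d}", chrom, start, length, strand))
    genes.sort(key=lambda g: (g.chrom, g.start))

    # label-only tracks may fall anywhere (overlaps with genes are realistic)
    sf_names = list(SUPERFAMILY_CLASS1)
    for i in range(spec.n_tes):
        chrom = pick_chrom()
        sf = sf_names[int(rng.integers(0, len(sf_names)))]
        length = int(rng.integers(800, 6001)) if sf in LTR_SUPERFAMILIES else int(rng.integers(200, 3001))
        start = int(rng.integers(0, spec.chrom_length - length))
        tracks.append(TrackFeature(
            f"TE{i + 1:04d}", "TE", chrom, start, start + length,
            "+" if rng.random() < 0.5 else "-",
            SUPERFAMILY_CLASS1[sf], sf, f"{sf}_{int(rng.integers(1, 7))}",
        ))
    for i in range(spec.n_repeat_units):
        chrom = pick_chrom()
        fam = _REPEAT_FAMILIES[int(rng.integers(0, len(_REPEAT_FAMILIES)))]
        length = int(rng.integers(100, 401))
        start = int(rng.integers(0, spec.chrom_length - length))
        tracks.append(TrackFeature(
            f"RU{i + 1:04d}", "repeat_unit", chrom, start, start + length,
            "+" if rng.random() < 0.5 else "-",
            "other", fam, f"{fam}_{int(rng.integers(1, 13))}",
        ))
    for i in range(spec.n_ncrnas):
        chrom = pick_chrom()
        length = int(rng.integers(80, 1501))
        start = int(rng.integers(0, spec.chrom_length - length))
        tracks.append(TrackFeature(
            f"ncRNA{i + 1:04d}", "ncRNA", chrom, start, start + length,
            "+" if rng.random() < 0.5 else "-", "other", "ncRNA", "",
        ))
    for i in range(spec.n_numt_nupt):
        kind = "NUMT" if i % 2 == 0 else "NUPT"
        chrom = pick_chrom()
        length = int(rng.integers(200, 4001))
        start = int(rng.integers(0, spec.chrom_length - length))
        tracks.append(TrackFeature(
            f"{kind}{i + 1:03d}", kind, chrom, start, start + length, "+",
            "other", kind, "",
        ))

    tracks.sort(key=lambda t: (t.chrom, t.start, t.feature_id))
    return Genome(spec, seqs, genes, tracks)
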