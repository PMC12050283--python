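"""Concatemer and background read simulation with per-read truth labels.

Rolling-circle amplification of a circular template yields a linear read
that is a rotation of the circle's monomer repeated `n_passes` times
(`n_passes = full passes + a uniform partial pass`).  The pass-count law
guarantees at least one full pass so tandem decomposition of the read is
well-posed.  Background reads are either plain genomic substrings (linear)
or substrings of planted genomic tandem arrays spanning >= 2 monomer
copies — the read classes the caller must reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._seq import revcomp
from .circles import CircleTemplate, monomer_sequence
from .genome import Genome

TRUTH_COLUMNS = [
    "read_id", "source", "template_id", "background_kind", "chrom", "start",
    "end", "monomer_length", "n_passes", "phase_offset", "strand",
    "n_sub", "n_ins", "n_del", "read_length",
]


@dataclass(frozen=True)
class ReadSimConfig:
    """Error and pass-count model for simulated reads."""

    mean_full_passes: float = 5.0
    pass_count_law: str = "poisson_shifted"  # or "geometric"
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    revcomp_prob: float = 0.5
    n_reads_per_template: int = 6
    seed: int = 0

    def validate(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")
        if self.mean_full_passes < 1:
            raise ValueError("mean_full_passes must be >= 1")
        if self.pass_count_law not in ("poisson_shifted", "geometric"):
            raise ValueError(f"unknown pass_count_law {self.pass_count_law!r}")


def apply_errors(seq: str, sub_rate: float, ins_rate: float, del_rate: float,
                 rng: np.random.Generator) -> tuple[str, int, int, int]:
    """Apply per-base substitution/insertion/deletion errors.

    Returns the mutated sequence and the realized error counts.
    """
    if sub_rate == ins_rate == del_rate == 0.0:
        return seq, 0, 0, 0
    bases = "ACGT"
    u = rng.random(len(seq))
    out: list[str] = []
    n_sub = n_ins = n_del = 0
    t1, t2, t3 = sub_rate, sub_rate + del_rate, sub_rate + del_rate + ins_rate
    for i, ch in enumerate(seq):
        x = u[i]
        if x < t1:
            alt = bases[int(rng.integers(0, 4))]
            while alt == ch:
                alt = bases[int(rng.integers(0, 4))]
            out.append(alt)
            n_sub += 1
        elif x < t2:
            n_del += 1  # base dropped
        elif x < t3:
            out.append(ch)
            out.append(bases[int(rng.integers(0, 4))])
            n_ins += 1
        else:
            out.append(ch)
    return "".join(out), n_sub, n_ins, n_del


def _draw_full_passes(config: ReadSimConfig, rng: np.random.Generator) -> int:
    if config.pass_count_law == "poisson_shifted":
        return 1 + int(rng.poisson(config.mean_full_passes - 1.0))
    # geometric on {1, 2, ...} with the requested mean
    return int(rng.geometric(1.0 / config.mean_full_passes))


def simulate_rca_reads(
    genome: Genome,
    templates: list[CircleTemplate],
    config: ReadSimConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate concatemer reads for every template.

    Returns `(reads, truth)` where `reads` maps read_id to sequence and
    `truth` has one row per read.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    reads: dict[str, str] = {}
    rows = []
    for template in templates:
        monomer = monomer_sequence(genome, template)
        m = len(monomer)
        for j in range(config.n_reads_per_template):
            phase = int(rng.integers(0, m))
            n_full = _draw_full_passes(config, rng)
            partial = float(rng.random())
            rotated = monomer[phase:] + monomer[:phase]
            clean = rotated * n_full + rotated[: int(partial * m)]
            seq, n_sub, n_ins, n_del = apply_errors(
                clean, config.sub_rate, config.ins_rate, config.del_rate, rng)
            strand = "+"
            if rng.random() < config.revcomp_prob:
                seq = revcomp(seq)
                strand = "-"
            read_id = f"{template.template_id}_r{j + 1:03d}"
            reads[read_id] = seq
            rows.append({
                "read_id": read_id, "source": "rca",
                "template_id": template.template_id, "background_kind": "",
                "chrom": "", "start": -1, "end": -1,
                "monomer_length": m,
                "n_passes": n_full + partial, "phase_offset": phase,
                "strand": strand, "n_sub": n_sub, "n_ins": n_ins,
                "n_del": n_del, "read_length": len(seq),
            })
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def simulate_background_reads(
    genome: Genome,
    n_linear: int,
    n_tandem: int,
    length_law=None,
    error_config: ReadSimConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate linear genomic reads and genomic-tandem-array reads.

    Linear reads are contiguous substrings of the genome; tandem reads are
    substrings of a planted tandem array spanning at least two monomer
    copies.  Error rates come from `error_config` (default error-free).
    """
    rng = np.random.default_rng(seed)
    if length_law is None:
        def length_law(r):
            return int(np.clip(round(r.lognormal(np.log(2000.0), 0.5)), 500, 20_000))

    arrays = genome.tandem_arrays
    if n_tandem > 0 and not arrays:
        raise ValueError("n_tandem > 0 requires at least one genomic tandem array")

    sub = ins = dele = 0.0
    if error_config is not None:
        error_config.validate()
        sub, ins, dele = error_config.sub_rate, error_config.ins_rate, error_config.del_rate

    reads: dict[str, str] = {}
    rows = []
    chroms = genome.chrom_names
    for i in range(n_linear):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = len(genome.seqs[chrom])
        length = min(length_law(rng), clen - 1)
        start = int(rng.integers(0, clen - length))
        clean = genome.fetch(chrom, start, start + length)
        seq, n_sub, n_ins, n_del = apply_errors(clean, sub, ins, dele, rng)
        strand = "+"
        if rng.random() < 0.5:
            seq, strand = revcomp(seq), "-"
        read_id = f"linear_r{i + 1:04d}"
        reads[read_id] = seq
        rows.append({
            "read_id": read_id, "source": "background", "template_id": "",
            "background_kind": "linear", "chrom": chrom, "start": start,
            "end": start + length, "monomer_length": -1, "n_passes": np.nan,
            "phase_offset": -1, "strand": strand, "n_sub": n_sub,
            "n_ins": n_ins, "n_del": n_del, "read_length": len(seq),
        })
    for i in range(n_tandem):
        arr = arrays[int(rng.integers(0, len(arrays)))]
        mono = arr.monomer_length
        max_len = arr.length
        length = int(rng.integers(2 * mono, max_len + 1))
        start = arr.start + int(rng.integers(0, max_len - length + 1))
        clean = genome.fetch(arr.chrom, start, start + length)
        seq, n_sub, n_ins, n_del = apply_errors(clean, sub, ins, dele, rng)
        strand = "+"
        if rng.random() < 0.5:
            seq, strand = revcomp(seq), "-"
        read_id = f"tandem_r{i + 1:04d}"
        reads[read_id] = seq
        rows.append({
            "read_id": read_id, "source": "background", "template_id": "",
            "background_kind": "genomic_tandem", "chrom": arr.chrom,
            "start": start, "end": start + length, "monomer_length": mono,
            "n_passes": np.nan, "phase_offset": -1, "strand": strand,
            "n_sub": n_sub, "n_ins": n_ins, "n_del": n_del,
            "read_length": len(seq),
        })
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth
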