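"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALPHABET = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random DNA of the given length with expected GC fraction `gc`."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(ALPHABET, size=length, p=p))


def mutate_positions(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly `n_subs` distinct positions with a different base."""
    if n_subs == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in pos:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()
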