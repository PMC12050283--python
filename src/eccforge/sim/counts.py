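"""Zero-inflated Poisson count matrices with planted effects.

Emulates an ecGene-by-sample read-count matrix for a 2-group, 2-replicate
design.  Background features follow Bernoulli(1 - pi) * Poisson(lambda);
planted exclusive features are structurally present (count >= 1, pi = 0,
boosted lambda) in every replicate of one group and structurally absent
(zero) in the other; planted differential features are present in both
groups with a lambda fold-change in the "up" group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CountSimDesign:
    """Design of the simulated count matrix.

    Defaults: 2000 features, pi = 0.3, lambda = 10, 40 features planted per
    effect class with a 5x effect multiplier.
    """

    n_features: int = 2000
    group_labels: tuple[str, str] = ("A", "B")
    n_replicates: int = 2
    base_lambda: float = 10.0
    zero_inflation_pi: float = 0.3
    n_exclusive_a: int = 40
    n_exclusive_b: int = 40
    n_differential: int = 40
    effect_multiplier: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.zero_inflation_pi <= 1.0:
            raise ValueError("zero_inflation_pi must lie in [0, 1]")
        n_planted = self.n_exclusive_a + self.n_exclusive_b + self.n_differential
        if n_planted > self.n_features:
            raise ValueError("more planted features than features")
        if self.base_lambda <= 0 or self.effect_multiplier <= 0:
            raise ValueError("rates and effects must be positive")

    @property
    def sample_names(self) -> list[str]:
        a, b = self.group_labels
        return [f"{a}_rep{i + 1}" for i in range(self.n_replicates)] + \
               [f"{b}_rep{i + 1}" for i in range(self.n_replicates)]

    @property
    def groups(self) -> pd.Series:
        a, b = self.group_labels
        return pd.Series(
            [a] * self.n_replicates + [b] * self.n_replicates,
            index=self.sample_names, name="group",
        )


def simulate_count_matrix(design: CountSimDesign) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate `(counts, truth)` for the design.

    `counts` is a features x samples integer DataFrame; `truth` labels each
    feature `null`, `exclusive_A`, `exclusive_B`, `differential_A_up` or
    `differential_B_up` (group letters follow `design.group_labels`).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n, r = design.n_features, design.n_replicates
    a, b = design.group_labels
    samples = design.sample_names
    features = [f"feat{i + 1:05d}" for i in range(n)]

    # disjoint planted index sets
    planted = rng.choice(
        n, size=design.n_exclusive_a + design.n_exclusive_b + design.n_differential,
        replace=False)
    idx_ea = planted[: design.n_exclusive_a]
    idx_eb = planted[design.n_exclusive_a: design.n_exclusive_a + design.n_exclusive_b]
    idx_d = planted[design.n_exclusive_a + design.n_exclusive_b:]

    lam = design.base_lambda
    boost = max(5.0, lam * design.effect_multiplier)

    counts = rng.poisson(lam, size=(n, 2 * r))
    zeros = rng.random((n, 2 * r)) < design.zero_inflation_pi
    counts[zeros] = 0

    truth = pd.Series("null", index=features, name="truth")

    def present(n_rows, cols):
        """Structurally present block: pi = 0 and count forced >= 1."""
        block = rng.poisson(boost, size=(n_rows, len(cols)))
        block[block == 0] = 1
        return block

    acols, bcols = list(range(r)), list(range(r, 2 * r))
    counts[idx_ea[:, None], acols] = present(len(idx_ea), acols)
    counts[idx_ea[:, None], bcols] = 0
    counts[idx_eb[:, None], bcols] = present(len(idx_eb), bcols)
    counts[idx_eb[:, None], acols] = 0
    truth.iloc[idx_ea] = f"exclusive_{a}"
    truth.iloc[idx_eb] = f"exclusive_{b}"

    # differential: present in both groups, lambda fold-change in the up group
    half = len(idx_d) // 2
    for rows, up in ((idx_d[:half], a), (idx_d[half:], b)):
        if len(rows) == 0:
            continue
        upcols = acols if up == a else bcols
        downcols = bcols if up == a else acols
        counts[rows[:, None], upcols] = present(len(rows), upcols)
        down = rng.poisson(lam, size=(len(rows), len(downcols)))
        down[down == 0] = 1
        counts[rows[:, None], downcols] = down
        truth.iloc[rows] = f"differential_{up}_up"

    frame = pd.DataFrame(counts, index=features, columns=samples)
    return frame, truth
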