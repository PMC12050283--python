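"""GMPR normalization and EMD permutation testing of eccDNA count matrices.

Zero-inflated count matrices defeat total-count and median-of-ratios
normalization, so size factors follow GMPR (geometric mean of pairwise
ratios): for samples i, j the ratio r_ij is the median of c_ki / c_kj over
features k non-zero in both, and s_i is the geometric mean of r_ij over
partners j, rescaled so the factors have geometric mean 1.

Each feature's between-group difference is scored with the 1-D earth
mover's distance between the groups' normalized counts — the integral of
|ECDF_A - ECDF_B| over the value axis, computed exactly (no binning).
Significance comes from a label-permutation null pooled across features
(all distinct non-identity unordered splits when few exist; a 2v2 design
has 2), with an add-one p estimator and Benjamini-Hochberg q-values.
Features with q below the threshold are classified `exclusive` when raw
counts are positive in every replicate of one group and zero in every
replicate of the other, otherwise `differential` toward the group with
the higher mean normalized count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, gmean


class NoSharedFeaturesError(ValueError):
    """A sample shares no non-zero feature with any other sample."""


class DegenerateDesignError(ValueError):
    """Fewer than two distinct label splits exist."""


@dataclass
class SizeFactors:
    factors: pd.Series  # one positive real per sample, geometric mean 1
    n_shared: pd.DataFrame  # pairwise shared-feature counts

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


def gmpr_size_factors(counts: pd.DataFrame) -> SizeFactors:
    """GMPR size factors of a features x samples count matrix."""
    if counts.shape[1] < 2:
        raise ValueError("GMPR needs at least two samples")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    c = counts.to_numpy(dtype=float)
    samples = list(counts.columns)
    n = len(samples)
    shared = np.zeros((n, n), dtype=int)
    raw = np.empty(n)
    for i in range(n):
        ratios = []
        partners = 0
        for j in range(n):
            mask = (c[:, i] > 0) & (c[:, j] > 0)
            shared[i, j] = int(mask.sum())
            if shared[i, j] > 0:
                # the self-comparison contributes a median ratio of 1,
                # exactly as in the reference GMPR; with it the size
                # factor of an equal-composition sample is proportional
                # to its sequencing depth
                ratios.append(np.median(c[mask, i] / c[mask, j]))
                if j != i:
                    partners += 1
        if partners == 0:
            raise NoSharedFeaturesError(
                f"sample {samples[i]!r} shares no non-zero feature with any other sample")
        raw[i] = gmean(ratios)
    factors = raw / gmean(raw)
    return SizeFactors(
        pd.Series(factors, index=samples, name="size_factor"),
        pd.DataFrame(shared, index=samples, columns=samples),
    )


def normalize_counts(counts: pd.DataFrame,
                     size_factors: SizeFactors | None = None) -> pd.DataFrame:
    sf = size_factors or gmpr_size_factors(counts)
    return counts / sf.factors


def emd_score(values_a, values_b) -> float:
    """Exact 1-D earth mover's distance between two samples.

    The integral over x of |ECDF_A(x) - ECDF_B(x)|; for equal group sizes
    this is the mean absolute difference of the sorted values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    xs = np.sort(np.concatenate([a, b]))
    a_sorted, b_sorted = np.sort(a), np.sort(b)
    fa = np.searchsorted(a_sorted, xs[:-1], side="right") / a.size
    fb = np.searchsorted(b_sorted, xs[:-1], side="right") / b.size
    return float(np.sum(np.abs(fa - fb) * np.diff(xs)))


def _group_columns(groups: pd.Series) -> tuple[list, list, str, str]:
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ga, gb = labels
    cols_a = [s for s in groups.index if groups[s] == ga]
    cols_b = [s for s in groups.index if groups[s] == gb]
    return cols_a, cols_b, ga, gb


def _all_splits(n_samples: int, n_a: int):
    """All distinct unordered assignments of n_a sample slots to group A."""
    seen = set()
    for comb in combinations(range(n_samples), n_a):
        key = comb
        if n_samples - n_a == n_a:
            rest = tuple(sorted(set(range(n_samples)) - set(comb)))
            key = min(comb, rest)
        if key not in seen:
            seen.add(key)
            yield comb


def permutation_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    size_factors: SizeFactors | None = None,
) -> pd.DataFrame:
    """Per-feature EMD with pooled-permutation p and BH q values.

    The null pools EMD scores over every feature and every non-identity
    label split (all distinct splits when fewer than `n_perm` exist,
    otherwise `n_perm` random ones drawn with `seed`).
    p = (1 + #null >= observed) / (1 + #null).
    """
    groups = groups.loc[counts.columns]
    cols_a, cols_b, _, _ = _group_columns(groups)
    sf = size_factors or gmpr_size_factors(counts)
    norm = normalize_counts(counts, sf)
    x = norm.to_numpy(dtype=float)
    order = list(counts.columns)
    idx_a = [order.index(s) for s in cols_a]
    n_samples, n_a = len(order), len(idx_a)

    observed = np.array([
        emd_score(row[idx_a], np.delete(row, idx_a)) for row in x
    ])

    all_splits = list(_all_splits(n_samples, n_a))
    identity = tuple(sorted(idx_a))
    null_splits = [s for s in all_splits
                   if tuple(sorted(s)) != identity
                   and tuple(sorted(set(range(n_samples)) - set(s))) != identity]
    if not null_splits:
        raise DegenerateDesignError(
            "fewer than two distinct label splits; permutation null undefined")
    if len(null_splits) > n_perm:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(null_splits), size=n_perm, replace=False)
        null_splits = [null_splits[i] for i in sorted(keep)]

    pool = []
    for split in null_splits:
        ia = list(split)
        for row in x:
            pool.append(emd_score(row[ia], np.delete(row, ia)))
    pool = np.sort(np.asarray(pool))
    n_null = pool.size
    n_ge = n_null - np.searchsorted(pool, observed, side="left")
    p = (1.0 + n_ge) / (1.0 + n_null)
    q = false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {"emd": observed, "p": p, "q": q}, index=counts.index)


CLASS_LABELS = ("exclusive", "differential", "not_significant")


def classify_features(
    counts: pd.DataFrame,
    groups: pd.Series,
    results: pd.DataFrame,
    size_factors: SizeFactors | None = None,
    q_threshold: float = 0.05,
) -> pd.Series:
    """Class labels per feature given EMD results.

    q >= threshold -> `not_significant`; otherwise `exclusive_<G>` when
    raw counts are positive in every replicate of group G and zero in
    every replicate of the other; otherwise `differential_<G>_up` toward
    the group with the higher mean normalized count.
    """
    groups = groups.loc[counts.columns]
    cols_a, cols_b, ga, gb = _group_columns(groups)
    norm = normalize_counts(counts, size_factors)
    labels = []
    for feat in counts.index:
        if results.loc[feat, "q"] >= q_threshold:
            labels.append("not_significant")
            continue
        raw_a = counts.loc[feat, cols_a].to_numpy()
        raw_b = counts.loc[feat, cols_b].to_numpy()
        if (raw_a > 0).all() and (raw_b == 0).all():
            labels.append(f"exclusive_{ga}")
        elif (raw_b > 0).all() and (raw_a == 0).all():
            labels.append(f"exclusive_{gb}")
        else:
            mean_a = norm.loc[feat, cols_a].mean()
            mean_b = norm.loc[feat, cols_b].mean()
            up = ga if mean_a >= mean_b else gb
            labels.append(f"differential_{up}_up")
    return pd.Series(labels, index=counts.index, name="class_label")


class DifferentialAbundance:
    """EMD differential-abundance model over a 2-group count matrix.

    Parameters
    ----------
    counts : features x samples non-negative integer DataFrame.
    groups : sample -> group label Series covering every column, 2 groups.
    """

    def __init__(self, counts: pd.DataFrame, groups: pd.Series):
        missing = [s for s in counts.columns if s not in groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        self.counts = counts
        self.groups = groups.loc[counts.columns]
        _group_columns(self.groups)

    def fit(self, n_perm: int = 1000, seed: int = 0,
            q_threshold: float = 0.05) -> "DifferentialAbundanceResults":
        sf = gmpr_size_factors(self.counts)
        results = permutation_test(
            self.counts, self.groups, n_perm=n_perm, seed=seed, size_factors=sf)
        labels = classify_features(
            self.counts, self.groups, results, sf, q_threshold)
        frame = results.copy()
        frame["class_label"] = labels
        return DifferentialAbundanceResults(self, sf, frame, q_threshold)


class DifferentialAbundanceResults:
    """Fitted per-feature EMD scores, q-values and class labels."""

    def __init__(self, model: DifferentialAbundance, size_factors: SizeFactors,
                 frame: pd.DataFrame, q_threshold: float):
        self.model = model
        self.size_factors = size_factors
        self.frame = frame
        self.q_threshold = q_threshold

    @property
    def n_significant(self) -> int:
        return int((self.frame["class_label"] != "not_significant").sum())

    def class_counts(self) -> pd.Series:
        return self.frame["class_label"].value_counts()

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["class_label"] != "not_significant"]

    def summary(self) -> str:
        lines = [
            "EMD differential abundance",
            f"  features:            {len(self.frame)}",
            f"  samples:             {len(self.model.counts.columns)} "
            f"({dict(self.model.groups.value_counts())})",
            f"  q threshold:         {self.q_threshold}",
            f"  significant:         {self.n_significant}",
            "  size factors:        "
            + ", ".join(f"{s}={v:.3f}" for s, v in self.size_factors.factors.items()),
            "  class counts:",
        ]
        for label, count in self.class_counts().items():
            lines.append(f"    {label:24s} {count}")
        return "\n".join(lines)
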