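"""Inferential layer: permutation test on between-sex mean distances,
Cohen's d, one-way ANOVA with R^2, Pearson correlation, and ICC(3,k).

The permutation test asks whether the Euclidean distance between the male
and female mean vectors of a feature matrix is larger than expected under
random assignment of specimens to sexes: sex labels are shuffled without
replacement, the distance is recomputed each replicate, and the add-one
p-value (count of permuted distances >= observed, plus one, over B + 1)
is reported, so p is never exactly zero.  The accompanying effect size is
Cohen's d computed on the projection scores along the observed sex axis —
the same univariate reduction used for SShD/SCoD scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dimorphism import FeatureMatrix, build_axis, project_scores

__all__ = [
    "PermutationResult",
    "AnovaResult",
    "IccResult",
    "permutation_distance_test",
    "cohens_d",
    "anova_oneway",
    "pearson_r",
    "icc_3k",
]


@dataclass
class PermutationResult:
    observed_distance: float
    n_permutations: int
    p_value: float
    cohens_d: float
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "observed_distance": self.observed_distance,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "cohens_d_projection": self.cohens_d,
            "seed": self.seed,
        }


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    R2: float
    cohens_d: float

    def to_json_dict(self) -> dict:
        return {
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "R2": self.R2,
            "cohens_d": self.cohens_d,
        }


@dataclass
class IccResult:
    icc_3k: float
    k: int
    n: int


def _split_groups(values, labels) -> tuple[np.ndarray, np.ndarray, str, str]:
    """Split into (first, second) groups with labels sorted, so F precedes M
    and d is oriented male minus female."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    g1 = values[labels == levels[0]]
    g2 = values[labels == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    return g1, g2, levels[0], levels[1]


def cohens_d(values, labels) -> float:
    """Standardized mean difference (second group minus first, groups taken
    in sorted label order, so F/M labels give male minus female) divided by
    the pooled standard deviation with n1 + n2 - 2 denominator."""
    g1, g2, *_ = _split_groups(values, labels)
    n1, n2 = len(g1), len(g2)
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (
        n1 + n2 - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation; d undefined")
    return float((g2.mean() - g1.mean()) / np.sqrt(pooled_var))


def anova_oneway(values, labels) -> AnovaResult:
    """Classical one-way ANOVA for two groups with R^2 and Cohen's d.

    F = t^2 of the pooled two-sample t statistic; R^2 = SS_between /
    SS_total; df = (1, n - 2).
    """
    g1, g2, *_ = _split_groups(values, labels)
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total sum of squares")
    ss_between = len(g1) * (g1.mean() - grand) ** 2 + len(g2) * (
        g2.mean() - grand
    ) ** 2
    F, p = sps.f_oneway(g1, g2)
    n = len(values)
    try:
        d = cohens_d(values, labels)
    except ValueError:
        d = float("inf") if g1.mean() != g2.mean() else 0.0
    return AnovaResult(
        F=float(F),
        df1=1,
        df2=n - 2,
        p=float(p),
        R2=float(ss_between / ss_total),
        cohens_d=d,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def permutation_distance_test(
    X: FeatureMatrix, n_perm: int = 10000, seed: int = 0
) -> PermutationResult:
    """Permutation test on the distance between sex-specific mean vectors.

    The null distribution is generated by shuffling the sex labels of the
    rows without replacement and recomputing the between-mean distance for
    each of ``n_perm`` replicates (vectorized).  p is the add-one
    proportion of permuted distances >= observed.  Cohen's d is computed
    on the projection scores along the observed female-to-male axis.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X.validate_for_axis()
    sexes = X.sex_array
    male = sexes == "M"
    n = len(sexes)
    n_m = int(male.sum())
    n_f = n - n_m
    vals = X.values

    fm = vals[~male].mean(axis=0)
    mm = vals[male].mean(axis=0)
    observed = float(np.linalg.norm(mm - fm))

    rng = np.random.default_rng(seed)
    # B x n male-indicator matrix: each row a label shuffle without replacement
    order = rng.random((n_perm, n)).argsort(axis=1)
    perm_male = order < n_m
    col_sums = vals.sum(axis=0)
    male_sums = perm_male.astype(float) @ vals
    perm_mm = male_sums / n_m
    perm_fm = (col_sums - male_sums) / n_f
    perm_dist = np.linalg.norm(perm_mm - perm_fm, axis=1)

    p = (int((perm_dist >= observed - 1e-12).sum()) + 1) / (n_perm + 1)

    axis = build_axis(X)
    scores = project_scores(X, axis)["score"].to_numpy()
    try:
        d = cohens_d(scores, sexes)
    except ValueError:
        # point-mass groups: mean difference with zero pooled spread
        d = float("inf")
    return PermutationResult(
        observed_distance=observed,
        n_permutations=n_perm,
        p_value=p,
        cohens_d=d,
        seed=seed,
    )


def icc_3k(ratings) -> IccResult:
    """Intraclass correlation ICC(3,k): two-way mixed model, consistency,
    average measures, (BMS - EMS) / BMS.

    ``ratings`` is an n-stimuli x k-raters matrix (array or DataFrame);
    the design must be complete — incomplete designs (each rater scoring a
    random subset) must be subset to complete cases by the caller, never
    silently imputed here.
    """
    R = np.asarray(
        ratings.values if isinstance(ratings, pd.DataFrame) else ratings,
        dtype=float,
    )
    if R.ndim != 2:
        raise ValueError("ratings must be a 2-D stimulus x rater matrix")
    n, k = R.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 stimuli and 2 raters")
    if np.isnan(R).any():
        raise ValueError(
            "ratings matrix has missing cells; subset to a complete design first"
        )
    grand = R.mean()
    ss_rows = k * ((R.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((R.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((R - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms == 0:
        raise ValueError("zero between-stimulus variance; ICC undefined")
    return IccResult(icc_3k=float((bms - ems) / bms), k=k, n=n)
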