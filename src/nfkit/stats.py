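"""Inferential layer: one-way repeated-measures ANOVA with partial eta-squared,
Bonferroni pairwise tests, Pearson brain-behavior correlation, and the
a-priori noncentral-F sample-size computation.

The RM-ANOVA is the classical within-subject decomposition for one factor
with k levels over n subjects:

    SS_error = SS_total − SS_subjects − SS_condition
    F = MS_condition / MS_error,  df = (k−1, (n−1)(k−1))
    η²p = F·df1 / (F·df1 + df2)

Sample size follows the within-factors convention of a-priori RM power
analysis: noncentrality λ = f²·N·m·ε/(1−ρ) with df1 = (m−1)ε and
df2 = (N−1)(m−1)ε, where f is Cohen's f, m the number of repeated
measurements, ρ the assumed correlation among them, and ε the nonsphericity
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from nfkit.core import ParameterError


@dataclass
class AnovaResult:
    """F, degrees of freedom, p, and partial eta-squared for one within factor."""

    F: float
    df_effect: float
    df_error: float
    p: float
    eta2p: float = field(init=False)
    epsilon: float = 1.0  # sphericity correction applied to the p-value (1 = none)

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ParameterError("F must be non-negative")
        self.eta2p = partial_eta_squared(self.F, self.df_effect, self.df_error)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_adj: float
    zero_variance: bool = False


@dataclass
class PowerSpec:
    """A-priori power-analysis inputs for a one-way RM design."""

    f: float = 0.25          # Cohen's f
    alpha: float = 0.05
    power: float = 0.85
    m: int = 3               # repeated measurements
    rho: float = 0.5         # assumed correlation among repeated measures
    epsilon: float = 1.0     # nonsphericity coefficient

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ParameterError("effect size f must be positive")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ParameterError("target power must be in (0, 1)")
        if self.m < 2:
            raise ParameterError("need at least 2 repeated measurements")
        if not 0 <= self.rho < 1:
            raise ParameterError("rho must be in [0, 1)")
        if not 1.0 / (self.m - 1) < self.epsilon <= 1:
            raise ParameterError("epsilon must be in (1/(m-1), 1]")


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        values = data.to_numpy(dtype=float)
        labels = [str(c) for c in data.columns]
    else:
        values = np.asarray(data, dtype=float)
        labels = [f"c{j}" for j in range(values.shape[1])] if values.ndim == 2 else []
    if values.ndim != 2:
        raise ParameterError("data must be an (n_subjects, k_conditions) matrix")
    if np.isnan(values).any():
        raise ParameterError("missing cells are not allowed (no imputation)")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ParameterError("need at least 2 subjects and 2 conditions")
    return values, labels


def rm_anova(data, sphericity_correction: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on an (n subjects × k conditions) matrix.

    With ``sphericity_correction=True`` a Greenhouse-Geisser epsilon scales
    the degrees of freedom of the p-value (F and η²p are unchanged).
    """
    x, _ = _as_matrix(data)
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_subjects = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_condition = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_error = ss_total - ss_subjects - ss_condition
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_error = ss_error / df2
    tiny = 1e-12 * max(ss_total, 1.0)  # guard: all-identical columns give SS ≈ 0
    if ms_error <= tiny:
        F = 0.0 if ss_condition <= tiny else np.inf
    else:
        F = (ss_condition / df1) / ms_error
    eps = 1.0
    if sphericity_correction:
        eps = greenhouse_geisser_epsilon(x)
    p = float(st.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
    return AnovaResult(F=float(F), df_effect=df1, df_error=df2, p=p, epsilon=eps)


def greenhouse_geisser_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser nonsphericity estimate from the condition covariance."""
    x = np.asarray(x, dtype=float)
    k = x.shape[1]
    S = np.cov(x, rowvar=False)
    C = np.eye(k) - np.ones((k, k)) / k
    D = C @ S @ C
    num = np.trace(D) ** 2
    den = (k - 1) * np.trace(D @ D)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """η²p = F·df1 / (F·df1 + df2)."""
    if df1 <= 0 or df2 <= 0:
        raise ParameterError("degrees of freedom must be positive")
    if F < 0:
        raise ParameterError("F must be non-negative")
    return float(F * df1 / (F * df1 + df2))


def bonferroni_pairwise(data, labels: Sequence[str] | None = None) -> list[PairwiseResult]:
    """Paired two-sided t-tests for all condition pairs, Bonferroni-adjusted.

    A zero-variance difference (identical paired columns) has no defined t;
    it is reported non-significant (p = 1) with ``zero_variance=True``.
    """
    x, inferred = _as_matrix(data)
    labels = list(labels) if labels is not None else inferred
    k = x.shape[1]
    n_pairs = k * (k - 1) // 2
    results = []
    for i, j in combinations(range(k), 2):
        diff = x[:, i] - x[:, j]
        if np.allclose(diff.std(ddof=1), 0):
            results.append(
                PairwiseResult(
                    pair=(labels[i], labels[j]),
                    mean_diff=float(diff.mean()),
                    t=0.0,
                    df=len(diff) - 1,
                    p_raw=1.0,
                    p_adj=1.0,
                    zero_variance=True,
                )
            )
            continue
        t, p = st.ttest_rel(x[:, i], x[:, j])
        results.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                mean_diff=float(diff.mean()),
                t=float(t),
                df=len(diff) - 1,
                p_raw=float(p),
                p_adj=float(min(1.0, p * n_pairs)),
            )
        )
    return results


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("zero variance in x or y")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def rm_anova_power(n: int, spec: PowerSpec) -> float:
    """Power of the within-factors RM-ANOVA F-test at N subjects."""
    if n < 2:
        return 0.0
    lam = spec.f**2 * n * spec.m * spec.epsilon / (1.0 - spec.rho)
    df1 = (spec.m - 1) * spec.epsilon
    df2 = (n - 1) * (spec.m - 1) * spec.epsilon
    fcrit = st.f.isf(spec.alpha, df1, df2)
    return float(st.ncf.sf(fcrit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, max_n: int = 10_000) -> int:
    """Smallest N whose RM-ANOVA power reaches the target."""
    for n in range(2, max_n + 1):
        if rm_anova_power(n, spec) >= spec.power:
            return n
    raise ParameterError(f"target power {spec.power} unreachable below N = {max_n}")
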