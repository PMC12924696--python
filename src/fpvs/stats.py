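"""Group-level inference: repeated-measures ANOVA with sphericity
correction and effect sizes, FDR-corrected post-hocs, default-prior Bayes
factors, split-half reliability, dependent-correlation comparison, and
effect-size / sample-size conversion.

The RM-ANOVA is a classical balanced (split-plot) decomposition written
directly against marginal means; it handles any number of within-subject
factors plus an optional between-subject factor. Bayes factors follow the
default-prior (Cauchy on standardized effects) construction with Monte
Carlo integration over the scale hyperparameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import logsumexp

__all__ = [
    "AnovaTable",
    "BayesResult",
    "CorrelationComparison",
    "EffectSizeReport",
    "rm_anova",
    "fdr_adjust",
    "paired_contrasts",
    "bayes_rm_anova",
    "split_half_reliability",
    "compare_dependent_correlations",
    "effect_size_and_power",
]


@dataclass
class AnovaTable:
    """Per-effect F, degrees of freedom, p, partial eta squared, epsilon."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}")
        return row.iloc[0]

    def __repr__(self) -> str:  # pragma: no cover
        return self.table.to_string(index=False)


@dataclass
class BayesResult:
    """BF10 per tested effect with Monte Carlo error."""

    bf10: dict[str, float]
    error: dict[str, float]      # relative Monte Carlo error per effect
    iterations: int

    def __post_init__(self) -> None:
        for name, bf in self.bf10.items():
            if not bf > 0:
                raise ValueError(f"BF10 for {name!r} must be positive")


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    r12: float
    n: int
    fisher_z_statistic: float
    p: float

    def __post_init__(self) -> None:
        for r in (self.r1, self.r2, self.r12):
            if not -1 <= r <= 1:
                raise ValueError("correlations must lie in [-1, 1]")
        if self.n < 4:
            raise ValueError("n must be >= 4")


@dataclass
class EffectSizeReport:
    partial_eta_sq: float
    cohens_f: float
    alpha: float
    power: float
    n_required: int
    achieved_power: float = float("nan")


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------

def _center(a: np.ndarray, axis: int) -> np.ndarray:
    return a - a.mean(axis=axis, keepdims=True)


def _effect_array(d: np.ndarray, axes: tuple[int, ...],
                  keep_axes: tuple[int, ...]) -> np.ndarray:
    """Marginal-mean array over ``keep_axes`` with centering applied along
    ``axes`` (a subset of keep_axes)."""
    drop = tuple(i for i in range(d.ndim) if i not in keep_axes)
    a = d.mean(axis=drop) if drop else d.copy()
    # axis indices shift after the mean; recompute positions
    remaining = [i for i in range(d.ndim) if i in keep_axes]
    for ax in axes:
        a = _center(a, remaining.index(ax))
    return a


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
    between: str | None = None,
    sphericity_alpha: float = 0.05,
) -> AnovaTable:
    """Balanced repeated-measures (split-plot) ANOVA.

    ``data`` is long format; replicate rows per (subject, cell) are averaged
    first. Every subject must contribute every within-factor cell, and with
    a between factor the groups must be equal-sized. Greenhouse-Geisser
    epsilon is computed for every within effect with numerator df > 1 and
    applied to the p-value when Mauchly's test rejects sphericity at
    ``sphericity_alpha``. Partial eta squared is
    ``SS_effect / (SS_effect + SS_error)``.
    """
    cols = [subject] + within + ([between] if between else [])
    agg = data.groupby(cols, observed=True)[dv].mean().reset_index()

    w_levels = {f: sorted(agg[f].unique()) for f in within}
    subjects = sorted(agg[subject].unique())
    if between:
        group_of = agg.groupby(subject, observed=True)[between].first()
        groups = sorted(group_of.unique())
        subj_by_group = {g: sorted(group_of[group_of == g].index) for g in groups}
        sizes = {g: len(s) for g, s in subj_by_group.items()}
        if len(set(sizes.values())) != 1:
            raise ValueError(f"unbalanced groups: {sizes}")
        n_per = next(iter(sizes.values()))
        b = len(groups)
    else:
        groups = ["_all"]
        subj_by_group = {"_all": subjects}
        n_per = len(subjects)
        b = 1
    if n_per < 2:
        raise ValueError("need at least 2 subjects per group")

    shape = (b, n_per) + tuple(len(w_levels[f]) for f in within)
    d = np.full(shape, np.nan)
    lookup = agg.set_index(cols)[dv]
    for gi, g in enumerate(groups):
        for si, s in enumerate(subj_by_group[g]):
            for cell in itertools.product(*(w_levels[f] for f in within)):
                key = (s, *cell) if not between else (s, *cell, g)
                try:
                    d[(gi, si) + tuple(
                        w_levels[f].index(c) for f, c in zip(within, cell)
                    )] = lookup.loc[key]
                except KeyError as exc:
                    raise ValueError(f"missing cell for subject {s}: {cell}") from exc
    if np.isnan(d).any():
        raise ValueError("design has missing cells")

    axis_b, axis_s = 0, 1
    w_axes = {f: 2 + i for i, f in enumerate(within)}
    n_total = d.size

    def ss_of(arr: np.ndarray) -> float:
        return float(n_total / arr.size * np.sum(arr ** 2))

    # error terms -----------------------------------------------------------
    # subjects within groups (error for between effects)
    a_subj = _effect_array(d, axes=(axis_s,), keep_axes=(axis_b, axis_s))
    ss_subj = ss_of(a_subj)
    df_subj = b * (n_per - 1)

    def within_error(v_axes: tuple[int, ...]) -> tuple[float, float]:
        keep = (axis_b, axis_s) + v_axes
        a = _effect_array(d, axes=(axis_s,) + v_axes, keep_axes=keep)
        dfe = b * (n_per - 1)
        for ax in v_axes:
            dfe *= d.shape[ax] - 1
        return ss_of(a), dfe

    # effect terms ----------------------------------------------------------
    factor_axes = {**w_axes}
    if between:
        factor_axes[between] = axis_b
    factor_names = ([between] if between else []) + within

    rows = []
    for r in range(1, len(factor_names) + 1):
        for combo in itertools.combinations(factor_names, r):
            axes = tuple(factor_axes[f] for f in combo)
            a = _effect_array(d, axes=axes, keep_axes=axes)
            ss = ss_of(a)
            df_num = 1.0
            for ax in axes:
                df_num *= d.shape[ax] - 1
            v_axes = tuple(ax for ax in axes if ax >= 2)
            if v_axes:
                ss_err, df_err = within_error(v_axes)
            else:
                ss_err, df_err = ss_subj, df_subj
            if df_err <= 0:
                raise ValueError("singular design: no error degrees of freedom")
            if ss_err <= 0:
                if ss > 1e-12:
                    raise ValueError(
                        "singular design: zero error sum of squares"
                    )
                f_val = 0.0  # no effect, no error: report F = 0
            else:
                f_val = (ss / df_num) / (ss_err / df_err)
            eps = np.nan
            p = stats.f.sf(f_val, df_num, df_err)
            if v_axes and df_num > 1:
                eps, mauchly_p = _gg_epsilon(d, v_axes, b, n_per)
                if mauchly_p < sphericity_alpha:
                    p = stats.f.sf(f_val, df_num * eps, df_err * eps)
            rows.append({
                "effect": "*".join(combo),
                "F": f_val,
                "df_num": df_num,
                "df_den": float(df_err),
                "p": p,
                "partial_eta_sq": ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
                "epsilon": eps,
            })
    return AnovaTable(pd.DataFrame(rows))


def _gg_epsilon(
    d: np.ndarray, v_axes: tuple[int, ...], b: int, n_per: int
) -> tuple[float, float]:
    """Greenhouse-Geisser epsilon and Mauchly p for a within effect."""
    keep = (0, 1) + v_axes
    drop = tuple(i for i in range(d.ndim) if i not in keep)
    m = d.mean(axis=drop) if drop else d
    # flatten within cells -> (b, n, prod levels)
    m = m.reshape(b, n_per, -1)
    centered = m - m.mean(axis=1, keepdims=True)
    flat = centered.reshape(b * n_per, -1)
    s = flat.T @ flat / (b * (n_per - 1))

    contrast = None
    for ax in v_axes:
        h = linalg.helmert(d.shape[ax], full=False)
        contrast = h if contrast is None else np.kron(contrast, h)
    e = contrast @ s @ contrast.T
    k = e.shape[0]
    tr = np.trace(e)
    tr2 = np.trace(e @ e)
    eps = (tr ** 2) / (k * tr2) if tr2 > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / k, 1.0))

    # Mauchly's sphericity test (chi-square approximation)
    sign, logdet = np.linalg.slogdet(e)
    if sign <= 0 or tr <= 0:
        return eps, 0.0
    log_w = logdet - k * np.log(tr / k)
    n_e = b * (n_per - 1)
    factor = n_e - (2 * k ** 2 + k + 2) / (6.0 * k)
    chi2 = -factor * log_w
    dof = k * (k + 1) / 2.0 - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    return eps, p


# --------------------------------------------------------------------------
# FDR and post-hoc contrasts
# --------------------------------------------------------------------------

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def paired_contrasts(
    cell_values: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Two-tailed paired t-tests with joint BH-FDR adjustment.

    ``cell_values`` maps a condition label to a per-participant vector (all
    the same length and participant order). A zero-variance nonzero
    difference leaves t undefined and is flagged in the ``error`` column.
    """
    rows = []
    for a, b in comparisons:
        x, y = np.asarray(cell_values[a], float), np.asarray(cell_values[b], float)
        if len(x) != len(y):
            raise ValueError(f"unequal lengths for {a} vs {b}")
        if len(x) < 2:
            raise ValueError("need at least 2 paired observations")
        diff = x - y
        n = len(diff)
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                rows.append({"a": a, "b": b, "t": 0.0, "df": n - 1,
                             "p": 1.0, "error": None})
            else:
                rows.append({"a": a, "b": b, "t": np.nan, "df": n - 1,
                             "p": np.nan, "error": "zero-variance difference"})
            continue
        t = diff.mean() / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), n - 1)
        rows.append({"a": a, "b": b, "t": float(t), "df": n - 1,
                     "p": float(p), "error": None})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    return out


# --------------------------------------------------------------------------
# Bayes factors
# --------------------------------------------------------------------------

def _orthonormal_codes(labels: pd.Series) -> np.ndarray:
    """Centered orthonormal (Helmert) codes for a categorical column."""
    levels = sorted(labels.unique())
    h = linalg.helmert(len(levels), full=False)  # (l-1, l)
    idx = labels.map({lev: i for i, lev in enumerate(levels)}).to_numpy()
    return h.T[idx]  # (n, l-1)


def _log_marginal(y: np.ndarray, blocks: list[np.ndarray],
                  g: np.ndarray) -> float:
    """log m(y | g) up to a g-independent constant.

    Model: y = mu 1 + sum_j X_j b_j + e with b_j ~ N(0, g_j sigma^2 I),
    flat prior on mu, Jeffreys on sigma^2. Marginalizing b, mu, sigma^2:
    m(y|g) prop |V|^-1/2 (1'V^-1 1)^-1/2 Q^-(n-1)/2 with
    V = I + sum g_j X_j X_j' and Q the V^-1 residual quadratic form.
    """
    n = len(y)
    v = np.eye(n)
    for gj, x in zip(g, blocks):
        v += gj * (x @ x.T)
    c, low = linalg.cho_factor(v, lower=True)
    logdet = 2 * np.sum(np.log(np.diag(c)))
    ones = np.ones(n)
    vi_y = linalg.cho_solve((c, low), y)
    vi_1 = linalg.cho_solve((c, low), ones)
    s11 = ones @ vi_1
    q = y @ vi_y - (ones @ vi_y) ** 2 / s11
    return -0.5 * logdet - 0.5 * np.log(s11) - 0.5 * (n - 1) * np.log(q)


def _mc_log_marginal(
    y: np.ndarray,
    blocks: list[np.ndarray],
    scales: list[float],
    iterations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte Carlo average of m(y|g) over the g-priors.

    Each g_j ~ InverseGamma(1/2, r_j^2 / 2) (a Cauchy(r_j) prior on the
    standardized effect scale). Returns (log mean, relative MC error).
    """
    logs = np.empty(iterations)
    r2 = np.array(scales) ** 2
    for i in range(iterations):
        gam = rng.gamma(0.5, 2.0 / r2)
        g = 1.0 / gam
        logs[i] = _log_marginal(y, blocks, g)
    log_mean = logsumexp(logs) - np.log(iterations)
    w = np.exp(logs - log_mean)
    rel_err = float(w.std(ddof=1) / np.sqrt(iterations))
    return float(log_mean), rel_err


def bayes_rm_anova(
    data: pd.DataFrame,
    dv: str,
    effects: list[str],
    subject: str,
    iterations: int = 10000,
    seed: int = 0,
    r_fixed: float = 0.5,
    r_random: float = 1.0,
) -> BayesResult:
    """Default-prior Bayes factors for within/between effects.

    For each tested effect (a column of ``data``; interactions as
    ``"A*B"``), BF10 compares the model {subject + effect} against the
    subject-only null, under Cauchy priors of scale ``r_fixed`` on
    standardized fixed effects and ``r_random`` on subject effects,
    integrated by Monte Carlo. Deterministic given ``seed``.
    """
    agg_cols = [subject] + sorted(
        {f for e in effects for f in e.split("*")}
    )
    table = data.groupby(agg_cols, observed=True)[dv].mean().reset_index()
    y = table[dv].to_numpy(dtype=float)
    y = y - y.mean()
    subj_codes = _orthonormal_codes(table[subject])

    rng = np.random.default_rng(seed)
    log_null, err_null = _mc_log_marginal(
        y, [subj_codes], [r_random], iterations, rng
    )

    bf10: dict[str, float] = {}
    err: dict[str, float] = {}
    for eff in effects:
        parts = eff.split("*")
        x = None
        for pcol in parts:
            codes = _orthonormal_codes(table[pcol])
            if x is None:
                x = codes
            else:
                x = np.einsum("ni,nj->nij", x, codes).reshape(len(table), -1)
        rng_eff = np.random.default_rng(
            seed + 1 + sum(ord(c) for c in eff)  # stable across interpreter runs
        )
        log_full, err_full = _mc_log_marginal(
            y, [subj_codes, x], [r_random, r_fixed], iterations, rng_eff
        )
        bf10[eff] = float(np.exp(log_full - log_null))
        err[eff] = float(np.hypot(err_full, err_null))
    return BayesResult(bf10=bf10, error=err, iterations=iterations)


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------

def split_half_reliability(
    odd_trial_values: np.ndarray, even_trial_values: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between odd- and even-trial estimates."""
    x = np.asarray(odd_trial_values, float)
    y = np.asarray(even_trial_values, float)
    if len(x) != len(y):
        raise ValueError("halves must be paired per participant")
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one half")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def compare_dependent_correlations(
    r1: float, r2: float, r12: float, n: int
) -> CorrelationComparison:
    """Fisher-Z test for two dependent correlations with no shared variable.

    The two correlations come from the same participants; ``r12`` is the
    cross-correlation between the paired measures and is used as the
    (approximate) correlation between the two Fisher-transformed
    estimates:

        Z = (z1 - z2) / sqrt(2 (1 - r12) / (n - 3))

    With r12 = 0 this reduces to the independent two-correlation Z test.
    """
    for r in (r1, r2, r12):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("n too small (need >= 4)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(2.0 * (1.0 - r12) / (n - 3))
    if se == 0:
        raise ValueError("degenerate cross-correlation r12 = 1")
    z_stat = (z1 - z2) / se
    p = 2 * stats.norm.sf(abs(z_stat))
    return CorrelationComparison(r1, r2, r12, n, float(z_stat), float(p))


# --------------------------------------------------------------------------
# effect size and power
# --------------------------------------------------------------------------

def effect_size_and_power(
    partial_eta_sq: float | None = None,
    f: float | None = None,
    alpha: float = 0.05,
    power: float = 0.95,
    m_levels: int = 2,
    rho: float = 0.5,
    epsilon: float = 1.0,
) -> EffectSizeReport:
    """Convert effect sizes and find the required n for a within-factor
    repeated-measures ANOVA.

    ``f = sqrt(eta2 / (1 - eta2))``. The required sample size is the
    smallest N for which the noncentral-F power reaches ``power`` under the
    repeated-measures convention ``lambda = f^2 N m epsilon / (1 - rho)``
    with numerator df ``(m - 1) epsilon`` and denominator df
    ``(N - 1)(m - 1) epsilon``.
    """
    if (partial_eta_sq is None) == (f is None):
        raise ValueError("give exactly one of partial_eta_sq or f")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if partial_eta_sq is not None:
        if not 0 <= partial_eta_sq < 1:
            raise ValueError("partial eta squared must lie in [0, 1)")
        f = float(np.sqrt(partial_eta_sq / (1.0 - partial_eta_sq)))
    else:
        if f < 0:
            raise ValueError("f must be >= 0")
        partial_eta_sq = f ** 2 / (1.0 + f ** 2)

    def power_at(n: int) -> float:
        lam = f ** 2 * n * m_levels * epsilon / (1.0 - rho)
        df1 = (m_levels - 1) * epsilon
        df2 = (n - 1) * (m_levels - 1) * epsilon
        if df2 <= 0:
            return 0.0
        fcrit = stats.f.isf(alpha, df1, df2)
        return float(stats.ncf.sf(fcrit, df1, df2, lam))

    n_req = 2
    achieved = power_at(n_req)
    if f > 0:
        while achieved < power and n_req < 100000:
            n_req += 1
            achieved = power_at(n_req)
    else:
        n_req = 0
        achieved = float("nan")
    return EffectSizeReport(
        partial_eta_sq=float(partial_eta_sq),
        cohens_f=float(f),
        alpha=alpha,
        power=power,
        n_required=n_req,
        achieved_power=achieved,
    )
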