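"""Univariate and multivariate screening of compounds across origin groups.

Per-compound one-way fixed-effects ANOVA supplies the p < 0.05 filter that
selects discriminant-analysis inputs; one-way MANOVA (Wilks' lambda with
Rao's F approximation, Pillai's trace with its standard F approximation)
tests the joint group effect; observed power and required-sample-size
calculations use the noncentral F distribution with the plug-in
noncentrality estimate lambda = F * df1 (the convention of mainstream GLM
software, which is biased but matches the published "observed power").

No multiplicity correction is applied to the per-compound filter by default
— the reference analysis reports raw per-compound F tests — but a
Bonferroni option is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .table_io import GroupSummaryTable, SampleTable

logger = logging.getLogger(__name__)


def sig_code_from_p(p: float) -> str:
    """Star convention: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class AnovaRow:
    """One compound's one-way ANOVA result across groups."""

    compound: str
    f_value: float
    df_between: int
    df_within: int
    p_value: float | None
    sig_code: str
    degenerate: bool = False


def _group_blocks(samples: SampleTable) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Group labels, concentration matrix, and integer group index per row."""
    groups = samples.groups
    gidx = np.array([groups.index(g) for g in samples.df["group"]])
    x = samples.conc.to_numpy(dtype=float)
    return groups, x, gidx


def anova_per_compound(samples: SampleTable) -> list[AnovaRow]:
    """One-way fixed-effects ANOVA for every compound, in input order.

    A compound identical in every sample (zero between- and within-group
    variance) gets F = 0, p = 1 and a degenerate flag; zero within-group
    variance with real group differences gets F = inf, p = 0.
    """
    groups, x, gidx = _group_blocks(samples)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    n = len(samples)
    g = len(groups)
    dfb, dfw = g - 1, n - g
    if dfw <= 0:
        raise ValueError("no within-group degrees of freedom")
    counts = np.bincount(gidx, minlength=g).astype(float)
    rows: list[AnovaRow] = []
    for j, name in enumerate(samples.compounds):
        v = x[:, j]
        gm = np.array([v[gidx == k].mean() for k in range(g)])
        ssb = float(np.sum(counts * (gm - v.mean()) ** 2))
        ssw = float(np.sum((v - gm[gidx]) ** 2))
        if ssw <= 0 and ssb <= 0:
            rows.append(AnovaRow(name, 0.0, dfb, dfw, 1.0, "ns", degenerate=True))
            continue
        if ssw <= 0:
            rows.append(AnovaRow(name, math.inf, dfb, dfw, 0.0, "***", degenerate=True))
            continue
        f = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f, dfb, dfw))
        rows.append(AnovaRow(name, f, dfb, dfw, p, sig_code_from_p(p)))
    return rows


def rows_from_summary(summary: GroupSummaryTable) -> list[AnovaRow]:
    """AnovaRows carrying the summary table's printed F and star codes.

    p-values are not printed in the reference table, so ``p_value`` is None;
    :func:`filter_significant` understands the star codes at the standard
    thresholds.
    """
    g = len(summary.groups)
    n = sum(summary.n[gr] for gr in summary.groups)
    rows = []
    for c in summary.compounds:
        rows.append(
            AnovaRow(
                compound=c.name,
                f_value=float("nan") if c.f_value is None else c.f_value,
                df_between=g - 1,
                df_within=n - g,
                p_value=None,
                sig_code=c.sig_code or "ns",
            )
        )
    return rows


_CODE_ALPHA = {"***": 0.001, "**": 0.01, "*": 0.05, "ns": math.inf}


def filter_significant(
    rows: Sequence[AnovaRow], alpha: float = 0.05, bonferroni: bool = False
) -> list[str]:
    """Compounds significant at ``alpha``, input order preserved.

    Rows without a numeric p-value are judged by their star code, which only
    supports the standard thresholds 0.05 / 0.01 / 0.001.
    """
    if bonferroni and rows:
        alpha = alpha / len(rows)
    kept = []
    for row in rows:
        if row.p_value is not None:
            if row.p_value < alpha:
                kept.append(row.compound)
        else:
            if alpha not in (0.05, 0.01, 0.001) and alpha < 1:
                raise ValueError(
                    "star codes only support alpha in {0.05, 0.01, 0.001}; "
                    "supply numeric p-values"
                )
            if alpha >= 1 or _CODE_ALPHA[row.sig_code] <= alpha:
                kept.append(row.compound)
    if not kept:
        logger.warning("filter_significant: no compound passed alpha=%g", alpha)
    return kept


# ---------------------------------------------------------------------------
# MANOVA


@dataclass
class ManovaResult:
    """One-way MANOVA statistics from the eigenvalues of W^-1 B."""

    eigenvalues: np.ndarray
    wilks_lambda: float
    wilks_f: float
    wilks_df: tuple[float, float]
    wilks_p: float
    pillai_trace: float
    pillai_f: float
    pillai_df: tuple[float, float]
    pillai_p: float
    observed_power_wilks: float
    observed_power_pillai: float
    n_obs: int
    n_groups: int
    n_vars: int
    dropped: list[str] = field(default_factory=list)


def scatter_matrices(samples: SampleTable, compounds: Sequence[str] | None = None):
    """Within-group (W) and between-group (B) scatter matrices."""
    sub = samples.subset(compounds) if compounds is not None else samples
    groups, x, gidx = _group_blocks(sub)
    grand = x.mean(axis=0)
    p = x.shape[1]
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for k in range(len(groups)):
        xk = x[gidx == k]
        d = xk - xk.mean(axis=0)
        w += d.T @ d
        diff = (xk.mean(axis=0) - grand)[:, None]
        b += len(xk) * (diff @ diff.T)
    return w, b


def manova(
    samples: SampleTable,
    compounds: Sequence[str] | None = None,
    alpha: float = 0.05,
    drop_degenerate: bool = True,
) -> ManovaResult:
    """One-way MANOVA on the given compound subset.

    Compounds constant across all samples carry no information and make the
    within-group scatter singular; they are dropped with a logged notice
    when ``drop_degenerate`` is set. A still-singular W raises ``ValueError``
    directing the caller to the tolerance screen.
    """
    names = list(compounds) if compounds is not None else samples.compounds
    dropped = []
    if drop_degenerate:
        conc = samples.conc
        for name in list(names):
            if float(conc[name].var()) == 0.0:
                names.remove(name)
                dropped.append(name)
        if dropped:
            logger.info("manova: dropped constant compounds %s", dropped)
    if not names:
        raise ValueError("no non-constant compounds left for MANOVA")
    w, b = scatter_matrices(samples, names)
    n = len(samples)
    g = len(samples.groups)
    p = len(names)
    if n - g < p:
        raise ValueError(
            f"within-group df {n - g} < {p} variables: W is singular; "
            "filter collinear compounds (tolerance screen) first"
        )
    try:
        eig = np.linalg.eigvals(np.linalg.solve(w, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group scatter; filter collinear compounds first"
        ) from exc
    eig = np.sort(np.clip(eig.real, 0.0, None))[::-1]
    s = min(p, g - 1)
    eig = eig[: max(s, 1)]

    wilks = float(np.prod(1.0 / (1.0 + eig)))
    pillai = float(np.sum(eig / (1.0 + eig)))

    # Rao's F approximation for Wilks' lambda
    df1_w = p * (g - 1)
    denom = p**2 + (g - 1) ** 2 - 5
    t = math.sqrt((p**2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    wu = n - 1 - (p + g) / 2.0
    df2_w = wu * t - (df1_w - 2) / 2.0
    lam_t = wilks ** (1.0 / t) if wilks > 0 else 0.0
    wilks_f = ((1 - lam_t) / lam_t) * (df2_w / df1_w) if lam_t > 0 else math.inf
    wilks_p = float(stats.f.sf(wilks_f, df1_w, df2_w)) if math.isfinite(wilks_f) else 0.0

    # standard F approximation for Pillai's trace
    m = (abs(p - g + 1) - 1) / 2.0
    n0 = (n - g - p - 1) / 2.0
    df1_p = s * (2 * m + s + 1)
    df2_p = s * (2 * n0 + s + 1)
    if pillai >= s:
        pillai_f, pillai_p = math.inf, 0.0
    else:
        pillai_f = ((2 * n0 + s + 1) / (2 * m + s + 1)) * (pillai / (s - pillai))
        pillai_p = float(stats.f.sf(pillai_f, df1_p, df2_p))

    return ManovaResult(
        eigenvalues=eig,
        wilks_lambda=wilks,
        wilks_f=wilks_f,
        wilks_df=(df1_w, df2_w),
        wilks_p=wilks_p,
        pillai_trace=pillai,
        pillai_f=pillai_f,
        pillai_df=(df1_p, df2_p),
        pillai_p=pillai_p,
        observed_power_wilks=observed_power(wilks_f, df1_w, df2_w, alpha),
        observed_power_pillai=observed_power(pillai_f, df1_p, df2_p, alpha),
        n_obs=n,
        n_groups=g,
        n_vars=p,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Power


def observed_power(f: float, df1: float, df2: float, alpha: float = 0.05) -> float:
    """Post-hoc power at the observed F, plug-in noncentrality lambda = F*df1.

    This is the convention of mainstream GLM software; it is a biased
    estimate (the observed F stands in for the true effect) and is reported
    here because the reference analysis quotes it.
    """
    if not math.isfinite(f):
        return 1.0
    if df2 <= 0 or df1 <= 0:
        return float("nan")
    lam = f * df1
    crit = stats.f.isf(alpha, df1, df2)
    if lam == 0:
        return alpha
    return float(stats.ncf.sf(crit, df1, df2, lam))


@dataclass
class PowerSpec:
    """Prospective power-analysis inputs for a one-way design.

    effect_size is the root-mean-square standardized effect (RMSSE): the
    root mean square of the standardized group-mean deviations,
    sqrt(sum_g ((mu_g - mu)/sigma)^2 / (g - 1)).
    """

    effect_size: float
    n_groups: int
    alpha: float = 0.05
    target_power: float = 0.8
    weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.target_power < 1:
            raise ValueError("alpha and target_power must be in (0,1)")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.n_groups < 2:
            raise ValueError("need at least two groups")
        if self.weights is not None:
            if len(self.weights) != self.n_groups or min(self.weights) <= 0:
                raise ValueError("weights must be positive, one per group")


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Integer allocation of `total` by weights, each group >= 1."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    base = np.maximum(np.floor(w * total).astype(int), 1)
    while base.sum() < total:
        base[int(np.argmax(w * total - base))] += 1
    while base.sum() > total:
        over = np.where(base > 1)[0]
        base[over[int(np.argmin((w * total - base)[over]))]] -= 1
    return base.tolist()


def power_at_n(spec: PowerSpec, total_n: int) -> float:
    """Noncentral-F power of the overall test at a given total sample size.

    Noncentrality lambda = total_n * (g-1)/g * RMSSE^2, i.e. equal-magnitude
    standardized deviations spread over the allocated groups.
    """
    g = spec.n_groups
    df1 = g - 1
    df2 = total_n - g
    if df2 < 1:
        return 0.0
    lam = total_n * (g - 1) / g * spec.effect_size**2
    crit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, max_n: int = 1_000_000) -> int:
    """Smallest total n whose noncentral-F power reaches ``target_power``.

    The allocation weights only constrain the minimum feasible total
    (every group needs >= 1 sample and df2 >= 1); power is evaluated on the
    total via :func:`power_at_n`, which is monotone in n.
    """
    weights = spec.weights or [1.0] * spec.n_groups
    n = spec.n_groups + 1
    while n <= max_n:
        _allocate(n, weights)  # raises/validates feasibility
        if power_at_n(spec, n) >= spec.target_power:
            return n
        n += 1
    raise ValueError(
        f"target power {spec.target_power} unreachable below n={max_n} "
        f"at effect size {spec.effect_size}"
    )


# ---------------------------------------------------------------------------
# Correlations


def pairwise_correlations(
    samples: SampleTable, compounds: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-sided p-values (t transform).

    Zero-variance compounds yield NaN rows/columns (flagged via a logged
    warning) rather than an error.
    """
    names = list(compounds) if compounds is not None else samples.compounds
    x = samples.conc[names].to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation p-values")
    sd = x.std(axis=0, ddof=1)
    degenerate = [names[j] for j in np.nonzero(sd == 0)[0]]
    if degenerate:
        logger.warning("pairwise_correlations: zero-variance compounds %s", degenerate)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    rdf = pd.DataFrame(r, index=names, columns=names)
    pdf = pd.DataFrame(p, index=names, columns=names)
    return rdf, pdf
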