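"""Canonical linear discriminant analysis and correlation-matrix PCA.

The discriminant side follows the classical canonical formulation: the
discriminant functions are the eigenvectors of W^-1 B (W = pooled
within-group scatter, B = between-group scatter), scaled so each canonical
score has unit pooled within-group variance. The model reports the
eigenvalue chain with canonical correlations sqrt(lambda/(1+lambda)) and
percent-of-variance shares, Bartlett's sequential chi-square tests of the
residual Wilks' lambda, the structure matrix (pooled within-group
correlations of each variable with each function, whose per-variable maxima
are the "discrimination power"), and group centroids in canonical space.

Variables are pre-screened for collinearity by tolerance (1 - R^2 of each
variable on the other candidates, computed within pooled groups); variables
below the minimum tolerance (default 0.001, the convention of mainstream
discriminant software) are excluded iteratively, lowest first.

Classification assigns each case to the nearest group centroid in canonical
space (equal priors by default), which equals the Mahalanobis rule in raw
space when the pooled covariance is nonsingular. Leave-one-out
cross-validation refits the canonical functions without each case in turn.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .screening import scatter_matrices
from .table_io import SampleTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tolerance screening


def _pooled_within_centered(samples: SampleTable, names: Sequence[str]) -> np.ndarray:
    groups = samples.groups
    x = samples.conc[list(names)].to_numpy(dtype=float)
    gl = samples.df["group"].to_numpy()
    out = x.astype(float).copy()
    for g in groups:
        mask = gl == g
        out[mask] -= out[mask].mean(axis=0)
    return out


def _tolerances(xw: np.ndarray) -> np.ndarray:
    """1 - R^2 of each column on the others, on group-centered data."""
    n, p = xw.shape
    tol = np.empty(p)
    for j in range(p):
        y = xw[:, j]
        ssy = float(y @ y)
        if ssy == 0.0:
            tol[j] = 0.0
            continue
        if p == 1:
            tol[j] = 1.0
            continue
        others = np.delete(xw, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        tol[j] = max(float(resid @ resid) / ssy, 0.0)
    return tol


def tolerance_screen(
    samples: SampleTable,
    compounds: Sequence[str] | None = None,
    min_tol: float = 0.001,
) -> tuple[list[str], dict[str, float]]:
    """Iteratively exclude collinear variables by pooled within-group tolerance.

    Returns (kept, excluded) where ``excluded`` maps each removed variable
    to the tolerance it had when removed (0 for exact collinearity).
    """
    names = list(compounds) if compounds is not None else samples.compounds
    excluded: dict[str, float] = {}
    while True:
        if not names:
            raise ValueError("tolerance screen excluded every variable")
        xw = _pooled_within_centered(samples, names)
        tol = _tolerances(xw)
        worst = int(np.argmin(tol))
        if tol[worst] >= min_tol:
            return names, excluded
        excluded[names[worst]] = float(tol[worst])
        logger.info(
            "tolerance_screen: excluding %r (tolerance %.3g)", names[worst], tol[worst]
        )
        del names[worst]


# ---------------------------------------------------------------------------
# Canonical LDA


@dataclass
class LdaModel:
    """Fitted canonical discriminant model."""

    compounds: list[str]
    group_labels: list[str]
    group_sizes: dict[str, int]
    coef: np.ndarray                      # p x m, unit within-group score variance
    grand_mean: np.ndarray                # p, for score centering
    eigenvalues: np.ndarray               # m, descending
    canonical_corr: np.ndarray
    pct_variance: np.ndarray
    wilks_chain: list[tuple[float, float, int, float]]   # (lambda_k, chi2, df, p)
    structure: pd.DataFrame               # compounds x functions
    tolerances: dict[str, float]
    excluded: list[str]
    centroids: pd.DataFrame               # groups x functions
    priors: dict[str, float]

    @property
    def n_functions(self) -> int:
        return int(self.coef.shape[1])

    def transform(self, samples: SampleTable) -> pd.DataFrame:
        """Canonical scores of the given samples."""
        x = samples.conc[self.compounds].to_numpy(dtype=float)
        scores = (x - self.grand_mean) @ self.coef
        cols = [f"F{k + 1}" for k in range(self.n_functions)]
        return pd.DataFrame(scores, index=samples.df.index, columns=cols)

    def predict(self, samples: SampleTable) -> list[str]:
        """Nearest-centroid assignment in canonical space under the priors."""
        scores = self.transform(samples).to_numpy()
        cent = self.centroids.to_numpy()
        d2 = ((scores[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        logp = np.log([self.priors[g] for g in self.group_labels])
        crit = d2 - 2.0 * logp
        return [self.group_labels[i] for i in np.argmin(crit, axis=1)]


def fit_lda(
    samples: SampleTable,
    compounds: Sequence[str] | None = None,
    priors: str = "equal",
    min_tol: float = 0.001,
    screen: bool = True,
    allow_pinv: bool = False,
) -> LdaModel:
    """Fit canonical discriminant functions on the given compound subset.

    ``priors`` is "equal" (default) or "proportional". The pooled
    within-group scatter must be invertible on the (tolerance-screened)
    subset; ``allow_pinv=True`` explicitly enables a pseudo-inverse
    fallback for rank-deficient scatter instead of raising.
    """
    names = list(compounds) if compounds is not None else samples.compounds
    tolerances: dict[str, float] = {}
    excluded: list[str] = []
    if screen:
        kept, removed = tolerance_screen(samples, names, min_tol)
        excluded = list(removed)
        names = kept
        xw = _pooled_within_centered(samples, names)
        tolerances = dict(zip(names, _tolerances(xw)))
    w, b = scatter_matrices(samples, names)
    groups = samples.groups
    g = len(groups)
    n = len(samples)
    p = len(names)
    if g < 2:
        raise ValueError("need at least two groups")
    m = min(g - 1, p)

    try:
        # symmetric-definite generalized eigenproblem B v = lambda W v
        eigval, eigvec = linalg.eigh(b, w)
    except linalg.LinAlgError:
        if not allow_pinv:
            cond = np.linalg.cond(w)
            raise ValueError(
                f"singular pooled within-group scatter (cond={cond:.3g}) on "
                f"{names}; tighten the tolerance screen or pass allow_pinv=True"
            ) from None
        eigval, eigvec = np.linalg.eig(np.linalg.pinv(w) @ b)
        eigval, eigvec = eigval.real, eigvec.real
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        # rescale to v' W v = 1 where possible
        for k in range(eigvec.shape[1]):
            q = float(eigvec[:, k] @ w @ eigvec[:, k])
            if q > 0:
                eigvec[:, k] /= math.sqrt(q)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order][:m], 0.0, None)
    vec = eigvec[:, order][:, :m]
    # eigh returns v' W v = 1; rescale to unit pooled within-group *variance*
    coef = vec * math.sqrt(n - g)

    x = samples.conc[names].to_numpy(dtype=float)
    grand_mean = x.mean(axis=0)
    scores = (x - grand_mean) @ coef

    # orient each function so its largest-|structure| entry is positive
    structure = _structure_matrix(samples, names, scores)
    for k in range(m):
        col = structure[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coef[:, k] *= -1
            scores[:, k] *= -1
            structure[:, k] *= -1

    total = eigval.sum()
    pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    canon = np.sqrt(eigval / (1.0 + eigval))

    # Bartlett's sequential tests of residual discrimination
    chain: list[tuple[float, float, int, float]] = []
    scale = n - 1 - (p + g) / 2.0
    for k in range(m):
        lam_k = float(np.prod(1.0 / (1.0 + eigval[k:])))
        chi2 = -scale * math.log(lam_k) if lam_k > 0 else math.inf
        df = (p - k) * (g - 1 - k)
        pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
        chain.append((lam_k, chi2, df, pval))

    gl = samples.df["group"].to_numpy()
    sizes = {grp: int((gl == grp).sum()) for grp in groups}
    cent = np.vstack([scores[gl == grp].mean(axis=0) for grp in groups])
    fcols = [f"F{k + 1}" for k in range(m)]
    if priors == "equal":
        pri = {grp: 1.0 / g for grp in groups}
    elif priors == "proportional":
        pri = {grp: sizes[grp] / n for grp in groups}
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")

    return LdaModel(
        compounds=names,
        group_labels=groups,
        group_sizes=sizes,
        coef=coef,
        grand_mean=grand_mean,
        eigenvalues=eigval,
        canonical_corr=canon,
        pct_variance=pct,
        wilks_chain=chain,
        structure=pd.DataFrame(structure, index=names, columns=fcols),
        tolerances=tolerances,
        excluded=excluded,
        centroids=pd.DataFrame(cent, index=groups, columns=fcols),
        priors=pri,
    )


def _structure_matrix(
    samples: SampleTable, names: Sequence[str], scores: np.ndarray
) -> np.ndarray:
    """Pooled within-group correlations between variables and canonical scores."""
    xw = _pooled_within_centered(samples, names)
    gl = samples.df["group"].to_numpy()
    sw = scores.copy()
    for g in samples.groups:
        mask = gl == g
        sw[mask] -= sw[mask].mean(axis=0)
    n_minus_g = len(samples) - len(samples.groups)
    cov = xw.T @ sw / n_minus_g
    sd_x = np.sqrt((xw**2).sum(axis=0) / n_minus_g)
    sd_s = np.sqrt((sw**2).sum(axis=0) / n_minus_g)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / sd_x[:, None] / sd_s[None, :]
    return np.nan_to_num(corr, nan=0.0)


def discrimination_power(model: LdaModel) -> list[tuple[str, float]]:
    """Per-variable max |structure coefficient| across functions, descending.

    Ties are broken by the model's (input-table) variable order, so the
    ranking is deterministic.
    """
    power = model.structure.abs().max(axis=1)
    order = sorted(
        range(len(power)), key=lambda i: (-power.iloc[i], i)
    )
    return [(model.compounds[i], float(power.iloc[i])) for i in order]


# ---------------------------------------------------------------------------
# Classification


@dataclass
class ConfusionMatrix:
    """Counts of true vs predicted group, with per-group and overall rates (%)."""

    counts: pd.DataFrame
    method: str
    unclassifiable: int = 0

    @property
    def per_group_rate(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts), index=self.counts.index)
        return 100.0 * diag / self.counts.sum(axis=1)

    @property
    def overall_rate(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / float(self.counts.to_numpy().sum())


def classify(
    model: LdaModel, samples: SampleTable, method: str = "original"
) -> ConfusionMatrix:
    """Confusion matrix by resubstitution ("original") or "loocv".

    LOOCV refits the canonical functions without each case (same compound
    set, no re-screening) and classifies the held-out case. A fold whose
    removal leaves a group with fewer than 2 members is flagged and the case
    counted unclassifiable (it appears in no cell of its row).
    """
    groups = model.group_labels
    truth = samples.df["group"].to_numpy()
    counts = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    unclassifiable = 0
    if method == "original":
        pred = model.predict(samples)
        for t, pr in zip(truth, pred):
            counts.loc[t, pr] += 1
    elif method == "loocv":
        for i, sid in enumerate(samples.df.index):
            rest = SampleTable(samples.df.drop(index=sid))
            if min(rest.df["group"].value_counts()) < 2:
                logger.warning("loocv: fold %r leaves a group under 2 members", sid)
                unclassifiable += 1
                continue
            try:
                sub = fit_lda(
                    rest,
                    model.compounds,
                    priors="equal" if min(model.priors.values()) == max(model.priors.values()) else "proportional",
                    screen=False,
                )
            except ValueError:
                logger.warning("loocv: fold %r singular, case unclassifiable", sid)
                unclassifiable += 1
                continue
            one = SampleTable(samples.df.loc[[sid]])
            counts.loc[truth[i], sub.predict(one)[0]] += 1
    else:
        raise ValueError("method must be 'original' or 'loocv'")
    return ConfusionMatrix(counts=counts, method=method, unclassifiable=unclassifiable)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    """Eigendecomposition of the correlation (or covariance) matrix."""

    eigenvalues: np.ndarray
    loadings: pd.DataFrame        # variables x components (eigvec * sqrt(eigval))
    scores: pd.DataFrame          # samples x components
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    retained: int                 # Kaiser criterion: eigenvalue > 1
    dropped: list[str] = field(default_factory=list)


def fit_pca(
    samples: SampleTable,
    compounds: Sequence[str] | None = None,
    standardize: bool = True,
) -> PcaResult:
    """PCA of the correlation matrix (default) or covariance matrix.

    Constant variables are dropped with a warning. Components are retained
    by the Kaiser criterion (correlation-matrix eigenvalue > 1) and oriented
    so each component's largest-|loading| entry is positive.
    """
    names = list(compounds) if compounds is not None else samples.compounds
    if len(samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = samples.conc[names].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    dropped = [names[j] for j in np.nonzero(sd == 0)[0]]
    if dropped:
        logger.warning("fit_pca: dropping constant variables %s", dropped)
        keep = sd > 0
        x = x[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]
        sd = sd[keep]
    centered = x - x.mean(axis=0)
    z = centered / sd if standardize else centered
    mat = np.corrcoef(x, rowvar=False) if standardize else np.cov(x, rowvar=False)
    mat = np.atleast_2d(mat)
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        col = eigvec[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, k] *= -1
    loadings = eigvec * np.sqrt(eigval)
    scores = z @ eigvec
    pct = 100.0 * eigval / eigval.sum()
    cum = np.cumsum(pct)
    cols = [f"PC{k + 1}" for k in range(len(eigval))]
    return PcaResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(loadings, index=names, columns=cols),
        scores=pd.DataFrame(scores, index=samples.df.index, columns=cols),
        pct_variance=pct,
        cumulative_pct=cum,
        retained=int((eigval > 1.0).sum()),
        dropped=dropped,
    )
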