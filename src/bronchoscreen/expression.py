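"""Differential expression with donor random intercepts.

The study design repeatedly samples the same few donors, so per-gene
models carry a donor random intercept:

``y = X beta + u_donor + eps``, ``u ~ N(0, tau^2)``, ``eps ~ N(0, sigma^2)``.

Estimation is REML with the variance ratio ``gamma = tau^2 / sigma^2``
profiled out: for fixed gamma the marginal covariance per donor block is
``sigma^2 (I + gamma J)``, whose inverse square root is available in
closed form, so beta is a generalized-least-squares fit of transformed
data and the REML criterion is a one-dimensional function of gamma
(coarse log-grid scan plus bounded refinement; the tau = 0 boundary is
allowed and reduces the fit exactly to OLS).

Per-timepoint models regress on CSE dose, alcohol status and age; the
pooled model adds a days-treated covariate (numeric by default,
categorical weeks behind a flag). Covariates aliased with the rest of the
design (e.g. sex with only three donors) are dropped with a warning.
Coefficient p-values are Wald tests against a t reference with residual
degrees of freedom ``n - rank(X)`` (normal reference via ``use_t=False``),
and per-scope q-values come from the Benjamini-Hochberg step-up
procedure. DEGs are genes with q below the FDR level and |log2FC| above
``log2(min_fold)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

SCOPES = ("week1", "week2", "week3", "pooled")


@dataclass
class ExpressionStudy:
    """Normalized log2-scale expression matrix plus sample covariates.

    ``expr`` is genes x samples; ``samples`` is indexed by sample id with
    columns donor, age, alcohol, cse (0 or 3), weeks (1/2/3).
    """

    expr: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.samples.index):
            raise ValueError("expression columns must match sample-sheet rows")
        required = {"donor", "age", "alcohol", "cse", "weeks"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
        if self.samples[sorted(required)].isna().any().any():
            raise ValueError("missing covariates in sample sheet")


@dataclass
class DegCriteria:
    fdr: float = 0.05
    min_fold: float = 2.0

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")


@dataclass
class LmmFit:
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    sigma2: float
    tau2: float
    df_resid: int
    columns: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove columns linearly dependent on earlier ones (earlier wins)."""
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    tol = X.shape[0] * np.finfo(float).eps
    keep_idx: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j] / scale[j]
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > tol:
            basis = np.column_stack([basis, resid / norm])
            keep_idx.append(j)
    dropped = [names[i] for i in range(len(names)) if i not in keep_idx]
    if dropped:
        warnings.warn(f"dropping aliased design columns: {dropped}", stacklevel=3)
    return X[:, keep_idx], [names[i] for i in keep_idx], dropped


class _GroupDesign:
    """Precomputed donor-block structure shared across genes."""

    def __init__(self, X: np.ndarray, names: list[str], groups: np.ndarray):
        codes, uniq = pd.factorize(np.asarray(groups))
        if uniq.size < 2:
            raise ValueError("need >= 2 donor groups for a random intercept")
        order = np.argsort(codes, kind="stable")
        self.order = order
        self.X, self.names, self.dropped = _drop_aliased(X[order], list(names))
        if self.X.shape[1] == 0:
            raise ValueError("design matrix has no identifiable columns")
        self.codes = codes[order]
        self.sizes = np.bincount(self.codes)
        self.starts = np.concatenate([[0], np.cumsum(self.sizes)])
        self.n, self.p = self.X.shape

    def transform(self, M: np.ndarray, gamma: float) -> np.ndarray:
        """Apply the blockwise whitener (I + gamma J)^(-1/2) / row scale."""
        out = M.astype(float, copy=True)
        for g, m in enumerate(self.sizes):
            s, e = self.starts[g], self.starts[g + 1]
            a = (1.0 - 1.0 / np.sqrt(1.0 + m * gamma)) / m
            block = out[s:e]
            block -= a * block.sum(axis=0, keepdims=True)
        return out

    def logdet_v(self, gamma: float) -> float:
        return float(np.sum(np.log1p(self.sizes * gamma)))


def _reml_neglog(gd: _GroupDesign, y: np.ndarray, gamma: float) -> float:
    Xt = gd.transform(gd.X, gamma)
    yt = gd.transform(y[:, None], gamma)[:, 0]
    beta, res, rank, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    rss = float(((yt - Xt @ beta) ** 2).sum())
    if rss <= 0:
        rss = np.finfo(float).tiny
    xtx = Xt.T @ Xt
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    nmp = gd.n - gd.p
    return nmp * np.log(rss / nmp) + gd.logdet_v(gamma) + logdet_xtx


_GAMMA_GRID = np.concatenate([[0.0], np.logspace(-4, 4, 25)])


def _fit_gene(gd: _GroupDesign, y: np.ndarray, use_t: bool) -> LmmFit:
    crit = np.array([_reml_neglog(gd, y, g) for g in _GAMMA_GRID])
    best = int(np.argmin(crit))
    if best == 0:
        gamma_hat = 0.0
        # allow refinement just above zero in case the optimum is interior
        res = minimize_scalar(
            lambda lg: _reml_neglog(gd, y, 10.0**lg),
            bounds=(-8.0, np.log10(_GAMMA_GRID[1])),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if res.fun < crit[0] - 1e-10:
            gamma_hat = 10.0**res.x
    else:
        lo = _GAMMA_GRID[max(best - 1, 1)]
        hi = _GAMMA_GRID[min(best + 1, _GAMMA_GRID.size - 1)]
        if lo == hi:
            gamma_hat = lo
        else:
            res = minimize_scalar(
                lambda lg: _reml_neglog(gd, y, 10.0**lg),
                bounds=(np.log10(lo), np.log10(hi)),
                method="bounded",
                options={"xatol": 1e-6},
            )
            gamma_hat = 10.0**res.x
            if crit[best] < res.fun:
                gamma_hat = _GAMMA_GRID[best]

    Xt = gd.transform(gd.X, gamma_hat)
    yt = gd.transform(y[:, None], gamma_hat)[:, 0]
    xtx = Xt.T @ Xt
    beta = np.linalg.solve(xtx, Xt.T @ yt)
    rss = float(((yt - Xt @ beta) ** 2).sum())
    df = gd.n - gd.p
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    if use_t:
        pv = 2.0 * sps.t.sf(np.abs(tstat), df)
    else:
        pv = 2.0 * sps.norm.sf(np.abs(tstat))
    pv = np.where(np.isfinite(tstat) | (beta == 0), pv, 0.0)
    return LmmFit(
        beta=beta,
        se=se,
        pvalues=pv,
        sigma2=sigma2,
        tau2=gamma_hat * sigma2,
        df_resid=df,
        columns=list(gd.names),
        dropped=list(gd.dropped),
    )


def fit_random_intercept_lmm(
    y,
    X,
    groups,
    columns: list[str] | None = None,
    use_t: bool = True,
) -> LmmFit:
    """REML fit of a linear model with one random intercept per group.

    Parameters
    ----------
    y
        Response vector (one gene's expression across samples).
    X
        Fixed-effects design matrix (include the intercept column).
    groups
        Group (donor) label per sample; at least two distinct groups.
    columns
        Optional design column names, used in alias warnings.
    use_t
        Wald p-values against a t reference with ``n - rank(X)`` degrees
        of freedom (default), or the normal approximation when False.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2D with one row per element of y")
    names = columns or [f"x{i}" for i in range(X.shape[1])]
    gd = _GroupDesign(X, names, np.asarray(groups))
    return _fit_gene(gd, y[gd.order], use_t)


def _build_design(
    samples: pd.DataFrame, scope: str, days_coding: str
) -> tuple[np.ndarray, list[str], pd.Index]:
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if scope == "pooled":
        sub = samples
    else:
        week = int(scope.removeprefix("week"))
        sub = samples[samples["weeks"] == week]
    if sub["cse"].nunique() < 2:
        raise ValueError(f"scope {scope!r} does not include both CSE doses")
    cols = {
        "intercept": np.ones(len(sub)),
        "cse": (sub["cse"].to_numpy(dtype=float) > 0).astype(float),
        "alcohol": sub["alcohol"].to_numpy(dtype=float),
        "age": sub["age"].to_numpy(dtype=float),
    }
    if "sex" in sub.columns:
        sex = sub["sex"]
        cols["sex"] = (
            pd.factorize(sex)[0].astype(float) if sex.dtype == object else
            sex.to_numpy(dtype=float)
        )
    if scope == "pooled":
        if days_coding == "numeric":
            cols["days_treated"] = sub["weeks"].to_numpy(dtype=float) * 7.0
        elif days_coding == "categorical":
            for w in sorted(sub["weeks"].unique())[1:]:
                cols[f"weeks_{w}"] = (sub["weeks"] == w).to_numpy(dtype=float)
        else:
            raise ValueError("days_coding must be numeric|categorical")
    X = np.column_stack(list(cols.values()))
    return X, list(cols), sub.index


def differential_expression(
    study: ExpressionStudy,
    scope: str = "pooled",
    days_coding: str = "numeric",
    use_t: bool = True,
) -> pd.DataFrame:
    """Per-gene random-intercept LMM over one analysis scope.

    Returns a table with one row per gene: ``gene``, ``log2fc`` (the CSE
    coefficient), ``se``, ``p``, ``q`` (BH within scope), ``tau2``,
    ``sigma2``.
    """
    X, names, sample_idx = _build_design(study.samples, scope, days_coding)
    donors = study.samples.loc[sample_idx, "donor"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        gd = _GroupDesign(X, names, donors)
    if "cse" not in gd.names:
        raise ValueError("CSE coefficient aliased out of the design")
    cse_idx = gd.names.index("cse")
    mat = study.expr[sample_idx].to_numpy(dtype=float)

    rows = []
    for gi, gene in enumerate(study.expr.index):
        fit = _fit_gene(gd, mat[gi, gd.order], use_t)
        rows.append(
            {
                "gene": gene,
                "log2fc": fit.beta[cse_idx],
                "se": fit.se[cse_idx],
                "p": fit.pvalues[cse_idx],
                "tau2": fit.tau2,
                "sigma2": fit.sigma2,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table[["gene", "log2fc", "se", "p", "q", "tau2", "sigma2"]]


def select_degs(
    table: pd.DataFrame, criteria: DegCriteria | None = None
) -> tuple[set, set]:
    """Split a DEG table into up / down gene sets at the FDR + fold cut."""
    criteria = criteria or DegCriteria()
    criteria.validate()
    if table.empty:
        return set(), set()
    thr = np.log2(criteria.min_fold)
    sig = table["q"] < criteria.fdr
    up = set(table.loc[sig & (table["log2fc"] > thr), "gene"])
    down = set(table.loc[sig & (table["log2fc"] < -thr), "gene"])
    return up, down


def pca_qc(
    study: ExpressionStudy, residualize: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA of the gene-centered matrix for QC.

    With ``residualize=True`` donor-level structure (donor identity and
    the donor-constant age/alcohol covariates it absorbs) is projected out
    per gene before the decomposition, exposing the treatment signal.

    Returns (scores DataFrame samples x PCs, variance fractions).
    """
    mat = study.expr.to_numpy(dtype=float).T  # samples x genes
    if mat.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if residualize:
        donors = pd.get_dummies(study.samples["donor"]).to_numpy(dtype=float)
        proj = donors @ np.linalg.pinv(donors)
        mat = mat - proj @ mat
    centered = mat - mat.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("constant expression matrix: no variance to decompose")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(centered.shape[0], centered.shape[1])
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=study.expr.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, frac
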