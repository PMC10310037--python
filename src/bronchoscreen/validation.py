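"""Secondary-screen statistics: one-way ANOVA, Dunnett many-to-one
comparisons, and validated-hit classification.

Dunnett's procedure compares every treatment group against a shared
control using the pooled within-group variance from *all* groups. The
test statistics ``t_i = (mean_i - mean_0) / sqrt(s^2 (1/n_i + 1/n_0))``
are jointly multivariate t with an equicorrelation structure induced by
the shared control (``corr_ij = lambda_i lambda_j`` with
``lambda_i = sqrt(n_i / (n_i + n_0))``). Two-sided adjusted p-values are
tail probabilities of ``max_j |T_j|`` under that joint null, evaluated by
Monte-Carlo with a fixed seed (the draw is cached per group-size
structure); the single-comparison case reduces analytically to the pooled
two-sample t-test. Unequal group sizes are supported.

Raw (un-normalized) readouts are used throughout, matching how the
validation screen is analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pooled_variance: float  # within-group mean square, shared with Dunnett
    df_between: int
    df_within: int


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Ordinary one-way ANOVA over labelled groups.

    Every group needs at least two values; the within-group mean square is
    exposed for reuse as the Dunnett pooled variance.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        arrays[label] = arr
    n_total = sum(a.size for a in arrays.values())
    grand = np.concatenate(list(arrays.values())).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    mse = ss_within / df_w
    if mse == 0.0:
        f = 0.0 if ss_between == 0.0 else np.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_b) / mse
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, float(mse), df_b, df_w)


_MAXT_CACHE: dict[tuple, np.ndarray] = {}


def _null_max_abs_t(
    lambdas: tuple[float, ...], df: int, n_draws: int, seed: int
) -> np.ndarray:
    """Sorted Monte-Carlo sample of max_j |T_j| for the Dunnett null."""
    key = (lambdas, df, n_draws, seed)
    if key not in _MAXT_CACHE:
        rng = np.random.default_rng(seed)
        lam = np.array(lambdas)
        z0 = rng.standard_normal(n_draws)
        eps = rng.standard_normal((n_draws, lam.size))
        z = lam * z0[:, None] + np.sqrt(1.0 - lam**2) * eps
        s = np.sqrt(rng.chisquare(df, n_draws) / df)
        m = np.max(np.abs(z) / s[:, None], axis=1)
        m.sort()
        _MAXT_CACHE[key] = m
    return _MAXT_CACHE[key]


def dunnett_many_to_one(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    alpha: float = 0.05,
    n_draws: int = 200_000,
    seed: int = 12345,
) -> pd.DataFrame:
    """Dunnett two-sided many-to-one comparisons against a shared control.

    Returns a DataFrame with one row per treatment group: ``group``,
    ``mean_diff`` (treatment - control), ``t``, ``p_adj`` and
    ``significant`` at ``alpha``. For a single treatment group the
    adjusted p is the exact pooled two-sample t-test p; for k >= 2 it is
    estimated from a cached 200k-draw Monte-Carlo sample of the
    equicorrelated max-|t| null (accuracy ~1e-3).
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    treatments = [g for g in groups if g != control_label]
    if not treatments:
        raise ValueError("need at least one treatment group")
    anova = anova_oneway(groups)
    mse, df = anova.pooled_variance, anova.df_within

    ctrl = np.asarray(groups[control_label], dtype=float)
    n0 = ctrl.size
    rows = []
    lambdas = []
    tvals = []
    for g in treatments:
        arr = np.asarray(groups[g], dtype=float)
        diff = arr.mean() - ctrl.mean()
        se = np.sqrt(mse * (1.0 / arr.size + 1.0 / n0))
        if se == 0.0:
            if diff == 0.0:
                t = 0.0
            else:
                warnings.warn(
                    "zero pooled variance with unequal means; p = 0 reported",
                    stacklevel=2,
                )
                t = np.inf * np.sign(diff)
        else:
            t = diff / se
        lambdas.append(np.sqrt(arr.size / (arr.size + n0)))
        tvals.append(t)
        rows.append({"group": g, "mean_diff": float(diff), "t": float(t)})

    k = len(treatments)
    for i, row in enumerate(rows):
        t_abs = abs(tvals[i])
        if not np.isfinite(t_abs):
            p = 0.0
        elif k == 1:
            p = float(2.0 * sps.t.sf(t_abs, df))
        else:
            null = _null_max_abs_t(
                tuple(round(l, 9) for l in lambdas), df, n_draws, seed
            )
            # upper tail with add-one smoothing; never exactly 0
            exceed = null.size - np.searchsorted(null, t_abs, side="left")
            p = float((exceed + 1) / (null.size + 1))
        row["p_adj"] = min(p, 1.0)
        row["significant"] = row["p_adj"] < alpha
    return pd.DataFrame(rows)


def dunnett_from_table(
    table: pd.DataFrame,
    value_col: str,
    control_label: str,
    group_col: str = "group",
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Dunnett comparisons from a long-format (group, value) table."""
    groups = {
        str(g): sub[value_col].to_numpy(dtype=float)
        for g, sub in table.groupby(group_col, sort=False)
    }
    return dunnett_many_to_one(groups, control_label, alpha=alpha, **kwargs)


def classify_validated_hits(
    area: pd.DataFrame,
    mucin: pd.DataFrame,
    count: pd.DataFrame,
    nuclear: pd.DataFrame,
    alpha: float = 0.05,
    manual_exclusions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Combine per-readout Dunnett results into validated-hit categories.

    All four inputs are Dunnett result tables over the same compound
    groups (``group``, ``mean_diff``, ``p_adj``). A compound is

    * **Swell**-validated: significant area increase, no significant count
      decrease, no significant mucin increase;
    * **Mucus**-validated: significant mucin decrease, no significant
      nuclear-intensity decrease, no significant count decrease, no
      significant area decrease.

    Manual exclusions (visual-inspection flags) are applied last and
    recorded in the ``audit`` column.
    """
    frames = {"area": area, "mucin": mucin, "count": count, "nuclear": nuclear}
    merged = None
    for name, df in frames.items():
        sub = df[["group", "mean_diff", "p_adj"]].rename(
            columns={"mean_diff": f"{name}_diff", "p_adj": f"{name}_p"}
        )
        merged = sub if merged is None else merged.merge(sub, on="group", how="outer")
    if merged["area_p"].isna().any() or merged["mucin_p"].isna().any():
        raise ValueError("result sets do not cover the same compounds")

    def sig_up(p, d):
        return (p < alpha) & (d > 0)

    def sig_down(p, d):
        return (p < alpha) & (d < 0)

    swell = (
        sig_up(merged["area_p"], merged["area_diff"])
        & ~sig_down(merged["count_p"], merged["count_diff"])
        & ~sig_up(merged["mucin_p"], merged["mucin_diff"])
    )
    mucus = (
        sig_down(merged["mucin_p"], merged["mucin_diff"])
        & ~sig_down(merged["nuclear_p"], merged["nuclear_diff"])
        & ~sig_down(merged["count_p"], merged["count_diff"])
        & ~sig_down(merged["area_p"], merged["area_diff"])
    )
    rows = []
    excl = set(manual_exclusions or [])
    for cat, mask in (("Swell", swell), ("Mucus", mucus)):
        for _, r in merged[mask].iterrows():
            rows.append(
                {
                    "group": r["group"],
                    "category": cat,
                    "validated": r["group"] not in excl,
                    "audit": "manual_exclusion" if r["group"] in excl else "",
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "category", "validated", "audit"]
    ).sort_values(["category", "group"]).reset_index(drop=True)
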