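"""Primary-screen hit calling from MAD-based control thresholds.

A compound x concentration is a **swell hit** when, on its plate's
normalized scale,

* at least ``min_passing_replicates`` replicate wells exceed the 3%-CSE
  control median area fold change by ``effect_k`` control MADs,
* *all* usable replicates keep a spheroid count no lower than
  ``tox_k`` MADs below the 0%-CSE control count median (the 0% wells have
  the lower counts and serve as the healthy reference), and
* at least ``min_passing_replicates`` replicates do not raise the MUC5AC
  log2 fold change more than ``cross_k`` MADs above the 3%-control median
  (cross-readout filter).

A **mucus hit** mirrors this: the per-replicate effect clause requires the
MUC5AC log2FC to fall ``effect_k`` MADs below the 3%-control median *and*
the well's total nuclear intensity to stay within ``tox_k`` MADs of the
3%-control median (the 3% wells have the lower intensity); the count
toxicity clause is unchanged; the cross-readout filter rejects compounds
whose area fold change falls ``cross_k`` MADs below the 3%-control median.

Stating the effect threshold as a bare multiple of the MAD (fold change
above ``effect_k * MAD``) is degenerate: control fold changes center at 1,
so any MAD below 0.5 would pass nearly every well. The default
``centered`` interpretation therefore measures exceedance from the control
median; the bare-multiple reading remains available via
``interpretation="literal"``.
Effect inequalities are strict: a replicate exactly at an effect
threshold does not pass. The "within k MADs" toxicity
and cross-readout bounds are inclusive. Control statistics are always per
plate, never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import ROLE_COMPOUND, ROLE_CONTROL_0, ROLE_CONTROL_3, mad

MIN_CONTROL_WELLS = 4


class HitCallingError(ValueError):
    pass


@dataclass
class HitRuleParams:
    """Multipliers and replicate logic for the hit rules."""

    effect_k: float = 2.0
    tox_k: float = 3.0
    cross_k: float = 2.0
    min_passing_replicates: int = 2
    toxicity_sidedness: str = "one_sided_lower"  # or "two_sided"
    interpretation: str = "centered"  # or "literal"

    def validate(self) -> None:
        if self.effect_k <= 0 or self.tox_k <= 0 or self.cross_k <= 0:
            raise ValueError("MAD multipliers must be positive")
        if self.min_passing_replicates < 1:
            raise ValueError("min_passing_replicates must be >= 1")
        if self.toxicity_sidedness not in ("one_sided_lower", "two_sided"):
            raise ValueError("toxicity_sidedness must be one_sided_lower|two_sided")
        if self.interpretation not in ("centered", "literal"):
            raise ValueError("interpretation must be centered|literal")


def control_statistics(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-plate control medians and MADs used as hit-rule thresholds.

    From DMSO + 3% wells: area fold change, MUC5AC log2FC and total
    nuclear intensity; from DMSO + 0% wells: spheroid counts. Indexed by
    plate. Raises when a plate has fewer than four wells of a required
    control role; warns when a MAD is exactly zero (degenerate
    thresholds).
    """
    stats_rows = {}
    for plate, grp in normalized.groupby("plate", sort=False):
        row = {}
        for role, col, prefix in (
            (ROLE_CONTROL_3, "area_fold_change", "area_fc"),
            (ROLE_CONTROL_3, "mucin_log2fc", "mucin_l2fc"),
            (ROLE_CONTROL_3, "total_nuclear_intensity", "nuclear"),
            (ROLE_CONTROL_0, "spheroid_count", "count0"),
        ):
            vals = grp.loc[grp["role"] == role, col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < MIN_CONTROL_WELLS:
                raise HitCallingError(
                    f"plate {plate!r}: {vals.size} usable {role} wells for "
                    f"{col}; >= {MIN_CONTROL_WELLS} required"
                )
            row[f"{prefix}_median"] = float(np.median(vals))
            row[f"{prefix}_mad"] = mad(vals)
            if row[f"{prefix}_mad"] == 0.0:
                warnings.warn(
                    f"plate {plate!r}: zero MAD for {role}/{col}; "
                    "thresholds are degenerate",
                    stacklevel=2,
                )
        stats_rows[plate] = row
    return pd.DataFrame.from_dict(stats_rows, orient="index")


def _per_well_frame(normalized: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    comp = normalized[normalized["role"] == ROLE_COMPOUND].copy()
    missing = set(comp["plate"]) - set(stats.index)
    if missing:
        raise HitCallingError(f"no control statistics for plates {sorted(missing)}")
    return comp.join(stats, on="plate")


def _count_tox_ok(df: pd.DataFrame, params: HitRuleParams) -> pd.Series:
    lo = df["count0_median"] - params.tox_k * df["count0_mad"]
    ok = df["spheroid_count"] >= lo
    if params.toxicity_sidedness == "two_sided":
        ok &= df["spheroid_count"] <= df["count0_median"] + params.tox_k * df["count0_mad"]
    return ok


def _finalize(
    per_well: pd.DataFrame,
    category: str,
    effect_ok: pd.Series,
    well_usable: pd.Series,
    count_ok: pd.Series,
    nuclear_ok: pd.Series,
    cross_ok: pd.Series,
    params: HitRuleParams,
) -> pd.DataFrame:
    """Reduce per-well clause outcomes to per compound x concentration calls."""
    g = per_well.assign(
        _eff=effect_ok & well_usable,
        _usable=well_usable,
        _count=count_ok | ~well_usable,  # only usable wells constrain
        _nuc=nuclear_ok | ~well_usable,
        _cross=cross_ok & well_usable,
    ).groupby(["compound", "concentration"], sort=True)

    out = g.agg(
        usable_replicates=("_usable", "sum"),
        n_effect_pass=("_eff", "sum"),
        count_toxicity_pass=("_count", "all"),
        nuclear_toxicity_pass=("_nuc", "all"),
        n_cross_pass=("_cross", "sum"),
    ).reset_index()

    m = params.min_passing_replicates
    out["category"] = category
    out["effect_pass"] = out["n_effect_pass"] >= m
    out["cross_readout_pass"] = out["n_cross_pass"] >= m
    callable_ = out["usable_replicates"] >= m
    out["final_hit"] = (
        callable_
        & out["effect_pass"]
        & out["count_toxicity_pass"]
        & out["nuclear_toxicity_pass"]
        & out["cross_readout_pass"]
    )
    out.loc[~callable_, "category"] = "none"
    out.loc[~callable_, "final_hit"] = False
    cols = [
        "compound",
        "concentration",
        "category",
        "final_hit",
        "usable_replicates",
        "n_effect_pass",
        "effect_pass",
        "count_toxicity_pass",
        "nuclear_toxicity_pass",
        "n_cross_pass",
        "cross_readout_pass",
    ]
    return out[cols]


def _usable(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.Series:
    ok = ~df["manual_exclusion"].astype(bool) if "manual_exclusion" in df else True
    usable = np.isfinite(df[list(cols)]).all(axis=1)
    return usable & ok


def call_swell_hits(
    normalized: pd.DataFrame,
    stats: pd.DataFrame,
    params: HitRuleParams | None = None,
) -> pd.DataFrame:
    """Evaluate the swell (area-restoring) hit rule per compound x conc."""
    params = params or HitRuleParams()
    params.validate()
    df = _per_well_frame(normalized, stats)
    usable = _usable(
        df, ("area_fold_change", "spheroid_count", "mucin_log2fc")
    )
    if params.interpretation == "centered":
        thr = df["area_fc_median"] + params.effect_k * df["area_fc_mad"]
    else:  # bare MAD multiple, uncentered
        thr = params.effect_k * df["area_fc_mad"]
    effect_ok = df["area_fold_change"] > thr
    count_ok = _count_tox_ok(df, params)
    cross_ok = df["mucin_log2fc"] <= (
        df["mucin_l2fc_median"] + params.cross_k * df["mucin_l2fc_mad"]
    )
    nuclear_ok = pd.Series(True, index=df.index)  # not part of the swell rule
    return _finalize(
        df, "swell", effect_ok, usable, count_ok, nuclear_ok, cross_ok, params
    )


def call_mucus_hits(
    normalized: pd.DataFrame,
    stats: pd.DataFrame,
    params: HitRuleParams | None = None,
) -> pd.DataFrame:
    """Evaluate the mucus (MUC5AC-reducing) hit rule per compound x conc."""
    params = params or HitRuleParams()
    params.validate()
    df = _per_well_frame(normalized, stats)
    usable = _usable(
        df,
        (
            "area_fold_change",
            "spheroid_count",
            "mucin_log2fc",
            "total_nuclear_intensity",
        ),
    )
    if params.interpretation == "centered":
        thr = df["mucin_l2fc_median"] - params.effect_k * df["mucin_l2fc_mad"]
    else:
        thr = -params.effect_k * df["mucin_l2fc_mad"]
    nuclear_lo = df["nuclear_median"] - params.tox_k * df["nuclear_mad"]
    nuclear_ok = df["total_nuclear_intensity"] >= nuclear_lo
    if params.toxicity_sidedness == "two_sided":
        nuclear_ok &= df["total_nuclear_intensity"] <= (
            df["nuclear_median"] + params.tox_k * df["nuclear_mad"]
        )
    # joint per-replicate effect clause: mucin decrease AND healthy nuclei
    effect_ok = (df["mucin_log2fc"] < thr) & nuclear_ok
    count_ok = _count_tox_ok(df, params)
    cross_ok = df["area_fold_change"] >= (
        df["area_fc_median"] - params.cross_k * df["area_fc_mad"]
    )
    # nuclear intensity is audited inside the effect clause, not as a
    # separate all-replicates gate
    all_nuclear = pd.Series(True, index=df.index)
    return _finalize(
        df, "mucus", effect_ok, usable, count_ok, all_nuclear, cross_ok, params
    )


def consolidate_hits(
    swell_calls: pd.DataFrame,
    mucus_calls: pd.DataFrame,
    manual_exclusions: list[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Union of final hits across categories, with manual exclusions.

    ``manual_exclusions`` lists (compound, concentration) pairs flagged on
    visual inspection; matching hits stay in the table with
    ``final_hit=False`` and an ``audit`` note. Sorted by category then
    compound id; a dual-category compound appears once per category.
    """
    hits = pd.concat(
        [swell_calls[swell_calls["final_hit"]], mucus_calls[mucus_calls["final_hit"]]],
        ignore_index=True,
    )
    hits["audit"] = ""
    if manual_exclusions:
        excl = {(c, float(k)) for c, k in manual_exclusions}
        mask = [
            (row.compound, float(row.concentration)) in excl
            for row in hits.itertuples()
        ]
        hits.loc[mask, "final_hit"] = False
        hits.loc[mask, "audit"] = "manual_exclusion"
    return hits.sort_values(["category", "compound", "concentration"]).reset_index(
        drop=True
    )
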