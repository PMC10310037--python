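"""Plate- and donor-level normalization of well readouts.

Two schemes are used in the screening workflow:

* **Donor normalization** (characterization assays): each well readout is
  divided by the arithmetic mean of the untreated (0% CSE) control wells of
  the same donor x timepoint group, removing donor-to-donor scale
  differences.

* **Plate normalization** (primary screen): the well mean spheroid area is
  divided by the per-plate *median* of the DMSO + 3% CSE control wells
  (``area_fold_change``), and the well mean MUC5AC ratio is divided by the
  per-plate 3%-control median and log2-transformed (``mucin_log2fc``).
  Control wells are normalized alongside compound wells so the MAD
  thresholds used downstream live on the same scale.

The MAD here is the plain median absolute deviation; the Gaussian
consistency factor 1.4826 is applied only on request.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

ROLE_CONTROL_0 = "control_0pct"
ROLE_CONTROL_3 = "control_3pct"
ROLE_COMPOUND = "compound"

MIN_CONTROL_WELLS = 4


class NormalizationError(ValueError):
    """Raised when a control group required for normalization is missing."""


def mad(values: Sequence[float], scaled: bool = False) -> float:
    """Median absolute deviation of ``values``.

    Parameters
    ----------
    values
        Finite numbers; at least one is required.
    scaled
        Multiply by 1.4826 (consistency with the normal SD) when True.
        The default is the raw MAD.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise NormalizationError(
            "MAD requires at least one finite value (insufficient control wells)"
        )
    m = np.median(np.abs(arr - np.median(arr)))
    return float(m * 1.4826) if scaled else float(m)


def normalize_to_donor_control(
    table: pd.DataFrame,
    value_col: str,
    group_cols: Sequence[str] = ("donor", "timepoint"),
    role_col: str = "role",
    control_role: str = ROLE_CONTROL_0,
    out_col: str | None = None,
) -> pd.DataFrame:
    """Divide each well readout by its donor-group 0%-CSE control mean.

    Each ``group_cols`` group must contain at least one well with
    ``role == control_role``; the readout of every well in the group is
    divided by the arithmetic mean of those control wells.
    """
    out_col = out_col or f"{value_col}_donor_norm"
    out = table.copy()
    out[out_col] = np.nan
    for key, grp in table.groupby(list(group_cols), sort=False):
        ctrl = grp.loc[grp[role_col] == control_role, value_col]
        ctrl = ctrl[np.isfinite(ctrl)]
        if ctrl.empty:
            raise NormalizationError(
                f"group {key!r} has no {control_role} control wells"
            )
        out.loc[grp.index, out_col] = grp[value_col] / ctrl.mean()
    return out


def normalize_plate(
    table: pd.DataFrame,
    area_col: str = "mean_area",
    mucin_col: str = "mean_mucin_ratio",
    plate_col: str = "plate",
    role_col: str = "role",
) -> pd.DataFrame:
    """Per-plate control-median normalization of the two screen readouts.

    Adds ``area_fold_change`` (well mean area / plate median of the
    DMSO + 3% CSE control mean areas) and ``mucin_log2fc`` (log2 of the
    analogous MUC5AC-ratio quotient). Control wells are normalized too.

    Raises
    ------
    NormalizationError
        If a plate has fewer than four DMSO + 3% control wells, or a
        reference median is non-positive.
    """
    out = table.copy()
    out["area_fold_change"] = np.nan
    out["mucin_log2fc"] = np.nan
    for plate, grp in table.groupby(plate_col, sort=False):
        ctrl = grp[grp[role_col] == ROLE_CONTROL_3]
        if len(ctrl) < MIN_CONTROL_WELLS:
            raise NormalizationError(
                f"plate {plate!r} has {len(ctrl)} {ROLE_CONTROL_3} wells; "
                f">= {MIN_CONTROL_WELLS} required"
            )
        area_ref = float(np.nanmedian(ctrl[area_col]))
        if not area_ref > 0:
            raise NormalizationError(
                f"plate {plate!r}: non-positive reference median area {area_ref}"
            )
        mucin_ctrl = ctrl[mucin_col].to_numpy(dtype=float)
        if not np.nanmedian(mucin_ctrl) > 0:
            raise NormalizationError(
                f"plate {plate!r}: non-positive reference median mucin ratio"
            )
        # reference median taken on the log2 scale so that control log2FCs
        # are centered at exactly 0 (identical to the ratio median for odd
        # control counts; geometric middle-pair mean for even counts)
        with np.errstate(divide="ignore", invalid="ignore"):
            mucin_ref_log = float(np.nanmedian(np.log2(mucin_ctrl)))
            out.loc[grp.index, "area_fold_change"] = grp[area_col] / area_ref
            out.loc[grp.index, "mucin_log2fc"] = (
                np.log2(grp[mucin_col].to_numpy(dtype=float)) - mucin_ref_log
            )
    return out
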