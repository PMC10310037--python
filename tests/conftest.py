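import warnings

import numpy as np
import pandas as pd
import pytest

import bronchoscreen as bs


@pytest.fixture(scope="session")
def small_screen():
    """One simulated plate with planted effect classes, normalized."""
    params = bs.ScreenSimParams(n_compounds=40, seed=11)
    wells, truth = bs.simulate_screen(params)
    norm = bs.normalize_plate(wells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = bs.control_statistics(norm)
    return params, wells, truth, norm, stats


def make_stats(
    plate="P01",
    area_median=1.0,
    area_mad=0.1,
    mucin_median=0.0,
    mucin_mad=0.15,
    nuclear_median=1e6,
    nuclear_mad=5e4,
    count_median=40.0,
    count_mad=2.0,
) -> pd.DataFrame:
    """Hand-built per-plate control statistics for rule-level tests."""
    return pd.DataFrame(
        {
            "area_fc_median": [area_median],
            "area_fc_mad": [area_mad],
            "mucin_l2fc_median": [mucin_median],
            "mucin_l2fc_mad": [mucin_mad],
            "nuclear_median": [nuclear_median],
            "nuclear_mad": [nuclear_mad],
            "count0_median": [count_median],
            "count0_mad": [count_mad],
        },
        index=[plate],
    )


def make_compound_wells(
    fold_changes,
    counts=None,
    mucin_l2fc=None,
    nuclear=None,
    compound="C001",
    concentration=1.0,
    plate="P01",
) -> pd.DataFrame:
    """Replicate wells of one compound on one plate (normalized scale)."""
    n = len(fold_changes)
    return pd.DataFrame(
        {
            "plate": plate,
            "well": [f"A{i + 1}" for i in range(n)],
            "role": "compound",
            "compound": compound,
            "concentration": concentration,
            "replicate": range(1, n + 1),
            "area_fold_change": fold_changes,
            "spheroid_count": counts if counts is not None else [40.0] * n,
            "mucin_log2fc": mucin_l2fc if mucin_l2fc is not None else [0.0] * n,
            "total_nuclear_intensity": nuclear if nuclear is not None else [1e6] * n,
            "manual_exclusion": False,
        }
    )
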