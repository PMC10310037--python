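"""Hit-rule logic: hand-evaluated examples, brute-force oracle, properties."""

import warnings

import numpy as np
import pandas as pd
import pytest

import bronchoscreen as bs
from bronchoscreen.hits import HitCallingError, HitRuleParams

from conftest import make_compound_wells, make_stats


# ---------------------------------------------------------------------------
# independent brute-force evaluator: plain loops over wells and clauses


def brute_force_calls(norm, stats, params, category):
    """Re-evaluate the hit rules clause by clause with explicit loops."""
    results = {}
    comp = norm[norm["role"] == "compound"]
    for (cid, conc), grp in comp.groupby(["compound", "concentration"]):
        eff = cnt = crs = usable = 0
        count_all_ok = True
        for _, w in grp.iterrows():
            s = stats.loc[w["plate"]]
            needed = [w["area_fold_change"], w["spheroid_count"], w["mucin_log2fc"]]
            if category == "mucus":
                needed.append(w["total_nuclear_intensity"])
            if w.get("manual_exclusion", False) or not all(
                np.isfinite(v) for v in needed
            ):
                continue
            usable += 1
            if category == "swell":
                if params.interpretation == "centered":
                    thr = s["area_fc_median"] + params.effect_k * s["area_fc_mad"]
                else:
                    thr = params.effect_k * s["area_fc_mad"]
                if w["area_fold_change"] > thr:
                    eff += 1
                if w["mucin_log2fc"] <= (
                    s["mucin_l2fc_median"] + params.cross_k * s["mucin_l2fc_mad"]
                ):
                    crs += 1
            else:
                if params.interpretation == "centered":
                    thr = s["mucin_l2fc_median"] - params.effect_k * s["mucin_l2fc_mad"]
                else:
                    thr = -params.effect_k * s["mucin_l2fc_mad"]
                nuc_ok = w["total_nuclear_intensity"] >= (
                    s["nuclear_median"] - params.tox_k * s["nuclear_mad"]
                )
                if params.toxicity_sidedness == "two_sided":
                    nuc_ok = nuc_ok and w["total_nuclear_intensity"] <= (
                        s["nuclear_median"] + params.tox_k * s["nuclear_mad"]
                    )
                if w["mucin_log2fc"] < thr and nuc_ok:
                    eff += 1
                if w["area_fold_change"] >= (
                    s["area_fc_median"] - params.cross_k * s["area_fc_mad"]
                ):
                    crs += 1
            lo = s["count0_median"] - params.tox_k * s["count0_mad"]
            ok = w["spheroid_count"] >= lo
            if params.toxicity_sidedness == "two_sided":
                ok = ok and w["spheroid_count"] <= (
                    s["count0_median"] + params.tox_k * s["count0_mad"]
                )
            if not ok:
                count_all_ok = False
        m = params.min_passing_replicates
        if usable < m:
            results[(cid, conc)] = (False, usable)
        else:
            hit = eff >= m and crs >= m and count_all_ok
            results[(cid, conc)] = (hit, usable)
    return results


def _assert_matches_brute_force(norm, stats, params):
    for category, caller in (
        ("swell", bs.call_swell_hits),
        ("mucus", bs.call_mucus_hits),
    ):
        calls = caller(norm, stats, params)
        brute = brute_force_calls(norm, stats, params, category)
        assert len(calls) == len(brute)
        for row in calls.itertuples():
            hit, usable = brute[(row.compound, row.concentration)]
            assert row.final_hit == hit, (category, row.compound, row.concentration)
            assert row.usable_replicates == usable


# ---------------------------------------------------------------------------


class TestControlStatistics:
    def test_hand_example(self):
        rows = []
        for i, fc in enumerate([0.9, 1.0, 1.1, 1.0]):
            rows.append(
                {"plate": "P1", "well": f"A{i}", "role": "control_3pct",
                 "area_fold_change": fc, "mucin_log2fc": 0.0,
                 "total_nuclear_intensity": 1e6, "spheroid_count": 40}
            )
        for i in range(4):
            rows.append(
                {"plate": "P1", "well": f"B{i}", "role": "control_0pct",
                 "area_fold_change": 1.0, "mucin_log2fc": 0.0,
                 "total_nuclear_intensity": 1e6, "spheroid_count": 40}
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = bs.control_statistics(pd.DataFrame(rows))
        assert stats.loc["P1", "area_fc_median"] == 1.0
        assert stats.loc["P1", "area_fc_mad"] == pytest.approx(0.05)

    def test_identical_controls_warn_zero_mad(self, small_screen):
        rows = pd.DataFrame(
            {
                "plate": "P1",
                "well": [f"A{i}" for i in range(8)],
                "role": ["control_3pct"] * 4 + ["control_0pct"] * 4,
                "area_fold_change": 1.0,
                "mucin_log2fc": 0.0,
                "total_nuclear_intensity": 1e6,
                "spheroid_count": 40,
            }
        )
        with pytest.warns(UserWarning, match="zero MAD"):
            stats = bs.control_statistics(rows)
        assert (stats.filter(like="_mad") == 0).all().all()

    def test_per_plate_no_pooling(self, small_screen):
        """Two plates with different control spreads get different MADs."""
        params, wells, truth, norm, stats = small_screen
        p2 = norm.copy()
        p2["plate"] = "P02"
        p2["area_fold_change"] = 1 + (p2["area_fold_change"] - 1) * 3
        both = pd.concat([norm, p2], ignore_index=True)
        s = bs.control_statistics(both)
        assert s.loc["P02", "area_fc_mad"] == pytest.approx(
            3 * s.loc["P01", "area_fc_mad"]
        )

    def test_too_few_controls_errors(self):
        rows = pd.DataFrame(
            {
                "plate": "P9",
                "well": ["A1", "A2", "A3", "A4", "B1"],
                "role": ["control_3pct"] * 4 + ["control_0pct"],
                "area_fold_change": [0.9, 1.0, 1.1, 1.0, 1.0],
                "mucin_log2fc": 0.0,
                "total_nuclear_intensity": 1e6,
                "spheroid_count": 40,
            }
        )
        with pytest.raises(HitCallingError, match="P9"):
            bs.control_statistics(rows)


class TestSwellRule:
    def test_two_of_three_hand_example(self):
        """FCs {1.4, 1.35, 0.9} vs median 1, MAD 0.1: 2 exceed 1.2 -> hit."""
        norm = make_compound_wells([1.4, 1.35, 0.9])
        calls = bs.call_swell_hits(norm, make_stats())
        assert calls["final_hit"].iloc[0]
        assert calls["n_effect_pass"].iloc[0] == 2

    def test_count_toxicity_blocks_hit(self):
        norm = make_compound_wells([1.4, 1.35, 0.9], counts=[40, 40, 33])
        calls = bs.call_swell_hits(norm, make_stats())  # bound 40 - 6 = 34
        assert not calls["final_hit"].iloc[0]
        assert not calls["count_toxicity_pass"].iloc[0]

    def test_mucin_increase_cross_filter(self):
        norm = make_compound_wells([1.4, 1.35, 1.3], mucin_l2fc=[0.5, 0.6, 0.0])
        calls = bs.call_swell_hits(norm, make_stats())  # cross bound 0.3
        assert not calls["final_hit"].iloc[0]
        assert not calls["cross_readout_pass"].iloc[0]

    def test_threshold_tie_does_not_pass(self):
        norm = make_compound_wells([1.2, 1.2, 1.2])
        calls = bs.call_swell_hits(norm, make_stats())  # threshold exactly 1.2
        assert calls["n_effect_pass"].iloc[0] == 0

    def test_literal_interpretation_flag(self):
        norm = make_compound_wells([0.5, 0.5, 0.5])
        stats = make_stats(area_mad=0.1)
        centered = bs.call_swell_hits(norm, stats)
        literal = bs.call_swell_hits(
            norm, stats, HitRuleParams(interpretation="literal")
        )
        assert centered["n_effect_pass"].iloc[0] == 0
        assert literal["n_effect_pass"].iloc[0] == 3  # 0.5 > 2 * 0.1

    def test_too_few_usable_wells_uncallable(self):
        norm = make_compound_wells([1.4, np.nan, np.nan])
        calls = bs.call_swell_hits(norm, make_stats())
        assert calls["category"].iloc[0] == "none"
        assert not calls["final_hit"].iloc[0]
        assert calls["usable_replicates"].iloc[0] == 1


class TestMucusRule:
    def test_two_of_three_hand_example(self):
        """log2FCs {-0.8, -0.7, -0.1} vs median 0, MAD 0.15: 2 below -0.3."""
        norm = make_compound_wells(
            [1.0, 1.0, 1.0], mucin_l2fc=[-0.8, -0.7, -0.1]
        )
        calls = bs.call_mucus_hits(norm, make_stats())
        assert calls["final_hit"].iloc[0]
        assert calls["n_effect_pass"].iloc[0] == 2

    def test_nuclear_intensity_joint_clause(self):
        """Two replicates with low nuclei leave only one passing the joint
        effect-and-intensity test: not a hit."""
        norm = make_compound_wells(
            [1.0, 1.0, 1.0],
            mucin_l2fc=[-0.8, -0.7, -0.6],
            nuclear=[1e6, 8e5, 8e5],  # bound 1e6 - 3*5e4 = 8.5e5
        )
        calls = bs.call_mucus_hits(norm, make_stats())
        assert not calls["final_hit"].iloc[0]
        assert calls["n_effect_pass"].iloc[0] == 1

    def test_area_decrease_cross_filter(self):
        norm = make_compound_wells(
            [0.7, 0.75, 1.0], mucin_l2fc=[-0.8, -0.7, -0.6]
        )
        calls = bs.call_mucus_hits(norm, make_stats())  # bound 1 - 0.2 = 0.8
        assert not calls["cross_readout_pass"].iloc[0]
        assert not calls["final_hit"].iloc[0]


class TestConsolidation:
    def test_empty_inputs(self):
        empty = bs.call_swell_hits(
            make_compound_wells([1.0, 1.0, 1.0]), make_stats()
        )
        out = bs.consolidate_hits(empty, empty)
        assert out.empty

    def test_union_of_categories(self):
        swell = bs.call_swell_hits(make_compound_wells([1.4, 1.4, 1.4]), make_stats())
        mucus = bs.call_mucus_hits(
            make_compound_wells([1.0, 1.0, 1.0], mucin_l2fc=[-1, -1, -1],
                                compound="C002"),
            make_stats(),
        )
        out = bs.consolidate_hits(swell, mucus)
        assert len(out) == 2
        assert set(out["category"]) == {"swell", "mucus"}

    def test_manual_exclusion_audited(self):
        mucus = bs.call_mucus_hits(
            make_compound_wells([1.0, 1.0, 1.0], mucin_l2fc=[-1, -1, -1]),
            make_stats(),
        )
        out = bs.consolidate_hits(mucus.iloc[0:0], mucus, [("C001", 1.0)])
        assert not out["final_hit"].iloc[0]
        assert out["audit"].iloc[0] == "manual_exclusion"


class TestProperties:
    def test_matches_brute_force_on_simulated_screen(self, small_screen):
        _, _, _, norm, stats = small_screen
        _assert_matches_brute_force(norm, stats, HitRuleParams())

    @pytest.mark.parametrize("sidedness", ["one_sided_lower", "two_sided"])
    def test_matches_brute_force_other_params(self, small_screen, sidedness):
        _, _, _, norm, stats = small_screen
        params = HitRuleParams(
            effect_k=1.5, tox_k=2.5, toxicity_sidedness=sidedness,
            interpretation="literal",
        )
        _assert_matches_brute_force(norm, stats, params)

    def test_effect_k_monotonicity(self, small_screen):
        """Raising effect_k never adds hits; lowering tox_k never adds hits."""
        _, _, _, norm, stats = small_screen
        base = bs.call_swell_hits(norm, stats, HitRuleParams(effect_k=2.0))
        tighter = bs.call_swell_hits(norm, stats, HitRuleParams(effect_k=3.0))
        base_hits = set(map(tuple, base[base.final_hit][["compound", "concentration"]].values))
        tight_hits = set(map(tuple, tighter[tighter.final_hit][["compound", "concentration"]].values))
        assert tight_hits <= base_hits
        tox = bs.call_mucus_hits(norm, stats, HitRuleParams(tox_k=1.0))
        base_m = bs.call_mucus_hits(norm, stats, HitRuleParams(tox_k=3.0))
        tox_hits = set(map(tuple, tox[tox.final_hit][["compound", "concentration"]].values))
        base_m_hits = set(map(tuple, base_m[base_m.final_hit][["compound", "concentration"]].values))
        assert tox_hits <= base_m_hits

    def test_audit_completeness(self, small_screen):
        """Every non-hit carries at least one failing flag."""
        _, _, _, norm, stats = small_screen
        for caller in (bs.call_swell_hits, bs.call_mucus_hits):
            calls = caller(norm, stats)
            non_hits = calls[~calls["final_hit"]]
            flags = non_hits[
                ["effect_pass", "count_toxicity_pass", "nuclear_toxicity_pass",
                 "cross_readout_pass"]
            ].all(axis=1)
            callable_ = non_hits["usable_replicates"] >= 2
            assert not (flags & callable_).any()
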