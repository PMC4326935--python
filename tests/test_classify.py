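"""Detectability rule, rank-sum testing, fold-change convention, five classes."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mirlifespan import (
    CtMatrix,
    assign_expression_classes,
    classification_summary,
    delta_ct,
    detection_profile,
    signed_fold_change,
    wilcoxon_two_group,
)
from mirlifespan.classify import UntestableError, bonferroni_threshold


def ranksum_permutation_oracle(a, b):
    """Brute-force two-sided permutation p for the group-A midrank sum."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    w_obs = ranks[: len(a)].sum()
    sums = [ranks[list(idx)].sum() for idx in combinations(range(n), len(a))]
    lo = sum(1 for w in sums if w <= w_obs + 1e-9)
    hi = sum(1 for w in sums if w >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lo, hi) / len(sums))


class TestDetectionProfile:
    def make(self, det_a, n_a, det_b, n_b, min_frac=0.30):
        """One assay: det_x finite of n_x values per cohort."""
        samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
        vals = [30.0] * det_a + [np.nan] * (n_a - det_a)
        vals += [30.0] * det_b + [np.nan] * (n_b - det_b)
        ct = CtMatrix(pd.DataFrame({"m": vals}, index=samples))
        meta = pd.DataFrame({
            "sample_id": samples,
            "group": ["preterm"] * n_a + ["adult"] * n_b,
            "age": [0.0] * n_a + [30.0] * n_b,
            "gender": ["F"] * (n_a + n_b),
        })
        return detection_profile(ct, meta, min_frac=min_frac)

    def test_boundary_fraction_is_detectable(self):
        prof = self.make(3, 10, 0, 10)
        assert prof.table.loc["m", "frac_a"] == pytest.approx(0.30)
        assert bool(prof.table.loc["m", "flag_a"])
        assert "m" in prof.detectable_any

    def test_one_sided_detection_suffices(self):
        prof = self.make(9, 30, 0, 60)
        assert "m" in prof.detectable_any
        assert "m" not in prof.detectable_both

    def test_detected_nowhere_is_excluded(self):
        prof = self.make(0, 30, 0, 60)
        assert len(prof.detectable_any) == 0

    def test_lowering_min_frac_never_shrinks_detectable_set(self):
        for det in range(0, 11):
            strict = self.make(det, 10, 0, 10, min_frac=0.5)
            loose = self.make(det, 10, 0, 10, min_frac=0.2)
            assert set(strict.detectable_any) <= set(loose.detectable_any)

    def test_min_frac_out_of_range(self):
        with pytest.raises(ValueError):
            self.make(3, 10, 0, 10, min_frac=1.5)


class TestWilcoxon:
    def test_textbook_separation(self):
        res = wilcoxon_two_group([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(2 / math.comb(6, 3))
        assert res.exact
        assert res.direction == "higher_in_a"  # lower delta-Ct = more abundant

    def test_identical_groups_p_one(self):
        res = wilcoxon_two_group([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.direction == "tie"

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_permutation_oracle_8v8(self, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(0, 1, 8), 1)  # rounding induces ties
        b = np.round(rng.normal(0.5, 1, 8), 1)
        res = wilcoxon_two_group(a, b)
        assert res.exact
        assert res.p_value == pytest.approx(ranksum_permutation_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 5), (5, 5), (6, 7), (4, 10)])
    def test_exact_matches_oracle_across_sizes_with_ties(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 100 + n_b)
        a = rng.integers(0, 4, n_a).astype(float)
        b = rng.integers(0, 4, n_b).astype(float)
        res = wilcoxon_two_group(a, b)
        assert res.p_value == pytest.approx(ranksum_permutation_oracle(a, b), abs=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        res = wilcoxon_two_group(rng.normal(0, 1, 30), rng.normal(1, 1, 60))
        assert not res.exact
        assert res.p_value < 1e-4

    def test_all_censored_group_is_untestable(self):
        with pytest.raises(UntestableError):
            wilcoxon_two_group([np.nan, np.nan], [1.0, 2.0, 3.0])


class TestSignedFoldChange:
    def test_no_change_is_plus_one(self):
        assert signed_fold_change(5.0, 5.0) == 1.0

    def test_lower_expressed_numerator_is_negative(self):
        # numerator cohort 0.678 cycles higher delta-Ct = 1.6-fold less expressed
        fc = signed_fold_change(5.0 + math.log2(1.6), 5.0)
        assert fc == pytest.approx(-1.6)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_antisymmetry_and_magnitude(self, a, b):
        fc = signed_fold_change(a, b)
        assert abs(fc) >= 1.0
        if abs(fc) > 1.0 + 1e-12:
            assert signed_fold_change(b, a) == pytest.approx(-fc, rel=1e-9)


class TestBonferroni:
    def test_detectable_panel_of_228_gives_printed_threshold(self):
        assert round(bonferroni_threshold(0.05, 228), 5) == 0.00022


def build_five_class_study(seed=0, n_a=12, n_b=24, effect=6.0):
    """Tiny panel engineered to hit every class label deterministically."""
    rng = np.random.default_rng(seed)
    samples = [f"P{i}" for i in range(n_a)] + [f"A{i}" for i in range(n_b)]
    meta = pd.DataFrame({
        "sample_id": samples,
        "group": ["preterm"] * n_a + ["adult"] * n_b,
        "age": [0.0] * n_a + [30.0] * n_b,
        "gender": list(np.where(rng.random(n_a + n_b) < 0.5, "F", "M")),
    })
    control = rng.normal(25, 0.2, n_a + n_b)

    def ct_col(mean_a, mean_b, sd=0.3):
        vals = control + np.r_[rng.normal(mean_a, sd, n_a), rng.normal(mean_b, sd, n_b)]
        return np.where(vals >= 40.0, np.nan, vals)

    cols = {
        "none": ct_col(25.0, 25.0),       # censored everywhere
        "const": ct_col(5.0, 5.0),
        "pre_only": ct_col(5.0, 25.0),
        "adult_only": ct_col(25.0, 5.0),
        "down": ct_col(5.0, 5.0 + effect),
        "up": ct_col(5.0 + effect, 5.0),
        "RNU48": control,
    }
    ct = CtMatrix(pd.DataFrame(cols, index=samples))
    return ct, meta


@pytest.fixture(scope="module")
def assignments():
    ct, meta = build_five_class_study()
    delta = delta_ct(ct, "RNU48")
    profile = detection_profile(delta, meta)
    return assign_expression_classes(profile, delta, meta)


class TestAssignClasses:
    def test_decision_tree_hits_all_five_classes(self, assignments):
        got = assignments["class_label"]
        assert got["none"] == "nonexpressed"
        assert got["const"] == "age_constant"
        assert got["pre_only"] == "preterm_only"
        assert got["adult_only"] == "adult_only"
        assert got["down"] == "down_in_adult"
        assert got["up"] == "up_in_adult"

    def test_partition_every_mirna_exactly_one_label(self, assignments):
        assert assignments["class_label"].notna().all()
        assert len(assignments) == 6

    def test_p_value_present_iff_detectable_in_both(self, assignments):
        tested = assignments["p_value"].notna()
        assert set(assignments.index[tested]) == {"const", "down", "up"}

    def test_fold_change_magnitude_at_least_one(self, assignments):
        fc = assignments["signed_fold_change"].dropna()
        assert (fc.abs() >= 1.0).all()

    def test_down_class_has_negative_adult_fold_change(self, assignments):
        assert assignments.loc["down", "signed_fold_change"] < 0
        assert assignments.loc["up", "signed_fold_change"] > 0

    def test_threshold_uses_detectable_count(self, assignments):
        n_detectable = 5  # all but "none"
        assert assignments.attrs["per_test_alpha"] == pytest.approx(0.05 / n_detectable)


class TestClassificationSummary:
    def make_assignments(self, counts):
        rows = []
        for lab, n in counts.items():
            rows += [{"mirna_id": f"{lab}{i}", "class_label": lab} for i in range(n)]
        df = pd.DataFrame(rows).set_index("mirna_id")
        df.attrs.update(group_a="preterm", group_b="adult")
        return df

    def test_up_share_of_differential(self):
        s = classification_summary(self.make_assignments({
            "nonexpressed": 137, "age_constant": 104, "preterm_only": 1,
            "adult_only": 22, "down_in_adult": 20, "up_in_adult": 81,
        }))
        assert s["panel_size"] == 365
        assert s["differential_total"] == 124
        assert round(s["differential_shares_percent"]["up_in_adult"]) == 65

    def test_single_class_input(self):
        s = classification_summary(self.make_assignments({"age_constant": 7}))
        assert s["percent_of_panel"]["age_constant"] == 100.0
        assert s["differential_total"] == 0

    def test_percentages_sum_to_100(self):
        s = classification_summary(self.make_assignments(
            {"nonexpressed": 3, "age_constant": 4, "up_in_adult": 5}))
        assert sum(s["percent_of_panel"].values()) == pytest.approx(100.0)
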