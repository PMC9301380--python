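"""Rank-sum testing, enrichment tables and subset contrasts.

The exact-mode Wilcoxon implementation is checked against an independent
full-permutation oracle that enumerates every assignment of the pooled
midranks to the two groups.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cdr3delta.association import (
    compare_subsets,
    enrichment_by_frequency_class,
    length_distribution_by_class,
    sample_metric,
    spearman_correlation_matrix,
    wilcoxon_rank_sum,
)
from cdr3delta.statistics import StatisticsError


def _midranks(values):
    """Independent midrank computation (average rank over ties)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def permutation_oracle_p(a, b):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    ranks = _midranks(pooled)
    n = len(a)
    w_obs = sum(ranks[:n])
    sums = [sum(ranks[i] for i in idx) for idx in combinations(range(len(pooled)), n)]
    le = sum(w <= w_obs + 1e-9 for w in sums) / len(sums)
    ge = sum(w >= w_obs - 1e-9 for w in sums) / len(sums)
    return min(1.0, 2 * min(le, ge))


def test_identical_groups_give_p_one():
    res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert res.p_value == 1.0
    assert res.median_difference == 0.0


def test_constant_identical_groups_are_degenerate():
    res = wilcoxon_rank_sum([5, 5], [5, 5])
    assert res.p_value == 1.0 and res.method == "degenerate"


def test_small_sample_exact_p():
    res = wilcoxon_rank_sum([1, 2], [3, 4])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(1 / 3)


def test_exact_mode_matches_permutation_oracle():
    rng = np.random.default_rng(31)
    for _ in range(30):
        n_a = int(rng.integers(1, 9))
        n_b = int(rng.integers(1, 9))
        a = rng.normal(size=n_a)  # continuous, tie-free
        b = rng.normal(size=n_b)
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(permutation_oracle_p(a, b), abs=1e-12)


def test_statistic_is_rank_sum_with_midranks():
    res = wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 3.0])
    # ranks: 1, (2+3+4)/3 = 3 for each tied 2.0, 5
    assert res.statistic == pytest.approx(1 + 3 + 3)


def test_group_swap_symmetry():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=9), rng.normal(size=12) + 0.5
    r_ab = wilcoxon_rank_sum(a, b)
    r_ba = wilcoxon_rank_sum(b, a)
    assert r_ab.p_value == pytest.approx(r_ba.p_value)
    assert r_ab.median_difference == pytest.approx(-r_ba.median_difference)


def _tiny_annotated():
    rows = []
    for sid, rep, props in (("S1", "r1", 3), ("S2", "r2", 4)):
        # 4 clonotypes in the non-expanded class; `props` of them are J1
        for i in range(4):
            rows.append(
                {
                    "sample_id": sid,
                    "donor_id": "D01",
                    "replicate_id": rep,
                    "subset_label": "CD27pos",
                    "junction": f"{sid}NT{i}",
                    "junction_aa": "CACDTLGDTDKLIF",
                    "read_count": 2,
                    "productive": True,
                    "cdr3_length": 12,
                    "aa5": "L",
                    "is_hAA5": True,
                    "inv_t": True,
                    "j_region": "J1" if i < props else "J3",
                    "n_insertions": 0,
                    "germline_encoded": True,
                    "frequency": 0.0005,
                    "frequency_class": "non_expanded",
                }
            )
    return pd.DataFrame(rows)


def test_enrichment_proportions_and_donor_average():
    out = enrichment_by_frequency_class(_tiny_annotated(), "J1_usage")
    reps = out[(out.level == "replicate") & (out.frequency_class == "non_expanded")]
    assert sorted(reps["proportion"]) == [0.75, 1.0]
    donor = out[(out.level == "donor") & (out.frequency_class == "non_expanded")]
    assert donor["proportion"].iloc[0] == pytest.approx((0.75 + 1.0) / 2)


def test_empty_class_emitted_as_missing():
    out = enrichment_by_frequency_class(_tiny_annotated(), "hAA5")
    hyper = out[(out.level == "replicate") & (out.frequency_class == "hyperexpanded")]
    assert hyper["proportion"].isna().all()
    assert (hyper["n_clonotypes"] == 0).all()


def test_length_distribution_normalises_per_class():
    ann = _tiny_annotated()
    ann.loc[ann.index[:2], "cdr3_length"] = 16
    out = length_distribution_by_class(ann)
    for _, g in out.groupby("frequency_class"):
        assert g["mean_proportion"].sum() == pytest.approx(1.0)


def test_length_distribution_simple_fractions():
    ann = _tiny_annotated().iloc[:3].copy()  # one sample, lengths {12, 12, 16}
    ann.loc[ann.index[2], "cdr3_length"] = 16
    out = length_distribution_by_class(ann, restrict_to=None)
    frac = dict(zip(out["cdr3_length"], out["mean_proportion"]))
    assert frac[12] == pytest.approx(2 / 3)
    assert frac[16] == pytest.approx(1 / 3)


def test_spearman_matrix_extremes_and_missing():
    df = pd.DataFrame(
        {
            "up": [1.0, 2.0, 3.0, 4.0],
            "down": [8.0, 6.0, 4.0, 2.0],
            "flat": [1.0, 1.0, 1.0, 1.0],
        }
    )
    corr = spearman_correlation_matrix(df)
    assert corr.loc["up", "down"] == pytest.approx(-1.0)
    assert corr.loc["up", "up"] == 1.0
    assert np.isnan(corr.loc["up", "flat"])
    with pytest.raises(StatisticsError):
        spearman_correlation_matrix(df.iloc[:2])


def test_spearman_independent_columns_near_zero():
    rng = np.random.default_rng(17)
    hits = 0
    for _ in range(40):
        df = pd.DataFrame(rng.normal(size=(200, 2)), columns=["x", "y"])
        if abs(spearman_correlation_matrix(df).loc["x", "y"]) < 0.2:
            hits += 1
    assert hits >= 38  # |rho| < 0.2 in the vast majority of independent draws


def _two_subset_annotated():
    ann = _tiny_annotated()
    other = ann.copy()
    other["sample_id"] = other["sample_id"].str.replace("S", "T")
    other["subset_label"] = "CD27neg"
    return pd.concat([ann, other], ignore_index=True)


def test_identical_subsets_compare_equal():
    res = compare_subsets(_two_subset_annotated(), "CD27pos", "CD27neg", "shannon")
    assert res.p_value == 1.0
    assert res.median_difference == pytest.approx(0.0)


def test_subset_swap_negates_median_difference():
    ann = _two_subset_annotated()
    ann.loc[ann.subset_label == "CD27neg", "read_count"] = [2, 2, 50, 2, 2, 2, 60, 2]
    r1 = compare_subsets(ann, "CD27pos", "CD27neg", "shannon")
    r2 = compare_subsets(ann, "CD27neg", "CD27pos", "shannon")
    assert r1.median_difference == pytest.approx(-r2.median_difference)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_absent_subset_raises():
    with pytest.raises(StatisticsError, match="absent"):
        compare_subsets(_tiny_annotated(), "CD27pos", "NKG2Dbright", "shannon")


def test_sample_metric_feature_proportion():
    vals = sample_metric(_tiny_annotated(), "feature_proportion", feature="J1_usage",
                         frequency_class="non_expanded")
    assert vals["S1"] == pytest.approx(0.75)
    assert vals["S2"] == pytest.approx(1.0)


def test_benjamini_hochberg_extension_matches_step_up_rule():
    from cdr3delta.association import benjamini_hochberg

    p = [0.01, 0.04, 0.03, 0.005]
    adj = benjamini_hochberg(p)
    # independent hand computation of the step-up adjustment
    order = np.argsort(p)  # 3, 0, 2, 1
    expected = {3: 0.02, 0: 0.02, 2: 0.04, 1: 0.04}
    for i, e in expected.items():
        assert adj[i] == pytest.approx(e)


def test_mean_t_interval_covers_mean_and_is_symmetric():
    from cdr3delta.association import mean_ci_t

    mean, lo, hi = mean_ci_t([1.0, 2.0, 3.0, 4.0])
    assert mean == pytest.approx(2.5)
    assert lo < mean < hi
    assert (mean - lo) == pytest.approx(hi - mean)
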