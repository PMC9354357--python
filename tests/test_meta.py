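"""Unit and property tests for the combination statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from finmeta.meta import (
    EvidenceTable,
    StudyDesign,
    bh_adjust,
    combined_p,
    compute_weights,
    effective_direction,
    run_meta,
    stat_fin,
    stat_in,
    stat_min,
    z_transform,
)

W2 = [0.7071, 0.7071]


class TestWeights:
    def test_reference_three_study_design(self, design3):
        w = compute_weights(design3)
        # sqrt(20/73), sqrt(25/73), sqrt(28/73)
        assert np.allclose(w.values, [0.5234, 0.5852, 0.6193], atol=5e-5)

    def test_single_study_weight_is_one(self):
        d = StudyDesign(("only",), ((7, 3),))
        assert compute_weights(d).values == pytest.approx([1.0])

    def test_equal_totals_give_sqrt_half(self):
        d = StudyDesign(("a", "b"), ((10, 10), (5, 15)))
        assert np.allclose(compute_weights(d).values, np.sqrt(0.5))

    def test_missing_gene_rule_renormalises(self, design3):
        w = compute_weights(design3, present=("s1", "s3"))
        assert np.allclose(w.values, np.sqrt([20 / 48, 28 / 48]))

    def test_empty_subset_rejected(self, design3):
        with pytest.raises(ValueError, match="no study evidence"):
            compute_weights(design3, present=())

    def test_nonpositive_replicates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            StudyDesign(("a",), ((0, 10),))

    @given(
        totals=st.lists(
            st.tuples(st.integers(1, 500), st.integers(1, 500)), min_size=1, max_size=8
        )
    )
    def test_squares_sum_to_one(self, totals):
        d = StudyDesign(tuple(f"s{i}" for i in range(len(totals))), tuple(totals))
        w = compute_weights(d)
        assert np.sum(w.values**2) == pytest.approx(1.0)
        assert np.all(w.values > 0)


class TestZTransform:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, 0.0), (0.025, 1.95996), (0.99, -2.32635)],
    )
    def test_reference_quantiles(self, p, expected):
        assert z_transform(p) == pytest.approx(expected, abs=1e-5)

    def test_matches_normal_quantile_oracle(self):
        p = np.linspace(0.001, 0.999, 97)
        assert np.allclose(z_transform(p), stats.norm.ppf(1 - p))

    def test_strictly_decreasing(self):
        p = np.linspace(0.01, 0.99, 50)
        assert np.all(np.diff(z_transform(p)) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            z_transform(1.5)

    def test_boundary_clamped_finite(self):
        assert np.isfinite(z_transform(0.0))
        assert np.isfinite(z_transform(1.0))


class TestStatistics:
    def test_in_reference_value(self):
        assert stat_in([0.01, 0.02], W2) == pytest.approx(3.0971, abs=2e-4)

    def test_in_all_half_is_zero(self):
        assert stat_in([0.5, 0.5, 0.5], [0.6, 0.6, 0.52]) == pytest.approx(0.0)

    def test_in_single_study(self):
        assert stat_in([0.05], [1.0]) == pytest.approx(1.6449, abs=1e-4)

    def test_min_mismatched_reference_value(self):
        assert stat_min([0.01, 0.02], [1, -1], W2) == pytest.approx(0.1928, abs=2e-4)

    def test_min_equals_in_when_concordant_and_significant(self):
        assert stat_min([0.01, 0.02], [1, 1], W2) == pytest.approx(
            stat_in([0.01, 0.02], W2)
        )

    def test_min_rejects_bad_direction(self):
        with pytest.raises(ValueError, match="direction"):
            stat_min([0.1], [0], [1.0])

    def test_fin_branches(self):
        n_conc, b_conc = stat_fin([0.01, 0.02], [1, 1], W2)
        n_mism, b_mism = stat_fin([0.01, 0.02], [1, -1], W2)
        assert (b_conc, b_mism) == ("concordant", "mismatched")
        assert n_conc == pytest.approx(3.0971, abs=2e-4)
        assert n_mism == pytest.approx(0.1928, abs=2e-4)

    def test_fin_single_study_is_concordant(self):
        n, branch = stat_fin([0.05], [-1], [1.0])
        assert branch == "concordant"
        assert n == pytest.approx(z_transform(0.05))

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.001, 0.999), st.sampled_from([-1, 1]), st.floats(0.1, 1.0)
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_min_antisymmetry(self, data):
        p, d, w = map(list, zip(*data))
        n = stat_min(p, d, w)
        flipped = stat_min(p, [-x for x in d], w)
        assert flipped == pytest.approx(-n)
        assert combined_p(flipped, "two_sided") == pytest.approx(
            combined_p(n, "two_sided")
        )

    @given(
        p=st.lists(st.floats(0.001, 0.45), min_size=2, max_size=6),
        sign=st.sampled_from([-1, 1]),
    )
    def test_fin_equals_in_on_concordant_small_p(self, p, sign):
        """For concordant genes with every p < 0.5, |z| = z so FIN = IN exactly
        (up to the direction sign for down-regulated genes)."""
        w = [1.0 / np.sqrt(len(p))] * len(p)
        n_fin, branch = stat_fin(p, [sign] * len(p), w)
        assert branch == "concordant"
        assert n_fin == stat_in(p, w)

    @given(
        p=st.lists(st.floats(0.001, 0.999), min_size=2, max_size=6),
        flip=st.integers(0, 5),
    )
    def test_fin_equals_min_on_mismatched(self, p, flip):
        d = [1] * len(p)
        d[flip % len(p)] = -1
        if all(x == d[0] for x in d):
            return
        w = [1.0 / np.sqrt(len(p))] * len(p)
        n_fin, branch = stat_fin(p, d, w)
        assert branch == "mismatched"
        assert n_fin == stat_min(p, d, w)

    def test_concordant_monotonicity(self):
        """Decreasing any p strictly increases N and decreases the one-sided p."""
        p = [0.2, 0.3, 0.4]
        w = list(compute_weights(StudyDesign(("a", "b", "c"), ((5, 5),) * 3)).values)
        base = stat_in(p, w)
        for i in range(3):
            better = list(p)
            better[i] = p[i] / 2
            n2 = stat_in(better, w)
            assert n2 > base
            assert combined_p(n2, "one_sided") < combined_p(base, "one_sided")


class TestCombinedP:
    def test_zero_statistic_two_sided_is_one(self):
        assert combined_p(0.0, "two_sided") == 1.0

    def test_reference_tail_values(self):
        assert combined_p(3.0971, "one_sided") == pytest.approx(9.8e-4, rel=2e-2)
        assert combined_p(0.1928, "two_sided") == pytest.approx(0.847, abs=5e-4)

    def test_matches_survival_oracle(self):
        for n in np.linspace(-4, 4, 33):
            assert combined_p(n, "one_sided") == pytest.approx(1 - stats.norm.cdf(n))
            assert combined_p(n, "two_sided") == pytest.approx(
                2 * (1 - stats.norm.cdf(abs(n)))
            )


def bh_oracle(p):
    """Brute-force step-up: sort, p*(m/rank), cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_output_dominates_input(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert np.all(bh_adjust(p) >= p)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=200)
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p))


class TestEffectiveDirection:
    @pytest.mark.parametrize("n,expected", [(7.58, "+"), (-7.53, "-")])
    def test_mismatched_sign_of_statistic(self, n, expected):
        assert effective_direction(n, "mismatched") == expected

    def test_concordant_keeps_shared_direction(self):
        assert effective_direction(-3.0, "concordant", shared_direction=1) == "+"
        assert effective_direction(3.0, "concordant", shared_direction=-1) == "-"

    def test_zero_statistic_defaults_up(self):
        assert effective_direction(0.0, "mismatched") == "+"


class TestRunMeta:
    def test_toy_calls(self, toy_evidence):
        """Hand evaluation of the 4-gene, 2-study table.

        g1 (concordant, tiny p, big FC) is a DEG for every method; g4
        (single-study, tiny p, big FC) likewise.  g3 is null.  g2 has
        perfectly balanced conflicting evidence: its MIN/FIN statistic is
        exactly 0 (combined p = 1) so MIN/FIN cannot call it, while IN finds
        it highly significant but strikes it post hoc as conflicting.
        """
        fin = run_meta(toy_evidence, "FIN").set_index("gene")
        inn = run_meta(toy_evidence, "IN").set_index("gene")
        mn = run_meta(toy_evidence, "MIN").set_index("gene")

        assert set(fin.index[fin["is_DEG"]]) == {"g1", "g4"}
        assert set(inn.index[inn["is_DEG"]]) == {"g1", "g4"}
        assert set(mn.index[mn["is_DEG"]]) == {"g1", "g4"}

        assert fin.loc["g2", "branch"] == "mismatched"
        assert fin.loc["g2", "Ng"] == pytest.approx(0.0, abs=1e-12)
        assert fin.loc["g2", "pvalue_combined"] == pytest.approx(1.0)
        assert inn.loc["g2", "conflicting"]
        assert not inn.loc["g2", "is_DEG"]
        # IN's raw statistic for g2 is large: only the post-hoc rule excludes it
        assert inn.loc["g2", "Ng"] > 6
        assert inn.loc["g2", "fdr"] < 0.05

    def test_single_study_gene_in_equals_study_p(self, toy_evidence):
        inn = run_meta(toy_evidence, "IN").set_index("gene")
        assert inn.loc["g4", "pvalue_combined"] == pytest.approx(1e-6, rel=1e-6)

    def test_min_fin_agree_on_mismatched(self, toy_evidence):
        fin = run_meta(toy_evidence, "FIN").set_index("gene")
        mn = run_meta(toy_evidence, "MIN").set_index("gene")
        mism = fin.index[fin["branch"] == "mismatched"]
        assert len(mism) > 0
        for g in mism:
            assert fin.loc[g, "Ng"] == mn.loc[g, "Ng"]
            assert fin.loc[g, "pvalue_combined"] == mn.loc[g, "pvalue_combined"]
            assert fin.loc[g, "is_DEG"] == mn.loc[g, "is_DEG"]

    def test_effect_strings(self, toy_evidence):
        fin = run_meta(toy_evidence, "FIN").set_index("gene")
        assert fin.loc["g1", "effect"] == "++"
        assert fin.loc["g2", "effect"] == "+-"
        assert fin.loc["g4", "effect"] == "+·"

    def test_fc_filter_toggle(self, toy_evidence):
        no_filter = run_meta(toy_evidence, "FIN", fc_filter=False).set_index("gene")
        with_filter = run_meta(
            toy_evidence, "FIN", fc_filter=True, lfc_threshold=3.0
        ).set_index("gene")
        assert no_filter.loc["g1", "is_DEG"]
        assert not with_filter.loc["g1", "is_DEG"]  # mean |lfc| = 2 < 3

    def test_in_prefilter_mode_drops_conflicting_before_bh(self, toy_evidence):
        pre = run_meta(toy_evidence, "IN", in_conflict_mode="prefilter").set_index(
            "gene"
        )
        assert np.isnan(pre.loc["g2", "fdr"])
        assert not pre.loc["g2", "is_DEG"]

    def test_unknown_method_rejected(self, toy_evidence):
        with pytest.raises(ValueError, match="unknown method"):
            run_meta(toy_evidence, "fisher")

    def test_deterministic(self, toy_evidence):
        a = run_meta(toy_evidence, "FIN")
        b = run_meta(toy_evidence, "FIN")
        pd.testing.assert_frame_equal(a, b)

    def test_bh_dominates_raw_p(self, toy_evidence):
        for method in ("IN", "MIN", "FIN"):
            t = run_meta(toy_evidence, method)
            ok = t["fdr"].notna()
            assert np.all(t.loc[ok, "fdr"] >= t.loc[ok, "pvalue_combined"] - 1e-15)


class TestEvidenceTable:
    def test_mismatched_missingness_rejected(self, design3):
        pv = pd.DataFrame(
            {"s1": [0.1], "s2": [np.nan], "s3": [0.2]}, index=["g"]
        )
        lfc = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="missingness"):
            EvidenceTable(design3, pv, lfc)

    def test_all_absent_gene_dropped(self, design3):
        pv = pd.DataFrame(
            {"s1": [0.1, np.nan], "s2": [0.2, np.nan], "s3": [0.3, np.nan]},
            index=["keep", "drop"],
        )
        lfc = pv.copy()
        ev = EvidenceTable(design3, pv, lfc)
        assert list(ev.genes) == ["keep"]

    def test_zero_lfc_counts_as_up(self, design3):
        pv = pd.DataFrame({"s1": [0.1], "s2": [0.1], "s3": [0.1]}, index=["g"])
        lfc = pd.DataFrame({"s1": [0.0], "s2": [1.0], "s3": [2.0]}, index=["g"])
        ev = EvidenceTable(design3, pv, lfc)
        assert np.all(ev.directions() == 1)
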