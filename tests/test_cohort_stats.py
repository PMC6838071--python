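"""Recurrence, co-occurrence, KM/log-rank, exact Wilcoxon, Z-scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdcscreen import cohort_stats as cs


class TestRecurrence:
    def test_counts_and_fractions(self):
        matrix = pd.DataFrame(
            {"A:gain": [1, 1, 1, 0], "B:loss": [1, 0, 0, 0]},
            index=list("wxyz"),
        )
        table = cs.recurrence(matrix)
        a = table.set_index("event")
        assert a.loc["A:gain", "count"] == 3
        assert a.loc["A:gain", "fraction"] == 0.75
        assert a.loc["B:loss", "fraction"] == 0.25

    def test_empty_matrix(self):
        assert len(cs.recurrence(pd.DataFrame())) == 0

    def test_display_filter(self):
        matrix = pd.DataFrame({"A:gain": [1] * 9 + [0], "B:loss": [1] + [0] * 9})
        table = cs.recurrence(matrix, min_fraction=0.10)
        assert list(table["event"]) == ["A:gain"]

    def test_simulated_cohort_matches_spec_frequency(self):
        from pdcscreen.synthetic import CohortSpec, generate_cohort_matrix

        spec = CohortSpec(seed=42)
        matrix = generate_cohort_matrix(spec)
        table = cs.recurrence(matrix).set_index("event")
        for gene, (kind, p) in spec.gene_alteration_freqs.items():
            obs = table.loc[f"{gene}:{kind}", "fraction"]
            half_width = 1.96 * np.sqrt(p * (1 - p) / spec.n_samples)
            assert abs(obs - p) <= half_width, (gene, obs, p)


class TestCooccurrence:
    def test_inclusion_exclusion_on_printed_counts(self):
        c = cs.cooccurrence(41, 21, 18, 161)
        assert c.union_count == 44
        assert round(100 * c.union_fraction) == 27
        assert round(100 * c.fraction_a) == 25
        assert round(100 * c.fraction_b) == 13
        assert round(100 * c.fraction_both) == 11

    def test_disjoint_union_is_sum(self):
        c = cs.cooccurrence(10, 5, 0, 100)
        assert c.union_count == 15

    def test_nested_sets(self):
        c = cs.cooccurrence(7, 7, 7, 50)
        assert c.union_count == 7 and c.jaccard == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            cs.cooccurrence(5, 3, 4, 100)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_inclusion_exclusion_identities(self, data):
        n = data.draw(st.integers(1, 500))
        a = data.draw(st.integers(0, n))
        b = data.draw(st.integers(0, n))
        both = data.draw(st.integers(max(0, a + b - n), min(a, b)))
        c = cs.cooccurrence(a, b, both, n)
        assert c.union_count == a + b - both
        assert 0 <= c.union_count <= n
        assert c.union_fraction == pytest.approx(c.fraction_a + c.fraction_b
                                                 - c.fraction_both)


def survival_frame(times, events, groups):
    return pd.DataFrame(
        {"sample": [f"s{i}" for i in range(len(times))],
         "time": times, "event": events, "group": groups}
    )


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        rec = survival_frame([1, 2, 3], [0, 0, 0], ["g"] * 3)
        km = cs.km_estimate(rec)["g"]
        assert np.allclose(km["survival"], 1.0)

    def test_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        rec = survival_frame(times, [1] * 5, ["g"] * 5)
        km = cs.km_estimate(rec)["g"].set_index("time")["survival"]
        for i, t in enumerate(times, start=1):
            assert km.loc[t] == pytest.approx(1 - i / 5)

    def test_textbook_interleaved_censoring(self):
        """S after events at 1, 3, 5, 6 with censoring at 2 and 4."""
        rec = survival_frame([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1], ["g"] * 6)
        km = cs.km_estimate(rec)["g"].set_index("time")["survival"]
        assert km.loc[1] == pytest.approx(5 / 6)
        assert km.loc[3] == pytest.approx(5 / 6 * 3 / 4)
        assert km.loc[5] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)
        assert km.loc[6] == pytest.approx(0.0)

    def test_negative_times_rejected(self):
        rec = survival_frame([-1.0], [1], ["g"])
        with pytest.raises(ValueError):
            cs.km_estimate(rec)


def logrank_oracle(records):
    """Hand hypergeometric O-E / V sums over distinct event times."""
    groups = sorted(records["group"].unique())
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(records.loc[records["event"] == 1, "time"].unique()):
        at_risk = records[records["time"] >= t]
        n = len(at_risk)
        n1 = (at_risk["group"] == groups[0]).sum()
        deaths = records[(records["time"] == t) & (records["event"] == 1)]
        d = len(deaths)
        d1 = (deaths["group"] == groups[0]).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        base = survival_frame([1, 2, 3, 4], [1, 1, 0, 1], ["a"] * 4)
        dup = base.copy()
        dup["group"] = "b"
        stat, p = cs.logrank_test(pd.concat([base, dup], ignore_index=True))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_example_matches_hand_oracle(self):
        rec = survival_frame(
            [1, 2, 3, 4, 5, 6, 7, 8],
            [1, 1, 0, 1, 1, 0, 1, 1],
            ["a", "a", "a", "a", "b", "b", "b", "b"],
        )
        stat, p = cs.logrank_test(rec)
        assert stat == pytest.approx(logrank_oracle(rec), rel=1e-9)

    def test_label_swap_invariance(self):
        rec = survival_frame([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 1],
                             ["a", "b", "a", "b", "a", "b"])
        swapped = rec.copy()
        swapped["group"] = swapped["group"].map({"a": "b", "b": "a"})
        assert cs.logrank_test(rec)[0] == pytest.approx(cs.logrank_test(swapped)[0])

    def test_no_events_vacuous(self):
        rec = survival_frame([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert cs.logrank_test(rec) == (0.0, 1.0)


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    center = n * (len(pooled) + 1) / 2
    obs = abs(ranks[:n].sum() - center)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        stat = abs(ranks[list(idx)].sum() - center)
        count += stat >= obs - 1e-12
        total += 1
    return count / total


class TestWilcoxon:
    def test_separated_5v3_exact_p(self):
        p = cs.wilcoxon_ranksum([1, 2, 3, 4, 5], [10, 20, 30])
        assert p == pytest.approx(2 / 56)

    def test_matches_enumeration_for_small_samples(self, rng):
        for n, m in [(3, 3), (4, 3), (5, 4), (5, 5), (2, 6)]:
            x = rng.normal(0, 1, n)
            y = rng.normal(0.8, 1, m)
            p = cs.wilcoxon_ranksum(x, y)
            assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y))

    def test_symmetry_in_arguments(self, rng):
        x, y = rng.normal(0, 1, 4), rng.normal(1, 1, 5)
        assert cs.wilcoxon_ranksum(x, y) == pytest.approx(cs.wilcoxon_ranksum(y, x))

    def test_identical_samples_near_one(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + rng.normal(0, 1e-9, 4)  # jitter breaks ties only
        assert cs.wilcoxon_ranksum(x, y) > 0.6

    def test_ties_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="ties"):
            p = cs.wilcoxon_ranksum([1, 1, 2], [1, 2, 3])
        assert 0 < p <= 1


class TestZscore:
    def test_hand_computed_row(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z = cs.zscore_normalize(mat)
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])
        z_pop = cs.zscore_normalize(mat, ddof=0)
        assert np.allclose(z_pop.loc["g"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_gene_zeroed_and_flagged(self):
        mat = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                           index=["flat", "var"], columns=list("abc"))
        z = cs.zscore_normalize(mat)
        assert np.allclose(z.loc["flat"], 0.0)
        assert z.attrs["constant_genes"] == ["flat"]

    def test_rows_standardized(self, rng):
        mat = pd.DataFrame(rng.normal(5, 2, (10, 8)))
        z = cs.zscore_normalize(mat)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.zscore_normalize(pd.DataFrame([[1.0]]))
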