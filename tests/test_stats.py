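"""Rate tables, regional comparisons, Spearman summaries and asymmetry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import meghfo as m
from meghfo.stats import _compare_samples, dunn_posthoc

from conftest import make_rate_table, region_rate_table


def event(channel, cls="ripple", t=5.0, freq=None):
    freq = freq if freq is not None else (120.0 if cls == "ripple" else 300.0)
    return m.CandidateEvent(channel, t, t + 0.05, t + 0.02, freq,
                            25.0, 1.0, cls, 6.0)


class TestComputeRates:
    def test_count_over_duration(self, layout):
        events = [event("TR01", t=1.0 + 0.1 * i) for i in range(30)]
        table = m.compute_rates(events, layout, 10.0)
        row = table[(table.channel_label == "TR01")
                    & (table.class_label == "ripple")]
        assert row["rate"].iloc[0] == 3.0

    def test_empty_events_give_all_zero_table(self, layout):
        table = m.compute_rates([], layout, 10.0)
        assert len(table) == 275 * 2
        assert (table["rate"] == 0).all()

    def test_per_class_counting(self, layout):
        events = [event("CL01", "ripple", t=1 + i) for i in range(5)]
        events += [event("CL01", "fast_ripple", t=20 + i) for i in range(2)]
        table = m.compute_rates(events, layout, 10.0)
        sel = table[table.channel_label == "CL01"].set_index("class_label")
        assert sel.loc["ripple", "rate"] == 0.5
        assert sel.loc["fast_ripple", "rate"] == pytest.approx(0.2)

    def test_rate_conservation(self, layout):
        rng = np.random.default_rng(3)
        chans = rng.choice(layout.channel_labels[:50], size=200)
        events = [
            event(c, "ripple" if i % 3 else "fast_ripple", t=1 + 0.01 * i)
            for i, c in enumerate(chans)
        ]
        table = m.compute_rates(events, layout, 10.0)
        total = (table["rate"] * table["recording_minutes"]).sum()
        assert total == pytest.approx(len(events))

    def test_unknown_channel_rejected(self, layout):
        with pytest.raises(KeyError):
            m.compute_rates([event("nope")], layout, 10.0)


class TestGroupMatrix:
    def test_single_subject_matrix_equals_rates(self, layout):
        t = make_rate_table(layout, {"TR01": 2.0}, subject_id="a")
        mat = m.channelwise_group_matrix([t], {"a": "g"})
        row = mat[(mat.channel_label == "TR01") & (mat.class_label == "ripple")]
        assert row["mean_rate"].iloc[0] == 2.0

    def test_mean_of_two_subjects(self, layout):
        t1 = make_rate_table(layout, {"TR01": 1.0}, subject_id="a")
        t2 = make_rate_table(layout, {"TR01": 3.0}, subject_id="b")
        mat = m.channelwise_group_matrix([t1, t2], {"a": "g", "b": "g"})
        row = mat[(mat.channel_label == "TR01") & (mat.class_label == "ripple")]
        assert row["mean_rate"].iloc[0] == 2.0

    def test_boosted_region_mean_exceeds_others(self, layout):
        tables = [
            region_rate_table(layout, {"TL": 5.0, "TR": 1.0},
                              subject_id=f"s{i}", jitter=i)
            for i in range(4)
        ]
        mat = m.channelwise_group_matrix(
            tables, {f"s{i}": "g" for i in range(4)}
        )
        rip = mat[mat.class_label == "ripple"]
        tl = rip[rip.region == "TL"]["mean_rate"].mean()
        tr = rip[rip.region == "TR"]["mean_rate"].mean()
        assert tl > 3 * tr

    def test_unassigned_subject_rejected(self, layout):
        t = make_rate_table(layout, {}, subject_id="a")
        with pytest.raises(KeyError, match="without a group"):
            m.channelwise_group_matrix([t], {"b": "g"})


class TestCompareRegions:
    def test_identical_groups_give_null_result(self, layout):
        t1 = region_rate_table(layout, {"TL": 5.0}, subject_id="a", jitter=1)
        t2 = t1.assign(subject_id="b")
        mat = m.channelwise_group_matrix([t1, t2], {"a": "g1", "b": "g2"})
        res = m.compare_regions(mat, regions=["TL"], classes=["ripple"])[0]
        assert res.p_value > 0.99
        assert abs(res.statistic) < 1e-9

    def test_t_statistic_matches_closed_form(self):
        rng = np.random.default_rng(8)
        a = rng.normal(5.0, 1.0, size=24)
        b = rng.normal(6.0, 1.0, size=24)
        res = _compare_samples({"g1": a, "g2": b}, "CL", "ripple")
        assert res.test_used == "t_unpaired"
        # pooled-variance two-sample t computed from first principles
        na, nb = a.size, b.size
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
            na + nb - 2
        )
        t_closed = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t_closed, abs=1e-9)

    def test_anova_f_matches_closed_form(self):
        rng = np.random.default_rng(0)
        groups = {f"g{k}": rng.normal(5.0 + k, 1.0, size=20) for k in range(3)}
        res = _compare_samples(groups, "CL", "ripple")
        assert res.test_used == "anova_tukey"
        arrays = list(groups.values())
        grand = np.concatenate(arrays).mean()
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in arrays)
        ssw = sum(((x - x.mean()) ** 2).sum() for x in arrays)
        k, n = len(arrays), sum(len(x) for x in arrays)
        f_closed = (ssb / (k - 1)) / (ssw / (n - k))
        assert res.statistic == pytest.approx(f_closed, abs=1e-9)
        assert set(res.posthoc) == {("g0", "g1"), ("g0", "g2"), ("g1", "g2")}

    def test_skewed_samples_take_nonparametric_branch(self):
        rng = np.random.default_rng(10)
        a = rng.exponential(1.0, size=30) ** 3
        b = rng.exponential(2.0, size=30) ** 3
        res = _compare_samples({"g1": a, "g2": b}, "CL", "ripple")
        assert res.test_used == "mann_whitney"
        three = {"g1": a, "g2": b, "g3": rng.exponential(1.5, 30) ** 3}
        res3 = _compare_samples(three, "CL", "ripple")
        assert res3.test_used == "kruskal_dunn"
        assert len(res3.posthoc) == 3

    def test_all_zero_rates_flagged_degenerate(self, layout):
        t1 = make_rate_table(layout, {}, subject_id="a")
        t2 = make_rate_table(layout, {}, subject_id="b")
        mat = m.channelwise_group_matrix([t1, t2], {"a": "g1", "b": "g2"})
        res = m.compare_regions(mat, regions=["TL"], classes=["ripple"])[0]
        assert res.degenerate
        assert np.isnan(res.p_value)

    def test_unknown_region_rejected(self, layout):
        t = make_rate_table(layout, {"TL01": 1.0}, subject_id="a")
        mat = m.channelwise_group_matrix([t], {"a": "g"})
        with pytest.raises(KeyError):
            m.compare_regions(mat.loc[mat.region != "OR"], regions=["OR"])

    def test_dunn_matches_hand_computation(self):
        """Dunn z for 3 small tie-free groups, checked against the textbook
        rank-sum formula evaluated by hand."""
        samples = {
            "a": np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]),
            "b": np.array([9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0]),
            "c": np.array([17.0, 18.0, 19.0, 20.0, 21.0, 22.0, 23.0, 24.0]),
        }
        out = dunn_posthoc(samples)
        # mean ranks: a=4.5, b=12.5, c=20.5; N=24, var base = 24*25/12 = 50
        se = np.sqrt(50.0 * (1 / 8 + 1 / 8))
        from scipy.stats import norm

        z_ab = (4.5 - 12.5) / se
        p_ab = min(1.0, 2 * norm.sf(abs(z_ab)) * 3)
        assert out[("a", "b")] == pytest.approx(p_ab, abs=1e-12)
        assert out[("a", "c")] < out[("a", "b")]


class TestSpearman:
    def test_monotone_and_reversed_pairs(self, layout):
        tables = []
        for i in range(6):
            # TL rate rises with subject index, TR falls, CL rises with TL
            rates = {"TL": 1.0 + i, "CL": 2.0 + 2 * i, "TR": 6.0 - i}
            tables.append(
                region_rate_table(layout, rates, subject_id=f"s{i}")
            )
        mats, _ = m.cross_region_spearman(tables)
        corr = mats["ripple"]
        assert corr.loc["TL", "CL"] == pytest.approx(1.0)
        assert corr.loc["TL", "TR"] == pytest.approx(-1.0)

    def test_independent_regions_have_weak_median_rho(self, layout):
        rng = np.random.default_rng(12)
        tables = []
        for i in range(100):
            rates = {r: float(rng.uniform(1, 10)) for r in m.REGIONS}
            tables.append(
                region_rate_table(layout, rates, subject_id=f"s{i}")
            )
        _, summary = m.cross_region_spearman(tables, classes=["ripple"])
        assert abs(summary["median_rho"].iloc[0]) < 0.1

    def test_constant_region_recorded_as_missing(self, layout):
        tables = [
            region_rate_table(layout, {"TL": 1.0 + i, "TR": 2.0},
                              subject_id=f"s{i}")
            for i in range(5)
        ]
        mats, _ = m.cross_region_spearman(tables, classes=["ripple"])
        assert np.isnan(mats["ripple"].loc["TL", "TR"])

    def test_requires_three_subjects(self, layout):
        tables = [region_rate_table(layout, {"TL": 1.0}, subject_id="a")]
        with pytest.raises(ValueError, match="3 subjects"):
            m.cross_region_spearman(tables)


class TestAsymmetryIndex:
    def test_equal_rates_give_zero(self, layout):
        t = region_rate_table(layout, {"TL": 2.0, "TR": 2.0})
        assert m.asymmetry_index(t, "T", "ripple").ai == 0.0

    def test_left_only_gives_200(self, layout):
        t = region_rate_table(layout, {"TL": 1.5})
        assert m.asymmetry_index(t, "T", "ripple").ai == 200.0

    def test_direct_evaluation(self, layout):
        t = region_rate_table(layout, {"TL": 1.0, "TR": 3.0})
        assert m.asymmetry_index(t, "T", "ripple").ai == pytest.approx(-100.0)

    def test_all_pools_five_pairs(self, layout):
        t = region_rate_table(
            layout, {r: 2.0 for r in ["CL", "FL", "OL", "PL", "TL"]}
        )
        assert m.asymmetry_index(t, "All", "ripple").ai == 200.0

    def test_both_zero_is_an_error_not_zero(self, layout):
        t = make_rate_table(layout, {})
        with pytest.raises(ValueError, match="undefined"):
            m.asymmetry_index(t, "T", "ripple")

    def test_midline_channels_never_contribute(self, layout):
        t = region_rate_table(layout, {"CF": 9.0, "TL": 1.0, "TR": 1.0})
        assert m.asymmetry_index(t, "All", "ripple").ai == 0.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        left=st.floats(min_value=0.001, max_value=50.0),
        right=st.floats(min_value=0.001, max_value=50.0),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_antisymmetry_and_scale_invariance(self, layout, left, right, scale):
        t_lr = region_rate_table(layout, {"TL": left, "TR": right})
        t_rl = region_rate_table(layout, {"TL": right, "TR": left})
        t_sc = region_rate_table(
            layout, {"TL": left * scale, "TR": right * scale}
        )
        ai = m.asymmetry_index(t_lr, "T", "ripple").ai
        assert abs(ai) <= 200.0
        assert m.asymmetry_index(t_rl, "T", "ripple").ai == pytest.approx(-ai)
        assert m.asymmetry_index(t_sc, "T", "ripple").ai == pytest.approx(
            ai, abs=1e-9
        )


class TestAsymmetryTests:
    def test_symmetric_ai_not_lateralized(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0.0, 10.0, size=400)
        vals -= vals.mean()  # exactly centred
        res = m.test_asymmetry({"g": vals}, "T", "ripple")
        one_sample = [r for r in res if r.test_used == "t_one_sample"][0]
        assert one_sample.p_value > 0.9

    def test_shifted_ai_strongly_lateralized(self):
        rng = np.random.default_rng(14)
        vals = 50.0 + rng.normal(0.0, 1.0, size=10)
        res = m.test_asymmetry({"g": vals}, "T", "ripple")
        assert res[0].p_value < 0.01

    def test_identical_groups_between_comparison_null(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(5.0, 10.0, size=12)
        res = m.test_asymmetry({"g1": vals, "g2": vals.copy()})
        between = [r for r in res if r.test_used == "t_unpaired"][0]
        assert between.p_value > 0.99

    def test_zero_variance_sample_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            m.test_asymmetry({"g": [5.0, 5.0, 5.0]})


class TestTreatmentContrast:
    @staticmethod
    def poisson_tables(layout, rng, n_subjects, region_rates, prefix):
        tables = []
        for i in range(n_subjects):
            rates = {}
            for region, lam in region_rates.items():
                for ch in layout.channels_in_region(region):
                    rates[ch] = rng.poisson(lam) / 10.0
            tables.append(
                make_rate_table(layout, rates, subject_id=f"{prefix}{i}")
            )
        return tables

    def test_null_contrast_false_positive_rate(self, layout):
        """Identical arms: ~5% of regional tests significant at alpha=.05."""
        rng = np.random.default_rng(2)
        n_sig = n_tot = 0
        for _ in range(50):
            drug = self.poisson_tables(layout, rng, 6, {"TL": 5.0, "TR": 5.0},
                                       "d")
            plac = self.poisson_tables(layout, rng, 6, {"TL": 5.0, "TR": 5.0},
                                       "p")
            res = m.treatment_contrast(drug, plac, regions=["TL", "TR"],
                                       classes=["ripple"])
            n_sig += sum(r.p_value < 0.05 for r in res if not r.degenerate)
            n_tot += sum(not r.degenerate for r in res)
        assert 0.01 <= n_sig / n_tot <= 0.10

    def test_halved_rate_detected_with_power(self, layout):
        """A -50% drug effect in two regions is found at alpha=.05."""
        rng = np.random.default_rng(17)
        wins = 0
        reps = 10
        for _ in range(reps):
            drug = self.poisson_tables(
                layout, rng, 8, {"TL": 5.0, "OR": 5.0, "PR": 10.0}, "d"
            )
            plac = self.poisson_tables(
                layout, rng, 8, {"TL": 10.0, "OR": 10.0, "PR": 10.0}, "p"
            )
            res = m.treatment_contrast(
                drug, plac, regions=["TL", "OR"], classes=["ripple"]
            )
            wins += all(r.p_value < 0.05 for r in res)
        assert wins / reps > 0.8

    def test_empty_arms_all_degenerate(self, layout):
        drug = [make_rate_table(layout, {}, subject_id="d0")]
        plac = [make_rate_table(layout, {}, subject_id="p0")]
        res = m.treatment_contrast(drug, plac)
        assert all(r.degenerate for r in res)
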