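import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dorsalhorn.stats import (
    PhaseCorrelation,
    aggregate_animals,
    compare_groups,
    normalize_to_sham,
    phase_correlation,
)


def _histology_frame(day=21, sham=(12.0, 12.0, 12.0), cuff=(3.0, 3.0)):
    rows = []
    for i, v in enumerate(sham):
        rows.append(dict(day=day, group="sham", animal=f"s{i}", side="ipsilateral",
                         lamina="LII", marker="IB4", value=v))
    for i, v in enumerate(cuff):
        rows.append(dict(day=day, group="cuff", animal=f"c{i}", side="ipsilateral",
                         lamina="LII", marker="IB4", value=v))
    return pd.DataFrame(rows)


class TestNormalizeToSham:
    def test_cuff_equal_to_sham_mean_is_100pct(self):
        df = _histology_frame(cuff=(12.0, 12.0))
        norm = normalize_to_sham(df)
        cuff = norm[norm["group"] == "cuff"].iloc[0]
        assert cuff["mean_pct_of_sham"] == pytest.approx(100.0)

    def test_quarter_of_sham_mean_is_25pct(self):
        df = _histology_frame(sham=(12.0, 12.0), cuff=(3.0,))
        norm = normalize_to_sham(df)
        cuff = norm[norm["group"] == "cuff"].iloc[0]
        assert cuff["mean_pct_of_sham"] == pytest.approx(25.0)

    def test_sham_series_is_identically_100(self):
        df = _histology_frame()
        norm = normalize_to_sham(df)
        sham = norm[norm["group"] == "sham"]
        assert np.allclose(sham["mean_pct_of_sham"], 100.0)

    def test_sides_normalized_by_matching_sham_side(self):
        rows = []
        for side, sham_v, cuff_v in (("ipsilateral", 10.0, 5.0), ("contralateral", 20.0, 20.0)):
            rows.append(dict(day=5, group="sham", animal="s0", side=side,
                             lamina="LII", marker="IB4", value=sham_v))
            rows.append(dict(day=5, group="cuff", animal="c0", side=side,
                             lamina="LII", marker="IB4", value=cuff_v))
        norm = normalize_to_sham(pd.DataFrame(rows))
        cuff = norm[norm["group"] == "cuff"].set_index("side")["mean_pct_of_sham"]
        assert cuff["ipsilateral"] == pytest.approx(50.0)
        assert cuff["contralateral"] == pytest.approx(100.0)

    def test_missing_sham_stratum_raises_naming_it(self):
        df = _histology_frame()
        df = df[df["group"] == "cuff"]
        with pytest.raises(ValueError, match="sham"):
            normalize_to_sham(df)

    def test_sem_is_nonnegative(self):
        norm = normalize_to_sham(_histology_frame())
        assert (norm["sem_pct"] >= 0).all()


class TestCompareGroups:
    def test_bonferroni_adjustment_definition(self, rng):
        rows = []
        for day in (5, 7, 10):
            for g in ("sham", "cuff"):
                for i in range(6):
                    rows.append(dict(day=day, group=g, animal=f"{g}{i}", endpoint="vf",
                                     value=rng.normal(10.0, 1.0)))
        res = compare_groups(pd.DataFrame(rows), design="behavior")
        contrasts = res[res["test"] == "bonferroni_contrast"]
        m = contrasts["day"].nunique()
        assert np.allclose(contrasts["p_adj"], np.minimum(1.0, m * contrasts["p_raw"]))

    def test_identical_generative_groups_show_no_significance(self, rng):
        rows = []
        for day in (5, 7):
            for g in ("sham", "cuff"):
                for i in range(8):
                    rows.append(dict(day=day, group=g, animal=f"{g}{i}", endpoint="vf",
                                     value=rng.normal(10.0, 0.5)))
        res = compare_groups(pd.DataFrame(rows), design="behavior")
        contrasts = res[res["test"] == "bonferroni_contrast"]
        assert (contrasts["p_adj"] > 0.05).all()

    def test_80pct_reduction_is_detected_reliably(self):
        """A 6-vs-6 stratum with an 80% reduction and CV 20% flags
        sham-vs-cuff at p<0.05 in at least 95% of simulated cohorts."""
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            rows = []
            for g, mu in (("sham", 10.0), ("cuff", 2.0)):
                for i in range(6):
                    rows.append(dict(day=21, group=g, animal=f"{g}{i}", side="ipsilateral",
                                     lamina="LII", marker="IB4",
                                     value=max(rng.normal(mu, 0.2 * mu), 0.01)))
            res = compare_groups(pd.DataFrame(rows), design="histology", value_col="value")
            p = res[res["test"] == "sham_vs_cuff_ipsi"]["p_adj"].iloc[0]
            hits += p < 0.05
        assert hits / n_sim >= 0.95

    def test_type_one_error_near_nominal_under_null(self):
        """Sham-vs-cuff per-day comparison rejects ~5% of the time when
        both groups share the generative parameters."""
        rejections = 0
        n_sim = 1000
        for s in range(n_sim):
            rng = np.random.default_rng(7000 + s)
            a = rng.normal(10.0, 1.5, size=6)
            b = rng.normal(10.0, 1.5, size=6)
            from scipy import stats as sps

            rejections += sps.ttest_ind(a, b).pvalue < 0.05
        # binomial 99% interval around 0.05 for n=1000: ~[0.032, 0.068]
        assert 0.032 <= rejections / n_sim <= 0.068

    def test_paired_ipsi_contra_comparison_runs(self, rng):
        rows = []
        for i in range(6):
            base = rng.normal(10, 1)
            rows.append(dict(day=21, group="cuff", animal=f"c{i}", side="ipsilateral",
                             lamina="LII", marker="IB4", value=base * 0.3))
            rows.append(dict(day=21, group="cuff", animal=f"c{i}", side="contralateral",
                             lamina="LII", marker="IB4", value=base))
        for i in range(3):
            rows.append(dict(day=21, group="sham", animal=f"s{i}", side="ipsilateral",
                             lamina="LII", marker="IB4", value=rng.normal(10, 1)))
        res = compare_groups(pd.DataFrame(rows), design="histology", value_col="value")
        paired = res[res["test"] == "ipsi_vs_contra_cuff"]
        assert len(paired) == 1 and paired["p_raw"].iloc[0] < 0.05


def _pairs_frame(x, y, day=5):
    return pd.DataFrame(
        dict(day=day, animal=[f"a{i}" for i in range(len(x))], ib4_density=x, gad65_density=y)
    )


class TestPhaseCorrelation:
    def test_monotone_increasing_pairs_give_rho_one(self):
        df = _pairs_frame([1, 2, 3, 4, 5], [10, 20, 25, 50, 60])
        pc = phase_correlation(df, (5,))
        assert pc.r == pytest.approx(1.0)

    def test_perfect_inverse_ranks_give_rho_minus_one(self):
        df = _pairs_frame([1, 2, 3, 4], [4, 3, 2, 1])
        pc = phase_correlation(df, (5,))
        assert pc.r == pytest.approx(-1.0)

    def test_fewer_than_four_pairs_raises(self):
        df = _pairs_frame([1, 2, 3], [3, 2, 1])
        with pytest.raises(ValueError):
            phase_correlation(df, (5,))

    def test_n_counts_only_phase_days(self):
        df = pd.concat([_pairs_frame([1, 2, 3, 4], [1, 3, 2, 4], day=5),
                        _pairs_frame([1, 2, 3, 4], [1, 3, 2, 4], day=21)])
        pc = phase_correlation(df, (5,))
        assert pc.n == 4

    def test_exact_permutation_p_for_perfect_rank_agreement(self):
        # P(|rho| = 1) under random ranks of 5 items: 2/5! = 1/60
        df = _pairs_frame([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        pc = phase_correlation(df, (5,))
        assert pc.p == pytest.approx(2.0 / 120.0)

    def test_null_coupling_keeps_rho_small_at_n25(self):
        """With independent per-animal factors, |rho| over 25 pairs stays
        below 0.4 in at least 90% of cohorts."""
        ok = 0
        n_sim = 500
        for s in range(n_sim):
            rng = np.random.default_rng(40_000 + s)
            x = rng.lognormal(0.0, 0.3, size=25)
            y = rng.lognormal(0.0, 0.3, size=25)
            pc = phase_correlation(_pairs_frame(x, y), (5,))
            ok += abs(pc.r) < 0.4
        assert ok / n_sim >= 0.90

    @given(st.permutations(list(range(10))))
    def test_rho_invariant_under_monotone_transforms(self, ranks):
        x = np.arange(10, dtype=float)
        y = np.array(ranks, dtype=float)
        base = phase_correlation(_pairs_frame(x, y), (5,)).r
        trans = phase_correlation(_pairs_frame(np.exp(x / 3.0), y**3 + 2.0), (5,)).r
        assert base == pytest.approx(trans)


def test_aggregate_animals_averages_sections():
    rows = []
    for sec, v in enumerate((1.0, 2.0, 3.0)):
        rows.append(dict(day=5, group="cuff", animal="c0", side="ipsilateral",
                         lamina="LII", marker="IB4", section=sec, density=v))
    agg = aggregate_animals(pd.DataFrame(rows))
    assert len(agg) == 1 and agg["density"].iloc[0] == pytest.approx(2.0)
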