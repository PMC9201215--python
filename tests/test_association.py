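"""Mantel-Haenszel / CMH machinery, FDR, and the exhaustive scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

import episcan as ep
from episcan.association import _mh_cmh, bh_fdr, scan, snp_frequency_summary
from episcan.effect_coding import build_pattern_exposure
from naive_oracle import naive_bh, naive_cmh_statistic, naive_mh_or, naive_rbg_ci


def _table(*rows):
    return ep.StratifiedTable(np.array(rows, dtype=np.int64))


class TestMantelHaenszel:
    def test_symmetric_table_gives_unit_or(self):
        or_mh, _ = ep.mantel_haenszel_or(_table((10, 10, 10, 10)))
        assert or_mh == pytest.approx(1.0)

    def test_two_identical_strata_hand_value(self):
        # (2*400/60) / (2*100/60) = 4 by the MH formula
        or_mh, _ = ep.mantel_haenszel_or(_table((20, 10, 10, 20), (20, 10, 10, 20)))
        assert or_mh == pytest.approx(4.0)

    def test_single_stratum_equals_cross_product(self):
        # sex split of the 84-case/194-control design: males exposed
        or_mh, _ = ep.mantel_haenszel_or(_table((59, 25, 124, 70)))
        assert or_mh == pytest.approx(59 * 70 / (25 * 124))
        assert or_mh == pytest.approx(1.332, abs=5e-4)

    def test_zero_denominator_reports_infinite_or(self):
        or_mh, _ = ep.mantel_haenszel_or(_table((5, 5, 0, 10)))
        assert np.isinf(or_mh)


class TestCmh:
    def test_no_association_statistic_zero(self):
        t = _table((10, 10, 10, 10))
        assert ep.cmh_statistic(t, continuity=False) == pytest.approx(0.0)
        assert ep.cmh_test(t, continuity=False) == pytest.approx(1.0)

    def test_exposure_relabel_invariance(self):
        """Swapping exposed/unexposed in every stratum leaves p unchanged."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(1, 60, size=(3, 4))
            swapped = counts[:, [1, 0, 3, 2]]
            for cc in (True, False):
                assert ep.cmh_test(
                    ep.StratifiedTable(counts), continuity=cc
                ) == pytest.approx(
                    ep.cmh_test(ep.StratifiedTable(swapped), continuity=cc)
                )

    def test_single_stratum_matches_classical_chi_square(self):
        """One stratum: CMH = Pearson chi-square rescaled by (n-1)/n,
        with the same continuity correction; p-values near-identical."""
        counts = np.array([[20, 30, 15, 40]])
        n = counts.sum()
        for cc in (True, False):
            stat = ep.cmh_statistic(ep.StratifiedTable(counts), continuity=cc)
            res = chi2_contingency(counts.reshape(2, 2), correction=cc)
            assert stat == pytest.approx(res.statistic * (n - 1) / n, rel=1e-12)
            p = ep.cmh_test(ep.StratifiedTable(counts), continuity=cc)
            assert p == pytest.approx(res.pvalue, abs=3e-3)

    def test_degenerate_strata_give_na(self):
        t = _table((0, 0, 0, 0))
        assert np.isnan(ep.cmh_test(t))


class TestOracleEquivalence:
    """Vectorized implementation vs independent naive formulas."""

    def test_random_stratified_tables_match_naive(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            k = int(rng.integers(1, 5))
            counts = rng.integers(0, 200, size=(k, 4)).astype(float)
            strata = [tuple(row) for row in counts]
            r = _mh_cmh(counts[None])
            expect_or = naive_mh_or(strata)
            got_or = r["or_mh"][0]
            if np.isfinite(expect_or):
                assert got_or == pytest.approx(expect_or, rel=1e-12)
            else:
                assert np.isinf(got_or) == np.isinf(expect_or)
            lo, hi = naive_rbg_ci(strata)
            if np.isfinite(lo):
                assert r["ci_low"][0] == pytest.approx(lo, rel=1e-12)
                assert r["ci_high"][0] == pytest.approx(hi, rel=1e-12)
            stat = naive_cmh_statistic(strata)
            if np.isfinite(stat):
                assert r["stat"][0] == pytest.approx(stat, rel=1e-12)

    def test_against_statsmodels(self):
        import warnings

        import statsmodels.stats.contingency_tables as smct

        rng = np.random.default_rng(23)
        for _ in range(50):
            k = int(rng.integers(1, 4))
            counts = rng.integers(1, 150, size=(k, 4))
            st_tables = [row.reshape(2, 2) for row in counts]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm = smct.StratifiedTable(st_tables)
                sm_or = sm.oddsratio_pooled
                sm_stat = sm.test_null_odds(correction=True).statistic
            r = _mh_cmh(counts[None].astype(float))
            assert r["or_mh"][0] == pytest.approx(sm_or, rel=1e-10)
            assert r["stat"][0] == pytest.approx(sm_stat, rel=1e-8)


@settings(deadline=None, max_examples=100)
@given(
    counts=st.lists(
        st.tuples(*[st.integers(1, 80)] * 4), min_size=1, max_size=4
    )
)
def test_polarity_inversion_property(counts):
    """Flipping exposed<->unexposed inverts OR_MH and preserves the p."""
    arr = np.array(counts)
    flipped = arr[:, [1, 0, 3, 2]]
    t1, t2 = ep.StratifiedTable(arr), ep.StratifiedTable(flipped)
    or1, _ = ep.mantel_haenszel_or(t1)
    or2, _ = ep.mantel_haenszel_or(t2)
    assert or1 * or2 == pytest.approx(1.0)
    assert ep.cmh_test(t1) == pytest.approx(ep.cmh_test(t2))


class TestBhFdr:
    def test_hand_computed_example(self):
        q = bh_fdr([0.001, 0.02, 0.9])
        assert q == pytest.approx([0.003, 0.03, 0.9])

    def test_identical_pvalues_are_a_fixed_point(self):
        assert bh_fdr([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.random(50))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    def test_matches_naive_stepup(self):
        rng = np.random.default_rng(6)
        p = rng.random(40)
        assert bh_fdr(p) == pytest.approx(naive_bh(list(p)))

    def test_empty_and_nan_handling(self):
        assert bh_fdr([]).size == 0
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestScan:
    def test_enumeration_counts_on_17_snp_panel(self, template_cohort):
        G, samples, _ = template_cohort
        assert len(scan(G, samples, 1, full=True)) == 51
        assert len(scan(G, samples, 2, full=True)) == 1224
        assert len(scan(G, samples, 3, full=True)) == 18360

    def test_scan_rows_match_scalar_path(self, template_cohort):
        """The vectorized scan reproduces per-test stratify->MH->CMH."""
        G, samples, _ = template_cohort
        df = scan(G, samples, 2, full=True)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(df), 25, replace=False):
            row = df.iloc[i]
            res = ep.test_pattern(G, samples, tuple(row.snps.split(",")), row.pattern)
            assert res.n_exposed == row.n_exposed
            if np.isnan(row.p):
                assert np.isnan(res.p)
            else:
                assert res.p == pytest.approx(row.p, rel=1e-12)
                assert res.or_mh == pytest.approx(row.or_mh, rel=1e-12, nan_ok=True)

    def test_reported_rows_respect_alpha(self, template_cohort):
        G, samples, _ = template_cohort
        df = scan(G, samples, 1, alpha=0.05)
        assert (df["p"] < 0.05).all()

    def test_invalid_order_rejected(self, template_cohort):
        G, samples, _ = template_cohort
        with pytest.raises(ep.ValidationError):
            scan(G, samples, 4)

    def test_stratify_counts_partition_included(self, template_cohort):
        G, samples, _ = template_cohort
        exposure = build_pattern_exposure(G, (G.snp_ids[0],), "d")
        t = ep.stratify(exposure, samples)
        assert t.n_strata <= 4
        assert t.total() == int(exposure.included.sum())
        assert (t.counts[:, 0] + t.counts[:, 2]).sum() == int(
            exposure.exposed.sum()
        )


def test_snp_frequency_summary_membership_counts(template_cohort):
    import pandas as pd

    df = pd.DataFrame(
        {
            "snps": ["s1,s2,s3", "s1,s2,s4", "s1,s5,s6"],
            "pattern": ["dxdxa"] * 3,
        }
    )
    out = snp_frequency_summary(df)
    assert out.iloc[0].snp_id == "s1" and out.iloc[0]["count"] == 3
    assert out["count"].sum() == 9  # order x number of interactions
    assert len(snp_frequency_summary(df.iloc[:0])) == 0
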