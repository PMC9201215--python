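"""Two-locus EM phasing and the haplotype carrier association."""

import numpy as np
import pytest

import episcan as ep
from episcan.haplotypes import (
    carrier_mask,
    default_pairs,
    em_haplotype_freqs,
    hap_label,
    haplotype_scan,
)
from episcan.genotype_io import MISSING, SnpInfo


def _gametes_to_dosages(gam):
    d1 = (gam >= 2).sum(axis=1)
    d2 = (gam % 2).sum(axis=1)
    return d1, d2


class TestEm:
    def test_phase_certain_cohort_solved_in_one_iteration(self):
        """No double heterozygotes: EM equals direct gamete counting."""
        d1 = np.array([0, 0, 2, 2, 1, 1])
        d2 = np.array([0, 2, 0, 2, 0, 2])
        hf = em_haplotype_freqs(d1, d2)
        assert hf.n_iter == 1
        # gametes: 2x(0,0)+... count directly
        expect = np.array([3, 3, 3, 3]) / 12
        assert hf.freqs == pytest.approx(expect)

    def test_perfect_ld_recovers_complete_disequilibrium(self):
        d = np.array([0, 1, 2, 2, 1, 0, 2])
        hf = em_haplotype_freqs(d, d)
        p_alt = d.sum() / (2 * len(d))
        assert hf.freqs[3] == pytest.approx(p_alt, abs=1e-6)
        assert hf.freqs[1] == pytest.approx(0.0, abs=1e-6)
        assert hf.freqs[2] == pytest.approx(0.0, abs=1e-6)

    def test_frequency_recovery_from_simulated_gametes(self):
        truth = np.array([0.4, 0.3, 0.2, 0.1])
        rng = np.random.default_rng(9)
        gam = rng.choice(4, size=(1000, 2), p=truth)
        d1, d2 = _gametes_to_dosages(gam)
        hf = em_haplotype_freqs(d1, d2)
        assert np.abs(hf.freqs - truth).max() < 0.03

    def test_loglik_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            f = rng.dirichlet(np.ones(4))
            gam = rng.choice(4, size=(300, 2), p=f)
            d1, d2 = _gametes_to_dosages(gam)
            hf = em_haplotype_freqs(d1, d2)
            diffs = np.diff(hf.loglik_path)
            assert (diffs >= -1e-9).all()

    def test_initialization_robustness(self):
        rng = np.random.default_rng(13)
        gam = rng.choice(4, size=(500, 2), p=[0.35, 0.15, 0.2, 0.3])
        d1, d2 = _gametes_to_dosages(gam)
        base = em_haplotype_freqs(d1, d2).freqs
        for seed in range(3):
            start = np.random.default_rng(seed).dirichlet(np.ones(4))
            alt = em_haplotype_freqs(d1, d2, init=start).freqs
            assert np.abs(alt - base).max() < 1e-6

    def test_estimated_counts_sum_to_two_n(self):
        rng = np.random.default_rng(15)
        gam = rng.choice(4, size=(200, 2), p=[0.4, 0.1, 0.2, 0.3])
        d1, d2 = _gametes_to_dosages(gam)
        hf = em_haplotype_freqs(d1, d2)
        assert hf.freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_informative_subjects_returns_none(self):
        d = np.array([MISSING, MISSING])
        assert em_haplotype_freqs(d, d) is None


class TestCarrierAssignment:
    def test_unambiguous_diplotypes(self):
        hf = ep.HaplotypeFreqs(np.array([0.4, 0.3, 0.2, 0.1]), 0.0, 1)
        d1 = np.array([2, 0, 2, 0, MISSING])
        d2 = np.array([2, 0, 0, 2, 1])
        included, carrier = carrier_mask(d1, d2, hf, 3)  # alt-alt
        assert list(included) == [True] * 4 + [False]
        # (2,2) always carries alt-alt; (0,0)/(2,0)/(0,2) never do
        assert list(carrier) == [True, False, False, False, False]

    def test_double_heterozygote_resolves_to_likelier_phase(self):
        cis = ep.HaplotypeFreqs(np.array([0.45, 0.1, 0.1, 0.35]), 0.0, 1)
        trans = ep.HaplotypeFreqs(np.array([0.1, 0.45, 0.35, 0.1]), 0.0, 1)
        d = np.array([1]), np.array([1])
        _, car_cis = carrier_mask(*d, cis, 3)
        _, car_trans = carrier_mask(*d, trans, 3)
        assert car_cis[0] and not car_trans[0]

    def test_hap_labels_use_nucleotide_letters(self):
        s1 = SnpInfo("rs1", "SFTPA1", "C", "T")
        s2 = SnpInfo("rs2", "SFTPA1", "C", "G")
        assert hap_label(s1, s2, 0) == "CC"
        assert hap_label(s1, s2, 3) == "TG"
        assert hap_label(s1, s2, 2) == "TC"


class TestCarrierAssociation:
    def test_planted_carrier_or_recovered(self):
        """Risk-haplotype carriers enriched in cases at OR 2.4 are detected
        with an OR estimate close to truth and a significant CMH p."""
        G, samples, truth_carrier = ep.simulate_haplotype_cohort(
            (0.5, 0.1, 0.1, 0.3), 2.4, 600, 600, seed=4
        )
        res = ep.haplotype_dominant_test(G, samples, ("snpA", "snpB"), 3)
        assert res.effect_model == "dominant"
        assert res.direction == "risk"
        assert res.p < 1e-6
        assert res.ci95[0] <= 2.4 <= res.ci95[1]
        # hard phase assignment misclassifies few subjects in positive LD
        _, carrier = carrier_mask(
            G.column("snpA"),
            G.column("snpB"),
            em_haplotype_freqs(G.column("snpA"), G.column("snpB")),
            3,
        )
        assert (carrier == truth_carrier).mean() > 0.9

    def test_absent_haplotype_gives_na_row(self):
        G, samples, _ = ep.simulate_haplotype_cohort(
            (0.6, 0.0, 0.0, 0.4), 1.0, 100, 100, seed=0
        )
        res = ep.haplotype_dominant_test(G, samples, ("snpA", "snpB"), 1)
        assert "absent_haplotype" in res.flags
        assert np.isnan(res.p)

    def test_haplotype_scan_defaults_to_adjacent_intragenic_pairs(
        self, template_cohort
    ):
        G, samples, _ = template_cohort
        pairs = default_pairs(G)
        # 17-SNP panel: 4+3+3+1+1 adjacent within-gene pairs
        assert len(pairs) == 12
        df = haplotype_scan(G, samples, pairs=pairs[:2])
        assert len(df) == 8  # four haplotypes per pair
        valid = df["q"].notna()
        assert (df.loc[valid, "q"] >= df.loc[valid, "p"] - 1e-12).all()
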