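"""Synthetic cohort generator: HWE, LD, confounding, determinism."""

from dataclasses import replace

import numpy as np
import pytest

import episcan as ep
from episcan.simulate import (
    CovariateModel,
    GenerationError,
    LdPair,
    PlantedEffect,
    SimConfig,
    SnpSpec,
    sim_config_from_dict,
    study_template,
)
from episcan.genotype_io import ValidationError


class TestConfigValidation:
    def test_template_mirrors_study_design(self):
        cfg = study_template()
        assert cfg.n_cases == 84
        assert cfg.n_controls == 194
        assert len(cfg.snp_specs) == 17
        genes = [s.gene for s in cfg.snp_specs]
        assert genes.count("SFTPA1") == 5
        assert genes.count("SFTPA2") == 4
        assert genes.count("SFTPB") == 4
        assert genes.count("SFTPC") == 2
        assert genes.count("SFTPD") == 2
        assert all(0.2 <= s.maf <= 0.4 for s in cfg.snp_specs)
        cov = cfg.covariate_model
        assert cov.p_male == pytest.approx(124 / 194)
        assert cov.p_smoker == pytest.approx(91 / 194)
        # printed demographics: cases more male, fewer smokers
        assert cov.beta_male > 0 > cov.beta_smoker

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SnpSpec("rs1", "G", "A", "C", 0.7)
        with pytest.raises(ValidationError):
            PlantedEffect(("rs1",), "d", -2.0)
        with pytest.raises(ValidationError):
            PlantedEffect(("rs1",), "dxd", 2.0)
        with pytest.raises(ValidationError):
            LdPair(("a", "b"), (0.5, 0.5, 0.5, -0.5))
        spec = (SnpSpec("rs1", "G", "A", "C", 0.3),)
        with pytest.raises(ValidationError, match="unknown SNP"):
            SimConfig(10, 10, spec, effects=(PlantedEffect(("rsX",), "d", 2.0),))
        with pytest.raises(ValidationError, match="contradicts"):
            SimConfig(
                10,
                10,
                (
                    SnpSpec("rs1", "G", "A", "C", 0.3),
                    SnpSpec("rs2", "G", "A", "C", 0.3),
                ),
                ld_pairs=(LdPair(("rs1", "rs2"), (0.5, 0.3, 0.1, 0.1)),),
            )

    def test_yaml_mirror_roundtrip(self):
        cfg = sim_config_from_dict(
            {
                "n_cases": 20,
                "n_controls": 30,
                "snps": [
                    {"snp_id": "rs1", "gene": "G1", "ref": "A", "alt": "C", "maf": 0.3},
                    {"snp_id": "rs2", "gene": "G1", "ref": "A", "alt": "G", "maf": 0.2},
                ],
                "effects": [{"snps": ["rs1"], "pattern": "d", "odds_ratio": 2.0}],
                "covariates": {"beta_male": 0.3},
                "seed": 7,
            }
        )
        assert cfg.n_cases == 20 and len(cfg.snp_specs) == 2
        assert cfg.effects[0].odds_ratio == 2.0
        G, samples, truth = ep.simulate(cfg)
        assert G.n_subjects == 50
        assert "rs1|d" in truth.exposures


class TestSimulate:
    def test_hwe_genotype_frequencies(self):
        spec = (SnpSpec("rs1", "G", "A", "C", 0.3),)
        cfg = SimConfig(5000, 5000, spec, baseline_logit=0.0, seed=1)
        G, _, _ = ep.simulate(cfg)
        n = G.n_subjects
        counts = np.bincount(G.column("rs1"), minlength=3)
        expect = np.array([0.49, 0.42, 0.09])
        se = np.sqrt(expect * (1 - expect) / n)
        assert (np.abs(counts / n - expect) < 3 * se).all()

    def test_null_model_balances_case_control_genotypes(self):
        cfg = replace(study_template(seed=2), n_cases=3000, n_controls=3000)
        G, samples, _ = ep.simulate(cfg)
        is_case = np.array(
            [s.startswith("case") for s in G.subjects]
        )
        col = G.column(G.snp_ids[0]).astype(float)
        diff = col[is_case].mean() - col[~is_case].mean()
        # no genotype effect: dosage means agree within sampling noise
        assert abs(diff) < 4 * np.sqrt(2 * 0.5 / 3000)

    def test_seed_determinism_bytes(self, tmp_path):
        from episcan.genotype_io import write_samples, write_tsv_genotypes

        cfg = study_template(seed=5)
        for run in ("a", "b"):
            G, samples, _ = ep.simulate(cfg)
            write_tsv_genotypes(G, str(tmp_path / f"{run}.g.tsv"))
            write_samples(samples, str(tmp_path / f"{run}.s.tsv"))
        assert (tmp_path / "a.g.tsv").read_bytes() == (tmp_path / "b.g.tsv").read_bytes()
        assert (tmp_path / "a.s.tsv").read_bytes() == (tmp_path / "b.s.tsv").read_bytes()

    def test_ld_pair_reproduces_haplotype_frequencies(self):
        f = (0.4, 0.3, 0.2, 0.1)
        specs = (
            SnpSpec("rs1", "G", "A", "C", 0.3),  # alt freq f10+f11
            SnpSpec("rs2", "G", "A", "G", 0.4),  # alt freq f01+f11
        )
        cfg = SimConfig(
            1500, 1500, specs, ld_pairs=(LdPair(("rs1", "rs2"), f),),
            baseline_logit=0.0, seed=3,
        )
        G, _, _ = ep.simulate(cfg)
        hf = ep.em_haplotype_freqs(G.column("rs1"), G.column("rs2"))
        assert np.abs(hf.freqs - np.array(f)).max() < 0.02

    def test_confounders_shift_status_but_not_snps(self):
        """Sex/smoking associate with status; stratified SNP tests stay null."""
        cfg = study_template(seed=8)
        G, samples, _ = ep.simulate(cfg)
        frame = samples.frame
        case_male = (frame.status == "case") & (frame.sex == "male")
        # beta_male > 0: male fraction higher among cases (in expectation)
        p_male_case = case_male.sum() / (frame.status == "case").sum()
        assert p_male_case == pytest.approx(0.70, abs=0.15)
        pvals = []
        for rep in range(40):
            G, samples, _ = ep.simulate(study_template(seed=100 + rep))
            df = ep.scan(G, samples, 1, full=True, continuity=False)
            pvals.append(df.p.to_numpy())
        rate = np.nanmean(np.concatenate(pvals) < 0.05)
        assert 0.02 < rate < 0.08

    def test_planted_exposures_recorded_in_ground_truth(self):
        eff = PlantedEffect(("rs1059057", "rs2077079", "rs1124"), "dxdxa", 3.0)
        cfg = study_template(effects=[eff], seed=9)
        G, samples, truth = ep.simulate(cfg)
        key = eff.key
        expo = truth.exposures[key]
        rebuilt = ep.build_pattern_exposure(G, eff.snp_ids, "dxdxa")
        assert (expo == rebuilt.exposed).all()

    def test_unreachable_quota_raises(self, monkeypatch):
        import sys

        spec = (SnpSpec("rs1", "G", "A", "C", 0.3),)
        cfg = SimConfig(5000, 10, spec, baseline_logit=-14.0, seed=0)
        monkeypatch.setattr(sys.modules["episcan.simulate"], "_MAX_DRAWS", 20000)
        with pytest.raises(GenerationError, match="baseline_logit"):
            ep.simulate(cfg)

    def test_missingness_rate_applied(self):
        cfg = replace(study_template(seed=10), missing_rate=0.1)
        G, _, _ = ep.simulate(cfg)
        frac = (G.dosages == -1).mean()
        assert frac == pytest.approx(0.1, abs=0.02)
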