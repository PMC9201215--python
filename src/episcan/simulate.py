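"""Synthetic case-control cohorts with planted effect-pattern signals.

The generator emulates the study design the analysis assumes: unrelated
subjects, biallelic SNPs drawn under Hardy-Weinberg equilibrium at given
alt-allele frequencies (optionally in two-locus linkage disequilibrium via
haplotype frequencies), sex and smoking drawn independently, and disease
status from a logistic penetrance model

    logit P(case) = baseline + b_male*male + b_smoker*smoker
                    + sum_e log(OR_e) * indicator_e

where each planted effect's indicator is exactly the effect-coding
conjunction rule applied to the subject's genotypes.  Cases and controls
are accumulated by rejection sampling until both quotas are met, which
reproduces case-control ascertainment exactly; the intercept is therefore a
sampling-efficiency knob, not a population prevalence.

:func:`study_template` mirrors the surfactant-protein study design: 17 SNPs
across SFTPA1/SFTPA2/SFTPB/SFTPC/SFTPD, 84 cases vs 194 controls, and sex
and smoking margins and disease log-odds taken from the printed cohort
demographics.  Allele letters in the template are plausible stand-ins, not
authoritative dbSNP annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    SampleTable,
    SnpInfo,
    ValidationError,
)
from .effect_coding import PatternLike, as_pattern, code_component

_MAX_DRAWS = 10_000_000
_BATCH = 2048


class GenerationError(Exception):
    """The requested case/control quotas could not be reached."""


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: identity, alleles and alt-allele frequency."""

    snp_id: str
    gene: str
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValidationError(
                f"{self.snp_id}: MAF {self.maf} outside (0, 0.5]"
            )

    @property
    def info(self) -> SnpInfo:
        return SnpInfo(self.snp_id, self.gene, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class LdPair:
    """Two SNPs drawn jointly from four haplotype frequencies.

    ``hap_freqs`` orders haplotypes (ref-ref, ref-alt, alt-ref, alt-alt);
    the implied marginal alt frequencies must match the SNPs' MAFs.
    """

    snp_ids: tuple[str, str]
    hap_freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.hap_freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValidationError(
                f"LD pair {self.snp_ids}: haplotype frequencies must be a "
                "distribution over 4 haplotypes"
            )

    @property
    def alt_freqs(self) -> tuple[float, float]:
        f = self.hap_freqs
        return f[2] + f[3], f[1] + f[3]


@dataclass(frozen=True)
class CovariateModel:
    """Sex/smoking prevalences and their log-odds on disease."""

    p_male: float = 0.64
    p_smoker: float = 0.47
    beta_male: float = 0.0
    beta_smoker: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (("p_male", self.p_male), ("p_smoker", self.p_smoker)):
            if not (0 <= p <= 1):
                raise ValidationError(f"{name} = {p} outside [0, 1]")


@dataclass(frozen=True)
class PlantedEffect:
    """A SNP tuple, effect pattern and conditional odds ratio to plant."""

    snp_ids: tuple[str, ...]
    pattern: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValidationError(f"effect OR {self.odds_ratio} must be > 0")
        if len(as_pattern(self.pattern)) != len(self.snp_ids):
            raise ValidationError(
                f"pattern {self.pattern!r} does not match "
                f"{len(self.snp_ids)} SNPs"
            )

    @property
    def key(self) -> str:
        return ",".join(self.snp_ids) + "|" + as_pattern(self.pattern).label


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic cohort."""

    n_cases: int
    n_controls: int
    snp_specs: tuple[SnpSpec, ...]
    ld_pairs: tuple[LdPair, ...] = ()
    covariate_model: CovariateModel = CovariateModel()
    effects: tuple[PlantedEffect, ...] = ()
    baseline_logit: float = -1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("n_cases and n_controls must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")
        ids = [s.snp_id for s in self.snp_specs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP ids in snp_specs")
        by_id = {s.snp_id: s for s in self.snp_specs}
        seen = set()
        for pair in self.ld_pairs:
            for sid, implied in zip(pair.snp_ids, pair.alt_freqs):
                if sid not in by_id:
                    raise ValidationError(f"LD pair names unknown SNP {sid!r}")
                if sid in seen:
                    raise ValidationError(f"SNP {sid!r} in two LD pairs")
                seen.add(sid)
                if abs(by_id[sid].maf - implied) > 1e-6:
                    raise ValidationError(
                        f"LD pair {pair.snp_ids}: implied alt frequency "
                        f"{implied:.6f} for {sid} contradicts MAF "
                        f"{by_id[sid].maf}"
                    )
        for eff in self.effects:
            for sid in eff.snp_ids:
                if sid not in by_id:
                    raise ValidationError(
                        f"planted effect names unknown SNP {sid!r}"
                    )


@dataclass
class GroundTruth:
    """Realized per-subject exposures of each planted effect + echoed config."""

    config: SimConfig
    exposures: dict[str, np.ndarray] = field(default_factory=dict)
    n_draws: int = 0


def _draw_genotypes(
    rng: np.random.Generator, cfg: SimConfig, size: int
) -> np.ndarray:
    """HWE (or LD-pair) dosage draws, shape (size, n_snps), int8."""
    m = len(cfg.snp_specs)
    idx = {s.snp_id: j for j, s in enumerate(cfg.snp_specs)}
    in_ld = {sid for pair in cfg.ld_pairs for sid in pair.snp_ids}
    dos = np.empty((size, m), dtype=np.int8)
    for j, spec in enumerate(cfg.snp_specs):
        if spec.snp_id in in_ld:
            continue
        dos[:, j] = rng.binomial(2, spec.maf, size=size)
    for pair in cfg.ld_pairs:
        gametes = rng.choice(4, size=(size, 2), p=np.asarray(pair.hap_freqs))
        j1, j2 = idx[pair.snp_ids[0]], idx[pair.snp_ids[1]]
        dos[:, j1] = (gametes >= 2).sum(axis=1)  # alt at first locus
        dos[:, j2] = (gametes % 2).sum(axis=1)  # alt at second locus
    return dos


def _effect_indicator(
    dos: np.ndarray, cols: Sequence[int], pattern: PatternLike
) -> np.ndarray:
    """Conjunction-rule exposure indicator on a raw dosage block."""
    pat = as_pattern(pattern)
    ind = np.ones(len(dos), dtype=bool)
    for col, comp in zip(cols, pat.components):
        _, indicator = code_component(dos[:, col], comp)
        ind &= indicator
    return ind


def simulate(
    cfg: SimConfig, seed: Optional[int] = None
) -> tuple[GenotypeMatrix, SampleTable, GroundTruth]:
    """Draw a cohort under ``cfg``; returns genotypes, samples, ground truth.

    ``seed`` overrides ``cfg.seed``.  Identical config + seed reproduce the
    cohort exactly.  Raises :class:`GenerationError` when the case quota is
    unreachable within the draw cap (raise ``baseline_logit``).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    idx = {s.snp_id: j for j, s in enumerate(cfg.snp_specs)}
    cov = cfg.covariate_model
    log_ors = [np.log(e.odds_ratio) for e in cfg.effects]
    eff_cols = [[idx[s] for s in e.snp_ids] for e in cfg.effects]

    kept_dos: list[np.ndarray] = []
    kept_case: list[np.ndarray] = []
    kept_male: list[np.ndarray] = []
    kept_smoker: list[np.ndarray] = []
    kept_expo: list[np.ndarray] = []  # (B, n_effects)
    need_cases, need_controls = cfg.n_cases, cfg.n_controls
    got_cases = got_controls = 0
    n_draws = 0
    while got_cases < need_cases or got_controls < need_controls:
        if n_draws >= _MAX_DRAWS:
            raise GenerationError(
                f"drew {n_draws} subjects without filling quotas "
                f"({got_cases}/{need_cases} cases, "
                f"{got_controls}/{need_controls} controls); "
                "increase baseline_logit"
            )
        male = rng.random(_BATCH) < cov.p_male
        smoker = rng.random(_BATCH) < cov.p_smoker
        dos = _draw_genotypes(rng, cfg, _BATCH)
        logit = np.full(
            _BATCH, cfg.baseline_logit, dtype=np.float64
        )
        logit += cov.beta_male * male + cov.beta_smoker * smoker
        expo = np.zeros((_BATCH, len(cfg.effects)), dtype=bool)
        for e_i, (cols, e) in enumerate(zip(eff_cols, cfg.effects)):
            ind = _effect_indicator(dos, cols, e.pattern)
            expo[:, e_i] = ind
            logit += log_ors[e_i] * ind
        p_case = 1.0 / (1.0 + np.exp(-logit))
        is_case = rng.random(_BATCH) < p_case
        n_draws += _BATCH
        kept_dos.append(dos)
        kept_case.append(is_case)
        kept_male.append(male)
        kept_smoker.append(smoker)
        kept_expo.append(expo)
        got_cases += int(is_case.sum())
        got_controls += int((~is_case).sum())

    dos = np.concatenate(kept_dos)
    is_case = np.concatenate(kept_case)
    male = np.concatenate(kept_male)
    smoker = np.concatenate(kept_smoker)
    expo = np.concatenate(kept_expo)

    case_rows = np.flatnonzero(is_case)[: cfg.n_cases]
    control_rows = np.flatnonzero(~is_case)[: cfg.n_controls]
    rows = np.concatenate([case_rows, control_rows])
    subject_ids = [f"case_{i + 1:04d}" for i in range(cfg.n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(cfg.n_controls)
    ]

    dosages = dos[rows].copy()
    if cfg.missing_rate > 0:
        drop = rng.random(dosages.shape) < cfg.missing_rate
        dosages[drop] = MISSING

    G = GenotypeMatrix(
        snps=[s.info for s in cfg.snp_specs],
        subjects=subject_ids,
        dosages=dosages,
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "subject_id": subject_ids,
                "status": ["case"] * cfg.n_cases + ["control"] * cfg.n_controls,
                "sex": np.where(male[rows], "male", "female"),
                "smoking": np.where(smoker[rows], "smoker", "nonsmoker"),
            }
        )
    )
    truth = GroundTruth(
        config=cfg,
        exposures={
            e.key: expo[rows, e_i] for e_i, e in enumerate(cfg.effects)
        },
        n_draws=n_draws,
    )
    return G, samples, truth


# ---------------------------------------------------------------------------
# Study template
# ---------------------------------------------------------------------------

# 17-SNP five-gene surfactant-protein panel.  Allele letters are plausible
# synthetic stand-ins chosen once (SFTPA1 entries follow the haplotype
# letters the association literature reports for that gene).
_PANEL: tuple[tuple[str, str, str, str], ...] = (
    ("rs1059047", "SFTPA1", "C", "T"),
    ("rs1136450", "SFTPA1", "C", "G"),
    ("rs1136451", "SFTPA1", "A", "G"),
    ("rs1059057", "SFTPA1", "A", "G"),
    ("rs4253527", "SFTPA1", "C", "T"),
    ("rs1059046", "SFTPA2", "A", "C"),
    ("rs17886395", "SFTPA2", "C", "G"),
    ("rs1965707", "SFTPA2", "C", "T"),
    ("rs1965708", "SFTPA2", "C", "A"),
    ("rs2077079", "SFTPB", "A", "C"),
    ("rs3024798", "SFTPB", "A", "C"),
    ("rs1130866", "SFTPB", "C", "T"),
    ("rs7316", "SFTPB", "G", "A"),
    ("rs4715", "SFTPC", "A", "C"),
    ("rs1124", "SFTPC", "A", "G"),
    ("rs721917", "SFTPD", "T", "C"),
    ("rs2243639", "SFTPD", "C", "T"),
)

_TEMPLATE_MAFS = (0.20, 0.25, 0.30, 0.35, 0.40)

# Sex and smoking margins of the healthy controls (124/194 male, 91/194
# smokers) and disease log-odds implied by the printed case/control splits:
# male 59/25 in cases vs 124/70 in controls; smoker 30/54 vs 91/103.
_P_MALE = 124 / 194
_P_SMOKER = 91 / 194
_BETA_MALE = float(np.log((59 / 25) / (124 / 70)))
_BETA_SMOKER = float(np.log((30 / 54) / (91 / 103)))


def study_template(
    n_cases: int = 84,
    n_controls: int = 194,
    effects: Sequence[PlantedEffect] = (),
    seed: int = 0,
) -> SimConfig:
    """Ready-made SimConfig mirroring the surfactant-protein study design.

    17 named SNPs across the five SP genes, 84 cases vs 194 controls, sex
    and smoking margins and confounding log-odds from the study's printed
    demographics, MAFs cycling 0.20-0.40, and no planted genotype effects
    unless supplied.
    """
    specs = tuple(
        SnpSpec(sid, gene, ref, alt, _TEMPLATE_MAFS[i % len(_TEMPLATE_MAFS)])
        for i, (sid, gene, ref, alt) in enumerate(_PANEL)
    )
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        snp_specs=specs,
        covariate_model=CovariateModel(
            p_male=_P_MALE,
            p_smoker=_P_SMOKER,
            beta_male=_BETA_MALE,
            beta_smoker=_BETA_SMOKER,
        ),
        effects=tuple(effects),
        baseline_logit=-1.0,
        seed=seed,
    )


def simulate_haplotype_cohort(
    hap_freqs: Sequence[float],
    carrier_or: float,
    n_cases: int,
    n_controls: int,
    risk_hap_index: int = 3,
    covariate_model: Optional[CovariateModel] = None,
    baseline_logit: float = -1.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SampleTable, np.ndarray]:
    """Generative model for the haplotype carrier contrast.

    Draws two gametes per subject from ``hap_freqs`` (ordering as in
    :data:`episcan.haplotypes.HAPLOTYPES`), sets disease status from
    logit = baseline + covariate terms + log(carrier_or) * carrier, where
    carrier means the diplotype contains the risk haplotype.  Returns the
    two-SNP genotype matrix, the sample table, and the realized carrier
    indicator — the oracle against which EM phasing + carrier testing is
    checked.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
        raise ValidationError("hap_freqs must be a distribution over 4 haplotypes")
    if carrier_or <= 0:
        raise ValidationError("carrier_or must be > 0")
    cov = covariate_model or CovariateModel(
        p_male=_P_MALE,
        p_smoker=_P_SMOKER,
        beta_male=_BETA_MALE,
        beta_smoker=_BETA_SMOKER,
    )
    rng = np.random.default_rng(seed)
    log_or = np.log(carrier_or)

    kept: list[tuple[np.ndarray, ...]] = []
    got_cases = got_controls = 0
    n_draws = 0
    while got_cases < n_cases or got_controls < n_controls:
        if n_draws >= _MAX_DRAWS:
            raise GenerationError("quota unreachable; increase baseline_logit")
        gam = rng.choice(4, size=(_BATCH, 2), p=f)
        d1 = (gam >= 2).sum(axis=1).astype(np.int8)
        d2 = (gam % 2).sum(axis=1).astype(np.int8)
        carrier = (gam == risk_hap_index).any(axis=1)
        male = rng.random(_BATCH) < cov.p_male
        smoker = rng.random(_BATCH) < cov.p_smoker
        logit = (
            baseline_logit
            + cov.beta_male * male
            + cov.beta_smoker * smoker
            + log_or * carrier
        )
        is_case = rng.random(_BATCH) < 1.0 / (1.0 + np.exp(-logit))
        kept.append((d1, d2, carrier, male, smoker, is_case))
        got_cases += int(is_case.sum())
        got_controls += int((~is_case).sum())
        n_draws += _BATCH

    d1, d2, carrier, male, smoker, is_case = (
        np.concatenate([k[i] for k in kept]) for i in range(6)
    )
    rows = np.concatenate(
        [np.flatnonzero(is_case)[:n_cases], np.flatnonzero(~is_case)[:n_controls]]
    )
    subject_ids = [f"case_{i + 1:04d}" for i in range(n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(n_controls)
    ]
    G = GenotypeMatrix(
        snps=[
            SnpInfo("snpA", "GENE1", "C", "T"),
            SnpInfo("snpB", "GENE1", "A", "G"),
        ],
        subjects=subject_ids,
        dosages=np.column_stack([d1[rows], d2[rows]]),
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "subject_id": subject_ids,
                "status": ["case"] * n_cases + ["control"] * n_controls,
                "sex": np.where(male[rows], "male", "female"),
                "smoking": np.where(smoker[rows], "smoker", "nonsmoker"),
            }
        )
    )
    return G, samples, carrier[rows]


# ---------------------------------------------------------------------------
# YAML config mirror
# ---------------------------------------------------------------------------

def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from the YAML key-value mirror."""
    cov = d.get("covariates", {})
    return SimConfig(
        n_cases=int(d["n_cases"]),
        n_controls=int(d["n_controls"]),
        snp_specs=tuple(
            SnpSpec(
                s["snp_id"],
                s.get("gene", ""),
                s.get("ref", "A"),
                s.get("alt", "G"),
                float(s["maf"]),
            )
            for s in d.get("snps", [])
        ),
        ld_pairs=tuple(
            LdPair(tuple(p["snps"]), tuple(float(x) for x in p["hap_freqs"]))
            for p in d.get("ld_pairs", [])
        ),
        covariate_model=CovariateModel(
            p_male=float(cov.get("p_male", 0.64)),
            p_smoker=float(cov.get("p_smoker", 0.47)),
            beta_male=float(cov.get("beta_male", 0.0)),
            beta_smoker=float(cov.get("beta_smoker", 0.0)),
        ),
        effects=tuple(
            PlantedEffect(
                tuple(e["snps"]), str(e["pattern"]), float(e["odds_ratio"])
            )
            for e in d.get("effects", [])
        ),
        baseline_logit=float(d.get("baseline_logit", -1.0)),
        missing_rate=float(d.get("missing_rate", 0.0)),
        seed=int(d.get("seed", 0)),
    )


def load_sim_config(path: str) -> SimConfig:
    import yaml

    with open(path) as fh:
        return sim_config_from_dict(yaml.safe_load(fh))
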