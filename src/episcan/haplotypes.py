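"""Two-locus haplotype frequency estimation by EM and carrier association.

At two biallelic SNPs every unphased genotype pair determines its two
gametes uniquely except the double heterozygote (1,1), which is either the
*cis* pair {ref-ref, alt-alt} or the *trans* pair {ref-alt, alt-ref}.  The
standard EM resolution assigns the two phases fractionally in proportion to
the current haplotype frequencies (E-step) and re-estimates frequencies
from expected gamete counts (M-step); the log-likelihood is nondecreasing
and, absent double heterozygotes, a single M-step equals direct gamete
counting.

Risk-haplotype association uses a dominant (carrier) contrast: frequencies
are estimated on the pooled cohort (cases + controls) to keep phase
assignment symmetric, each subject is hard-assigned their most probable
diplotype, and carrier vs non-carrier of the risk haplotype is fed through
the stratified CMH machinery.  All four candidate haplotypes are tested per
pair with BH control across the haplotype scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    SampleTable,
    SnpInfo,
    ValidationError,
)
from .effect_coding import EffectPattern, PatternExposure
from .association import (
    _direction,
    _flags,
    _mh_cmh,
    bh_fdr,
    stratify,
)

#: Haplotypes at an ordered SNP pair, as (allele at SNP1, allele at SNP2)
#: with 0 = ref, 1 = alt: index 0 ref-ref, 1 ref-alt, 2 alt-ref, 3 alt-alt.
HAPLOTYPES = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class HaplotypeFreqs:
    """EM-estimated frequencies of the four haplotypes at an ordered pair."""

    freqs: np.ndarray
    loglik: float
    n_iter: int
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (4,):
            raise ValidationError("haplotype frequency vector must have length 4")
        if (self.freqs < 0).any() or abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValidationError("haplotype frequencies must be a distribution")


@dataclass
class HaplotypeResult:
    """Carrier-contrast association of one risk haplotype at one SNP pair."""

    snp_pair: tuple[str, str]
    risk_haplotype: str
    or_mh: float
    ci95: tuple[float, float]
    p: float
    q: Optional[float]
    n_carrier: int
    n_noncarrier: int
    direction: str
    flags: tuple[str, ...] = ()
    effect_model: str = "dominant"


def _pair_counts(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair counts over subjects non-missing at both SNPs."""
    ok = (d1 != MISSING) & (d2 != MISSING)
    return (
        np.bincount(d1[ok] * 3 + d2[ok], minlength=9)
        .reshape(3, 3)
        .astype(np.float64)
    )


def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """P(genotype pair) under HWE given haplotype frequencies (3x3)."""
    h00, h01, h10, h11 = f
    P = np.empty((3, 3))
    P[0, 0] = h00**2
    P[0, 1] = 2 * h00 * h01
    P[0, 2] = h01**2
    P[1, 0] = 2 * h00 * h10
    P[1, 1] = 2 * (h00 * h11 + h01 * h10)
    P[1, 2] = 2 * h01 * h11
    P[2, 0] = h10**2
    P[2, 1] = 2 * h10 * h11
    P[2, 2] = h11**2
    return P


def _loglik(n: np.ndarray, f: np.ndarray) -> float:
    P = _genotype_probs(f)
    mask = n > 0
    if (P[mask] <= 0).any():
        return -np.inf
    return float((n[mask] * np.log(P[mask])).sum())


def em_haplotype_freqs(
    dosages_1: np.ndarray,
    dosages_2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: Optional[Sequence[float]] = None,
) -> Optional[HaplotypeFreqs]:
    """Two-locus EM from unphased dosages at an ordered SNP pair.

    Subjects missing either dosage are dropped; with zero informative
    subjects the result is None.  Iteration stops when the largest
    frequency change drops below ``tol`` or after ``max_iter`` iterations.
    The default start is linkage equilibrium (product of allele
    frequencies); a custom ``init`` distribution may be supplied.
    """
    d1 = np.asarray(dosages_1)
    d2 = np.asarray(dosages_2)
    n = _pair_counts(d1, d2)
    N = n.sum()
    if N == 0:
        return None

    # fixed gamete contributions of the phase-certain genotype cells:
    # cell (g1, g2) adds to haplotype (i, j) counts
    fixed = np.zeros(4)
    fixed[0] = 2 * n[0, 0] + n[0, 1] + n[1, 0]  # ref-ref
    fixed[1] = 2 * n[0, 2] + n[0, 1] + n[1, 2]  # ref-alt
    fixed[2] = 2 * n[2, 0] + n[1, 0] + n[2, 1]  # alt-ref
    fixed[3] = 2 * n[2, 2] + n[1, 2] + n[2, 1]  # alt-alt
    n_dh = n[1, 1]  # double heterozygotes: cis {0,3} or trans {1,2}

    if init is None:
        p_alt1 = (d1[(d1 != MISSING) & (d2 != MISSING)].sum()) / (2 * N)
        p_alt2 = (d2[(d1 != MISSING) & (d2 != MISSING)].sum()) / (2 * N)
        f = np.array(
            [
                (1 - p_alt1) * (1 - p_alt2),
                (1 - p_alt1) * p_alt2,
                p_alt1 * (1 - p_alt2),
                p_alt1 * p_alt2,
            ]
        )
    else:
        f = np.asarray(init, dtype=np.float64)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-6:
            raise ValidationError("init must be a length-4 distribution")
        f = f / f.sum()

    path: list[float] = []
    for it in range(1, max_iter + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = fixed.copy()
        counts[0] += w * n_dh
        counts[3] += w * n_dh
        counts[1] += (1 - w) * n_dh
        counts[2] += (1 - w) * n_dh
        new_f = counts / (2 * N)
        delta = np.abs(new_f - f).max()
        f = new_f
        path.append(_loglik(n, f))
        if n_dh == 0 or delta < tol:
            return HaplotypeFreqs(
                freqs=f, loglik=path[-1], n_iter=it, loglik_path=path
            )
    return HaplotypeFreqs(freqs=f, loglik=path[-1], n_iter=max_iter, loglik_path=path)


# ---------------------------------------------------------------------------
# Carrier assignment and association
# ---------------------------------------------------------------------------

# diplotype (pair of haplotype indices) for each phase-certain genotype cell
_CERTAIN_DIPLOTYPE = {
    (0, 0): (0, 0),
    (0, 1): (0, 1),
    (0, 2): (1, 1),
    (1, 0): (0, 2),
    (1, 2): (1, 3),
    (2, 0): (2, 2),
    (2, 1): (2, 3),
    (2, 2): (3, 3),
}


def carrier_mask(
    dosages_1: np.ndarray,
    dosages_2: np.ndarray,
    freqs: HaplotypeFreqs,
    hap_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(included, carrier) masks for one risk haplotype.

    Each subject is assigned their most probable diplotype under the pooled
    EM frequencies; double heterozygotes resolve to the phase with the
    higher haplotype-frequency product (cis when f00*f11 >= f01*f10).
    """
    d1 = np.asarray(dosages_1)
    d2 = np.asarray(dosages_2)
    included = (d1 != MISSING) & (d2 != MISSING)
    f = freqs.freqs
    dh_pair = (0, 3) if f[0] * f[3] >= f[1] * f[2] else (1, 2)
    carrier = np.zeros(len(d1), dtype=bool)
    for (g1, g2), pair in _CERTAIN_DIPLOTYPE.items():
        if hap_index in pair:
            carrier |= included & (d1 == g1) & (d2 == g2)
    if hap_index in dh_pair:
        carrier |= included & (d1 == 1) & (d2 == 1)
    return included, carrier


def hap_label(snp_1: SnpInfo, snp_2: SnpInfo, hap_index: int) -> str:
    """Two-letter haplotype label from the pair's ref/alt nucleotides."""
    bits = HAPLOTYPES[hap_index]
    letters = []
    for snp, bit in zip((snp_1, snp_2), bits):
        ref = snp.ref_allele if snp.ref_allele is not None else "0"
        alt = snp.alt_allele if snp.alt_allele is not None else "1"
        letters.append(alt if bit else ref)
    return "".join(letters)


def _hap_index_from_label(snp_1: SnpInfo, snp_2: SnpInfo, label: str) -> int:
    for idx in range(4):
        if hap_label(snp_1, snp_2, idx) == label:
            return idx
    raise ValidationError(
        f"haplotype label {label!r} not among "
        f"{[hap_label(snp_1, snp_2, i) for i in range(4)]}"
    )


def haplotype_dominant_test(
    G: GenotypeMatrix,
    samples: SampleTable,
    snp_pair: tuple[str, str],
    risk_haplotype: str | int,
    freqs: Optional[HaplotypeFreqs] = None,
    continuity: bool = True,
) -> HaplotypeResult:
    """Carrier-vs-non-carrier CMH test of one risk haplotype.

    ``risk_haplotype`` is an allele-letter label (e.g. ``"TG"``) or an index
    into :data:`HAPLOTYPES`.  Frequencies are estimated by EM on the pooled
    cohort unless given.  A risk haplotype with estimated frequency 0
    yields an NA row (nan OR/p, ``absent_haplotype`` flag).
    """
    s1, s2 = snp_pair
    d1 = G.column(s1)
    d2 = G.column(s2)
    info1, info2 = G.snp(s1), G.snp(s2)
    hap_index = (
        risk_haplotype
        if isinstance(risk_haplotype, int)
        else _hap_index_from_label(info1, info2, risk_haplotype)
    )
    label = hap_label(info1, info2, hap_index)
    if freqs is None:
        freqs = em_haplotype_freqs(d1, d2)
    if freqs is None or freqs.freqs[hap_index] == 0:
        return HaplotypeResult(
            snp_pair=(s1, s2),
            risk_haplotype=label,
            or_mh=np.nan,
            ci95=(np.nan, np.nan),
            p=np.nan,
            q=None,
            n_carrier=0,
            n_noncarrier=0,
            direction="na",
            flags=("absent_haplotype",),
        )
    included, carrier = carrier_mask(d1, d2, freqs, hap_index)
    exposure = PatternExposure(
        snp_ids=(s1, s2),
        pattern=EffectPattern(("d", "d")),  # placeholder; contrast is carrier
        subjects=G.subjects,
        included=included,
        exposed=carrier,
    )
    table = stratify(exposure, samples)
    arr = (
        table.counts[None].astype(np.float64)
        if table.counts.size
        else np.zeros((1, 1, 4))
    )
    r = _mh_cmh(arr, continuity=continuity)
    or_mh = float(r["or_mh"][0])
    p = float(r["p"][0])
    n_car = int(r["n_exposed"][0])
    return HaplotypeResult(
        snp_pair=(s1, s2),
        risk_haplotype=label,
        or_mh=or_mh,
        ci95=(float(r["ci_low"][0]), float(r["ci_high"][0])),
        p=p,
        q=None,
        n_carrier=n_car,
        n_noncarrier=int(r["n_unexposed"][0]),
        direction=_direction(or_mh),
        flags=_flags(or_mh, p, n_car),
    )


def default_pairs(G: GenotypeMatrix) -> list[tuple[str, str]]:
    """Adjacent SNP pairs within each gene, in panel order."""
    pairs = []
    for a, b in zip(G.snps[:-1], G.snps[1:]):
        if a.gene and a.gene == b.gene:
            pairs.append((a.snp_id, b.snp_id))
    return pairs


def haplotype_scan(
    G: GenotypeMatrix,
    samples: SampleTable,
    pairs: Optional[Iterable[tuple[str, str]]] = None,
    continuity: bool = True,
) -> pd.DataFrame:
    """Test all four candidate haplotypes at each pair, BH across the scan.

    ``pairs`` defaults to adjacent pairs within each gene.  Returns one row
    per (pair, haplotype) with EM frequency, OR, CI, p and q.
    """
    if pairs is None:
        pairs = default_pairs(G)
    rows = []
    for s1, s2 in pairs:
        freqs = em_haplotype_freqs(G.column(s1), G.column(s2))
        for idx in range(4):
            res = haplotype_dominant_test(
                G, samples, (s1, s2), idx, freqs=freqs, continuity=continuity
            )
            rows.append(
                {
                    "snp_i": s1,
                    "snp_j": s2,
                    "haplotype": res.risk_haplotype,
                    "hap_freq": (
                        float(freqs.freqs[idx]) if freqs is not None else np.nan
                    ),
                    "n_carrier": res.n_carrier,
                    "n_noncarrier": res.n_noncarrier,
                    "or_mh": res.or_mh,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "p": res.p,
                    "direction": res.direction,
                    "flags": ",".join(res.flags),
                    "effect_model": res.effect_model,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df
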