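"""Stratified 2x2 association machinery and the exhaustive pattern scan.

Exposure contrasts are tested against case/control status in 2x2 tables
stratified by sex x smoking.  The common odds ratio is the Mantel-Haenszel
estimator

    OR_MH = sum_i(a_i d_i / n_i) / sum_i(b_i c_i / n_i)

with (a, b, c, d) = (case-exposed, case-unexposed, control-exposed,
control-unexposed) and n_i the stratum total; its 95% CI comes from the
Robins-Breslow-Greenland variance of log OR_MH.  Association is tested with
the Cochran-Mantel-Haenszel chi-square (1 df, optional Yates-style
continuity correction, on by default because strata are small in cohorts of
a few hundred subjects).  Multiplicity over a scan is controlled with
Benjamini-Hochberg FDR, applied within each scan order.

All estimators are written as vectorized direct formulas over a
``(tests, strata, 4)`` count tensor; the scalar API and the exhaustive
:func:`scan` share this single code path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    SampleTable,
    STRATUM_LABELS,
    ValidationError,
)
from .effect_coding import (
    EffectPattern,
    PatternExposure,
    PatternLike,
    all_patterns,
    as_pattern,
    build_pattern_exposure,
    code_component,
)

Z95 = 1.96  # normal quantile used for the RBG 95% CI

#: Fewer exposed subjects than this flags a test as sparse.
SPARSE_EXPOSED_MIN = 5


@dataclass
class StratifiedTable:
    """Per-stratum 2x2 case/control x exposed/unexposed counts.

    ``counts`` has shape ``(n_strata, 4)`` with columns
    (case_exposed, case_unexposed, control_exposed, control_unexposed).
    Empty strata are omitted at construction.
    """

    counts: np.ndarray
    stratum_labels: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError("counts must have shape (n_strata, 4)")
        if (self.counts < 0).any():
            raise ValidationError("negative cell count")
        if not self.stratum_labels:
            self.stratum_labels = [
                ("stratum", str(i)) for i in range(len(self.counts))
            ]

    @property
    def n_strata(self) -> int:
        return len(self.counts)

    @property
    def strata(self) -> list[np.ndarray]:
        """Each stratum as a 2x2 array [[case_exp, case_unexp],
        [control_exp, control_unexp]]."""
        return [row.reshape(2, 2) for row in self.counts]

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AssociationResult:
    """One tested hypothesis: SNP tuple, pattern, OR, CI, p, q, direction."""

    snp_ids: tuple[str, ...]
    pattern: str
    or_mh: float
    ci95: tuple[float, float]
    p: float
    q: Optional[float]
    n_exposed: int
    n_unexposed: int
    direction: str
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Vectorized core
# ---------------------------------------------------------------------------

def _mh_cmh(counts: np.ndarray, continuity: bool = True) -> dict[str, np.ndarray]:
    """MH odds ratio, RBG CI and CMH test over a (T, S, 4) count tensor.

    Strata with zero total contribute nothing.  Returns float arrays of
    length T: or_mh (may be 0, inf or nan), ci_low, ci_high, stat, p,
    n_exposed, n_unexposed.  p is nan when every stratum is degenerate
    (zero hypergeometric variance).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 2:
        counts = counts[None]
    a = counts[..., 0]
    b = counts[..., 1]
    c = counts[..., 2]
    d = counts[..., 3]
    n = a + b + c + d
    pos = n > 0
    safe_n = np.where(pos, n, 1.0)

    R_i = np.where(pos, a * d / safe_n, 0.0)
    S_i = np.where(pos, b * c / safe_n, 0.0)
    R = R_i.sum(axis=-1)
    S = S_i.sum(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        or_mh = np.where(S > 0, R / np.where(S > 0, S, 1.0), np.inf)
    or_mh = np.where((S == 0) & (R == 0), np.nan, or_mh)

    # Robins-Breslow-Greenland variance of log OR_MH
    P = np.where(pos, (a + d) / safe_n, 0.0)
    Q = np.where(pos, (b + c) / safe_n, 0.0)
    sum_PR = (P * R_i).sum(axis=-1)
    sum_PSQR = (P * S_i + Q * R_i).sum(axis=-1)
    sum_QS = (Q * S_i).sum(axis=-1)
    finite = (R > 0) & (S > 0)
    Rs = np.where(finite, R, 1.0)
    Ss = np.where(finite, S, 1.0)
    var = (
        sum_PR / (2 * Rs**2)
        + sum_PSQR / (2 * Rs * Ss)
        + sum_QS / (2 * Ss**2)
    )
    se = np.sqrt(np.where(finite, var, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        log_or = np.log(np.where(finite, or_mh, 1.0))
    ci_low = np.where(finite, np.exp(log_or - Z95 * se), np.nan)
    ci_high = np.where(finite, np.exp(log_or + Z95 * se), np.nan)

    # CMH chi-square with hypergeometric mean/variance per stratum
    row1 = a + b
    row2 = c + d
    col1 = a + c
    col2 = b + d
    m_a = np.where(pos, row1 * col1 / safe_n, 0.0)
    big = n > 1
    safe_n1 = np.where(big, n, 2.0)
    v_a = np.where(
        big,
        row1 * row2 * col1 * col2 / (safe_n1**2 * (safe_n1 - 1.0)),
        0.0,
    )
    dev = np.abs((a - m_a).sum(axis=-1))
    var_sum = v_a.sum(axis=-1)
    cc = 0.5 if continuity else 0.0
    num = (dev - cc) ** 2
    testable = var_sum > 0
    stat = np.where(testable, num / np.where(testable, var_sum, 1.0), np.nan)
    p = np.where(testable, chi2.sf(np.where(testable, stat, 0.0), 1), np.nan)

    return {
        "or_mh": or_mh,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "stat": stat,
        "p": p,
        "n_exposed": (a + c).sum(axis=-1),
        "n_unexposed": (b + d).sum(axis=-1),
    }


def _direction(or_mh: float) -> str:
    if np.isnan(or_mh):
        return "na"
    if or_mh > 1:
        return "risk"
    if or_mh < 1:
        return "protective"
    return "null"


def _flags(or_mh: float, p: float, n_exposed: float) -> tuple[str, ...]:
    out = []
    if n_exposed < SPARSE_EXPOSED_MIN:
        out.append("sparse")
    if np.isinf(or_mh):
        out.append("infinite_or")
    elif or_mh == 0:
        out.append("zero_or")
    if np.isnan(p):
        out.append("degenerate")
    return tuple(out)


# ---------------------------------------------------------------------------
# Scalar API
# ---------------------------------------------------------------------------

def stratify(exposure: PatternExposure, samples: SampleTable) -> StratifiedTable:
    """Per-stratum 2x2 counts for one exposure (sex x smoking strata).

    Included subjects missing either covariate (or absent from the sample
    table) are dropped; empty strata are omitted.  With zero usable
    subjects the result has zero strata — downstream estimators then return
    NA, which callers report as an NA row.
    """
    is_case, stratum = samples.align(exposure.subjects)
    usable = exposure.included & (stratum >= 0)
    code = stratum[usable] * 2 + is_case[usable]
    exp_code = code[exposure.exposed[usable]]
    n_all = np.bincount(code, minlength=8)
    n_exp = np.bincount(exp_code, minlength=8)
    counts = []
    labels = []
    for s in range(4):
        ce = n_exp[2 * s + 1]
        xe = n_exp[2 * s]
        cu = n_all[2 * s + 1] - ce
        xu = n_all[2 * s] - xe
        if ce + cu + xe + xu == 0:
            continue
        counts.append((ce, cu, xe, xu))
        labels.append(STRATUM_LABELS[s])
    counts_arr = (
        np.asarray(counts, dtype=np.int64)
        if counts
        else np.empty((0, 4), dtype=np.int64)
    )
    return StratifiedTable(counts=counts_arr, stratum_labels=labels)


def mantel_haenszel_or(t: StratifiedTable) -> tuple[float, tuple[float, float]]:
    """Mantel-Haenszel common OR and its RBG 95% CI.

    A zero denominator yields ``inf`` (reported, not raised); an empty
    table yields ``nan``.
    """
    r = _mh_cmh(t.counts[None] if t.counts.size else np.zeros((1, 1, 4)))
    return float(r["or_mh"][0]), (float(r["ci_low"][0]), float(r["ci_high"][0]))


def cmh_statistic(t: StratifiedTable, continuity: bool = True) -> float:
    """The CMH chi-square statistic (nan if every stratum is degenerate)."""
    r = _mh_cmh(
        t.counts[None] if t.counts.size else np.zeros((1, 1, 4)),
        continuity=continuity,
    )
    return float(r["stat"][0])


def cmh_test(t: StratifiedTable, continuity: bool = True) -> float:
    """CMH p-value from the chi-square distribution with 1 df."""
    r = _mh_cmh(
        t.counts[None] if t.counts.size else np.zeros((1, 1, 4)),
        continuity=continuity,
    )
    return float(r["p"][0])


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def test_pattern(
    G: GenotypeMatrix,
    samples: SampleTable,
    snp_ids: Iterable[str],
    pattern: PatternLike,
    continuity: bool = True,
    dominant_coding: str = "deviation",
) -> AssociationResult:
    """Run one exposure through stratify -> MH OR -> CMH test."""
    exposure = build_pattern_exposure(G, snp_ids, pattern, dominant_coding)
    table = stratify(exposure, samples)
    arr = (
        table.counts[None].astype(np.float64)
        if table.counts.size
        else np.zeros((1, 1, 4))
    )
    r = _mh_cmh(arr, continuity=continuity)
    or_mh = float(r["or_mh"][0])
    p = float(r["p"][0])
    n_exposed = int(r["n_exposed"][0])
    return AssociationResult(
        snp_ids=exposure.snp_ids,
        pattern=exposure.pattern.label,
        or_mh=or_mh,
        ci95=(float(r["ci_low"][0]), float(r["ci_high"][0])),
        p=p,
        q=None,
        n_exposed=n_exposed,
        n_unexposed=int(r["n_unexposed"][0]),
        direction=_direction(or_mh),
        flags=_flags(or_mh, p, n_exposed),
    )


# ---------------------------------------------------------------------------
# Exhaustive scan
# ---------------------------------------------------------------------------

def _component_maps(dominant_coding: str) -> tuple[np.ndarray, np.ndarray]:
    """(include, indicator) lookup over component x genotype code {0,1,2,3}."""
    inc = np.zeros((3, 4), dtype=np.float64)
    ind = np.zeros((3, 4), dtype=np.float64)
    inc[0, [0, 2]] = 1  # a: homozygotes only
    ind[0, 2] = 1
    inc[1, [0, 1, 2]] = 1  # d
    if dominant_coding == "deviation":
        ind[1, 1] = 1
    elif dominant_coding == "carrier":
        ind[1, [1, 2]] = 1
    else:
        raise ValidationError(f"unknown dominant coding {dominant_coding!r}")
    inc[2, [0, 1, 2]] = 1  # r
    ind[2, 2] = 1
    return inc, ind


def scan(
    G: GenotypeMatrix,
    samples: SampleTable,
    order: int,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
    continuity: bool = True,
    dominant_coding: str = "deviation",
    full: bool = False,
) -> pd.DataFrame:
    """Exhaustive scan of every SNP combination x every pattern of ``order``.

    Enumerates C(m, k) SNP tuples x 3**k patterns, runs each through
    stratify -> MH -> CMH, and attaches BH q-values computed across the
    whole scan.  Returns rows with p < ``alpha`` sorted by p (or the full
    enumeration-ordered table when ``full`` is True).  Rows with
    q <= ``fdr_alpha`` carry an ``fdr`` flag.
    """
    if order not in (1, 2, 3):
        raise ValidationError(f"scan order must be 1, 2 or 3, got {order}")
    k = order
    m = G.n_snps
    if m < k:
        raise ValidationError(f"panel of {m} SNPs cannot form {k}-SNP tuples")

    is_case, stratum = samples.align(G.subjects)
    g = G.dosages.astype(np.int64)
    g[g == MISSING] = 3
    sc = np.where(stratum >= 0, stratum * 2 + is_case, 8)

    inc_map, ind_map = _component_maps(dominant_coding)
    M_inc = reduce(np.kron, [inc_map] * k)
    M_exp = reduce(np.kron, [ind_map] * k)
    n_pat = 3**k
    n_geno = 4**k
    patterns = [p.label for p in all_patterns(k)]

    combos = list(itertools.combinations(range(m), k))
    snp_ids = G.snp_ids
    genes = [s.gene for s in G.snps]

    blocks = []
    for combo in combos:
        gj = g[:, combo[0]].copy()
        for idx in combo[1:]:
            gj = gj * 4 + g[:, idx]
        cnt = np.bincount(gj * 9 + sc, minlength=n_geno * 9).reshape(n_geno, 9)
        cnt8 = cnt[:, :8].astype(np.float64)
        exp = M_exp @ cnt8  # (n_pat, 8)
        inc = M_inc @ cnt8
        a = exp[:, 1::2]
        c = exp[:, 0::2]
        b = inc[:, 1::2] - a
        d = inc[:, 0::2] - c
        blocks.append(np.stack([a, b, c, d], axis=-1))  # (n_pat, 4, 4)

    counts_all = np.concatenate(blocks, axis=0)
    r = _mh_cmh(counts_all, continuity=continuity)
    q = bh_fdr(r["p"])

    snps_col = np.repeat(
        [",".join(snp_ids[i] for i in combo) for combo in combos], n_pat
    )
    genes_col = np.repeat(
        [",".join(genes[i] for i in combo) for combo in combos], n_pat
    )
    pattern_col = np.tile(patterns, len(combos))

    or_mh = r["or_mh"]
    p_arr = r["p"]
    n_exp_arr = r["n_exposed"].astype(np.int64)
    direction = np.where(
        np.isnan(or_mh), "na",
        np.where(or_mh > 1, "risk", np.where(or_mh < 1, "protective", "null")),
    )
    flag_col = []
    for i in range(len(or_mh)):
        fl = list(_flags(or_mh[i], p_arr[i], n_exp_arr[i]))
        if not np.isnan(q[i]) and q[i] <= fdr_alpha:
            fl.append("fdr")
        flag_col.append(",".join(fl))

    df = pd.DataFrame(
        {
            "snps": snps_col,
            "genes": genes_col,
            "pattern": pattern_col,
            "n_exposed": n_exp_arr,
            "n_unexposed": r["n_unexposed"].astype(np.int64),
            "or_mh": or_mh,
            "ci_low": r["ci_low"],
            "ci_high": r["ci_high"],
            "p": p_arr,
            "q": q,
            "direction": direction,
            "flags": flag_col,
        }
    )
    df.attrs["order"] = order
    df.attrs["n_tests"] = len(df)
    if full:
        return df
    out = df[df["p"] < alpha].sort_values("p", kind="stable")
    out = out.reset_index(drop=True)
    out.attrs["order"] = order
    out.attrs["n_tests"] = len(df)
    return out


def snp_frequency_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP membership counts among reported significant interactions.

    Counts, for each SNP, the number of rows whose SNP tuple contains it;
    sorted by descending count (ties broken by SNP id).
    """
    counts: dict[str, int] = {}
    for snps in results["snps"]:
        for sid in str(snps).split(","):
            counts[sid] = counts.get(sid, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(items, columns=["snp_id", "count"])
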