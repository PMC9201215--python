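"""Cross-disease comparison of significant SNP-tuple interactions.

Two scan outputs (each disease against a shared control group) are matched
on canonical SNP sets — SNP ids sorted lexicographically with the pattern
components permuted in lockstep, so ``dxa`` on (s2, s1) equals ``axd`` on
(s1, s2) — and classified:

``unique_a`` / ``unique_b``
    SNP set significant in only one disease.
``same_pattern_concordant``
    a shared pattern with odds ratios on the same side of 1 in both.
``same_pattern_discordant``
    a shared pattern with odds ratios on opposite sides of 1 — the
    disease-specific signature.
``different_pattern``
    same SNP set significant in both, but under disjoint pattern sets.

The classification is descriptive; no between-disease heterogeneity test
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import ValidationError
from .effect_coding import PatternLike, as_pattern

CATEGORIES = (
    "unique_a",
    "unique_b",
    "same_pattern_concordant",
    "same_pattern_discordant",
    "different_pattern",
)


@dataclass
class ComparisonRecord:
    """Shared/unique classification of one SNP set across two diseases."""

    snp_set: tuple[str, ...]
    entries_a: list[tuple[str, float]] = field(default_factory=list)
    entries_b: list[tuple[str, float]] = field(default_factory=list)
    category: str = ""
    direction_a: str = ""
    direction_b: str = ""


def canonicalize(
    snp_ids: Sequence[str], pattern: PatternLike
) -> tuple[tuple[str, ...], str]:
    """Canonical (sorted SNP tuple, lockstep-permuted pattern label) key."""
    pat = as_pattern(pattern)
    if len(pat) != len(snp_ids):
        raise ValidationError(
            f"pattern {pat.label!r} does not match {len(snp_ids)} SNPs"
        )
    order = sorted(range(len(snp_ids)), key=lambda i: snp_ids[i])
    snps = tuple(snp_ids[i] for i in order)
    label = "x".join(pat.components[i] for i in order)
    return snps, label


def _or_direction(ors: Iterable[float]) -> str:
    ors = [o for o in ors if np.isfinite(o) or np.isinf(o)]
    if not ors:
        return "na"
    risk = any(o > 1 for o in ors)
    prot = any(o < 1 for o in ors)
    if risk and prot:
        return "mixed"
    if risk:
        return "risk"
    if prot:
        return "protective"
    return "null"


def _entries(results: pd.DataFrame) -> dict[tuple[str, ...], list[tuple[str, float]]]:
    out: dict[tuple[str, ...], list[tuple[str, float]]] = {}
    for row in results.itertuples(index=False):
        snps = tuple(str(row.snps).split(","))
        key, label = canonicalize(snps, row.pattern)
        out.setdefault(key, []).append((label, float(row.or_mh)))
    return out


def compare(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> list[ComparisonRecord]:
    """Classify every SNP set significant in either disease.

    Inputs are scan outputs of the same order on the same panel (rows are
    the reported significant interactions).  Every canonical SNP set from
    either input appears in exactly one record.
    """
    for df in (results_a, results_b):
        if not {"snps", "pattern", "or_mh"} <= set(df.columns):
            raise ValidationError(
                "comparison inputs must have snps/pattern/or_mh columns"
            )
    orders_a = {len(str(s).split(",")) for s in results_a["snps"]}
    orders_b = {len(str(s).split(",")) for s in results_b["snps"]}
    if orders_a and orders_b and orders_a != orders_b:
        raise ValidationError(
            f"scan orders differ between inputs: {orders_a} vs {orders_b}"
        )
    ent_a = _entries(results_a)
    ent_b = _entries(results_b)
    records = []
    for key in sorted(set(ent_a) | set(ent_b)):
        ea = ent_a.get(key, [])
        eb = ent_b.get(key, [])
        rec = ComparisonRecord(
            snp_set=key,
            entries_a=ea,
            entries_b=eb,
            direction_a=_or_direction(o for _, o in ea),
            direction_b=_or_direction(o for _, o in eb),
        )
        if not eb:
            rec.category = "unique_a"
        elif not ea:
            rec.category = "unique_b"
        else:
            pats_a = {p for p, _ in ea}
            pats_b = {p for p, _ in eb}
            shared = pats_a & pats_b
            if not shared:
                rec.category = "different_pattern"
            else:
                discordant = any(
                    (oa - 1) * (ob - 1) < 0
                    for p in shared
                    for pa, oa in ea
                    if pa == p
                    for pb, ob in eb
                    if pb == p
                )
                rec.category = (
                    "same_pattern_discordant"
                    if discordant
                    else "same_pattern_concordant"
                )
        records.append(rec)
    return records


def comparison_frame(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Flatten comparison records into the output table dialect."""
    rows = []
    for rec in records:
        rows.append(
            {
                "snp_set": ",".join(rec.snp_set),
                "category": rec.category,
                "patterns_a": ";".join(p for p, _ in rec.entries_a),
                "ors_a": ";".join(f"{o:.4g}" for _, o in rec.entries_a),
                "patterns_b": ";".join(p for p, _ in rec.entries_b),
                "ors_b": ";".join(f"{o:.4g}" for _, o in rec.entries_b),
                "direction_a": rec.direction_a,
                "direction_b": rec.direction_b,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_set",
            "category",
            "patterns_a",
            "ors_a",
            "patterns_b",
            "ors_b",
            "direction_a",
            "direction_b",
        ],
    )


def compare_single_snp(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> pd.DataFrame:
    """Shared/unique single-SNP association table with direction labels.

    The textual equivalent of a two-disease Venn diagram: one row per SNP
    significant in either disease, with per-disease direction arrows.
    """
    recs = compare(results_a, results_b)
    rows = []
    for rec in recs:
        if len(rec.snp_set) != 1:
            raise ValidationError("single-SNP comparison needs order-1 scans")
        shared = rec.category not in ("unique_a", "unique_b")
        rows.append(
            {
                "snp_id": rec.snp_set[0],
                "in_a": bool(rec.entries_a),
                "in_b": bool(rec.entries_b),
                "shared": shared,
                "direction_a": rec.direction_a if rec.entries_a else "",
                "direction_b": rec.direction_b if rec.entries_b else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "in_a", "in_b", "shared", "direction_a", "direction_b"],
    )
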