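"""Additive/dominant/recessive genotype contrasts and multi-SNP exposures.

Each SNP's overall genetic effect is decomposed into three binary contrasts
suitable for a 2x2 case-control table:

``a`` (additive)
    alt-homozygote vs ref-homozygote; heterozygotes are excluded, since the
    additive effect is the difference between the two homozygote classes.
``d`` (dominance deviation)
    heterozygote vs both homozygote classes — the heterozygote's deviation
    from the homozygote midpoint.  An alternative carrier coding
    (dosage >= 1) is available for sensitivity analysis.
``r`` (recessive)
    alt-homozygote vs everything else.

A k-SNP effect pattern (e.g. ``dxdxa``) assigns one component per SNP; a
subject is *exposed* when every component indicator is simultaneously on,
and *included* when every component includes the subject (intersection of
the per-SNP inclusion masks).  Missing genotypes exclude a subject from any
pattern touching that SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, ValidationError

COMPONENTS = ("a", "d", "r")
DOMINANT_CODINGS = ("deviation", "carrier")


@dataclass(frozen=True)
class EffectPattern:
    """An ordered assignment of a/d/r components to the SNPs of a tuple."""

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("pattern needs at least one component")
        for c in self.components:
            if c not in COMPONENTS:
                raise ValidationError(
                    f"unknown effect component {c!r}; expected one of "
                    f"{COMPONENTS}"
                )

    @classmethod
    def from_label(cls, label: str) -> "EffectPattern":
        """Parse a label like ``"dxdxa"`` (components joined by ``x``)."""
        return cls(tuple(label.lower().split("x")))

    @property
    def label(self) -> str:
        return "x".join(self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __str__(self) -> str:
        return self.label


PatternLike = Union[EffectPattern, str, Sequence[str]]


def as_pattern(pattern: PatternLike) -> EffectPattern:
    if isinstance(pattern, EffectPattern):
        return pattern
    if isinstance(pattern, str):
        return EffectPattern.from_label(pattern)
    return EffectPattern(tuple(pattern))


def all_patterns(k: int) -> list[EffectPattern]:
    """The 3**k effect patterns of order ``k`` in lexicographic a<d<r order."""
    pats: list[tuple[str, ...]] = [()]
    for _ in range(k):
        pats = [p + (c,) for p in pats for c in COMPONENTS]
    return [EffectPattern(p) for p in pats]


@dataclass
class PatternExposure:
    """Per-subject inclusion mask and binary exposure for one SNP tuple.

    ``exposed`` is meaningful only where ``included`` is True; excluded
    entries are False by construction, so ``included & exposed == exposed``.
    """

    snp_ids: tuple[str, ...]
    pattern: EffectPattern
    subjects: list[str]
    included: np.ndarray
    exposed: np.ndarray


def code_component(
    dosages: np.ndarray,
    component: str,
    dominant_coding: str = "deviation",
) -> tuple[np.ndarray, np.ndarray]:
    """Inclusion mask and 0/1 indicator for one component at one SNP.

    Returns ``(include, indicator)`` boolean arrays; ``indicator`` is False
    wherever ``include`` is False.
    """
    if component not in COMPONENTS:
        raise ValidationError(f"unknown effect component {component!r}")
    if dominant_coding not in DOMINANT_CODINGS:
        raise ValidationError(f"unknown dominant coding {dominant_coding!r}")
    dosages = np.asarray(dosages)
    bad = ~np.isin(dosages, (0, 1, 2, MISSING))
    if bad.any():
        raise ValidationError(
            f"dosage {dosages[bad][0]} not in {{0,1,2,MISSING}}"
        )
    nonmissing = dosages != MISSING
    if component == "a":
        include = nonmissing & (dosages != 1)
        indicator = dosages == 2
    elif component == "d":
        include = nonmissing
        if dominant_coding == "deviation":
            indicator = dosages == 1
        else:  # carrier
            include_ge1 = dosages >= 1
            indicator = nonmissing & include_ge1
    else:  # r
        include = nonmissing
        indicator = dosages == 2
    return include, indicator & include


def build_pattern_exposure(
    G: GenotypeMatrix,
    snp_ids: Iterable[str],
    pattern: PatternLike,
    dominant_coding: str = "deviation",
) -> PatternExposure:
    """Conjunction of per-SNP component contrasts over a SNP tuple.

    included = intersection of the per-SNP inclusion masks; exposed =
    conjunction of the per-SNP indicators (all components simultaneously
    on).  Subjects missing any tuple SNP are excluded.
    """
    snp_ids = tuple(snp_ids)
    pattern = as_pattern(pattern)
    if len(pattern) != len(snp_ids):
        raise ValidationError(
            f"pattern {pattern.label!r} has {len(pattern)} components for "
            f"{len(snp_ids)} SNPs"
        )
    included = np.ones(G.n_subjects, dtype=bool)
    exposed = np.ones(G.n_subjects, dtype=bool)
    for sid, comp in zip(snp_ids, pattern.components):
        inc, ind = code_component(G.column(sid), comp, dominant_coding)
        included &= inc
        exposed &= ind
    exposed &= included
    return PatternExposure(
        snp_ids=snp_ids,
        pattern=pattern,
        subjects=G.subjects,
        included=included,
        exposed=exposed,
    )
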