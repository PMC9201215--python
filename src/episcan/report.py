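"""Run manifests, provenance-stamped TSV output, and scan summaries.

Every output table starts with ``#`` comment lines embedding the run
manifest (command, seed, package version, input digests).  Manifests are
deterministic — no wall-clock fields — so identical runs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import __version__ as _pkg_version

HYDROPHILIC_GENES = frozenset({"SFTPA1", "SFTPA2", "SFTPD"})
HYDROPHOBIC_GENES = frozenset({"SFTPB", "SFTPC"})


@dataclass
class RunManifest:
    """Provenance of one pipeline invocation, embedded in output headers."""

    command: str
    seed: Optional[int] = None
    version: str = _pkg_version
    input_digests: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def digest(path: str) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()[:16]

    def add_input(self, path: str) -> None:
        self.input_digests[str(path)] = self.digest(path)

    def header_lines(self) -> list[str]:
        lines = [
            f"episcan {self.version}",
            f"command: {self.command}",
        ]
        if self.seed is not None:
            lines.append(f"seed: {self.seed}")
        for path, dig in sorted(self.input_digests.items()):
            lines.append(f"input: {path} sha256:{dig}")
        return lines


def write_table(
    df: pd.DataFrame, path: str, manifest: Optional[RunManifest] = None
) -> None:
    """Write a TSV with '#' provenance header lines."""
    with open(path, "w") as fh:
        if manifest is not None:
            for line in manifest.header_lines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def classify_composition(genes: list[str]) -> str:
    """hydrophilic / hydrophobic / mixed / other, by gene membership."""
    gset = set(genes)
    if gset and gset <= HYDROPHILIC_GENES:
        return "hydrophilic"
    if gset and gset <= HYDROPHOBIC_GENES:
        return "hydrophobic"
    if gset & HYDROPHILIC_GENES and gset & HYDROPHOBIC_GENES:
        return "mixed"
    return "other"


def is_intragenic(genes: list[str]) -> bool:
    return len(set(genes)) == 1 and bool(genes[0])


def summarize_scan(results: pd.DataFrame, n_tests: Optional[int] = None) -> str:
    """Human-readable bookkeeping of a scan's reported interactions.

    Counts by direction, by effect-pattern composition (number of dominant/
    additive/recessive components), intragenic interactions, and the
    hydrophilic/hydrophobic gene-composition split.
    """
    lines = []
    n_tests = n_tests or results.attrs.get("n_tests")
    lines.append(f"reported interactions: {len(results)}")
    if n_tests:
        lines.append(f"tests executed: {n_tests}")
    if len(results) == 0:
        return "\n".join(lines) + "\n"
    n_fdr = int(results["flags"].fillna("").str.contains("fdr").sum())
    lines.append(f"FDR-significant (q <= 0.05): {n_fdr}")
    for direction in ("risk", "protective"):
        sub = results[results["direction"] == direction]
        if len(sub):
            ors = sub["or_mh"][~sub["or_mh"].isin([float("inf"), 0.0])]
            rng = (
                f", OR {ors.min():.2f}-{ors.max():.2f}" if len(ors) else ""
            )
            lines.append(f"{direction}: {len(sub)}{rng}")
    comp_counts: dict[str, int] = {}
    for pat in results["pattern"]:
        comp_counts[pat] = comp_counts.get(pat, 0) + 1
    lines.append(
        "by pattern: "
        + ", ".join(
            f"{pat} (n={n})"
            for pat, n in sorted(comp_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
    )
    genes_lists = [str(g).split(",") for g in results["genes"]]
    n_intra = sum(is_intragenic(g) for g in genes_lists)
    lines.append(f"intragenic interactions: {n_intra}")
    comp = {"hydrophilic": 0, "hydrophobic": 0, "mixed": 0, "other": 0}
    for g in genes_lists:
        comp[classify_composition(g)] += 1
    lines.append(
        "gene composition: "
        + ", ".join(f"{k} {v}" for k, v in comp.items() if v)
    )
    return "\n".join(lines) + "\n"
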