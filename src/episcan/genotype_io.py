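"""Genotype and sample-table containers plus VCF/TSV readers and writers.

Genotypes are stored as alt-allele dosages (0/1/2) in a subjects x SNPs
integer matrix; missing calls are coded as :data:`MISSING` (-1).  Dosage
polarity always follows the ALT allele as given in the input file — the
package never re-orients alleles by frequency, so odds-ratio directions are
stable across cohorts genotyped against the same reference.

Two on-disk dialects are supported:

* VCF with GT calls (read through cyvcf2; phased ``|`` and unphased ``/``
  separators are equivalent; any allele of ``.`` makes the call missing;
  multi-allelic or non-SNP records are skipped with a warning).
* A simple tab-separated dialect: header row of SNP ids, first column the
  subject id, cells in ``{0,1,2,NA}``.  Optional ``#snp`` metadata lines
  carry gene and allele annotations so the two dialects round-trip.

Sample tables are TSVs with columns subject_id/status/sex/smoking drawn from
closed vocabularies; a missing sex or smoking value is kept but flags the
subject for exclusion from stratified tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

STATUS_VOCAB = ("case", "control")
SEX_VOCAB = ("male", "female")
SMOKING_VOCAB = ("smoker", "nonsmoker")

#: Tokens read as a missing covariate value.
NA_TOKENS = ("", "NA", "na", ".", "NaN", "nan")


class GenotypeIOError(Exception):
    """A file could not be parsed as the expected dialect."""


class ValidationError(Exception):
    """Parsed content violates a container invariant or closed vocabulary."""


@dataclass(frozen=True)
class SnpInfo:
    """Identity and allele annotation of one biallelic SNP.

    Alleles are optional because the bare TSV dialect carries none; when both
    are present they must differ.  ``gene`` is free-form ("" if unknown).
    """

    snp_id: str
    gene: str = ""
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if self.ref_allele is not None and self.alt_allele is not None:
            if self.ref_allele == self.alt_allele:
                raise ValidationError(
                    f"{self.snp_id}: ref and alt alleles are both "
                    f"{self.ref_allele!r}"
                )


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs alt-allele dosage matrix with missingness.

    ``dosages`` has shape ``(n_subjects, n_snps)`` with values in
    ``{0, 1, 2, MISSING}``.
    """

    snps: list[SnpInfo]
    subjects: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.subjects), len(self.snps)):
            raise ValidationError(
                f"dosage grid {self.dosages.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} at subject "
                f"{self.subjects[i]!r}, SNP {self.snps[j].snp_id!r} is not "
                "in {0,1,2,MISSING}"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValidationError("duplicate subject identifiers")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP identifiers in panel")
        self._snp_index = {sid: k for k, sid in enumerate(ids)}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def snp(self, snp_id: str) -> SnpInfo:
        return self.snps[self.snp_index(snp_id)]

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP, aligned with ``subjects``."""
        return self.dosages[:, self.snp_index(snp_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.subjects == other.subjects
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class SampleTable:
    """Per-subject case/control status and stratification covariates.

    Wraps a validated DataFrame with columns subject_id, status, sex,
    smoking.  sex/smoking may be None (missing covariate); such subjects are
    excluded from stratified tests, with the exclusion count logged.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["subject_id", "status", "sex", "smoking"]
        missing_cols = [c for c in required if c not in self.frame.columns]
        if missing_cols:
            raise ValidationError(f"sample table lacks columns {missing_cols}")
        df = self.frame.loc[:, required].copy()
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicated subject_id {dup!r}")
        for col, vocab in (
            ("status", STATUS_VOCAB),
            ("sex", SEX_VOCAB),
            ("smoking", SMOKING_VOCAB),
        ):
            vals = df[col]
            if col != "status":
                vals = vals[vals.notna()]
            bad = ~vals.isin(vocab)
            if bad.any():
                tok = vals[bad].iloc[0]
                raise ValidationError(
                    f"unknown {col} token {tok!r}; expected one of {vocab}"
                )
        self.frame = df.reset_index(drop=True)
        self._row = {
            sid: i for i, sid in enumerate(self.frame["subject_id"])
        }

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    def n_cases(self) -> int:
        return int((self.frame["status"] == "case").sum())

    def n_controls(self) -> int:
        return int((self.frame["status"] == "control").sum())

    def align(self, subjects: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Case indicator and stratum code aligned to ``subjects``.

        Returns ``(is_case, stratum)`` where ``is_case`` is boolean and
        ``stratum`` is an int8 code in 0..3 (sex x smoking) or -1 when the
        subject is absent from the table or has a missing covariate.  The
        number of covariate-incomplete subjects is logged.
        """
        n = len(subjects)
        is_case = np.zeros(n, dtype=bool)
        stratum = np.full(n, -1, dtype=np.int8)
        status = self.frame["status"].to_numpy()
        sex = self.frame["sex"].to_numpy(dtype=object)
        smoking = self.frame["smoking"].to_numpy(dtype=object)
        n_incomplete = 0
        for i, sid in enumerate(subjects):
            row = self._row.get(sid)
            if row is None:
                n_incomplete += 1
                continue
            is_case[i] = status[row] == "case"
            sx, sm = sex[row], smoking[row]
            if sx in SEX_VOCAB and sm in SMOKING_VOCAB:
                stratum[i] = 2 * SEX_VOCAB.index(sx) + SMOKING_VOCAB.index(sm)
            else:
                n_incomplete += 1
        if n_incomplete:
            logger.info(
                "%d of %d subjects lack complete covariates and are "
                "excluded from stratified tests",
                n_incomplete,
                n,
            )
        return is_case, stratum


STRATUM_LABELS = [
    (sx, sm) for sx in SEX_VOCAB for sm in SMOKING_VOCAB
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read GT calls from a VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of alt alleles in the GT field; any allele of ``.``
    makes the call missing; ``/`` and ``|`` separators are equivalent.
    Multi-allelic or non-SNP records are skipped with a warning (or raise if
    ``skip_multiallelic`` is False).  A ``GENE=`` INFO tag, when present,
    populates :attr:`SnpInfo.gene`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeIOError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"duplicate sample names in VCF {path}")
    snps: list[SnpInfo] = []
    columns: list[np.ndarray] = []
    try:
        for rec_no, variant in enumerate(vcf, start=1):
            alts = variant.ALT
            if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1:
                msg = (
                    f"record {rec_no} ({variant.CHROM}:{variant.POS}) is "
                    "multi-allelic or not a SNP"
                )
                if skip_multiallelic:
                    warnings.warn(f"skipping {msg}", stacklevel=2)
                    continue
                raise ValidationError(msg)
            snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
            gene = variant.INFO.get("GENE") or ""
            snps.append(
                SnpInfo(snp_id, gene, variant.REF, alts[0])
            )
            col = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(variant.genotypes):
                alleles = gt[:-1]  # last entry is the phased flag
                if any(a < 0 for a in alleles):
                    col[i] = MISSING
                else:
                    col[i] = sum(1 for a in alleles if a == 1)
            columns.append(col)
    except ValidationError:
        raise
    except Exception as exc:
        raise GenotypeIOError(
            f"malformed VCF {path} near record {len(snps) + 1}: {exc}"
        ) from exc
    dosages = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(snps=snps, subjects=samples, dosages=dosages)


def write_vcf(G: GenotypeMatrix, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write a minimal sites+GT VCF (synthetic CHROM/POS, gene in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=episcan\n")
        for line in header_lines:
            fh.write(f"##{line}\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.subjects)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, snp in enumerate(G.snps):
            ref = snp.ref_allele or "A"
            alt = snp.alt_allele or ("G" if ref != "G" else "C")
            info = f"GENE={snp.gene}" if snp.gene else "."
            gts = "\t".join(gt_code[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"1\t{j + 1}\t{snp.snp_id}\t{ref}\t{alt}\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV genotype dialect
# ---------------------------------------------------------------------------

def read_tsv_genotypes(path: str) -> GenotypeMatrix:
    """Read the TSV genotype dialect (round-trips with the writer)."""
    meta: dict[str, SnpInfo] = {}
    header: Optional[list[str]] = None
    rows: list[tuple[str, list[int]]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#snp\t"):
                parts = line.split("\t")
                if len(parts) != 5:
                    raise GenotypeIOError(
                        f"{path}:{line_no}: #snp line needs "
                        "id/gene/ref/alt fields"
                    )
                _, sid, gene, ref, alt = parts
                meta[sid] = SnpInfo(
                    sid,
                    gene,
                    ref if ref != "." else None,
                    alt if alt != "." else None,
                )
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                if parts[0] != "subject_id":
                    raise GenotypeIOError(
                        f"{path}:{line_no}: header must start with subject_id"
                    )
                header = parts[1:]
                continue
            if len(parts) != len(header) + 1:
                raise GenotypeIOError(
                    f"{path}:{line_no}: expected {len(header) + 1} fields, "
                    f"got {len(parts)}"
                )
            vals = []
            for col, cell in enumerate(parts[1:], start=2):
                if cell == "NA":
                    vals.append(MISSING)
                elif cell in ("0", "1", "2"):
                    vals.append(int(cell))
                else:
                    raise ValidationError(
                        f"{path}:{line_no}: column {col}: cell {cell!r} "
                        "not in {0,1,2,NA}"
                    )
            rows.append((parts[0], vals))
    if header is None:
        raise GenotypeIOError(f"{path}: no header row")
    snps = [meta.get(sid, SnpInfo(sid)) for sid in header]
    subjects = [r[0] for r in rows]
    dosages = (
        np.array([r[1] for r in rows], dtype=np.int8)
        if rows
        else np.empty((0, len(header)), dtype=np.int8)
    )
    return GenotypeMatrix(snps=snps, subjects=subjects, dosages=dosages)


def write_tsv_genotypes(
    G: GenotypeMatrix, path: str, header_lines: Sequence[str] = ()
) -> None:
    """Write the TSV genotype dialect; byte-stable for identical input."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for snp in G.snps:
            if snp.gene or snp.ref_allele or snp.alt_allele:
                fh.write(
                    "#snp\t{}\t{}\t{}\t{}\n".format(
                        snp.snp_id,
                        snp.gene,
                        snp.ref_allele or ".",
                        snp.alt_allele or ".",
                    )
                )
        fh.write("subject_id\t" + "\t".join(G.snp_ids) + "\n")
        for i, sid in enumerate(G.subjects):
            cells = [
                "NA" if d == MISSING else str(int(d)) for d in G.dosages[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

def read_samples(path: str) -> SampleTable:
    """Read a subject_id/status/sex/smoking TSV into a :class:`SampleTable`."""
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, comment="#", keep_default_na=False
        )
    except Exception as exc:
        raise GenotypeIOError(f"cannot parse sample table {path}: {exc}") from exc
    for col in ("sex", "smoking"):
        if col in df.columns:
            df[col] = df[col].where(~df[col].isin(NA_TOKENS), other=None)
    if "status" in df.columns and df["status"].isin(NA_TOKENS).any():
        raise ValidationError(f"{path}: status may not be missing")
    return SampleTable(df)


def write_samples(
    samples: SampleTable, path: str, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("subject_id\tstatus\tsex\tsmoking\n")
        for row in samples.frame.itertuples(index=False):
            sex = row.sex if row.sex is not None else "NA"
            smoking = row.smoking if row.smoking is not None else "NA"
            fh.write(f"{row.subject_id}\t{row.status}\t{sex}\t{smoking}\n")
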