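"""Data containers and file I/O for dominant-coded mini-exome panels.

Genotypes are carried as a dense individuals x SNPs matrix of {0, 1},
where 1 means the individual carries at least one copy of the minor
allele (dominant coding).  SNP metadata travels in a pandas DataFrame
(one row per SNP) and gene membership in an ordered ``gene_id -> column
indices`` mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rvbench")

#: columns every SNP annotation table must carry
ANNOTATION_COLUMNS = (
    "snp_id",
    "chromosome",
    "gene_id",
    "maf",
    "nonsynonymous",
    "causal",
    "beta",
)

SNP_SET_MODES = ("rare_only", "all", "nonsynonymous_only")


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Fixed individuals x SNPs dominant-coded genotype matrix.

    Parameters
    ----------
    sample_ids
        Unique individual identifiers, one per row of `calls`.
    snp_ids
        Unique SNP identifiers, one per column of `calls`.
    calls
        Matrix of {0, 1}; entry (i, j) is 1 iff individual i carries at
        least one minor allele at SNP j.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP IDs")
        bad = ~np.isin(self.calls, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary genotype at sample {self.sample_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_snps(self, columns: np.ndarray) -> "GenotypePanel":
        """Return a new panel restricted to the given SNP column indices."""
        columns = np.asarray(columns, dtype=int)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[j] for j in columns],
            calls=self.calls[:, columns].copy(),
        )


GeneMap = dict  # gene_id -> np.ndarray of SNP column indices into a panel


@dataclass
class PhenotypeReplicates:
    """R binary phenotype vectors over one fixed sample ordering.

    `statuses` has replicates in rows and individuals in columns
    (1 = affected); `ethnicity` labels the subpopulation of each
    individual, in the same column order as the genotype panel.
    """

    replicate_ids: list[str]
    statuses: np.ndarray
    ethnicity: list[str]
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.replicate_ids = [str(r) for r in self.replicate_ids]
        self.statuses = np.asarray(self.statuses, dtype=np.int8)
        self.ethnicity = [str(e) for e in self.ethnicity]
        if self.statuses.ndim != 2:
            raise ValueError("statuses must be a 2-D matrix")
        if self.statuses.shape[0] != len(self.replicate_ids):
            raise ValueError("row count does not match replicate_ids")
        if self.statuses.shape[1] != len(self.ethnicity):
            raise ValueError("column count does not match ethnicity labels")
        if not np.isin(self.statuses, (0, 1)).all():
            raise ValueError("statuses must be 0/1")
        if self.validate:
            n_aff = self.statuses.sum(axis=1)
            bad = (n_aff == 0) | (n_aff == self.statuses.shape[1])
            if bad.any():
                raise ValueError(
                    f"replicate {self.replicate_ids[int(np.argmax(bad))]!r} "
                    "has no affected or no unaffected individuals"
                )

    @property
    def n_replicates(self) -> int:
        return self.statuses.shape[0]


def validate_annotation(annotation: pd.DataFrame, panel: GenotypePanel | None = None) -> pd.DataFrame:
    """Check an annotation table's columns, dtypes and value ranges."""
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    ann = annotation.copy()
    ann["snp_id"] = ann["snp_id"].astype(str)
    ann["maf"] = ann["maf"].astype(float)
    ann["nonsynonymous"] = ann["nonsynonymous"].astype(int).astype(bool)
    ann["causal"] = ann["causal"].astype(int).astype(bool)
    ann["beta"] = ann["beta"].astype(float)
    if ((ann["maf"] < 0) | (ann["maf"] > 0.5)).any():
        raise ValueError("maf outside [0, 0.5]")
    if panel is not None:
        uncovered = set(panel.snp_ids) - set(ann["snp_id"])
        if uncovered:
            raise ValueError(f"annotation does not cover panel SNPs: {sorted(uncovered)[:5]}")
    return ann


def build_gene_map(panel: GenotypePanel, annotation: pd.DataFrame) -> GeneMap:
    """Ordered gene_id -> SNP column indices, in panel column order."""
    by_snp = annotation.set_index("snp_id")["gene_id"]
    missing = [s for s in panel.snp_ids if s not in by_snp.index]
    if missing:
        raise ValueError(f"SNPs without gene assignment: {missing[:5]}")
    gene_map: GeneMap = {}
    for j, snp in enumerate(panel.snp_ids):
        gene_map.setdefault(str(by_snp[snp]), []).append(j)
    return {g: np.asarray(idx, dtype=int) for g, idx in gene_map.items()}


# ---------------------------------------------------------------------------
# genotype TSV
# ---------------------------------------------------------------------------


def read_genotype_tsv(path) -> GenotypePanel:
    """Read a dominant-coded genotype TSV.

    Layout: header row of SNP IDs (first cell names the sample-ID
    column), one row per individual, body entries 0/1.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    snp_header = header[1:]
    if len(set(snp_header)) != len(snp_header):
        raise ParseError(f"{path}: duplicate SNP IDs in header")
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample IDs")
    values = df.to_numpy()
    ok = np.isin(values, ("0", "1"))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ParseError(
            f"{path}: entry {values[i, j]!r} at sample {df.index[i]!r}, "
            f"SNP {df.columns[j]!r} is not 0/1"
        )
    return GenotypePanel(
        sample_ids=list(df.index),
        snp_ids=list(df.columns),
        calls=values.astype(np.int8),
    )


def write_genotype_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.calls, index=panel.sample_ids, columns=panel.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_as_dominant(path) -> GenotypePanel:
    """Read a VCF and recode genotypes to dominant 0/1 on the minor allele.

    Per biallelic site the minor allele is determined by allele count
    across the cohort (ties broken to ALT); an individual is coded 1 iff
    it carries at least one copy of that minor allele.  Multiallelic
    records are skipped with a warning; missing genotypes are coded 0
    (non-carrier) and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%s", variant.CHROM, variant.POS
            )
            continue
        # genotypes: rows [allele0, allele1, phased]; -1 marks missing
        gts = np.asarray([g[:2] for g in variant.genotypes], dtype=int)
        n_missing = int((gts < 0).any(axis=1).sum())
        if n_missing:
            logger.warning(
                "%s:%s: %d missing genotype(s) coded 0",
                variant.CHROM, variant.POS, n_missing,
            )
        observed = gts[gts >= 0]
        alt_count = int((observed == 1).sum())
        ref_count = int((observed == 0).sum())
        minor = 1 if alt_count <= ref_count else 0  # tie -> ALT
        carrier = ((gts == minor).any(axis=1)).astype(np.int8)
        snp_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        snp_ids.append(snp_id)
        columns.append(carrier)
    if not columns:
        raise ParseError(f"{path}: no usable biallelic records")
    return GenotypePanel(
        sample_ids=samples,
        snp_ids=snp_ids,
        calls=np.column_stack(columns),
    )


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def compute_maf(calls_column, raw_allele_counts: tuple[int, int] | None = None) -> float:
    """Minor allele frequency for one SNP.

    With `raw_allele_counts` = (minor, major) the MAF is the exact allele
    fraction.  Without them (0/1 dominant input) the carrier fraction f
    is back-transformed under Hardy-Weinberg equilibrium:
    f = 1 - (1 - q)^2, hence q = 1 - sqrt(1 - f).
    """
    if raw_allele_counts is not None:
        minor, major = raw_allele_counts
        total = minor + major
        if total <= 0:
            raise ValueError("raw allele counts empty")
        return min(minor, major) / total
    col = np.asarray(calls_column, dtype=float)
    if col.size == 0:
        raise ValueError("empty genotype column")
    f = float(col.mean())
    q = 1.0 - float(np.sqrt(1.0 - min(f, 1.0)))
    # fold to the minor side: a carrier fraction above 1 - 0.25 implies
    # the complementary allele is the rarer one
    return min(q, 1.0 - q)


# ---------------------------------------------------------------------------
# SNP-set selection
# ---------------------------------------------------------------------------


def select_snp_set(
    panel: GenotypePanel,
    annotation: pd.DataFrame,
    mode: str,
    maf_cut: float = 0.05,
) -> tuple[GenotypePanel, GeneMap]:
    """Restrict the panel to one of the paper-style SNP sets.

    ``rare_only`` keeps SNPs with MAF < `maf_cut`; ``nonsynonymous_only``
    keeps flagged SNPs; ``all`` is the identity.  Genes left without any
    SNP are dropped from the returned gene map.
    """
    if mode not in SNP_SET_MODES:
        raise ValueError(f"unknown SNP-set mode {mode!r}; expected one of {SNP_SET_MODES}")
    ann = validate_annotation(annotation, panel).set_index("snp_id")
    covered = [s for s in panel.snp_ids if s not in ann.index]
    if covered:
        raise ValueError(f"annotation does not cover SNPs: {covered[:5]}")
    keep = []
    for j, snp in enumerate(panel.snp_ids):
        row = ann.loc[snp]
        if mode == "all":
            keep.append(j)
        elif mode == "rare_only" and row["maf"] < maf_cut:
            keep.append(j)
        elif mode == "nonsynonymous_only" and bool(row["nonsynonymous"]):
            keep.append(j)
    sub = panel.subset_snps(np.asarray(keep, dtype=int))
    gene_map = build_gene_map(sub, annotation)
    return sub, gene_map


# ---------------------------------------------------------------------------
# result grid and auxiliary tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ("method", "gene_id", "replicate_id", "statistic", "p_value", "status")


def write_results_tsv(grid: pd.DataFrame, path) -> None:
    """Write a long-format ResultGrid TSV with deterministic row order."""
    out = grid.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            raise ValueError(f"result grid missing column {col!r}")
    out = out[list(RESULT_COLUMNS)]
    out = out.sort_values(["method", "gene_id", "replicate_id"], kind="stable")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_tsv(path) -> pd.DataFrame:
    grid = pd.read_csv(
        path, sep="\t",
        dtype={"method": str, "gene_id": str, "replicate_id": str, "status": str},
        na_values=["NA"], keep_default_na=False,
    )
    for col in RESULT_COLUMNS:
        if col not in grid.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return grid


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str, "gene_id": str})
    return validate_annotation(ann)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation)
    out = annotation.copy()
    out["nonsynonymous"] = out["nonsynonymous"].astype(int)
    out["causal"] = out["causal"].astype(int)
    out[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path, sample_ids: list[str] | None = None,
                       ethnicity: list[str] | None = None) -> PhenotypeReplicates:
    """Read the wide phenotype table (rows = replicates, columns = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_ids is not None:
        missing = set(sample_ids) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: phenotype table lacks samples {sorted(missing)[:5]}")
        df = df[list(sample_ids)]
    eth = ethnicity if ethnicity is not None else ["pop1"] * df.shape[1]
    return PhenotypeReplicates(
        replicate_ids=[str(r) for r in df.index],
        statuses=df.to_numpy(dtype=np.int8),
        ethnicity=eth,
    )


def write_phenotype_tsv(replicates: PhenotypeReplicates, sample_ids: list[str], path) -> None:
    df = pd.DataFrame(replicates.statuses, index=replicates.replicate_ids, columns=sample_ids)
    df.index.name = "replicate_id"
    df.to_csv(path, sep="\t")


def read_ethnicity_tsv(path, sample_ids: list[str] | None = None) -> list[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise ParseError(f"{path}: expected columns sample_id, population")
    by_sample = dict(zip(df["sample_id"], df["population"]))
    if sample_ids is None:
        return list(df["population"])
    missing = [s for s in sample_ids if s not in by_sample]
    if missing:
        raise ParseError(f"{path}: no ethnicity for samples {missing[:5]}")
    return [by_sample[s] for s in sample_ids]


def write_ethnicity_tsv(sample_ids: list[str], ethnicity: list[str], path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "population": ethnicity}).to_csv(
        path, sep="\t", index=False
    )
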