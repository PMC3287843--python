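"""Replicate-grid execution and evaluation statistics.

Runs the burden tests over every (method, gene, phenotype replicate)
cell and summarises the resulting p-value grid the way simulation
studies of rare-variant tests report it: mean significant genes per
replicate, true-discovery / false-positive / true-positive percentages,
a binomial-threshold classifier for spuriously associated genes, a
per-replicate population-stratification chi-square P, and the gametic
phase disequilibrium diagnostics G (per-SNP r^2 against the causal
SNPs) and S (panel-wide mean squared cross-chromosome correlation with
a column-permutation null and Z score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .burden import METHODS, PermutationPlan, run_gene
from .io import GeneMap, GenotypePanel, PhenotypeReplicates, validate_annotation

logger = logging.getLogger("rvbench")

BASE_METHODS = ("CMC", "WS", "PR", "CMAT")
DEFAULT_ALPHAS = (0.05, 0.005)


# ---------------------------------------------------------------------------
# grid execution
# ---------------------------------------------------------------------------


def _cell_seed(master: int, method_i: int, gene_i: int, rep_i: int) -> np.random.SeedSequence:
    """Deterministic per-cell seed: one SeedSequence keyed by indices."""
    return np.random.SeedSequence(entropy=master, spawn_key=(method_i, gene_i, rep_i))


def run_grid(
    panel: GenotypePanel,
    gene_map: GeneMap,
    annotation: pd.DataFrame,
    replicates: PhenotypeReplicates,
    methods=BASE_METHODS,
    plan: PermutationPlan | None = None,
) -> pd.DataFrame:
    """Run each requested method on every gene x phenotype replicate.

    Returns the long-format ResultGrid (one row per cell).  Each cell is
    seeded from the master seed and the (method, gene, replicate)
    indices, so any single result is reproducible in isolation.
    """
    plan = plan or PermutationPlan()
    if len(replicates.ethnicity) != panel.n_samples:
        raise ValueError("replicate sample count does not match panel")
    ann = validate_annotation(annotation, panel).set_index("snp_id")
    mafs_all = ann["maf"].reindex(panel.snp_ids).to_numpy()
    strata = np.asarray(replicates.ethnicity)
    records = []
    for mi, method in enumerate(methods):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        for gi, (gene, cols) in enumerate(gene_map.items()):
            gene_calls = panel.calls[:, cols]
            mafs = mafs_all[cols]
            for ri, rep in enumerate(replicates.replicate_ids):
                pheno = replicates.statuses[ri]
                seed = int(_cell_seed(plan.seed, mi, gi, ri).generate_state(1)[0] % (2**31))
                cell_plan = PermutationPlan(B=plan.B, seed=seed, tail=plan.tail)
                out = run_gene(
                    method, gene_calls, mafs, pheno,
                    strata=strata, plan=cell_plan, gene_id=gene,
                )
                records.append(
                    (method, gene, rep, out.statistic, out.p_value, out.status)
                )
    return pd.DataFrame(
        records,
        columns=["method", "gene_id", "replicate_id", "statistic", "p_value", "status"],
    )


# ---------------------------------------------------------------------------
# discovery summaries
# ---------------------------------------------------------------------------


def discovery_summary(grid: pd.DataFrame, causal_genes: set,
                      alphas=DEFAULT_ALPHAS) -> pd.DataFrame:
    """Per-method, per-alpha discovery table.

    Columns: mean significant genes per replicate, mean causal
    significant per replicate, true-discovery %, false-positive rate %
    over noncausal gene-replicate cells, true-positive rate % over
    causal cells.  True-discovery % is NaN when nothing is significant.
    """
    causal_genes = set(causal_genes)
    rows = []
    for method, sub in grid.groupby("method", sort=True):
        is_causal = sub["gene_id"].isin(causal_genes)
        n_reps = sub["replicate_id"].nunique()
        for alpha in alphas:
            sig = sub["p_value"] < alpha
            total_sig = float(sig.sum()) / n_reps
            causal_sig = float((sig & is_causal).sum()) / n_reps
            n_sig = int(sig.sum())
            td = 100.0 * (sig & is_causal).sum() / n_sig if n_sig else np.nan
            n_noncausal = int((~is_causal).sum())
            n_causal = int(is_causal.sum())
            fpr = 100.0 * (sig & ~is_causal).sum() / n_noncausal if n_noncausal else np.nan
            tpr = 100.0 * (sig & is_causal).sum() / n_causal if n_causal else np.nan
            rows.append((method, alpha, total_sig, causal_sig, td, fpr, tpr))
    return pd.DataFrame(
        rows,
        columns=[
            "method", "alpha", "mean_significant", "mean_causal_significant",
            "true_discovery_pct", "false_positive_rate_pct", "true_positive_rate_pct",
        ],
    )


def random_guess_true_discovery(n_causal: int, n_genes: int) -> float:
    """True-discovery % achieved by declaring genes significant at random."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return 100.0 * n_causal / n_genes


# ---------------------------------------------------------------------------
# spurious-gene classification
# ---------------------------------------------------------------------------


def spurious_threshold(n_reps: int = 200, alpha: float = 0.05,
                       percentile: float = 0.96) -> int:
    """Replicate-count cutoff for calling a gene spuriously associated.

    The smallest count c with Bin(n_reps, alpha) CDF(c) >= percentile
    (equivalently P(X > c) <= 1 - percentile), computed by exact pmf
    summation and floored at 1 so an all-zero null never labels genes.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    pmf = stats.binom.pmf(np.arange(n_reps + 1), n_reps, alpha)
    cdf = np.cumsum(pmf)
    c = int(np.searchsorted(cdf, percentile - 1e-12))
    return max(c, 1)


@dataclass
class SpuriousGeneReport:
    """Noncausal genes consistently significant across replicates."""

    threshold: int
    alpha: float
    spurious_genes: list[str]
    covariates: pd.DataFrame = field(repr=False)  # per-gene table
    sig_counts: pd.DataFrame = field(repr=False)  # gene x method counts


def classify_spurious(
    grid: pd.DataFrame,
    causal_genes: set,
    threshold: int,
    alpha: float = 0.05,
    annotation: pd.DataFrame | None = None,
    gene_map: GeneMap | None = None,
    G: pd.Series | None = None,
) -> SpuriousGeneReport:
    """Flag noncausal genes significant in >= `threshold` replicates by
    every one of the four base methods.

    `annotation`, `gene_map` and per-SNP `G` (indexed by snp_id) fill
    the per-gene covariate table (snp_count, mean_maf, mean_G) when
    available.
    """
    present = set(grid["method"])
    missing = set(BASE_METHODS) - present
    if missing:
        raise ValueError(f"grid lacks methods required for spurious classification: {sorted(missing)}")
    causal_genes = set(causal_genes)
    sub = grid[grid["method"].isin(BASE_METHODS)]
    counts = (
        sub.assign(sig=sub["p_value"] < alpha)
        .pivot_table(index="gene_id", columns="method", values="sig", aggfunc="sum")
        .fillna(0)
        .astype(int)
    )
    all_over = (counts >= threshold).all(axis=1)
    spurious = sorted(g for g in counts.index[all_over] if g not in causal_genes)

    genes = list(counts.index)
    cov = pd.DataFrame({"gene_id": genes}).set_index("gene_id")
    cov["causal"] = [g in causal_genes for g in genes]
    cov["spurious"] = [g in set(spurious) for g in genes]
    cov["snp_count"] = np.nan
    cov["mean_maf"] = np.nan
    cov["mean_G"] = np.nan
    if annotation is not None:
        ann = validate_annotation(annotation)
        per_gene = ann.groupby("gene_id")
        cov.loc[:, "snp_count"] = per_gene.size().reindex(genes).to_numpy(dtype=float)
        cov.loc[:, "mean_maf"] = per_gene["maf"].mean().reindex(genes).to_numpy()
        if G is not None:
            ann_g = ann.set_index("snp_id").join(G.rename("G"), how="left")
            cov.loc[:, "mean_G"] = (
                ann_g.groupby("gene_id")["G"].mean().reindex(genes).to_numpy()
            )
    return SpuriousGeneReport(
        threshold=threshold, alpha=alpha, spurious_genes=spurious,
        covariates=cov.reset_index(), sig_counts=counts,
    )


def export_covariates(report: SpuriousGeneReport, grid: pd.DataFrame, path=None) -> pd.DataFrame:
    """Per-gene covariate/significance-count table (one row per gene)."""
    counts = report.sig_counts.add_prefix("sig_count_")
    table = report.covariates.set_index("gene_id").join(counts, how="left").reset_index()
    table = table.sort_values("gene_id", kind="stable").reset_index(drop=True)
    if path is not None:
        table.to_csv(path, sep="\t", index=False, na_rep="NA")
    return table


# ---------------------------------------------------------------------------
# population stratification
# ---------------------------------------------------------------------------


@dataclass
class StratificationReport:
    """Per-replicate phenotype x ethnicity chi-square values."""

    replicate_ids: list[str]
    P: np.ndarray  # NaN where undefined
    correlation_with_hits: pd.DataFrame | None = None


def stratification_P(replicates: PhenotypeReplicates) -> StratificationReport:
    """Pearson chi-square of affection status against ethnicity, per replicate.

    Populations with zero members are dropped; if fewer than two remain
    the replicate's P is NaN.
    """
    labels = np.asarray(replicates.ethnicity)
    pops = [p for p in dict.fromkeys(labels) if (labels == p).sum() > 0]
    values = np.full(replicates.n_replicates, np.nan)
    for ri in range(replicates.n_replicates):
        status = replicates.statuses[ri]
        table = np.array(
            [[(status[labels == p] == s).sum() for p in pops] for s in (0, 1)],
            dtype=float,
        )
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            logger.debug("replicate %s: stratification P undefined", ri)
            continue
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        values[ri] = float(((table - expected) ** 2 / expected).sum())
    return StratificationReport(list(replicates.replicate_ids), values)


def correlate_P_with_hits(grid: pd.DataFrame, report: StratificationReport,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r between per-replicate P and significant-gene counts.

    Returns one row per method with r and its p-value; NaN when either
    series is constant or fewer than 3 replicates have a defined P.
    """
    P = pd.Series(report.P, index=report.replicate_ids, name="P")
    rows = []
    for method, sub in grid.groupby("method", sort=True):
        hits = (
            sub.assign(sig=sub["p_value"] < alpha)
            .groupby("replicate_id")["sig"].sum()
            .reindex(report.replicate_ids)
        )
        ok = P.notna() & hits.notna()
        r, pv = np.nan, np.nan
        if ok.sum() >= 3 and P[ok].nunique() > 1 and hits[ok].nunique() > 1:
            r, pv = stats.pearsonr(P[ok], hits[ok])
        else:
            logger.debug("correlate_P_with_hits: undefined for %s", method)
        rows.append((method, r, pv))
    return pd.DataFrame(rows, columns=["method", "r", "p_value"])


# ---------------------------------------------------------------------------
# gametic phase disequilibrium
# ---------------------------------------------------------------------------


def gpd_G(noncausal_calls: np.ndarray, causal_calls: np.ndarray) -> float:
    """r^2 from regressing one noncausal SNP on the causal genotypes.

    Ordinary least squares with intercept (least-squares pseudo-inverse
    when collinear); clipped to [0, 1].  NaN for a constant response.
    """
    y = np.asarray(noncausal_calls, dtype=float)
    X = np.atleast_2d(np.asarray(causal_calls, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if y.size < 2:
        raise ValueError("need more than one individual")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0.0:
        logger.debug("gpd_G: constant noncausal genotype; undefined")
        return np.nan
    A = np.column_stack([np.ones_like(y), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((y - A @ coef) ** 2).sum())
    return float(np.clip(1.0 - rss / tss, 0.0, 1.0))


def gpd_G_all(panel: GenotypePanel, annotation: pd.DataFrame) -> pd.Series:
    """G for every noncausal SNP in the panel (index: snp_id)."""
    ann = validate_annotation(annotation, panel).set_index("snp_id")
    causal_flags = ann["causal"].reindex(panel.snp_ids).to_numpy()
    causal_cols = np.flatnonzero(causal_flags)
    noncausal_cols = np.flatnonzero(~causal_flags)
    X = panel.calls[:, causal_cols].astype(float)
    A = np.column_stack([np.ones(panel.n_samples), X])
    # one pseudo-inverse, reused for every response column
    pinv = np.linalg.pinv(A)
    Y = panel.calls[:, noncausal_cols].astype(float)
    fitted = A @ (pinv @ Y)
    rss = ((Y - fitted) ** 2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.clip(1.0 - rss / tss, 0.0, 1.0)
    r2 = np.where(tss == 0.0, np.nan, r2)
    return pd.Series(r2, index=[panel.snp_ids[j] for j in noncausal_cols], name="G")


@dataclass
class GpdReport:
    """Panel-wide gametic phase disequilibrium summary."""

    S_observed: float
    null_mean: float
    null_sd: float
    Z: float
    null_max: float
    n_pairs: int
    B: int


def _pair_sample_r2(calls: np.ndarray, chrom: np.ndarray, n_pairs: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Squared Pearson correlations of random cross-chromosome column pairs.

    Pairs are drawn with replacement; draws landing on the same
    chromosome or on a constant column are rejected and redrawn.
    """
    n, m = calls.shape
    sd = calls.std(axis=0)
    usable = sd > 0
    chroms_usable = set(chrom[usable])
    if len(chroms_usable) < 2:
        raise ValueError("need >=2 chromosomes with a non-constant column")
    centered = (calls - calls.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    out = np.empty(n_pairs)
    filled = 0
    while filled < n_pairs:
        draw = max(2 * (n_pairs - filled), 64)
        i = rng.integers(0, m, size=draw)
        j = rng.integers(0, m, size=draw)
        ok = (chrom[i] != chrom[j]) & usable[i] & usable[j]
        i, j = i[ok], j[ok]
        take = min(i.size, n_pairs - filled)
        r = (centered[:, i[:take]] * centered[:, j[:take]]).mean(axis=0)
        out[filled:filled + take] = r**2
        filled += take
    return out


def gpd_S(panel: GenotypePanel, annotation: pd.DataFrame,
          n_pairs: int = 100_000, seed: int = 0) -> float:
    """Mean squared correlation over random cross-chromosome SNP pairs."""
    ann = validate_annotation(annotation, panel).set_index("snp_id")
    chrom = ann["chromosome"].reindex(panel.snp_ids).to_numpy()
    rng = np.random.default_rng(seed)
    r2 = _pair_sample_r2(panel.calls.astype(float), chrom, n_pairs, rng)
    return float(r2.mean())


def gpd_S_null(panel: GenotypePanel, annotation: pd.DataFrame,
               n_pairs: int = 100_000, B: int = 1000, seed: int = 0) -> GpdReport:
    """Permutation null for S: rows permuted independently within each
    column, S recomputed B times, Z = (S_obs - mean) / sd."""
    ann = validate_annotation(annotation, panel).set_index("snp_id")
    chrom = ann["chromosome"].reindex(panel.snp_ids).to_numpy()
    rng = np.random.default_rng(seed)
    calls = panel.calls.astype(float)
    s_obs = float(_pair_sample_r2(calls, chrom, n_pairs, rng).mean())
    null = np.empty(B)
    for b in range(B):
        permuted = rng.permuted(calls, axis=0)
        null[b] = _pair_sample_r2(permuted, chrom, n_pairs, rng).mean()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (s_obs - null_mean) / null_sd if null_sd > 0 else np.nan
    if null_sd == 0:
        logger.debug("gpd_S_null: zero null sd; Z undefined")
    return GpdReport(
        S_observed=s_obs, null_mean=null_mean, null_sd=null_sd, Z=float(z),
        null_max=float(null.max()), n_pairs=n_pairs, B=B,
    )


# ---------------------------------------------------------------------------
# power vs effect size
# ---------------------------------------------------------------------------


def power_effect_correlation(grid: pd.DataFrame, annotation: pd.DataFrame,
                             gene_map: GeneMap, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r, per method, between causal genes' significance counts
    and their aggregate effect measure sum_j maf_j * beta_j."""
    ann = validate_annotation(annotation)
    causal_genes = sorted(set(ann.loc[ann["causal"], "gene_id"]) & set(gene_map))
    effect = (
        ann.assign(mb=ann["maf"] * ann["beta"])
        .groupby("gene_id")["mb"].sum()
        .reindex(causal_genes)
    )
    rows = []
    for method, sub in grid.groupby("method", sort=True):
        counts = (
            sub[sub["gene_id"].isin(causal_genes)]
            .assign(sig=lambda d: d["p_value"] < alpha)
            .groupby("gene_id")["sig"].sum()
            .reindex(causal_genes)
        )
        r, pv = np.nan, np.nan
        if (
            len(causal_genes) >= 3
            and effect.nunique() > 1
            and counts.nunique() > 1
        ):
            r, pv = stats.pearsonr(effect, counts)
        else:
            logger.debug("power_effect_correlation: undefined for %s", method)
        rows.append((method, r, pv, len(causal_genes)))
    return pd.DataFrame(rows, columns=["method", "r", "p_value", "n_causal_genes"])
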