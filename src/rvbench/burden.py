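"""Gene-level rare-variant association tests and the permutation engine.

Implements the four burden-style tests compared in the package, all on
dominant-coded 0/1 genotypes:

* **CMC** — combined multivariate and collapsing: SNPs with MAF below a
  collapsing threshold are merged into one carrier indicator, the
  remaining SNPs keep their own columns, and cases are compared with
  controls by a two-sample Hotelling T^2 with an asymptotic F reference.
* **WS** — weighted sum: per-individual genotype scores weighted by the
  inverse null standard deviation of each variant (weights estimated
  from the unaffected group with +1 pseudo-counts), ranked over the
  cohort; the statistic is the rank sum over affected individuals, with
  significance by phenotype permutation.
* **PR** — proportion regression: the fraction of a gene's variant
  sites carried by each individual is the predictor in a logistic
  regression of disease status, tested by an asymptotic Wald z.
* **CMAT** — cumulative minor allele test: a 2x2 chi-square comparing
  the proportion of carried rare alleles between cases and controls,
  with significance by phenotype permutation; a stratified variant pools
  per-stratum tables in Mantel-Haenszel form with within-stratum
  permutation.

Permutation p-values use the add-one convention p = (1 + r) / (1 + B),
so p is never 0 and never below 1/(B+1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("rvbench")

METHODS = ("CMC", "WS", "PR", "CMAT", "CMAT_STRAT")

#: MAF below which CMC collapses SNPs into one subgroup
DEFAULT_COLLAPSE_CUT = 0.01
#: permutations for WS / CMAT significance
DEFAULT_PERMUTATIONS = 1000

_IRLS_MAXITER = 50
_IRLS_TOL = 1e-8
_SEPARATION_SLOPE = 30.0  # |slope| beyond this on a [0,1] predictor = separation


@dataclass(frozen=True)
class PermutationPlan:
    """Number of phenotype permutations and the seed that drives them."""

    B: int = DEFAULT_PERMUTATIONS
    seed: int = 0
    tail: str = "upper"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.tail != "upper":
            raise ValueError("only upper-tail permutation tests are defined")


@dataclass(frozen=True)
class TestOutcome:
    """One method's result on one gene for one phenotype vector."""

    method: str
    gene_id: str
    statistic: float
    p_value: float
    df_or_B: int
    status: str = "ok"  # "ok" | "degenerate"


# ---------------------------------------------------------------------------
# CMC
# ---------------------------------------------------------------------------


def cmc_collapse(gene_calls: np.ndarray, mafs: np.ndarray,
                 collapse_cut: float = DEFAULT_COLLAPSE_CUT) -> np.ndarray:
    """Collapse a gene's rare SNPs into one indicator column.

    SNPs with MAF < `collapse_cut` form a single column that is 1 when
    the individual carries at least one of them; every other SNP keeps
    its own column.
    """
    gene_calls = np.asarray(gene_calls)
    mafs = np.asarray(mafs, dtype=float)
    if gene_calls.ndim != 2 or gene_calls.shape[1] != mafs.size:
        raise ValueError("gene_calls columns must match mafs length")
    rare = mafs < collapse_cut
    columns = []
    if rare.any():
        columns.append((gene_calls[:, rare].max(axis=1)).astype(float))
    for j in np.flatnonzero(~rare):
        columns.append(gene_calls[:, j].astype(float))
    return np.column_stack(columns)


def hotelling_t2(design_cases: np.ndarray, design_controls: np.ndarray):
    """Two-sample Hotelling T^2 with pooled covariance and an F reference.

    Returns ``(T2, p, df_model, status)``.  A singular pooled covariance
    is handled by the Moore-Penrose pseudo-inverse with the model
    dimension replaced by the covariance's effective rank; rank 0 (no
    within-group variation at all) and insufficient sample size are
    degenerate (p = 1).
    """
    X1 = np.atleast_2d(np.asarray(design_cases, dtype=float))
    X2 = np.atleast_2d(np.asarray(design_controls, dtype=float))
    n1, k = X1.shape
    n2 = X2.shape[0]
    if X2.shape[1] != k:
        raise ValueError("case/control designs must share column count")
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    if n1 + n2 - 2 <= 0 or n1 + n2 - k - 1 <= 0:
        return 0.0, 1.0, k, "degenerate"
    d = X1.mean(axis=0) - X2.mean(axis=0)
    S1 = np.cov(X1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((k, k))
    S2 = np.cov(X2, rowvar=False, ddof=1) if n2 > 1 else np.zeros((k, k))
    S1 = np.atleast_2d(S1)
    S2 = np.atleast_2d(S2)
    pooled = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    rank = int(np.linalg.matrix_rank(pooled))
    if rank == 0:
        return 0.0, 1.0, k, "degenerate"
    Sinv = np.linalg.pinv(pooled, hermitian=True)
    t2 = float((n1 * n2) / (n1 + n2) * d @ Sinv @ d)
    t2 = max(t2, 0.0)
    df2 = n1 + n2 - rank - 1
    if df2 <= 0:
        return t2, 1.0, rank, "degenerate"
    f_stat = t2 * df2 / ((n1 + n2 - 2) * rank)
    p = float(stats.f.sf(f_stat, rank, df2))
    return t2, max(p, np.finfo(float).tiny), rank, "ok"


# ---------------------------------------------------------------------------
# WS
# ---------------------------------------------------------------------------


def _ws_scores(gene_calls: np.ndarray, phenotype: np.ndarray,
               weights_from: str = "unaffected") -> np.ndarray:
    """Per-individual weighted genotype scores for the WS test."""
    calls = np.asarray(gene_calls, dtype=float)
    pheno = np.asarray(phenotype, dtype=int)
    n = pheno.size
    if weights_from == "unaffected":
        unaff = pheno == 0
        n_u = int(unaff.sum())
        if n_u == 0:
            raise ValueError("WS weights need at least one unaffected individual")
        m_u = calls[unaff].sum(axis=0)
    elif weights_from == "pooled":
        n_u = n
        m_u = calls.sum(axis=0)
    else:
        raise ValueError(f"unknown weights_from {weights_from!r}")
    q_hat = (m_u + 1.0) / (2.0 * (n_u + 1.0))
    w = np.sqrt(n * q_hat * (1.0 - q_hat))
    return calls @ (1.0 / w)


def ws_statistic(gene_calls: np.ndarray, phenotype: np.ndarray,
                 weights_from: str = "unaffected") -> float:
    """Rank-sum of weighted genotype scores over affected individuals.

    Weights per SNP j are sqrt(n q_j (1-q_j)) with q_j estimated from
    the unaffected group with +1 pseudo-counts; ranks use midranks for
    ties.
    """
    scores = _ws_scores(gene_calls, phenotype, weights_from)
    ranks = stats.rankdata(scores, method="average")
    return float(ranks[np.asarray(phenotype, dtype=bool)].sum())


def _ws_statistic_batch(gene_calls: np.ndarray, pheno_matrix: np.ndarray,
                        weights_from: str = "unaffected") -> np.ndarray:
    """WS statistic for each row (phenotype vector) of `pheno_matrix`."""
    calls = np.asarray(gene_calls, dtype=float)
    P = np.asarray(pheno_matrix, dtype=float)  # B x n
    n = calls.shape[0]
    if weights_from == "unaffected":
        n_u = (1.0 - P).sum(axis=1)  # B
        m_u = (1.0 - P) @ calls  # B x m
    else:
        n_u = np.full(P.shape[0], float(n))
        m_u = np.broadcast_to(calls.sum(axis=0), (P.shape[0], calls.shape[1]))
    q_hat = (m_u + 1.0) / (2.0 * (n_u[:, None] + 1.0))
    w = np.sqrt(n * q_hat * (1.0 - q_hat))  # B x m
    scores = calls @ (1.0 / w).T  # n x B
    ranks = stats.rankdata(scores, method="average", axis=0)
    return np.einsum("bn,nb->b", P, ranks)


# ---------------------------------------------------------------------------
# PR
# ---------------------------------------------------------------------------


def pr_predictor(gene_calls: np.ndarray) -> np.ndarray:
    """Fraction of the gene's variant sites carried by each individual."""
    calls = np.asarray(gene_calls, dtype=float)
    return calls.mean(axis=1)


def pr_statistic(gene_calls: np.ndarray, phenotype: np.ndarray):
    """Logistic regression of status on the carried-site proportion.

    Returns ``(slope_z, p, status)`` where z is the Wald statistic on
    the slope and p its two-sided asymptotic p-value.  A constant
    predictor, non-convergence, or separation yields a degenerate
    outcome with p = 1.
    """
    import statsmodels.api as sm

    pheno = np.asarray(phenotype, dtype=float)
    if pheno.min() == pheno.max():
        raise ValueError("phenotype must not be constant")
    x = pr_predictor(gene_calls)
    if np.ptp(x) == 0.0:
        logger.debug("PR: constant carried-site proportion; degenerate")
        return 0.0, 1.0, "degenerate"
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(pheno, X).fit(
                method="newton", maxiter=_IRLS_MAXITER, tol=_IRLS_TOL, disp=0,
            )
        except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
            logger.debug("PR: logistic fit failed (%s); degenerate", exc)
            return 0.0, 1.0, "degenerate"
    slope = float(fit.params[1])
    if not fit.mle_retvals.get("converged", True) or abs(slope) > _SEPARATION_SLOPE:
        logger.debug("PR: non-convergence or separation (slope=%.3g); degenerate", slope)
        return 0.0, 1.0, "degenerate"
    z = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    if not np.isfinite(z) or not np.isfinite(p):
        return 0.0, 1.0, "degenerate"
    return z, max(p, np.finfo(float).tiny), "ok"


# ---------------------------------------------------------------------------
# CMAT
# ---------------------------------------------------------------------------


def _chi2_2x2(a: float, A: float, b: float, B: float) -> float:
    """Pearson chi-square (1 df, no continuity correction) on
    [[a, A-a], [b, B-b]]; 0 when a margin is empty."""
    obs = np.array([[a, A - a], [b, B - b]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if total == 0 or (col == 0).any() or (row == 0).any():
        return 0.0
    expected = np.outer(row, col) / total
    return float(((obs - expected) ** 2 / expected).sum())


def cmat_counts(gene_calls: np.ndarray, phenotype: np.ndarray):
    """Carried-locus counts (a, A, b, B) for the CMAT 2x2 table."""
    calls = np.asarray(gene_calls, dtype=float)
    pheno = np.asarray(phenotype, dtype=bool)
    loci = calls.shape[1]
    burden = calls.sum(axis=1)
    a = float(burden[pheno].sum())
    b = float(burden[~pheno].sum())
    A = float(loci * pheno.sum())
    B = float(loci * (~pheno).sum())
    return a, A, b, B


def cmat_statistic(gene_calls: np.ndarray, phenotype: np.ndarray) -> float:
    """CMAT chi-square comparing rare-allele proportions of cases and controls."""
    pheno = np.asarray(phenotype, dtype=bool)
    if pheno.all() or not pheno.any():
        raise ValueError("need at least one case and one control")
    a, A, b, B = cmat_counts(gene_calls, phenotype)
    return _chi2_2x2(a, A, b, B)


def _cmat_statistic_batch(gene_calls: np.ndarray, pheno_matrix: np.ndarray) -> np.ndarray:
    """CMAT chi-square for each row of a 0/1 phenotype matrix."""
    calls = np.asarray(gene_calls, dtype=float)
    P = np.asarray(pheno_matrix, dtype=float)
    loci = calls.shape[1]
    burden = calls.sum(axis=1)
    tot = float(burden.sum())
    n = calls.shape[0]
    a = P @ burden
    n_case = P.sum(axis=1)
    A = loci * n_case
    b = tot - a
    B = loci * (n - n_case)
    # closed-form Pearson chi-square on [[a, A-a], [b, B-b]]
    N = A + B
    col1 = a + b
    col2 = N - col1
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = N * (a * (B - b) - b * (A - a)) ** 2 / (A * B * col1 * col2)
    chi2 = np.where((col1 == 0) | (col2 == 0) | (A == 0) | (B == 0), 0.0, chi2)
    return np.asarray(chi2, dtype=float)


def cmat_stratified(gene_calls: np.ndarray, phenotype: np.ndarray, strata):
    """Mantel-Haenszel-pooled CMAT across population strata.

    Each stratum with at least one case and one control contributes its
    2x2 table; the pooled statistic is
    ``(sum_s (a_s - E_s))^2 / sum_s V_s`` with E_s, V_s the
    hypergeometric mean and variance of a_s under fixed margins.
    Returns ``(statistic, usable_strata, status)``.
    """
    calls = np.asarray(gene_calls, dtype=float)
    pheno = np.asarray(phenotype, dtype=bool)
    labels = np.asarray(strata)
    num, den = 0.0, 0.0
    usable = []
    for s in unique_labels(labels):
        mask = labels == s
        ph = pheno[mask]
        if not ph.any() or ph.all():
            logger.debug("stratum %r lacks cases or controls; skipped", s)
            continue
        a, A, b, B = cmat_counts(calls[mask], ph)
        N = A + B
        t = a + b
        E = A * t / N
        V = A * B * t * (N - t) / (N**2 * (N - 1.0)) if N > 1 else 0.0
        num += a - E
        den += V
        usable.append(s)
    if not usable or den <= 0:
        return 0.0, usable, "degenerate"
    return float(num**2 / den), usable, "ok"


def _cmat_stratified_batch(gene_calls: np.ndarray, pheno_matrix: np.ndarray,
                           strata) -> np.ndarray:
    """Pooled stratified-CMAT statistic per row of `pheno_matrix`.

    Assumes the rows are within-stratum permutations of one phenotype
    vector, so each stratum's case count (hence margins) is constant
    across rows and the usable-stratum set is fixed.
    """
    calls = np.asarray(gene_calls, dtype=float)
    P = np.asarray(pheno_matrix, dtype=float)
    labels = np.asarray(strata)
    loci = calls.shape[1]
    burden = calls.sum(axis=1)
    num = np.zeros(P.shape[0])
    den = 0.0
    any_usable = False
    for s in unique_labels(labels):
        mask = labels == s
        n_s = int(mask.sum())
        n_case = float(P[0, mask].sum())
        if n_case == 0 or n_case == n_s:
            continue
        a_s = P[:, mask] @ burden[mask]
        t = float(burden[mask].sum())
        A = loci * n_case
        N = loci * n_s
        E = A * t / N
        V = A * (N - A) * t * (N - t) / (N**2 * (N - 1.0)) if N > 1 else 0.0
        num += a_s - E
        den += V
        any_usable = True
    if not any_usable or den <= 0:
        return np.zeros(P.shape[0])
    return num**2 / den


def unique_labels(values: np.ndarray):
    """Unique labels in order of first appearance."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


def permutation_matrix(phenotype: np.ndarray, B: int, rng: np.random.Generator,
                       strata=None) -> np.ndarray:
    """B uniformly shuffled copies of the phenotype vector (rows).

    With `strata`, labels are shuffled independently within each stratum
    so per-stratum case/control margins are preserved.
    """
    pheno = np.asarray(phenotype, dtype=np.int8)
    P = np.tile(pheno, (B, 1))
    if strata is None:
        P = rng.permuted(P, axis=1)
    else:
        labels = np.asarray(strata)
        for s in unique_labels(labels):
            idx = np.flatnonzero(labels == s)
            P[:, idx] = rng.permuted(P[:, idx], axis=1)
    return P


def permute_p(statistic_fn, gene_calls: np.ndarray, phenotype: np.ndarray,
              plan: PermutationPlan, strata=None) -> float:
    """Upper-tail phenotype-permutation p-value for any gene statistic.

    p = (1 + #{b : stat(permuted_b) >= stat(observed)}) / (B + 1).
    """
    rng = np.random.default_rng(plan.seed)
    observed = statistic_fn(gene_calls, phenotype)
    P = permutation_matrix(phenotype, plan.B, rng, strata=strata)
    exceed = sum(
        1 for b in range(plan.B) if statistic_fn(gene_calls, P[b]) >= observed
    )
    return (1 + exceed) / (plan.B + 1)


def _permute_p_batch(batch_fn, gene_calls, phenotype, plan: PermutationPlan,
                     strata=None) -> tuple[float, float]:
    """Vectorised permutation p; returns (observed statistic, p)."""
    rng = np.random.default_rng(plan.seed)
    pheno = np.asarray(phenotype, dtype=np.int8)
    observed = float(batch_fn(gene_calls, pheno[None, :])[0])
    P = permutation_matrix(pheno, plan.B, rng, strata=strata)
    null = batch_fn(gene_calls, P)
    exceed = int((null >= observed).sum())
    return observed, (1 + exceed) / (plan.B + 1)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def run_gene(method: str, gene_calls: np.ndarray, mafs: np.ndarray,
             phenotype: np.ndarray, strata=None,
             plan: PermutationPlan | None = None,
             gene_id: str = "", collapse_cut: float = DEFAULT_COLLAPSE_CUT,
             ws_weights_from: str = "unaffected") -> TestOutcome:
    """Run one association test on one gene and one phenotype vector.

    CMC and PR report asymptotic p-values; WS, CMAT and CMAT_STRAT use
    phenotype permutation under `plan`.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    plan = plan or PermutationPlan()
    pheno = np.asarray(phenotype, dtype=np.int8)
    if pheno.min() == pheno.max():
        logger.debug("gene %s: constant phenotype; degenerate", gene_id)
        return TestOutcome(method, gene_id, 0.0, 1.0, 0, "degenerate")

    if method == "CMC":
        design = cmc_collapse(gene_calls, mafs, collapse_cut)
        aff = pheno == 1
        t2, p, df, status = hotelling_t2(design[aff], design[~aff])
        return TestOutcome(method, gene_id, t2, p, df, status)

    if method == "PR":
        z, p, status = pr_statistic(gene_calls, pheno)
        return TestOutcome(method, gene_id, z, p, 0, status)

    if method == "WS":
        def batch(calls, P):
            return _ws_statistic_batch(calls, P, weights_from=ws_weights_from)
        stat, p = _permute_p_batch(batch, gene_calls, pheno, plan)
        return TestOutcome(method, gene_id, stat, p, plan.B, "ok")

    if method == "CMAT":
        stat, p = _permute_p_batch(_cmat_statistic_batch, gene_calls, pheno, plan)
        return TestOutcome(method, gene_id, stat, p, plan.B, "ok")

    # CMAT_STRAT
    if strata is None:
        raise ValueError("CMAT_STRAT requires strata")
    stat0, usable, status = cmat_stratified(gene_calls, pheno, strata)
    if status == "degenerate":
        return TestOutcome(method, gene_id, 0.0, 1.0, plan.B, "degenerate")

    def batch(calls, P):
        return _cmat_stratified_batch(calls, P, strata)

    stat, p = _permute_p_batch(batch, gene_calls, pheno, plan, strata=strata)
    return TestOutcome(method, gene_id, stat, p, plan.B, "ok")
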