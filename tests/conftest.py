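import numpy as np
import pandas as pd
import pytest

from rvbench.io import GenotypePanel, PhenotypeReplicates


def make_annotation(snp_ids, gene_ids, mafs, chrom=None, nonsyn=None,
                    causal=None, beta=None) -> pd.DataFrame:
    n = len(snp_ids)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chrom if chrom is not None else ["chr1"] * n,
            "gene_id": gene_ids,
            "maf": mafs,
            "nonsynonymous": nonsyn if nonsyn is not None else [True] * n,
            "causal": causal if causal is not None else [False] * n,
            "beta": beta if beta is not None else [0.0] * n,
        }
    )


@pytest.fixture
def tiny_panel():
    """6 individuals x 4 SNPs across 2 genes on 2 chromosomes."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 2, size=(6, 4))
    panel = GenotypePanel(
        sample_ids=[f"S{i}" for i in range(6)],
        snp_ids=["a", "b", "c", "d"],
        calls=calls,
    )
    annotation = make_annotation(
        ["a", "b", "c", "d"],
        ["g1", "g1", "g2", "g2"],
        [0.01, 0.10, 0.04, 0.03],
        chrom=["chr1", "chr1", "chr2", "chr2"],
    )
    return panel, annotation


@pytest.fixture
def tiny_replicates():
    statuses = np.array([[1, 1, 1, 0, 0, 0], [1, 0, 1, 0, 1, 0], [0, 1, 0, 1, 0, 1]])
    return PhenotypeReplicates(
        replicate_ids=["r1", "r2", "r3"],
        statuses=statuses,
        ethnicity=["p1", "p1", "p1", "p2", "p2", "p2"],
    )
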