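import numpy as np
import pytest
import scipy.sparse as sp

from pairtcr.io_tenx import ContigRecord, ExpressionMatrix
from pairtcr.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 genes x 3 cells with entries (0,0)=5 and (1,2)=2."""
    counts = sp.csr_matrix(np.array([[5, 0, 0], [0, 0, 2]]))
    return ExpressionMatrix(
        gene_ids=["GeneA", "GeneB"],
        barcodes=["AAAA-1", "CCCC-1", "GGGG-1"],
        counts=counts,
    )


def make_contig(barcode="AAACCTGAGAAACCAT-1", chain="TRA", umis=5, reads=20,
                cdr3_nt="TGTGCTAGCTTT", cdr3_aa="CASF", v_gene="TRAV1",
                j_gene="TRAJ2", productive=True, is_cell=True,
                high_confidence=True, **kw) -> ContigRecord:
    return ContigRecord(
        barcode=barcode, is_cell=is_cell, high_confidence=high_confidence,
        chain=chain, v_gene=v_gene, d_gene=kw.get("d_gene", ""),
        j_gene=j_gene, c_gene=kw.get("c_gene", "TRAC"), cdr3_aa=cdr3_aa,
        cdr3_nt=cdr3_nt, reads=reads, umis=umis, productive=productive,
        raw_clonotype_id=kw.get("raw_clonotype_id", ""),
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with every planted effect switched on; shared read-only."""
    cfg = CohortConfig(
        n_samples_per_arm=1,
        n_cells_per_sample=400,
        n_genes=600,
        sig_shift={("M2", "sephin1", "tumor_d15"): 0.5},
        expansion_damp=0.4,
        trog_rate={"blood_d0": 0.005, "blood_d15": 0.005, "tumor_d15": 0.137},
        trog_donor_mix=0.8,
        seed=42,
    )
    return cfg, generate_cohort(cfg)


def random_expression_matrix(rng, n_genes=30, n_cells=20) -> ExpressionMatrix:
    counts = rng.poisson(1.2, size=(n_genes, n_cells))
    return ExpressionMatrix(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        barcodes=[f"BC{i:04d}-1" for i in range(n_cells)],
        counts=sp.csr_matrix(counts),
    )
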