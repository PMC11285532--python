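import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cellvuln.config import RunConfig, SimConfig
from cellvuln.containers import CountMatrix
from cellvuln.simulate import SimStudy, simulate_counts, simulate_study


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Scaled-down study design for fast unit tests.

    Planted counts shrink with the gene universe so every stage still has
    signal and the filler pools stay comfortably non-empty.
    """
    return SimConfig(
        n_genes=800, cells_per_subject=300,
        n_markers_per_type=10, n_regional_degs=100,
        n_gwas_genes_per_disease=20, gwas_overlap_vulnerable=15,
        drug_overlap_vulnerable=30, n_drug_targets_per_class=20,
        n_disease_shared=60, n_disease_own=50, n_disease_null=150,
    )


@pytest.fixture(scope="session")
def small_counts(small_sim_config):
    return simulate_counts(small_sim_config, seed=7)


@pytest.fixture(scope="session")
def small_study(small_sim_config) -> SimStudy:
    return simulate_study(small_sim_config, seed=7)


@pytest.fixture()
def run_config() -> RunConfig:
    return RunConfig(seed=0)


def make_count_matrix(counts, gene_ids=None, cell_ids=None, **meta_cols) -> CountMatrix:
    """Build a CountMatrix from a dense array plus optional metadata columns."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"C{i}" for i in range(n_cells)]
    cell_meta = pd.DataFrame(index=list(cell_ids))
    for col, values in meta_cols.items():
        cell_meta[col] = list(values)
    return CountMatrix(
        counts=sp.csc_matrix(counts),
        gene_ids=np.array(gene_ids, dtype=object),
        cell_ids=np.array(cell_ids, dtype=object),
        cell_meta=cell_meta,
    )


@pytest.fixture()
def tiny_10x_dir(tmp_path):
    """Hand-written 3-gene x 4-cell MatrixMarket triplet with 5 nonzeros."""
    d = tmp_path / "tenx"
    d.mkdir()
    (d / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        "3 4 5\n"
        "1 1 2\n"
        "2 1 3\n"
        "3 2 1\n"
        "1 3 4\n"
        "2 4 7\n"
    )
    (d / "features.tsv").write_text(
        "ENSG01\tGENEA\tGene Expression\n"
        "ENSG02\tGENEB\tGene Expression\n"
        "ENSG03\tMT-CO1\tGene Expression\n"
    )
    (d / "barcodes.tsv").write_text("AAAC\nAAAG\nAAAT\nAACA\n")
    (d / "cell_meta.tsv").write_text(
        "barcode\tsubject\tregion\tmajor_type\tsubtype\tdoublet\n"
        "AAAC\tTL1\tTL\tEX\tEX-L4\tfalse\n"
        "AAAG\tTL1\tTL\tINH\tINH-PVALB\ttrue\n"
        "AAAT\tFL1\tFL\tEX\tEX-L5\tfalse\n"
        "AACA\tFL1\tFL\tAstro\tAstro\tfalse\n"
    )
    return d
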