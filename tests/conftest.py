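import numpy as np
import pandas as pd
import pytest

import runner_burden as rb


@pytest.fixture(scope="session")
def small_variant_dataset():
    """Variant-level null dataset small enough for pipeline tests."""
    cfg = rb.SimConfig(n_genes=400, seed=5)
    records, ann, truth = rb.simulate_variant_dataset(cfg)
    return records, ann, truth, cfg


@pytest.fixture()
def toy_records():
    """Hand-built variant records covering both genes and all columns."""
    return pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "pos": [100, 200, 300, 400],
        "ref": ["A"] * 4,
        "alt": ["G"] * 4,
        "gene_id": ["GENE1", "GENE1", "GENE2", "GENE2"],
        "consequence": ["missense", "stop-gain", "missense", "missense"],
        "score": [0.5, 0.9, np.nan, 0.2],
        "case_ac": [1, 2, 3, 1],
        "case_an": [200, 200, 200, 200],
        "ctrl_ac": [0, 1, 2, 1],
        "ctrl_an": [200, 200, 200, 200],
        "af_p1": [0.001, np.nan, 0.004, 0.02],
        "af_p2": [0.002, np.nan, 0.002, 0.02],
    })


@pytest.fixture()
def toy_annotation():
    return pd.DataFrame({
        "gene_id": ["GENE1", "GENE2"],
        "length_kb": [3.477, 2.0],
        "gc": [0.5, 0.6],
        "oe_mis": [0.9, np.nan],
        "mu_mis": [2e-6, 1e-6],
        "oe_lof": [0.5, 0.7],
        "mu_lof": [4e-7, 3e-7],
    })


def write_vcf(path, body_lines, n_samples, fmt="GT"):
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Quality">',
        "##contig=<ID=chr1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"S{i}" for i in range(n_samples)),
    ]
    path.write_text("\n".join(header + body_lines) + "\n")
    return path
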