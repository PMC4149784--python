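import numpy as np
import pandas as pd
import pytest

from regulonprint.expression import ExpressionMatrix
from regulonprint.simulate import SimConfig, gen_expression, gen_regions


@pytest.fixture
def small_config():
    """A desk-scale synthetic study: few genes per class, default noise."""
    return SimConfig(
        n_genes_per_class={"Aft": 6, "Cth2": 5, "Ace1": 4, "Mac1": 4,
                           "Yap5": 3, "null": 20},
        n_aft_candidates=1, n_cth2_candidates=4, seed=7)


@pytest.fixture
def small_study(small_config):
    matrix, truth = gen_expression(small_config)
    return small_config, matrix, truth


def make_matrix(gene_values, genotype="wt", condition_pairs=None):
    """Hand-built ExpressionMatrix from {gene: {(genotype, condition): [reps]}}."""
    conditions = {}
    for gene, groups in gene_values.items():
        for (gt, cond), reps in groups.items():
            for i, v in enumerate(reps, 1):
                conditions.setdefault(f"{gt}_{cond}_r{i}", {})[gene] = v
    values = pd.DataFrame(conditions)
    rows = []
    for sample in values.columns:
        gt, cond, rep = sample.rsplit("_", 2)
        rows.append({"sample": sample, "genotype": gt, "condition": cond,
                     "replicate": int(rep[1:])})
    samples = pd.DataFrame(rows).set_index("sample")
    return ExpressionMatrix(values=values, samples=samples, unit="RPKM")
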