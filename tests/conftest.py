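import numpy as np
import pytest

from abatrans.boolean_classifier import CONDITIONS
from abatrans.io_core import ExpressionMatrix, Sample, SampleDesign


def make_design(replicates: int = 3, tissue: str = "guard_cell") -> SampleDesign:
    samples = []
    for genotype, treatment in CONDITIONS:
        for rep in range(1, replicates + 1):
            sid = f"{tissue}_{genotype}_{treatment}_{rep}"
            samples.append(Sample(sid, tissue, genotype, treatment, rep))
    return SampleDesign(samples)


def matrix_from_condition_means(
    gene_ids, cond_means, replicates=3, noise_sd=0.0, seed=0, tissue="guard_cell"
) -> ExpressionMatrix:
    """Build a matrix whose samples take per-condition means (canonical order)."""
    design = make_design(replicates, tissue)
    cond_idx = [CONDITIONS.index(s.condition) for s in design.samples]
    cond_means = np.atleast_2d(np.asarray(cond_means, dtype=float))
    values = cond_means[:, cond_idx].astype(float)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, values.shape)
    return ExpressionMatrix(list(gene_ids), values, design)


@pytest.fixture
def design24() -> SampleDesign:
    return make_design()
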