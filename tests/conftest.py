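import numpy as np
import pandas as pd
import pytest

from nfmeta.studies import ExpressionStudy
from nfmeta.synthdata import SyntheticConfig, generate_study_set


def make_study(
    matrix: np.ndarray,
    na: int,
    nb: int,
    probe_ids=None,
    gene_ids=None,
    study_id: str = "S1",
    species: str = "human",
) -> ExpressionStudy:
    """Small hand-built study: first ``na`` columns are group A."""
    n = matrix.shape[0]
    probe_ids = probe_ids or [f"P{i:03d}" for i in range(n)]
    gene_ids = gene_ids or [f"G{i:03d}" for i in range(n)]
    cols = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
    return ExpressionStudy(
        study_id=study_id,
        species=species,
        matrix=pd.DataFrame(matrix, index=probe_ids, columns=cols),
        groups=pd.Series(["A"] * na + ["B"] * nb, index=cols),
        probe_map=pd.Series(gene_ids, index=probe_ids),
        comparison=("A", "B"),
    )


@pytest.fixture
def random_study():
    rng = np.random.default_rng(7)
    mat = rng.uniform(5, 10, (60, 10)) + rng.normal(0, 0.5, (60, 10))
    mat[:8, :5] += 2.5
    return make_study(mat, 5, 5)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort (default config, fixed seed)."""
    cfg = SyntheticConfig(seed=11)
    studies, truth, orthologs = generate_study_set(cfg)
    return cfg, studies, truth, orthologs
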