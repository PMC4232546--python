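import numpy as np
import pandas as pd
import pytest

from gonadspec.simulate import SampleLayout, sample_table
from gonadspec.types import ExpressionMatrix


@pytest.fixture
def study_samples() -> pd.DataFrame:
    """Sample metadata for the study layout: 3 ovary, 3 testis, 7 somatic."""
    return sample_table(SampleLayout())


@pytest.fixture
def make_expr(study_samples):
    """Build an ExpressionMatrix from a genes x 13 array (study layout),
    optionally extended with extra stage columns."""

    def _make(values, gene_ids=None, n_stages: int = 0) -> ExpressionMatrix:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        meta = study_samples
        if n_stages:
            meta = sample_table(SampleLayout(stage=n_stages))
        if gene_ids is None:
            gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
        rpkm = pd.DataFrame(values, index=gene_ids, columns=meta.index)
        return ExpressionMatrix(rpkm=rpkm, sample_groups=meta)

    return _make
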