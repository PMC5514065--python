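import numpy as np
import pandas as pd
import pytest

from exomode.io import ExonExpressionMatrix, ExonRecord


def build_matrix(rows: dict[str, list[float]], samples: list[str], gene_map=None,
                 scale_state: str = "raw") -> ExonExpressionMatrix:
    """Construct a matrix from {exon_id: values}; optional {exon_id: gene_id}."""
    gene_map = gene_map or {}
    exons = tuple(
        ExonRecord.from_id(eid, gene_id=gene_map.get(eid)) for eid in rows
    )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    return ExonExpressionMatrix(exons=exons, values=values, scale_state=scale_state)


@pytest.fixture
def tiny_matrix():
    return build_matrix(
        {
            "chr1:100-200": [1.0, 2.0, 4.0],
            "chr1:300-400": [0.0, 0.0, 0.0],
            "chr1:500-600": [2.0, 1.0, 8.0],
        },
        samples=["s1", "s2", "s3"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
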