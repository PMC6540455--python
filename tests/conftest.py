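import numpy as np
import pytest

from cptsig import ExpressionMatrix, ProbeAnnotation


@pytest.fixture
def small_matrix():
    """3 features x 2 samples with simple values."""
    return ExpressionMatrix.from_arrays(
        ["p1", "p2", "p3"],
        ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


@pytest.fixture
def annotation():
    return ProbeAnnotation({"p1": "GENEA", "p2": "GENEA", "p3": "GENEB"})


def write_tsv_matrix(path, feature_ids, sample_ids, values):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(sample_ids) + "\n")
        for fid, row in zip(feature_ids, values):
            fh.write(fid + "\t" + "\t".join(str(v) for v in row) + "\n")
    return path
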