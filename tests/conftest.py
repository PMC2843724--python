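import numpy as np
import pandas as pd
import pytest

from whorlstat.io import ProbeIntensityTable, StudyDesign


@pytest.fixture
def toy_pair_file(tmp_path):
    """Three probes, two genes, on a 3x2 grid."""
    path = tmp_path / "arr1.pair"
    path.write_text(
        "# toy array\n"
        "PROBE_ID\tSEQ_ID\tX\tY\tPM\n"
        "p1\tgA\t1\t1\t100.0\n"
        "p2\tgA\t2\t1\t200.5\n"
        "p3\tgB\t3\t2\t50\n"
    )
    return path


@pytest.fixture
def five_whorl_design():
    rows = [
        (f"{t}_{p}", t, p)
        for t in ("SEP", "PET", "STA", "STD", "CAR")
        for p in ("pop1", "pop2", "pop3")
    ]
    return StudyDesign(
        entries=pd.DataFrame(rows, columns=["array_id", "tissue", "population"])
    )


def make_expression(values_by_array, design, gene_ids=None):
    """Assemble an ExpressionMatrix from a dict array_id -> gene vector."""
    from whorlstat.preprocess import ExpressionMatrix

    frame = pd.DataFrame(values_by_array)
    if gene_ids is not None:
        frame.index = gene_ids
    return ExpressionMatrix(values=frame[design.array_ids], design=design)
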