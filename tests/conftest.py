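import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ginigenes import CqTable, ExpressionMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_gini(values) -> float:
    """Independent Gini oracle: pairwise mean absolute difference,
    sum_ij |x_i - x_j| / (2 n^2 xbar)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean()))


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        {
            "s1": [10.0, 1.0, 0.0, np.nan],
            "s2": [10.0, 2.0, 0.0, np.nan],
            "s3": [10.0, 3.0, 0.0, np.nan],
        },
        index=pd.Index(["CONST", "RAMP", "ZERO", "MISSING"], name="Gene ID"),
    )
    return ExpressionMatrix(values=values, dataset_id="fixture")


@pytest.fixture
def atlas_tsv(tmp_path):
    """A 3-gene x 2-sample Expression Atlas style file with a comment line."""
    path = tmp_path / "atlas.tsv"
    path.write_text(
        "# Expression Atlas style fixture\n"
        "Gene ID\tGene Name\tliver\tkidney\n"
        "ENSG01\tACTB\t100.0\t200.0\n"
        "ENSG02\tGAPDH\t5.5\t\n"
        "ENSG03\tVPS29\t0.0\t1.0\n"
    )
    return path


@pytest.fixture
def cq_table() -> CqTable:
    """4 genes x 3 cell lines in triplicate; STAB is constant across lines,
    DOUBLE is exactly STAB*... (Cq shifted by -1 => doubled expression in
    the 2^-dCq sense), HIGH is censored in one line (Cq 33 > cutoff)."""
    rows = []
    design = {
        "STAB": {"A": 20.0, "B": 20.0, "C": 20.0},
        "DOUBLE": {"A": 19.0, "B": 19.0, "C": 19.0},
        "VARY": {"A": 18.0, "B": 22.0, "C": 26.0},
        "HIGH": {"A": 30.0, "B": 33.0, "C": 31.0},
    }
    for gene, lines in design.items():
        for line, cq in lines.items():
            for rep in (1, 2, 3):
                rows.append(
                    {"gene": gene, "cell_line": line, "replicate": rep, "cq": cq}
                )
    return CqTable(data=pd.DataFrame(rows), cutoff=32.0)
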