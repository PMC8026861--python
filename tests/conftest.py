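import numpy as np
import pandas as pd
import pytest

from sigmeta.meta import ExpressionDataset
from sigmeta.relations import Relation


def make_dataset(case, control, dataset_id="ds", genes=None):
    """Small ExpressionDataset from per-group genes x samples arrays."""
    case = np.atleast_2d(np.asarray(case, float))
    control = np.atleast_2d(np.asarray(control, float))
    n_genes = case.shape[0]
    if genes is None:
        genes = [f"G{i+1:03d}" for i in range(n_genes)]
    cols = [f"c{i}" for i in range(case.shape[1])] + [
        f"k{i}" for i in range(control.shape[1])
    ]
    matrix = pd.DataFrame(np.hstack([case, control]), index=genes, columns=cols)
    groups = pd.Series(
        ["case"] * case.shape[1] + ["control"] * control.shape[1], index=cols
    )
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix, groups=groups)


def rel(subject, obj, polarity, refs=5, s_kind=None, o_kind=None):
    if s_kind is None:
        s_kind = "disease" if subject in ("OBESITY", "MI") else "gene"
    if o_kind is None:
        o_kind = "disease" if obj in ("OBESITY", "MI") else "gene"
    return Relation(subject, obj, polarity, "regulation", refs, s_kind, o_kind)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_relations_tsv(tmp_path):
    path = tmp_path / "relations.tsv"
    path.write_text(
        "subject\tsubject_kind\tobject\tobject_kind\tpolarity\trelation_class\tref_count\tsentences\n"
        "OBESITY\tdisease\tNPPB\tgene\tnegative\tregulation\t5\tobesity lowers nppb\n"
        "NPPB\tgene\tMI\tdisease\tpositive\tregulation\t4\t\n"
        "OBESITY\tdisease\tLEP\tgene\tunknown\tregulation\t9\t\n"
    )
    return path
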