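"""Shared fixtures: the worked 5-node network and small expression studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from overconnect import DESet, ExpressionStudy, build_network


@pytest.fixture
def worked_network():
    """5-node network with hub A -> {B, C, D}; E is isolated.

    With DE = {B, C}: actual=2, n=2, r=3, N=5, expected=1.2, variance=0.36,
    ratio=5/3, z=4/3.
    """
    return build_network(
        [("A", "B", "activation"), ("A", "C", "inhibition"),
         ("A", "D", "unspecified")],
        {"A": "transcription_factor", "B": "kinase", "C": "protease"},
        extra_nodes={"E"},
    )


@pytest.fixture
def worked_de_set():
    return DESet({"B", "C"}, {"B": "up", "C": "down"})


def make_study(values, n_case=3, n_control=3, gene_ids=None):
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_control)]
    groups = {s: ("case" if s.startswith("case") else "control")
              for s in samples}
    return ExpressionStudy(genes, values, samples, groups)


@pytest.fixture
def tiny_study():
    """4 genes x (3 case + 3 control) with hand-checkable contrasts."""
    return make_study([
        [2, 2, 2, 1, 1, 1],      # log2fc = 1, zero variance
        [5, 5, 5, 5, 5, 5],      # log2fc = 0
        [4, 6, 5, 2, 2, 2],      # up with spread
        [1, 1, 1, 3, 3, 3],      # log2fc = -2
    ])


def write_study_tsv(study: ExpressionStudy, matrix_path, sheet_path):
    mat = pd.DataFrame(study.values, columns=study.sample_ids)
    mat.insert(0, "gene_id", study.gene_ids)
    mat.to_csv(matrix_path, sep="\t", index=False)
    pd.DataFrame({
        "sample": study.sample_ids,
        "group": [study.group_of[s] for s in study.sample_ids],
    }).to_csv(sheet_path, sep="\t", index=False)
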