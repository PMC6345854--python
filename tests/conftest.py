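import numpy as np
import pandas as pd
import pytest

import tdscreen as tds
from tdscreen.panel_io import CountTable, ProbeAnnotation, TDSPanel

#: fixed study seed for the whole suite
SEED = 20260926


@pytest.fixture(scope="session")
def cohort():
    """Default 20 wt + 20 disease simulated cohort."""
    return tds.simulate_cohort(tds.SimulationConfig(seed=SEED))


@pytest.fixture(scope="session")
def normalized(cohort):
    """(background-subtracted table, per-sample factor report)."""
    return tds.normalize_pipeline(cohort.table, cohort.annotation)


@pytest.fixture(scope="session")
def truth_panel(cohort):
    """Oracle 97-gene reference panel straight from the generator truth."""
    return tds.panel_from_truth(cohort.truth.genes)


@pytest.fixture(scope="session")
def lfc_matrix(cohort, normalized, truth_panel):
    """All-pairs disease-vs-healthy log2FC matrix (97 genes x 400 pairs)."""
    table, _ = normalized
    disease = cohort.sheet.samples_where(genotype="disease")
    healthy = cohort.sheet.samples_where(genotype="wt")
    return tds.pairwise_lfc_matrix(table, disease, healthy, truth_panel.genes)


@pytest.fixture(scope="session")
def null_scores_10k(lfc_matrix, truth_panel):
    """Scores of 10,000 pooled-symmetric null lists (shared across tests)."""
    nulls = tds.simulate_null_lists(lfc_matrix, 10_000, seed=SEED + 1)
    return tds.score_lists(nulls, truth_panel, weighted=False)


@pytest.fixture
def tiny_panel():
    """Hand-built 6-gene panel: 3 up, 3 down, one weight-2 gene."""
    frame = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "ref_direction": [1, 1, 1, -1, -1, -1],
            "ref_log2fc": [1.2, 0.9, 0.8, -1.5, -1.0, -0.8],
            "auc_test1": [0.95, 0.75, 0.72, 0.9, 0.78, 0.71],
            "auc_test2": [0.9, 0.7, 0.74, 0.88, 0.72, 0.73],
            "weight": [2.0, 0.75, 0.74, 2.0, 0.78, 0.73],
        }
    ).set_index("gene")
    return TDSPanel(frame)


def build_control_table(pos, hk, neg, endo, stage="raw"):
    """Assemble a CountTable + ProbeAnnotation from per-class row dicts.

    Each argument maps probe_id -> list of per-sample counts (equal length).
    """
    rows, data = [], {}
    for probe_id, counts in endo.items():
        rows.append((probe_id, probe_id, "tds", np.nan))
        data[probe_id] = counts
    for probe_id, counts in hk.items():
        rows.append((probe_id, probe_id, "housekeeper", np.nan))
        data[probe_id] = counts
    for i, (probe_id, counts) in enumerate(pos.items()):
        rows.append((probe_id, probe_id, "positive_control", float(2 ** (7 - 2 * i))))
        data[probe_id] = counts
    for probe_id, counts in neg.items():
        rows.append((probe_id, probe_id, "negative_control", np.nan))
        data[probe_id] = counts
    annot = ProbeAnnotation(
        pd.DataFrame(rows, columns=["probe_id", "gene", "probe_class", "expected_conc"])
    )
    n_samples = len(next(iter(data.values())))
    frame = pd.DataFrame(
        data, index=[f"s{i + 1}" for i in range(n_samples)]
    ).T
    frame.index.name = "probe_id"
    return CountTable(frame, stage=stage), annot


@pytest.fixture
def control_table_factory():
    return build_control_table
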