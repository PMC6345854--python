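"""Significance-threshold calibration for the signature scores.

The procedure scores (a) every disease/healthy sample pair's per-gene log2FC
list ("disease pairs": a 20 vs 20 cohort yields 400 lists) and (b) randomized
null lists built by resampling the pooled log2FC values, destroying the gene
structure. Comparing the two score distributions against the thresholds
|Z| >= 2 and |S| >= 0.27 yields false-positive rates (null lists crossing the
magnitude threshold) and false-negative rates (disease pairs failing to read
as *activated*, i.e. signed score below +threshold).

Two anchors bracket the score range: the Reference signature's own log2FC
list (all states consistent, the maximal Z) and the Model compound (its exact
negation, simulating a treatment returning every gene to healthy levels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .drug_scoring import S_SIGNIFICANCE, Z_SIGNIFICANCE, score_lfc_list
from .errors import IntegrityError
from .panel_io import CountTable, ProbeAnnotation, SampleSheet, TDSPanel

DEFAULT_N_NULL = 400


@dataclass
class CalibrationResult:
    disease_scores: pd.DataFrame  # columns z, ks_up, ks_down, s per pair
    null_scores: pd.DataFrame
    z_threshold: float
    s_threshold: float
    fp_rate_z: float
    fn_rate_z: float
    fp_rate_s: float
    fn_rate_s: float
    reference: dict | None = None  # anchor scores for the reference list
    model_compound: dict | None = None  # anchor scores for its negation

    def summary(self) -> dict:
        out = {
            "n_disease_pairs": int(len(self.disease_scores)),
            "n_null_lists": int(len(self.null_scores)),
            "z_threshold": self.z_threshold,
            "s_threshold": self.s_threshold,
            "fp_rate_z": self.fp_rate_z,
            "fn_rate_z": self.fn_rate_z,
            "fp_rate_s": self.fp_rate_s,
            "fn_rate_s": self.fn_rate_s,
            "mean_disease_z": float(self.disease_scores["z"].mean()),
            "mean_disease_s": float(self.disease_scores["s"].mean()),
            "mean_null_z": float(self.null_scores["z"].mean()),
            "mean_null_s": float(self.null_scores["s"].mean()),
        }
        if self.reference is not None:
            out["reference"] = {k: self.reference[k] for k in ("z", "s")}
        if self.model_compound is not None:
            out["model_compound"] = {k: self.model_compound[k] for k in ("z", "s")}
        return out

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.summary(), handle, indent=1)
            handle.write("\n")


def pairwise_lfc_matrix(
    table: CountTable | pd.DataFrame,
    disease_samples: Sequence[str],
    healthy_samples: Sequence[str],
    genes: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2FC for every (disease, healthy) sample pair.

    Column ``d|h`` holds log2((count_d + c) / (count_h + c)) per gene; a
    20 x 20 cohort yields 400 columns.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    if not list(disease_samples) or not list(healthy_samples):
        raise IntegrityError("both sample groups must be nonempty")
    missing = [g for g in genes if g not in counts.index]
    if missing:
        raise IntegrityError(f"genes absent from table: {missing}")
    d = counts.loc[genes, list(disease_samples)].to_numpy() + pseudocount
    h = counts.loc[genes, list(healthy_samples)].to_numpy() + pseudocount
    # genes x (n_d * n_h), disease index varying slowest
    ratio = d[:, :, None] / h[:, None, :]
    lfc = np.log2(ratio).reshape(len(genes), -1)
    cols = [f"{ds}|{hs}" for ds in disease_samples for hs in healthy_samples]
    return pd.DataFrame(lfc, index=list(genes), columns=cols)


def simulate_null_lists(
    matrix: pd.DataFrame,
    n_lists: int,
    seed: int | np.random.Generator | None = None,
    symmetric: bool = True,
) -> pd.DataFrame:
    """Randomized log2FC lists drawn from the pooled matrix values.

    Every cell is drawn uniformly with replacement from the pooled set of
    all matrix values, destroying the per-gene structure. With
    ``symmetric=True`` (default) each draw's sign is additionally flipped
    with probability 1/2, making the null exactly directionless so that the
    consistent/contradicting states are equiprobable regardless of any
    up/down imbalance in the signature.
    """
    if n_lists < 1:
        raise ValueError("n_lists must be >= 1")
    if matrix.empty:
        raise IntegrityError("log2FC matrix is empty")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pool = matrix.to_numpy().ravel()
    draws = rng.choice(pool, size=(len(matrix.index), n_lists), replace=True)
    if symmetric:
        signs = rng.choice([-1.0, 1.0], size=draws.shape)
        draws = draws * signs
    cols = [f"null_{i + 1}" for i in range(n_lists)]
    return pd.DataFrame(draws, index=matrix.index, columns=cols)


def score_lists(
    lists: pd.DataFrame, panel: TDSPanel, *, weighted: bool = False
) -> pd.DataFrame:
    """Score every column of a genes x lists log2FC matrix.

    Returns one row per list with columns z, ks_up, ks_down, s, n.
    """
    rows = []
    for col in lists.columns:
        res = score_lfc_list(lists[col], panel, weighted=weighted)
        rows.append(
            (col, res["z"], res["ks_up"], res["ks_down"], res["s"], res["n"])
        )
    return pd.DataFrame(
        rows, columns=["list", "z", "ks_up", "ks_down", "s", "n"]
    ).set_index("list")


def estimate_error_rates(
    disease_scores: pd.DataFrame,
    null_scores: pd.DataFrame,
    z_threshold: float = Z_SIGNIFICANCE,
    s_threshold: float = S_SIGNIFICANCE,
) -> CalibrationResult:
    """False-positive / false-negative rates at the given thresholds.

    FP: fraction of null lists whose score magnitude reaches the threshold.
    FN: fraction of disease pairs whose *signed* score falls below
    +threshold (a disease list must read as activated).
    """
    if disease_scores.empty or null_scores.empty:
        raise IntegrityError("score lists must be nonempty")
    fp_z = float((null_scores["z"].abs() >= z_threshold).mean())
    fn_z = float((disease_scores["z"] < z_threshold).mean())
    fp_s = float((null_scores["s"].abs() >= s_threshold).mean())
    fn_s = float((disease_scores["s"] < s_threshold).mean())
    return CalibrationResult(
        disease_scores=disease_scores,
        null_scores=null_scores,
        z_threshold=z_threshold,
        s_threshold=s_threshold,
        fp_rate_z=fp_z,
        fn_rate_z=fn_z,
        fp_rate_s=fp_s,
        fn_rate_s=fn_s,
    )


def calibrate(
    table: CountTable,
    annot: ProbeAnnotation,
    sheet: SampleSheet,
    panel: TDSPanel,
    *,
    n_null: int = DEFAULT_N_NULL,
    seed: int | np.random.Generator,
    weighted: bool = False,
    z_threshold: float = Z_SIGNIFICANCE,
    s_threshold: float = S_SIGNIFICANCE,
    symmetric_null: bool = True,
    pseudocount: float = 1.0,
    disease: str = "disease",
    healthy: str = "wt",
) -> CalibrationResult:
    """All-pairs + randomized-null calibration on a normalized cohort."""
    sheet.check_covers(table)
    disease_ids = [
        s for s in sheet.samples_where(genotype=disease) if s in table.samples
    ]
    healthy_ids = [
        s for s in sheet.samples_where(genotype=healthy) if s in table.samples
    ]
    matrix = pairwise_lfc_matrix(
        table, disease_ids, healthy_ids, panel.genes, pseudocount=pseudocount
    )
    nulls = simulate_null_lists(matrix, n_null, seed=seed, symmetric=symmetric_null)
    disease_scores = score_lists(matrix, panel, weighted=weighted)
    null_scores = score_lists(nulls, panel, weighted=weighted)
    result = estimate_error_rates(
        disease_scores, null_scores, z_threshold=z_threshold, s_threshold=s_threshold
    )
    result.reference = score_lfc_list(panel.ref_log2fc, panel, weighted=weighted)
    result.model_compound = score_lfc_list(
        -panel.ref_log2fc, panel, weighted=weighted
    )
    return result


def plot_score_distributions(result: CalibrationResult, path: str | Path) -> None:
    """Histogram of null vs disease-pair Z and S distributions (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, col, thr in (
        (axes[0], "z", result.z_threshold),
        (axes[1], "s", result.s_threshold),
    ):
        ax.hist(result.null_scores[col], bins=40, alpha=0.6, label="null", density=True)
        ax.hist(
            result.disease_scores[col],
            bins=40,
            alpha=0.6,
            label="disease pairs",
            density=True,
        )
        ax.axvline(thr, color="k", ls="--", lw=0.8)
        ax.axvline(-thr, color="k", ls="--", lw=0.8)
        ax.set_xlabel(col.upper() if col == "z" else "S")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
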