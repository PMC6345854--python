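"""Build the disease signature panel.

Per-gene two-group statistics (log2 fold change, Welch t, BH-FDR, ROC-AUC),
the preliminary selection gates, two-test cross-validation, AUC-based
weighting, and the Spearman correlation QC.

Scale conventions: fold changes are computed from untransformed (normalized)
count means with a pseudocount; the Welch t-test runs on log2(count + 1)
values for variance stabilization. AUC is computed with the disease group as
the positive class; for gating and weighting the orientation-free value
``max(auc, 1 - auc)`` is used so markers down in disease are not penalized,
while the raw oriented AUC is retained in the statistics table.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import IntegrityError
from .panel_io import CountTable, ProbeAnnotation, SampleSheet, TDSPanel

DEFAULT_LFC_THRESHOLD = 0.7
DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_AUC_THRESHOLD = 0.7
HIGH_AUC_THRESHOLD = 0.8  # both tests above this -> weight 2


def log2_fold_change(
    group_a: Sequence[float], group_b: Sequence[float], pseudocount: float = 1.0
) -> float:
    """log2((mean(A) + c) / (mean(B) + c)); A is the numerator group."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    return float(np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount)))


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t statistic (Satterthwaite df) and two-sided p.

    Degenerate case: both variances zero and equal means -> (0, 1) by
    convention; zero variances with unequal means -> (+-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch t-test needs n >= 2 per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roc_auc(disease_values: Sequence[float], healthy_values: Sequence[float]) -> float:
    """ROC-AUC with disease as the positive class (ties counted 1/2).

    Computed via the Mann-Whitney rank identity:
    ``AUC = (R_d - n_d(n_d+1)/2) / (n_d * n_h)`` where ``R_d`` is the rank
    sum of the disease values in the pooled ranking (midranks for ties).
    """
    d = np.asarray(disease_values, dtype=float)
    h = np.asarray(healthy_values, dtype=float)
    if d.size == 0 or h.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = sps.rankdata(np.concatenate([d, h]))
    u = ranks[: d.size].sum() - d.size * (d.size + 1) / 2.0
    return float(u / (d.size * h.size))


def oriented_auc(auc: float) -> float:
    """Orientation-free separation: max(auc, 1 - auc)."""
    return max(auc, 1.0 - auc)


def compute_gene_stats(
    table: CountTable,
    annot: ProbeAnnotation,
    sheet: SampleSheet,
    *,
    case: str = "disease",
    control: str = "wt",
    classes: Sequence[str] = ("tds",),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene statistics for one two-group (case vs control) comparison.

    Returns a DataFrame indexed by gene with columns log2fc, t_stat,
    p_value, fdr, auc (disease-positive) and auc_oriented. FDR is BH across
    the tested genes.
    """
    sheet.check_covers(table)
    case_ids = [s for s in sheet.samples_where(genotype=case) if s in table.samples]
    ctrl_ids = [s for s in sheet.samples_where(genotype=control) if s in table.samples]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise IntegrityError("each genotype group needs >= 2 samples in the table")
    probes = [p for p in annot.probes(classes) if p in table.counts.index]
    if not probes:
        raise IntegrityError(f"no probes of class {classes} in table")
    case_m = table.counts.loc[probes, case_ids].to_numpy()
    ctrl_m = table.counts.loc[probes, ctrl_ids].to_numpy()
    rows = []
    for i, gene in enumerate(probes):
        d, h = case_m[i], ctrl_m[i]
        lfc = log2_fold_change(d, h, pseudocount)
        t, p = welch_t(np.log2(d + 1.0), np.log2(h + 1.0))
        auc = roc_auc(d, h)
        rows.append((gene, lfc, t, p, auc))
    stats = pd.DataFrame(
        rows, columns=["gene", "log2fc", "t_stat", "p_value", "auc"]
    ).set_index("gene")
    stats["fdr"] = bh_adjust(stats["p_value"].to_numpy())
    stats["auc_oriented"] = stats["auc"].map(oriented_auc)
    return stats[["log2fc", "t_stat", "p_value", "fdr", "auc", "auc_oriented"]]


def select_preliminary_tds(
    stats: pd.DataFrame,
    *,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    auc_threshold: float = DEFAULT_AUC_THRESHOLD,
) -> list[str]:
    """Genes passing all three gates: |log2FC|, FDR, orientation-free AUC."""
    auc_or = (
        stats["auc_oriented"]
        if "auc_oriented" in stats.columns
        else stats["auc"].map(oriented_auc)
    )
    mask = (
        (stats["log2fc"].abs() >= lfc_threshold)
        & (stats["fdr"] <= fdr_threshold)
        & (auc_or >= auc_threshold)
    )
    return list(stats.index[mask])


def cross_validate_panel(
    test1: pd.DataFrame,
    test2: pd.DataFrame,
    *,
    auc_threshold: float = DEFAULT_AUC_THRESHOLD,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Keep genes with consistent nonzero log2FC direction in both tests and
    orientation-free AUC above threshold in at least one.

    Returns a DataFrame (index gene) with log2fc_1/2 and oriented auc_1/2
    for the validated genes. Genes missing from one test are excluded with
    a warning.
    """
    candidates = list(genes) if genes is not None else list(test1.index)
    missing = [g for g in candidates if g not in test1.index or g not in test2.index]
    if missing:
        warnings.warn(f"genes missing from one test, excluded: {missing}", stacklevel=2)
    candidates = [g for g in candidates if g not in set(missing)]
    t1 = test1.loc[candidates]
    t2 = test2.loc[candidates]
    auc1 = (
        t1["auc_oriented"] if "auc_oriented" in t1 else t1["auc"].map(oriented_auc)
    )
    auc2 = (
        t2["auc_oriented"] if "auc_oriented" in t2 else t2["auc"].map(oriented_auc)
    )
    sign1 = np.sign(t1["log2fc"])
    sign2 = np.sign(t2["log2fc"])
    keep = (sign1 == sign2) & (sign1 != 0) & (np.maximum(auc1, auc2) > auc_threshold)
    out = pd.DataFrame(
        {
            "log2fc_1": t1["log2fc"],
            "log2fc_2": t2["log2fc"],
            "auc_1": auc1,
            "auc_2": auc2,
        }
    )[keep]
    out.index.name = "gene"
    return out


def assign_weights(
    validated: pd.DataFrame, *, high_auc: float = HIGH_AUC_THRESHOLD
) -> TDSPanel:
    """Turn cross-validated genes into a weighted reference panel.

    Weight 2 when both tests' oriented AUCs exceed ``high_auc``; otherwise
    the larger of the two AUCs (monotone in marker quality, lands in the
    published (0.7, 1] bins). Reference log2FC is the mean of the two tests'
    estimates; its sign is the reference direction.
    """
    ref_log2fc = (validated["log2fc_1"] + validated["log2fc_2"]) / 2.0
    auc1, auc2 = validated["auc_1"], validated["auc_2"]
    double_high = (auc1 > high_auc) & (auc2 > high_auc)
    weight = np.where(double_high, 2.0, np.maximum(auc1, auc2))
    frame = pd.DataFrame(
        {
            "ref_direction": np.sign(ref_log2fc).astype(int),
            "ref_log2fc": ref_log2fc,
            "auc_test1": auc1,
            "auc_test2": auc2,
            "weight": weight,
        },
        index=validated.index,
    )
    frame.index.name = "gene"
    return TDSPanel(frame)


def build_panel(
    test1_table: CountTable,
    test1_sheet: SampleSheet,
    test2_table: CountTable,
    test2_sheet: SampleSheet,
    annot: ProbeAnnotation,
    *,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    auc_threshold: float = DEFAULT_AUC_THRESHOLD,
    pseudocount: float = 1.0,
) -> tuple[TDSPanel, dict]:
    """End-to-end panel construction from two normalized validation cohorts.

    Preliminary candidates are selected on test-1 statistics; candidates are
    then cross-validated across both tests and weighted. Returns the panel
    plus a gate-count audit dict.
    """
    stats1 = compute_gene_stats(test1_table, annot, test1_sheet, pseudocount=pseudocount)
    stats2 = compute_gene_stats(test2_table, annot, test2_sheet, pseudocount=pseudocount)
    preliminary = select_preliminary_tds(
        stats1,
        lfc_threshold=lfc_threshold,
        fdr_threshold=fdr_threshold,
        auc_threshold=auc_threshold,
    )
    validated = cross_validate_panel(
        stats1, stats2, auc_threshold=auc_threshold, genes=preliminary
    )
    if validated.empty:
        raise IntegrityError("no genes survived cross-validation")
    panel = assign_weights(validated)
    audit = {
        "n_candidates": int(len(stats1)),
        "n_preliminary": int(len(preliminary)),
        "n_validated": int(len(validated)),
        "n_weight_2": int((panel.weights == 2.0).sum()),
    }
    return panel, audit


def spearman_matrix(
    table: CountTable,
) -> tuple[pd.DataFrame, list[str] | None]:
    """Sample-sample Spearman correlation plus average-linkage leaf order.

    A constant sample has undefined rank correlation; its entries are NaN
    (warning issued) and the dendrogram order is then not computed.
    """
    if len(table.samples) < 2 or len(table.probes) < 2:
        raise IntegrityError("need >= 2 samples and >= 2 probes")
    corr = table.counts.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().any().any():
        constant = [s for s in corr.columns if corr[s].isna().any()]
        warnings.warn(
            f"constant sample(s), correlation undefined: {constant}", stacklevel=2
        )
        return corr, None
    from scipy.cluster import hierarchy

    dist = 1.0 - corr.to_numpy()
    condensed = dist[np.triu_indices_from(dist, k=1)]
    link = hierarchy.linkage(condensed, method="average")
    order = [corr.columns[i] for i in hierarchy.leaves_list(link)]
    return corr, order
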