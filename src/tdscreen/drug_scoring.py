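"""Compound scoring against the reference disease signature.

Two complementary statistics summarize a treatment-vs-vehicle comparison:

*Activation Z-score.* Each signature gene whose treatment log2FC is nonzero
is assigned a state ``x_i = +1`` (change consistent with the reference
disease direction) or ``-1`` (contradicting). Under the null that both states
are equiprobable, ``Z = (N+ - N-) / sqrt(N)`` is asymptotically standard
normal; ``Z >= 2`` reads as disease-activating, ``Z <= -2`` as
disease-repressing. The weighted variant uses
``Z = sum(w_i x_i) / sqrt(sum(w_i^2))``, which keeps unit variance under
independent random states.

*KS drug score.* The signature genes are ranked by treatment log2FC
(descending, ties broken by gene name). For a tag set occupying 1-based
positions ``V(1) < ... < V(t)`` in a ranking of length ``n``::

    a = max_j [ j/t - V(j)/n ]
    b = max_j [ V(j)/n - (j-1)/t ]
    ks = a if a > b else -b

``ks_up`` uses the reference up-regulated genes as tags and ``ks_down`` the
down-regulated ones. The drug score is ``S = ks_up - ks_down``, set to 0 when
both share a strict sign (an incoherent pattern); ``S > 0`` is
disease-activating, ``S < 0`` disease-repressing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, IntegrityError
from .panel_io import CountTable, TDSPanel
from .signature_builder import log2_fold_change, welch_t

DEG_LFC_THRESHOLD = 0.6
DEG_P_THRESHOLD = 0.05
Z_SIGNIFICANCE = 2.0
S_SIGNIFICANCE = 0.27


@dataclass
class GeneStateVector:
    """Signed consistency states of signature genes under one treatment."""

    states: pd.Series  # +1 / -1, indexed by included gene
    excluded: list[str]  # panel genes with no usable fold change

    @property
    def n(self) -> int:
        return int(len(self.states))

    @property
    def n_plus(self) -> int:
        return int((self.states == 1).sum())

    @property
    def n_minus(self) -> int:
        return int((self.states == -1).sum())


@dataclass
class DrugScore:
    """Scores and bookkeeping for one compound comparison."""

    z: float
    n: int
    n_plus: int
    n_minus: int
    ks_up: float
    ks_down: float
    s: float
    weighted: bool
    excluded_genes: list[str] = field(default_factory=list)
    deg_report: pd.DataFrame | None = None

    @property
    def no_evidence(self) -> bool:
        """True when no signature gene had a usable fold change (Z undefined)."""
        return self.n == 0

    def to_dict(self) -> dict:
        return {
            "z": None if math.isnan(self.z) else float(self.z),
            "n": self.n,
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "ks_up": float(self.ks_up),
            "ks_down": float(self.ks_down),
            "s": float(self.s),
            "weighted": self.weighted,
            "no_evidence": self.no_evidence,
            "excluded_genes": list(self.excluded_genes),
        }


def identify_degs(
    treated: pd.DataFrame | CountTable,
    control: pd.DataFrame | CountTable,
    *,
    lfc_threshold: float = DEG_LFC_THRESHOLD,
    p_threshold: float = DEG_P_THRESHOLD,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene treatment-vs-control log2FC and Welch p, with the DEG call.

    A gene is differentially expressed iff ``|log2FC| >= lfc_threshold`` and
    the raw two-sided Welch p-value is ``<= p_threshold``. Both arms need
    n >= 2 samples. The t-test runs on log2(count + 1) values.
    """
    tdf = treated.counts if isinstance(treated, CountTable) else treated
    cdf = control.counts if isinstance(control, CountTable) else control
    if tdf.shape[1] < 2 or cdf.shape[1] < 2:
        raise IntegrityError("each arm needs >= 2 samples")
    common = [g for g in tdf.index if g in cdf.index]
    if not common:
        raise CrossReferenceError("treated and control tables share no probes")
    rows = []
    for gene in common:
        t_vals = tdf.loc[gene].to_numpy(dtype=float)
        c_vals = cdf.loc[gene].to_numpy(dtype=float)
        lfc = log2_fold_change(t_vals, c_vals, pseudocount)
        _, p = welch_t(np.log2(t_vals + 1.0), np.log2(c_vals + 1.0))
        rows.append((gene, lfc, p))
    report = pd.DataFrame(rows, columns=["gene", "log2fc", "p_value"]).set_index("gene")
    report["is_deg"] = (report["log2fc"].abs() >= lfc_threshold) & (
        report["p_value"] <= p_threshold
    )
    return report


def gene_states(
    drug_lfc: pd.Series | Mapping[str, float],
    panel: TDSPanel,
    min_abs_lfc: float = 0.0,
) -> GeneStateVector:
    """Assign +1 (consistent with disease direction) / -1 (contradicting).

    Genes with ``|log2FC| <= min_abs_lfc`` (in particular exact zeros) are
    excluded and do not count toward N. Every panel gene must be present in
    ``drug_lfc``.
    """
    lfc = pd.Series(drug_lfc, dtype=float)
    missing = [g for g in panel.genes if g not in lfc.index]
    if missing:
        raise CrossReferenceError(f"panel genes missing fold changes: {missing}")
    lfc = lfc.reindex(panel.genes)
    excluded_mask = lfc.abs() <= min_abs_lfc
    included = lfc.index[~excluded_mask]
    states = (
        np.sign(lfc[included]) * panel.directions[included]
    ).astype(int)
    return GeneStateVector(states=states, excluded=list(lfc.index[excluded_mask]))


def activation_zscore(
    states: GeneStateVector, weights: pd.Series | None = None
) -> float:
    """Signed activation Z-score; NaN when no gene is included (no evidence)."""
    if states.n == 0:
        return float("nan")
    if weights is None:
        return float((states.n_plus - states.n_minus) / math.sqrt(states.n))
    w = weights.reindex(states.states.index)
    if w.isna().any():
        missing = list(w.index[w.isna()])
        raise CrossReferenceError(f"weights missing for genes: {missing}")
    return float((w * states.states).sum() / math.sqrt((w**2).sum()))


def ks_enrichment(ranked_genes: Sequence[str], tags: Iterable[str]) -> float:
    """Signed KS-style enrichment of a tag set within a ranked gene list.

    Positive values mean the tags concentrate at the top of the ranking.
    If the two one-sided maxima tie exactly, the positive one is returned.
    """
    ranked = list(ranked_genes)
    n = len(ranked)
    position = {g: i + 1 for i, g in enumerate(ranked)}
    if len(position) != n:
        raise IntegrityError("ranked gene list contains duplicates")
    tag_set = set(tags)
    if not tag_set:
        raise ValueError("tag set must be nonempty")
    missing = tag_set - position.keys()
    if missing:
        raise CrossReferenceError(f"tags not in ranked list: {sorted(missing)}")
    v = np.sort(np.array([position[g] for g in tag_set], dtype=float))
    t = len(v)
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a if a >= b else -b


def rank_by_lfc(drug_lfc: pd.Series, genes: Sequence[str]) -> list[str]:
    """Genes ordered by descending log2FC; ties broken by gene name."""
    return sorted(genes, key=lambda g: (-float(drug_lfc[g]), g))


def ks_drug_score(
    drug_lfc: pd.Series | Mapping[str, float],
    panel: TDSPanel,
    *,
    up_tags: Sequence[str] | None = None,
    down_tags: Sequence[str] | None = None,
) -> tuple[float, float, float]:
    """(ks_up, ks_down, S) for one treatment's panel fold changes.

    Tag sets default to the reference up/down signature genes; pass explicit
    subsets (e.g. the compound's DEGs within each class) to restrict them.
    """
    lfc = pd.Series(drug_lfc, dtype=float)
    missing = [g for g in panel.genes if g not in lfc.index]
    if missing:
        raise CrossReferenceError(f"panel genes missing fold changes: {missing}")
    up = list(up_tags) if up_tags is not None else panel.up_genes
    down = list(down_tags) if down_tags is not None else panel.down_genes
    if not up or not down:
        raise IntegrityError("need >= 1 up tag and >= 1 down tag")
    ranking = rank_by_lfc(lfc, panel.genes)
    ks_up = ks_enrichment(ranking, up)
    ks_down = ks_enrichment(ranking, down)
    s = 0.0 if ks_up * ks_down > 0 else ks_up - ks_down
    return ks_up, ks_down, s


def score_lfc_list(
    drug_lfc: pd.Series | Mapping[str, float],
    panel: TDSPanel,
    *,
    weighted: bool = False,
    min_abs_lfc: float = 0.0,
) -> dict:
    """Score one per-gene log2FC list: returns z, ks_up, ks_down, s, counts.

    This is the shared core of compound scoring and null calibration.
    """
    lfc = pd.Series(drug_lfc, dtype=float)
    states = gene_states(lfc, panel, min_abs_lfc=min_abs_lfc)
    z = activation_zscore(states, panel.weights if weighted else None)
    ks_up, ks_down, s = ks_drug_score(lfc, panel)
    return {
        "z": z,
        "ks_up": ks_up,
        "ks_down": ks_down,
        "s": s,
        "n": states.n,
        "n_plus": states.n_plus,
        "n_minus": states.n_minus,
        "excluded": states.excluded,
    }


def score_compound(
    treated: pd.DataFrame | CountTable,
    vehicle: pd.DataFrame | CountTable,
    panel: TDSPanel,
    *,
    weighted: bool = True,
    min_abs_lfc: float = 0.0,
    z_restrict_deg: bool = False,
    ks_tags: str = "ref",
    lfc_threshold: float = DEG_LFC_THRESHOLD,
    p_threshold: float = DEG_P_THRESHOLD,
    pseudocount: float = 1.0,
) -> DrugScore:
    """Full treatment-vs-vehicle scoring: DEGs, states, Z, KS drug score.

    ``z_restrict_deg`` limits the Z-score to panel genes called DEG (the
    restrictive reading); ``ks_tags`` is ``"ref"`` (reference signature
    genes as tags, the connectivity-map convention) or ``"deg"`` (tags
    restricted to the compound's DEGs within each direction class).
    """
    if ks_tags not in ("ref", "deg"):
        raise ValueError("ks_tags must be 'ref' or 'deg'")
    deg_report = identify_degs(
        treated,
        vehicle,
        lfc_threshold=lfc_threshold,
        p_threshold=p_threshold,
        pseudocount=pseudocount,
    )
    missing = [g for g in panel.genes if g not in deg_report.index]
    if missing:
        raise CrossReferenceError(f"panel genes absent from expression: {missing}")
    panel_lfc = deg_report.loc[panel.genes, "log2fc"]
    states = gene_states(panel_lfc, panel, min_abs_lfc=min_abs_lfc)
    if z_restrict_deg:
        deg_genes = set(deg_report.index[deg_report["is_deg"]])
        keep = [g for g in states.states.index if g in deg_genes]
        dropped = [g for g in states.states.index if g not in deg_genes]
        states = GeneStateVector(
            states=states.states[keep], excluded=states.excluded + dropped
        )
    z = activation_zscore(states, panel.weights if weighted else None)
    if ks_tags == "deg":
        deg_genes = set(deg_report.index[deg_report["is_deg"]])
        up = [g for g in panel.up_genes if g in deg_genes]
        down = [g for g in panel.down_genes if g in deg_genes]
        ks_up, ks_down, s = ks_drug_score(panel_lfc, panel, up_tags=up, down_tags=down)
    else:
        ks_up, ks_down, s = ks_drug_score(panel_lfc, panel)
    return DrugScore(
        z=z,
        n=states.n,
        n_plus=states.n_plus,
        n_minus=states.n_minus,
        ks_up=ks_up,
        ks_down=ks_down,
        s=s,
        weighted=weighted,
        excluded_genes=states.excluded,
        deg_report=deg_report,
    )
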