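"""Synthetic NanoString-like cohorts with known ground truth.

The generator emulates the structure of a custom nCounter panel run on whole
animals: 97 disease-signature probes, 108 pathway probes, 29 housekeepers,
6 positive-control spikes on a 4-fold concentration ladder and 8 negative
controls. Each sample carries a lane (hybridization-efficiency) factor and an
RNA-input factor; endogenous probes get an additive background and negative-
binomial counting noise; positive controls depend on the lane factor but not
on RNA input; negative controls are Poisson background.

Disease biology: each signature gene has a signed log2 effect ``delta_g`` and
a penetrance ``p_g`` — a diseased individual expresses the effect with
probability ``p_g``. Incomplete penetrance makes per-gene AUC vary, which is
what motivates AUC-based weighting downstream. A drug arm shifts each
signature gene's effect by ``-rho * delta_g``: ``rho = 1`` is the full
reversal ("Model compound"), ``rho = 0`` an inert compound and ``rho = -1`` a
disease mimic. Off-target activity perturbs a random fraction of pathway
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .panel_io import CountTable, ProbeAnnotation, SampleSheet, TDSPanel

#: positive-control concentration ladder (fM), the platform's 4-fold series
POS_CONC_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the assay and cohort design."""

    n_tds: int = 97
    n_pathway: int = 108
    n_housekeeper: int = 29
    n_pos: int = 6
    n_neg: int = 8
    n_wt: int = 20
    n_disease: int = 20
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    effect_log2_range: tuple[float, float] = (0.7, 2.5)
    penetrance_range: tuple[float, float] = (0.6, 1.0)
    nb_dispersion: float = 0.05
    background_mean: float = 12.0
    lane_sd: float = 0.1  # sd of log2 lane (hybridization) factor
    input_sd: float = 0.2  # sd of log2 RNA-input factor
    pos_gain: float = 600.0  # counts per fM for positive-control spikes
    off_target_range: tuple[float, float] = (0.6, 1.5)
    batch: str = "run1"
    trial: str = "sim"
    seed: int | None = None

    def validate(self) -> None:
        lo, hi = self.effect_log2_range
        plo, phi = self.penetrance_range
        if lo < 0 or hi < lo:
            raise IntegrityError("effect_log2_range must satisfy 0 <= lo <= hi")
        if not (0 <= plo <= phi <= 1):
            raise IntegrityError("penetrance_range must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.background_mean < 0:
            raise IntegrityError("dispersion and background must be nonnegative")
        if min(self.n_tds, self.n_housekeeper, self.n_neg) < 1 or self.n_pos < 1:
            raise IntegrityError("probe-class sizes must be >= 1")


@dataclass
class GroundTruth:
    """Per-gene and per-sample latent parameters stored with every cohort."""

    genes: pd.DataFrame  # index gene: baseline_log2, direction, effect, penetrance
    samples: pd.DataFrame  # index sample: lane_factor, input_factor, background
    drug: dict | None = None  # rho / off-target info for drug arms

    def to_dict(self) -> dict:
        return {
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "drug": self.drug,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        genes = pd.DataFrame(payload["genes"]).set_index("gene")
        samples = pd.DataFrame(payload["samples"]).set_index("sample_id")
        return cls(genes=genes, samples=samples, drug=payload.get("drug"))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle)
            handle.write("\n")


@dataclass
class SimulatedCohort:
    table: CountTable
    annotation: ProbeAnnotation
    sheet: SampleSheet
    truth: GroundTruth
    config: SimulationConfig


def make_annotation(config: SimulationConfig) -> ProbeAnnotation:
    """Probe annotation matching the configured panel sizes."""
    rows = []
    for i in range(config.n_tds):
        rows.append((f"TDS{i + 1:03d}", f"TDS{i + 1:03d}", "tds", np.nan))
    for i in range(config.n_pathway):
        rows.append((f"PWY{i + 1:03d}", f"PWY{i + 1:03d}", "pathway", np.nan))
    for i in range(config.n_housekeeper):
        rows.append((f"HK{i + 1:02d}", f"HK{i + 1:02d}", "housekeeper", np.nan))
    for i in range(config.n_pos):
        conc = POS_CONC_LADDER[i % len(POS_CONC_LADDER)] / (
            4.0 ** (i // len(POS_CONC_LADDER))
        )
        rows.append((f"POS_{chr(65 + i)}", f"POS_{chr(65 + i)}", "positive_control", conc))
    for i in range(config.n_neg):
        rows.append((f"NEG_{i + 1:02d}", f"NEG_{i + 1:02d}", "negative_control", np.nan))
    return ProbeAnnotation(
        pd.DataFrame(rows, columns=["probe_id", "gene", "probe_class", "expected_conc"])
    )


def draw_gene_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent per-gene parameters shared by all cohorts of one study.

    Signature genes get a random sign, an effect size uniform on the
    configured range and a penetrance uniform on its range; pathway and
    housekeeper genes have zero effect. Baselines are normal on log2 scale.
    """
    config.validate()
    annot = make_annotation(config)
    endo = annot.probes(("tds", "pathway", "housekeeper"))
    n = len(endo)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    frame = pd.DataFrame(
        {
            "baseline_log2": baseline,
            "direction": 0,
            "effect": 0.0,
            "penetrance": 0.0,
        },
        index=pd.Index(endo, name="gene"),
    )
    tds = annot.probes("tds")
    lo, hi = config.effect_log2_range
    plo, phi = config.penetrance_range
    frame.loc[tds, "direction"] = rng.choice([-1, 1], size=len(tds))
    frame.loc[tds, "effect"] = rng.uniform(lo, hi, size=len(tds))
    frame.loc[tds, "penetrance"] = rng.uniform(plo, phi, size=len(tds))
    return frame


def _draw_sample_factors(
    config: SimulationConfig, rng: np.random.Generator, sample_ids: Sequence[str]
) -> pd.DataFrame:
    n = len(sample_ids)
    frame = pd.DataFrame(
        {
            "lane_factor": 2.0 ** rng.normal(0.0, config.lane_sd, size=n),
            "input_factor": 2.0 ** rng.normal(0.0, config.input_sd, size=n),
            "background": np.full(n, config.background_mean),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return frame


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _simulate_samples(
    config: SimulationConfig,
    annot: ProbeAnnotation,
    gene_truth: pd.DataFrame,
    sample_ids: Sequence[str],
    diseased: bool,
    rng: np.random.Generator,
    drug_shift: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts (probes x samples) and sample factors for one homogeneous arm."""
    factors = _draw_sample_factors(config, rng, sample_ids)
    endo = gene_truth.index.to_numpy()
    tds_mask = (gene_truth["direction"] != 0).to_numpy()
    baseline = gene_truth["baseline_log2"].to_numpy()
    signed_effect = (gene_truth["direction"] * gene_truth["effect"]).to_numpy()
    penetrance = gene_truth["penetrance"].to_numpy()
    shift = (
        drug_shift.reindex(gene_truth.index).fillna(0.0).to_numpy()
        if drug_shift is not None
        else np.zeros(len(endo))
    )
    pos_probes = annot.probes("positive_control")
    neg_probes = annot.probes("negative_control")
    conc = annot.expected_conc.loc[pos_probes].to_numpy()
    columns = {}
    for sid in sample_ids:
        h = factors.at[sid, "lane_factor"]
        r = factors.at[sid, "input_factor"]
        b = factors.at[sid, "background"]
        log2_expr = baseline + shift
        if diseased:
            expressed = rng.random(len(endo)) < penetrance
            log2_expr = log2_expr + np.where(tds_mask & expressed, signed_effect, 0.0)
        mu = h * r * 2.0**log2_expr + b
        endo_counts = _nb_counts(mu, config.nb_dispersion, rng)
        pos_counts = rng.poisson(h * config.pos_gain * conc)
        neg_counts = rng.poisson(np.full(len(neg_probes), h * b))
        columns[sid] = np.concatenate([endo_counts, pos_counts, neg_counts])
    index = list(endo) + pos_probes + neg_probes
    counts = pd.DataFrame(columns, index=index).astype(int)
    counts.index.name = "probe_id"
    return counts, factors


def simulate_cohort(
    config: SimulationConfig,
    gene_truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """One wt + disease cohort with raw counts and stored ground truth.

    Pass ``gene_truth`` (from :func:`draw_gene_truth`) to share gene
    parameters across cohorts, e.g. for two validation tests of one study.
    """
    config.validate()
    if rng is None:
        if config.seed is None:
            raise IntegrityError("simulate_cohort needs config.seed or an rng")
        rng = np.random.default_rng(config.seed)
    if gene_truth is None:
        gene_truth = draw_gene_truth(config, rng)
    annot = make_annotation(config)
    wt_ids = [f"wt{i + 1:02d}" for i in range(config.n_wt)]
    dis_ids = [f"dis{i + 1:02d}" for i in range(config.n_disease)]
    if not wt_ids and not dis_ids:
        raise IntegrityError("cohort needs at least one sample")
    wt_counts, wt_factors = _simulate_samples(
        config, annot, gene_truth, wt_ids, diseased=False, rng=rng
    )
    dis_counts, dis_factors = _simulate_samples(
        config, annot, gene_truth, dis_ids, diseased=True, rng=rng
    )
    counts = pd.concat([wt_counts, dis_counts], axis=1)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": wt_ids + dis_ids,
                "genotype": ["wt"] * len(wt_ids) + ["disease"] * len(dis_ids),
                "treatment": "vehicle",
                "dose": "",
                "batch": config.batch,
                "trial": config.trial,
            }
        )
    )
    truth = GroundTruth(
        genes=gene_truth, samples=pd.concat([wt_factors, dis_factors])
    )
    return SimulatedCohort(
        table=CountTable(counts, stage="raw"),
        annotation=annot,
        sheet=sheet,
        truth=truth,
        config=config,
    )


def simulate_drug_arm(
    cohort: SimulatedCohort,
    rho: float,
    off_target_fraction: float = 0.0,
    n_treated: int = 8,
    treatment: str = "compound",
    seed: int | np.random.Generator | None = None,
) -> SimulatedCohort:
    """Treated diseased individuals with per-gene effects shifted by -rho*delta.

    ``rho`` in [-1, 1]: 1 reverses the disease signature fully, 0 is inert,
    -1 mimics the disease. ``off_target_fraction`` of pathway genes receive
    an additional random +-Uniform shift (range from the config).
    """
    if not -1.0 <= rho <= 1.0:
        raise IntegrityError("rho must lie in [-1, 1]")
    if not 0.0 <= off_target_fraction <= 1.0:
        raise IntegrityError("off_target_fraction must lie in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    config = cohort.config
    gene_truth = cohort.truth.genes
    shift = -rho * gene_truth["direction"] * gene_truth["effect"]
    pathway = cohort.annotation.probes("pathway")
    n_off = int(round(off_target_fraction * len(pathway)))
    off_targets: dict[str, float] = {}
    if n_off:
        chosen = rng.choice(np.array(pathway), size=n_off, replace=False)
        lo, hi = config.off_target_range
        magnitudes = rng.uniform(lo, hi, size=n_off)
        signs = rng.choice([-1.0, 1.0], size=n_off)
        for gene, mag, sign in zip(chosen, magnitudes, signs):
            off_targets[str(gene)] = float(sign * mag)
            shift.at[gene] = shift.at[gene] + sign * mag
    trt_ids = [f"trt{i + 1:02d}" for i in range(n_treated)]
    counts, factors = _simulate_samples(
        config,
        cohort.annotation,
        gene_truth,
        trt_ids,
        diseased=True,
        rng=rng,
        drug_shift=shift,
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": trt_ids,
                "genotype": "disease",
                "treatment": treatment,
                "dose": "",
                "batch": config.batch,
                "trial": config.trial,
            }
        )
    )
    truth = GroundTruth(
        genes=gene_truth,
        samples=factors,
        drug={"rho": rho, "off_targets": off_targets},
    )
    return SimulatedCohort(
        table=CountTable(counts, stage="raw"),
        annotation=cohort.annotation,
        sheet=sheet,
        truth=truth,
        config=config,
    )


def panel_from_truth(
    gene_truth: pd.DataFrame, *, high_penetrance: float = 0.9
) -> TDSPanel:
    """Reference panel straight from the generator's ground truth.

    Convenience for tests/benchmarks that want the *oracle* signature rather
    than one recovered by the builder: direction and log2FC come from the
    latent effects; weights map penetrance into the panel's weight scheme
    (2 for near-complete penetrance, else the penetrance clipped into
    (0.7, 1)). Genes with zero effect are omitted.
    """
    tds = gene_truth[(gene_truth["direction"] != 0) & (gene_truth["effect"] > 0)]
    pen = tds["penetrance"]
    weight = np.where(
        pen >= high_penetrance, 2.0, np.clip(pen, 0.705, 0.995)
    )
    frame = pd.DataFrame(
        {
            "ref_direction": tds["direction"].astype(int),
            "ref_log2fc": tds["direction"] * tds["effect"],
            "auc_test1": np.clip(pen, 0.0, 1.0),
            "auc_test2": np.clip(pen, 0.0, 1.0),
            "weight": weight,
        },
        index=tds.index,
    )
    frame.index.name = "gene"
    return TDSPanel(frame)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write counts, annotation, sample sheet and ground truth to a directory."""
    from . import panel_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "annotation": out / "annotation.csv",
        "samples": out / "samples.csv",
        "truth": out / "ground_truth.json",
    }
    panel_io.write_count_table(cohort.table, paths["counts"])
    panel_io.write_annotation(cohort.annotation, paths["annotation"])
    panel_io.write_sample_sheet(cohort.sheet, paths["samples"])
    cohort.truth.write(paths["truth"])
    return paths
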