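"""NanoString-style count normalization.

Three steps, applied in a fixed order:

1. **Positive-control scaling** removes per-lane hybridization-efficiency
   differences (including cartridge effects): every sample is multiplied by
   ``grand mean of per-sample positive-control means / its own mean``, so all
   samples end with the same positive-control mean.
2. **Housekeeper scaling** removes RNA-input differences using the geometric
   mean of housekeeper counts the same way (arithmetic mean of the per-sample
   geometric means as the reference level, so factors average ~1 in a run).
   Positive controls are spiked oligos and carry no RNA-input signal, so they
   are exempt from this scaling — which also preserves the equal
   positive-control means established in step 1 as a QC invariant.
3. **Background subtraction** estimates per-sample nonspecific binding from
   the negative controls as ``mu + 2*sigma`` (sample sd, n-1 denominator) and
   subtracts it from every scored signal probe (tds and pathway classes),
   clamping at zero. Housekeepers have finished their job as scaling anchors
   and, like the control rows, pass through unmodified, keeping their
   geometric means exactly equal across samples.

Factors are reported per sample; normalized counts are stored as reals and
never re-rounded.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, NormalizationError
from .panel_io import SIGNAL_CLASSES, CountTable, ProbeAnnotation

#: multiplier on sigma in the background threshold mu + K*sigma
BACKGROUND_SIGMA_MULTIPLIER = 2.0

#: replacement for zero housekeeper counts when computing geometric means
HK_ZERO_PSEUDOCOUNT = 0.5


def _require_stage(table: CountTable, stage: str, op: str) -> None:
    if table.stage != stage:
        raise IntegrityError(
            f"{op} expects a {stage!r} table, got {table.stage!r}"
        )


def positive_control_normalize(
    table: CountTable, annot: ProbeAnnotation
) -> tuple[CountTable, pd.DataFrame]:
    """Scale each sample so positive-control means equal the grand mean.

    Returns the scaled table (stage ``pos_normalized``) and a per-sample
    factor report with column ``pos_factor``.
    """
    _require_stage(table, "raw", "positive_control_normalize")
    if not table.samples:
        raise NormalizationError("count table has no samples")
    pos_probes = annot.probes("positive_control")
    if not pos_probes:
        raise NormalizationError("no positive-control probes in annotation")
    pos = table.counts.loc[pos_probes]
    sample_means = pos.mean(axis=0)
    zero = sample_means[sample_means <= 0]
    if len(zero):
        raise NormalizationError(
            f"all-zero positive controls in sample(s): {list(zero.index)}"
        )
    grand_mean = sample_means.mean()
    factors = grand_mean / sample_means
    scaled = table.counts * factors
    report = pd.DataFrame({"pos_factor": factors})
    report.index.name = "sample_id"
    return CountTable(scaled, stage="pos_normalized"), report


def housekeeper_normalize(
    table: CountTable, annot: ProbeAnnotation
) -> tuple[CountTable, pd.DataFrame]:
    """Scale each sample so housekeeper geometric means are equal.

    The factor multiplies all probes except the positive controls (spiked
    oligos independent of RNA input). Zero housekeeper counts are replaced
    by ``HK_ZERO_PSEUDOCOUNT`` for the factor computation only (warning
    issued); stored counts are untouched.
    """
    _require_stage(table, "pos_normalized", "housekeeper_normalize")
    hk_probes = annot.probes("housekeeper")
    if not hk_probes:
        raise NormalizationError("no housekeeper probes in annotation")
    hk = table.counts.loc[hk_probes]
    if (hk <= 0).any().any():
        if (hk.max(axis=0) <= 0).any():
            bad = list(hk.columns[hk.max(axis=0) <= 0])
            raise NormalizationError(f"all housekeepers zero in sample(s): {bad}")
        warnings.warn(
            "zero housekeeper counts replaced by "
            f"{HK_ZERO_PSEUDOCOUNT} for factor computation",
            stacklevel=2,
        )
        hk = hk.clip(lower=HK_ZERO_PSEUDOCOUNT)
    gmeans = np.exp(np.log(hk).mean(axis=0))
    reference = gmeans.mean()
    factors = reference / gmeans
    scaled = table.counts * factors
    pos_probes = [p for p in annot.probes("positive_control") if p in scaled.index]
    scaled.loc[pos_probes] = table.counts.loc[pos_probes]
    report = pd.DataFrame({"hk_factor": factors})
    report.index.name = "sample_id"
    return CountTable(scaled, stage="hk_normalized"), report


def subtract_background(
    table: CountTable, annot: ProbeAnnotation
) -> tuple[CountTable, pd.DataFrame]:
    """Subtract the per-sample negative-control threshold mu + 2*sigma.

    The threshold is computed per sample from that sample's negative-control
    counts (sample standard deviation, n-1). It is subtracted from every
    signal probe (tds, pathway); results are clamped at 0; housekeeper and
    control rows pass through.
    """
    _require_stage(table, "hk_normalized", "subtract_background")
    neg_probes = annot.probes("negative_control")
    if len(neg_probes) < 2:
        raise NormalizationError(
            "background estimation needs >=2 negative-control probes"
        )
    neg = table.counts.loc[neg_probes]
    mu = neg.mean(axis=0)
    sigma = neg.std(axis=0, ddof=1)
    threshold = mu + BACKGROUND_SIGMA_MULTIPLIER * sigma
    out = table.counts.copy()
    signal_probes = annot.probes(SIGNAL_CLASSES)
    endo = [p for p in signal_probes if p in out.index]
    out.loc[endo] = (out.loc[endo] - threshold).clip(lower=0.0)
    report = pd.DataFrame(
        {
            "background_mu": mu,
            "background_sigma": sigma,
            "background_threshold": threshold,
        }
    )
    report.index.name = "sample_id"
    return CountTable(out, stage="background_subtracted"), report


def normalize_pipeline(
    table: CountTable, annot: ProbeAnnotation
) -> tuple[CountTable, pd.DataFrame]:
    """Full chain: positive controls -> housekeepers -> background.

    Returns the background-subtracted table and the merged per-sample factor
    report (pos_factor, hk_factor, background_mu/sigma/threshold).
    """
    table, pos_report = positive_control_normalize(table, annot)
    table, hk_report = housekeeper_normalize(table, annot)
    table, bg_report = subtract_background(table, annot)
    report = pd.concat([pos_report, hk_report, bg_report], axis=1)
    return table, report


def write_factor_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, index_label="sample_id")
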