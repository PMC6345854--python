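"""Data model and readers/writers for probe annotations, count tables, sample
sheets, and reference signature panels.

Conventions
-----------
Count tables are probes-as-rows, samples-as-columns; the first CSV column
holds the probe_id and the header row the sample ids (the NanoString export
convention). The sectioned-CSV RCC dialect is supported for raw per-sample
files: the ``Code_Summary`` section is parsed, ``Header``/``Lane_Attributes``
sections are retained as opaque metadata. Signature panels are JSON.

Probe classes partition the panel exhaustively:

``tds``
    disease-signature targets, scored against the reference directions;
``pathway``
    reference pathway/toxicity targets, reported but not part of the score;
``housekeeper``
    stable genes used for RNA-content scaling;
``positive_control`` / ``negative_control``
    spiked oligos measuring per-lane hybridization efficiency / background.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, FormatError, IntegrityError

PROBE_CLASSES = (
    "tds",
    "pathway",
    "housekeeper",
    "positive_control",
    "negative_control",
)

#: probe classes measuring sample RNA (as opposed to spiked control oligos)
NON_CONTROL_CLASSES = ("tds", "pathway", "housekeeper")

#: probe classes scored downstream; background is subtracted from these only
SIGNAL_CLASSES = ("tds", "pathway")

STAGES = ("raw", "pos_normalized", "hk_normalized", "background_subtracted")

_RCC_CLASS_MAP = {
    "Endogenous": "tds",
    "Housekeeping": "housekeeper",
    "Positive": "positive_control",
    "Negative": "negative_control",
}

_CONC_RE = re.compile(r"^(?P<name>.+)\((?P<conc>[0-9.]+)\)$")


class ProbeAnnotation:
    """Probe identities and classes for one panel.

    Wraps a DataFrame with columns ``probe_id``, ``gene``, ``probe_class``
    and ``expected_conc`` (fM; positive controls only, NaN elsewhere).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in ("probe_id", "gene", "probe_class"):
            if col not in frame.columns:
                raise FormatError(f"annotation missing column {col!r}")
        if "expected_conc" not in frame.columns:
            frame["expected_conc"] = np.nan
        frame["expected_conc"] = pd.to_numeric(frame["expected_conc"], errors="coerce")
        dup = frame["probe_id"][frame["probe_id"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate probe_id(s): {sorted(set(dup))}")
        bad = set(frame["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise IntegrityError(f"unknown probe_class value(s): {sorted(bad)}")
        pos = frame["probe_class"] == "positive_control"
        if frame.loc[pos, "expected_conc"].isna().any():
            raise IntegrityError("positive_control probes require expected_conc")
        if (frame.loc[pos, "expected_conc"] < 0).any():
            raise IntegrityError("expected_conc must be nonnegative")
        if frame.loc[~pos, "expected_conc"].notna().any():
            raise IntegrityError("expected_conc only allowed on positive_control probes")
        self.frame = frame.reset_index(drop=True)

    def probes(self, probe_class: str | Sequence[str]) -> list[str]:
        """Probe ids belonging to one class (or any of several classes)."""
        classes = (probe_class,) if isinstance(probe_class, str) else tuple(probe_class)
        mask = self.frame["probe_class"].isin(classes)
        return list(self.frame.loc[mask, "probe_id"])

    @property
    def expected_conc(self) -> pd.Series:
        """Expected concentration (fM) indexed by positive-control probe_id."""
        pos = self.frame[self.frame["probe_class"] == "positive_control"]
        return pos.set_index("probe_id")["expected_conc"]

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeAnnotation) and self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)


class CountTable:
    """Probes x samples count matrix plus its normalization stage."""

    def __init__(self, counts: pd.DataFrame, stage: str = "raw"):
        if stage not in STAGES:
            raise IntegrityError(f"unknown stage {stage!r}; expected one of {STAGES}")
        counts = counts.copy()
        counts = counts.astype(float)
        if counts.index.duplicated().any():
            raise IntegrityError("duplicate probe_id in count table")
        if counts.columns.duplicated().any():
            raise IntegrityError("duplicate sample_id in count table")
        if counts.isna().any().any():
            raise IntegrityError("count table contains missing values")
        if (counts.values < 0).any():
            raise IntegrityError("count table contains negative counts")
        if stage == "raw" and not np.allclose(counts.values % 1.0, 0.0):
            raise IntegrityError("raw counts must be integers")
        self.counts = counts
        self.stage = stage

    @property
    def probes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise CrossReferenceError(f"samples not in table: {missing}")
        return CountTable(self.counts[list(sample_ids)], stage=self.stage)

    def with_counts(self, counts: pd.DataFrame, stage: str) -> "CountTable":
        return CountTable(counts, stage=stage)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.stage == other.stage
            and self.counts.equals(other.counts)
        )


class SampleSheet:
    """Per-sample metadata: genotype, treatment, dose, batch, trial.

    Unknown genotype/treatment strings are preserved verbatim.
    """

    COLUMNS = ("sample_id", "genotype", "treatment", "dose", "batch", "trial")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "sample_id" not in frame.columns:
            raise FormatError("sample sheet missing column 'sample_id'")
        for col in self.COLUMNS:
            if col not in frame.columns:
                frame[col] = ""
        frame = frame[list(self.COLUMNS)].fillna("").astype(str)
        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            raise IntegrityError(f"duplicate sample_id(s): {sorted(set(dup))}")
        self.frame = frame.reset_index(drop=True)

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids matching all equality conditions, e.g. genotype='wt'."""
        mask = pd.Series(True, index=self.frame.index)
        for col, value in conditions.items():
            if col not in self.frame.columns:
                raise KeyError(col)
            mask &= self.frame[col] == value
        return list(self.frame.loc[mask, "sample_id"])

    def check_covers(self, table: CountTable) -> None:
        """Every sample in the table must appear exactly once in the sheet."""
        missing = set(table.samples) - set(self.frame["sample_id"])
        if missing:
            raise CrossReferenceError(f"samples missing from sheet: {sorted(missing)}")

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSheet) and self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)


class TDSPanel:
    """Reference disease signature: per-gene direction, log2FC, AUCs, weight.

    ``ref_direction`` is +1 for genes up in disease, -1 for genes down;
    ``weight`` is 2 for double-high-AUC genes, else in (0.7, 1].
    """

    COLUMNS = ("ref_direction", "ref_log2fc", "auc_test1", "auc_test2", "weight")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.COLUMNS:
            if col not in frame.columns:
                raise FormatError(f"panel missing column {col!r}")
        if frame.index.name != "gene":
            if "gene" in frame.columns:
                frame = frame.set_index("gene")
            else:
                frame.index.name = "gene"
        if frame.index.duplicated().any():
            raise IntegrityError("duplicate gene in panel")
        frame = frame[list(self.COLUMNS)].astype(float)
        frame["ref_direction"] = frame["ref_direction"].astype(int)
        if not set(frame["ref_direction"]) <= {-1, 1}:
            raise IntegrityError("ref_direction must be +1 or -1")
        if (np.sign(frame["ref_log2fc"]) != frame["ref_direction"]).any():
            raise IntegrityError("sign(ref_log2fc) must equal ref_direction")
        for col in ("auc_test1", "auc_test2"):
            if ((frame[col] < 0) | (frame[col] > 1)).any():
                raise IntegrityError(f"{col} must lie in [0, 1]")
        w = frame["weight"]
        ok = (w == 2.0) | ((w > 0.7) & (w <= 1.0))
        if not ok.all():
            bad = list(frame.index[~ok])
            raise IntegrityError(
                f"weights must be 2 or in (0.7, 1]; offending genes: {bad}"
            )
        self.frame = frame

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def up_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["ref_direction"] == 1])

    @property
    def down_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["ref_direction"] == -1])

    @property
    def directions(self) -> pd.Series:
        return self.frame["ref_direction"]

    @property
    def weights(self) -> pd.Series:
        return self.frame["weight"]

    @property
    def ref_log2fc(self) -> pd.Series:
        return self.frame["ref_log2fc"]

    def to_dict(self) -> dict:
        genes = []
        for gene, row in self.frame.iterrows():
            genes.append(
                {
                    "gene": gene,
                    "ref_direction": int(row["ref_direction"]),
                    "ref_log2fc": float(row["ref_log2fc"]),
                    "auc_test1": float(row["auc_test1"]),
                    "auc_test2": float(row["auc_test2"]),
                    "weight": float(row["weight"]),
                }
            )
        return {"genes": genes}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TDSPanel":
        try:
            frame = pd.DataFrame(payload["genes"]).set_index("gene")
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed panel payload: {exc}") from exc
        return cls(frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, TDSPanel) and self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, fmt: str = "csv") -> CountTable:
    """Read a raw count table.

    ``fmt`` is ``csv``, ``tsv`` or ``rcc_dir`` (a directory of per-sample
    sectioned-CSV RCC files; see :func:`read_rcc_dir`, which also yields the
    probe annotation).
    """
    if fmt == "rcc_dir":
        table, _ = read_rcc_dir(path)
        return table
    if fmt not in ("csv", "tsv"):
        raise FormatError(f"unknown count-table format {fmt!r}")
    sep = "," if fmt == "csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2:
        raise FormatError("count table needs a probe_id column plus >=1 sample")
    frame = frame.set_index(frame.columns[0])
    frame.index.name = "probe_id"
    try:
        values = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count value: {exc}") from exc
    return CountTable(values, stage="raw")


def write_count_table(table: CountTable, path: str | Path, fmt: str = "csv") -> None:
    sep = "," if fmt == "csv" else "\t"
    out = table.counts.copy()
    if table.stage == "raw":
        out = out.astype(int)
    out.index.name = "probe_id"
    out.to_csv(path, sep=sep)


def read_normalized_table(path: str | Path, stage: str = "background_subtracted") -> CountTable:
    """Read a normalized (real-valued) count table written by the pipeline."""
    frame = pd.read_csv(path).set_index("probe_id")
    return CountTable(frame.astype(float), stage=stage)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path))


def write_annotation(annot: ProbeAnnotation, path: str | Path) -> None:
    annot.frame.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype=str, keep_default_na=False))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


def read_panel(path: str | Path) -> TDSPanel:
    with open(path) as handle:
        try:
            payload = json.load(handle)
        except json.JSONDecodeError as exc:
            raise FormatError(f"panel file is not valid JSON: {exc}") from exc
    return TDSPanel.from_dict(payload)


def write_panel(panel: TDSPanel, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(panel.to_dict(), handle, indent=1)
        handle.write("\n")


def check_panel_against_annotation(panel: TDSPanel, annot: ProbeAnnotation) -> None:
    """Every panel gene must be a tds-class probe in the annotation."""
    tds_genes = set(
        annot.frame.loc[annot.frame["probe_class"] == "tds", "gene"]
    )
    missing = [g for g in panel.genes if g not in tds_genes]
    if missing:
        raise CrossReferenceError(
            f"panel genes absent from annotation tds probes: {missing}"
        )


# ---------------------------------------------------------------------------
# RCC dialect


def _parse_rcc_sections(text: str, path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        open_m = re.fullmatch(r"<([A-Za-z_]+)>", line)
        close_m = re.fullmatch(r"</([A-Za-z_]+)>", line)
        if open_m:
            current = open_m.group(1)
            sections[current] = []
        elif close_m:
            current = None
        elif current is not None:
            sections[current].append(line)
    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: no Code_Summary section")
    return sections


def _parse_code_summary(lines: list[str], path: Path) -> pd.DataFrame:
    header = [c.strip() for c in lines[0].split(",")]
    required = ("CodeClass", "Name", "Accession", "Count")
    if any(col not in header for col in required):
        raise FormatError(f"{path}: Code_Summary must have columns {required}")
    rows = []
    for line in lines[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != len(header):
            raise FormatError(f"{path}: ragged Code_Summary row: {line!r}")
        rows.append(dict(zip(header, parts)))
    frame = pd.DataFrame(rows)
    try:
        frame["Count"] = frame["Count"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer count: {exc}") from exc
    if (frame["Count"] < 0).any():
        raise IntegrityError(f"{path}: negative count in Code_Summary")
    return frame


def read_rcc_dir(path: str | Path) -> tuple[CountTable, ProbeAnnotation]:
    """Read a directory of per-sample RCC files into one raw count table.

    CodeClass values Endogenous / Housekeeping / Positive / Negative map to
    probe classes tds / housekeeper / positive_control / negative_control.
    Positive-control expected concentration is parsed from the trailing
    parenthetical of the probe name (``POS_A(128)`` -> 128 fM); its absence
    is a format error. All files must share one probe set.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".rcc")
    if not files:
        raise FormatError(f"no .rcc files in {path}")
    columns: dict[str, pd.Series] = {}
    annot_frame: pd.DataFrame | None = None
    for file in files:
        sections = _parse_rcc_sections(file.read_text(), file)
        summary = _parse_code_summary(sections["Code_Summary"], file)
        sample_id = file.stem
        for line in sections.get("Sample_Attributes", []):
            key, _, value = line.partition(",")
            if key == "ID" and value:
                sample_id = value
        probe_ids, classes, genes, concs = [], [], [], []
        for _, row in summary.iterrows():
            if row["CodeClass"] not in _RCC_CLASS_MAP:
                raise FormatError(
                    f"{file}: unknown CodeClass {row['CodeClass']!r}"
                )
            cls = _RCC_CLASS_MAP[row["CodeClass"]]
            name = row["Name"]
            conc = np.nan
            match = _CONC_RE.match(name)
            if cls == "positive_control":
                if not match:
                    raise FormatError(
                        f"{file}: positive control {name!r} lacks (conc) suffix"
                    )
                name, conc = match.group("name"), float(match.group("conc"))
            elif match:
                name = match.group("name")  # e.g. NEG_A(0); value discarded
            probe_ids.append(name)
            classes.append(cls)
            genes.append(name)
            concs.append(conc)
        this_annot = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene": genes,
                "probe_class": classes,
                "expected_conc": concs,
            }
        )
        if annot_frame is None:
            annot_frame = this_annot
        elif not annot_frame.equals(this_annot):
            raise IntegrityError(f"{file}: probe set differs from other RCC files")
        if sample_id in columns:
            raise IntegrityError(f"duplicate sample id {sample_id!r} in RCC dir")
        columns[sample_id] = pd.Series(
            summary["Count"].to_numpy(), index=probe_ids, name=sample_id
        )
    counts = pd.DataFrame(columns)
    counts.index.name = "probe_id"
    return CountTable(counts, stage="raw"), ProbeAnnotation(annot_frame)
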