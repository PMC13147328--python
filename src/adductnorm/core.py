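"""Domain types, table I/O and validation shared by every pipeline stage.

The central object is :class:`FeatureTable`: a features x runs matrix of
LC-MS peak areas together with per-run metadata (injection order, run type,
batch, DNA concentration) and per-feature annotations (m/z, retention time).
Missing peak areas are held as NaN in memory and written as empty cells on
disk; zero is a valid measured intensity and is never treated as missing.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RunType",
    "RunMetadata",
    "FeatureTable",
    "NormalizationResult",
    "QcMetrics",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "subset_runs",
    "QC_RUN_TYPES",
]


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


class RunType(str, enum.Enum):
    """Role of an injection within the run sequence.

    ``iqc``/``eqc`` are pooled quality-control injections placed inside /
    bracketing the sequence; ``tech_replicate`` is the second vial of each
    internal-QC pair, injected purely to estimate technical variance.
    """

    SAMPLE = "sample"
    IQC = "iqc"
    EQC = "eqc"
    TECH_REPLICATE = "tech_replicate"

    @classmethod
    def coerce(cls, value: "RunType | str") -> "RunType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError as exc:
            raise ValidationError(
                f"unknown run_type {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from exc


#: Run types considered quality-control injections.
QC_RUN_TYPES = frozenset({RunType.IQC, RunType.EQC, RunType.TECH_REPLICATE})


@dataclass(frozen=True)
class RunMetadata:
    """A single injection: identity, order, role, batch and DNA amount."""

    run_id: str
    injection_index: int
    run_type: RunType
    batch: str = "B1"
    dna_concentration: float | None = None  # ng/uL, samples only

    def __post_init__(self) -> None:
        object.__setattr__(self, "run_type", RunType.coerce(self.run_type))
        if self.injection_index < 1 or int(self.injection_index) != self.injection_index:
            raise ValidationError(
                f"run {self.run_id!r}: injection_index must be a positive "
                f"integer, got {self.injection_index!r}"
            )
        if self.dna_concentration is not None and not self.dna_concentration > 0:
            raise ValidationError(
                f"run {self.run_id!r}: dna_concentration must be > 0 or absent, "
                f"got {self.dna_concentration!r}"
            )


@dataclass
class FeatureTable:
    """Features x runs peak-area matrix with run and feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by ``feature_id`` with one column per ``run_id``,
        in injection order. NaN encodes a missing (undetected) peak area.
    feature_meta
        DataFrame indexed by ``feature_id`` with columns ``mz`` (Da) and
        ``rt`` (seconds).
    runs
        Per-column :class:`RunMetadata`, same order as ``values.columns``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    runs: list[RunMetadata]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        run_ids = [r.run_id for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            raise ValidationError("duplicate run_id in run metadata")
        if list(self.values.columns) != run_ids:
            raise ValidationError(
                "values column order does not match run metadata order"
            )
        idx = [r.injection_index for r in self.runs]
        if len(set(idx)) != len(idx):
            raise ValidationError("duplicated injection_index in run metadata")
        if idx != sorted(idx):
            raise ValidationError(
                "runs are not in injection order; re-sort before constructing"
            )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature_id: {dupes}")
        if not self.feature_meta.index.equals(self.values.index):
            raise ValidationError("feature_meta index does not match values index")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("negative peak area encountered")
        if "mz" in self.feature_meta.columns and (self.feature_meta["mz"] <= 0).any():
            raise ValidationError("feature m/z must be > 0")
        if "rt" in self.feature_meta.columns and (self.feature_meta["rt"] < 0).any():
            raise ValidationError("feature rt must be >= 0")

    # -- convenience accessors ------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    @property
    def run_types(self) -> np.ndarray:
        return np.array([r.run_type for r in self.runs], dtype=object)

    @property
    def injection_indices(self) -> np.ndarray:
        return np.array([r.injection_index for r in self.runs], dtype=float)

    @property
    def batches(self) -> np.ndarray:
        return np.array([r.batch for r in self.runs], dtype=object)

    def run_mask(self, run_types: Iterable[RunType | str]) -> np.ndarray:
        wanted = {RunType.coerce(t) for t in run_types}
        return np.array([r.run_type in wanted for r in self.runs], dtype=bool)

    def with_values(self, values: pd.DataFrame) -> "FeatureTable":
        """Return a copy sharing metadata with new (aligned) values."""
        return FeatureTable(
            values=values,
            feature_meta=self.feature_meta.loc[values.index].copy(),
            runs=list(self.runs),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            feature_meta=self.feature_meta.copy(),
            runs=list(self.runs),
        )


@dataclass
class NormalizationResult:
    """A corrected table plus the factor surface that produced it.

    ``corrected = raw / factor * rescale`` cell-wise, where ``factor`` is a
    per-run vector (sample-based methods) or a per-feature-per-run matrix
    (feature-based methods), and ``rescale`` is the median of the factors
    (per feature for feature-based methods) applied to keep corrected data
    on the original intensity scale.
    """

    table: FeatureTable
    factors: pd.Series | pd.DataFrame
    method: str
    rescale_constant: float | pd.Series

    def reconstruct_raw(self) -> pd.DataFrame:
        """Invert the correction: corrected * factor / rescale = raw."""
        corrected = self.table.values
        if isinstance(self.factors, pd.Series):  # per-run
            return corrected.mul(self.factors, axis=1) / self.rescale_constant
        raw = corrected * self.factors
        if isinstance(self.rescale_constant, pd.Series):
            return raw.div(self.rescale_constant, axis=0)
        return raw / self.rescale_constant


@dataclass
class QcMetrics:
    """Per-feature robust quality metrics with pass/retain flags.

    ``rsd_star`` is the scaled-MAD relative standard deviation of the
    technical replicates, ``d_ratio`` the MAD(replicates)/MAD(samples)
    dispersion ratio; both unitless. Flags use strict ``<`` thresholds.
    """

    frame: pd.DataFrame  # columns: rsd_star, d_ratio, rsd_pass, dratio_pass, retained
    rsd_threshold: float
    dratio_threshold: float

    def __post_init__(self) -> None:
        required = {"rsd_star", "d_ratio", "rsd_pass", "dratio_pass", "retained"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"QcMetrics frame missing columns {sorted(missing)}")
        if not (self.frame["retained"] == (self.frame["rsd_pass"] & self.frame["dratio_pass"])).all():
            raise ValidationError("retained flag must equal rsd_pass AND dratio_pass")

    @property
    def retained_ids(self) -> pd.Index:
        return self.frame.index[self.frame["retained"]]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NA_TOKENS = {"", "na", "nan", "n/a"}


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype={0: str})


def read_feature_table(
    values_path: str | Path,
    run_meta_path: str | Path,
    feature_meta_path: str | Path,
) -> FeatureTable:
    """Read a feature table from its three CSV/TSV files.

    The values file has ``feature_id`` in the first column and one column
    per run. Missing areas may be empty cells or NA tokens. Runs are
    re-sorted into injection order if the file order differs.
    """
    values = _read_csv(values_path)
    values = values.set_index(values.columns[0])
    values.index = values.index.astype(str)
    values.index.name = "feature_id"
    values = values.apply(pd.to_numeric, errors="coerce")

    run_df = _read_csv(run_meta_path)
    if "run_id" not in run_df.columns or "injection_index" not in run_df.columns:
        raise ValidationError("run metadata needs run_id and injection_index columns")
    runs = []
    for rec in run_df.to_dict("records"):
        conc = rec.get("dna_concentration")
        if conc is not None and (pd.isna(conc) or str(conc).strip().lower() in _NA_TOKENS):
            conc = None
        runs.append(
            RunMetadata(
                run_id=str(rec["run_id"]),
                injection_index=int(rec["injection_index"]),
                run_type=RunType.coerce(rec.get("run_type", "sample")),
                batch=str(rec.get("batch", "B1")),
                dna_concentration=None if conc is None else float(conc),
            )
        )
    order = np.argsort([r.injection_index for r in runs], kind="stable")
    if not np.array_equal(order, np.arange(len(runs))):
        logger.info("run metadata not in injection order; re-sorting")
        runs = [runs[i] for i in order]

    missing_runs = [r.run_id for r in runs if r.run_id not in values.columns]
    if missing_runs:
        raise ValidationError(f"runs in metadata absent from values: {missing_runs}")
    extra = set(values.columns) - {r.run_id for r in runs}
    if extra:
        raise ValidationError(f"runs in values absent from metadata: {sorted(extra)}")
    values = values[[r.run_id for r in runs]]

    fmeta = _read_csv(feature_meta_path)
    fmeta = fmeta.set_index(fmeta.columns[0])
    fmeta.index = fmeta.index.astype(str)
    fmeta.index.name = "feature_id"
    if not fmeta.index.equals(values.index):
        try:
            fmeta = fmeta.loc[values.index]
        except KeyError as exc:
            raise ValidationError("feature metadata does not cover all features") from exc
    return FeatureTable(values=values, feature_meta=fmeta, runs=runs)


def write_feature_table(table: FeatureTable, out_prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write values / run metadata / feature metadata CSVs.

    Returns the three written paths; ``read_feature_table`` on them
    reproduces the table (values within floating tolerance).
    """
    if table.n_features == 0:
        raise ValidationError("refusing to write a table with no features")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    values_path = prefix.with_name(prefix.name + "_values.csv")
    run_path = prefix.with_name(prefix.name + "_runs.csv")
    feat_path = prefix.with_name(prefix.name + "_features.csv")

    table.values.to_csv(values_path, na_rep="")
    run_records = [
        {
            "run_id": r.run_id,
            "injection_index": r.injection_index,
            "run_type": r.run_type.value,
            "batch": r.batch,
            "dna_concentration": "" if r.dna_concentration is None else r.dna_concentration,
        }
        for r in table.runs
    ]
    pd.DataFrame(run_records).to_csv(run_path, index=False)
    table.feature_meta.to_csv(feat_path)
    return values_path, run_path, feat_path


def subset_runs(table: FeatureTable, run_type_set: Iterable[RunType | str]) -> FeatureTable:
    """Restrict the table's columns to runs of the given types, order kept."""
    wanted = {RunType.coerce(t) for t in run_type_set}
    if not wanted:
        raise ValidationError("run_type_set must be non-empty")
    keep = [r for r in table.runs if r.run_type in wanted]
    if not keep:
        raise ValidationError(
            f"no runs of type {sorted(t.value for t in wanted)} in table"
        )
    cols = [r.run_id for r in keep]
    return FeatureTable(
        values=table.values[cols].copy(),
        feature_meta=table.feature_meta.copy(),
        runs=keep,
    )
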