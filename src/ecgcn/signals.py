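"""Cohort manifests, ROI time-series I/O, and ROI-level signal preprocessing.

The pipeline operates on one mean time series per cortical region of
interest (ROI).  A subject is a ``T x R`` matrix: ``T`` time points sampled
every ``tr_seconds`` and ``R`` ROIs.  Voxel-level preprocessing (slice
timing, motion correction, spatial normalisation, parcellation) is assumed
to have happened upstream; this module starts from the parcellated series
and offers the standard ROI-level steps: nuisance regression, zero-phase
band-pass filtering, and per-column standardisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .exceptions import FormatError, SchemaError, ValidationError

MANIFEST_COLUMNS = ("subject_id", "label", "age", "gender", "series_path")
VALID_LABELS = ("MDD", "HC")
VALID_GENDERS = ("F", "M")


@dataclass
class RoiTimeSeries:
    """One subject's ``T x R`` matrix of mean ROI signals.

    Parameters
    ----------
    subject_id
        Cohort-unique subject identifier.
    data
        ``T x R`` float array; rows are time points, columns are ROIs.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    roi_names
        Optional list of ``R`` ROI names.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be a 2-D matrix")
        t, r = self.data.shape
        if t < 2:
            raise ValidationError(f"need at least 2 time points, got T={t}")
        if r < 2:
            raise ValidationError(f"need at least 2 ROIs, got R={r}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("time-series data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.roi_names is not None and len(self.roi_names) != r:
            raise ValidationError("roi_names length must equal number of ROIs")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class CohortManifest:
    """Cohort roster: one row per subject with label, phenotypes and file path."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"manifest is missing required columns: {missing}")
        dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
        if dupes:
            raise ValidationError(f"duplicate subject_id values: {sorted(set(dupes))}")
        bad_labels = sorted(set(df["label"]) - set(VALID_LABELS))
        if bad_labels:
            raise ValidationError(
                f"unknown labels {bad_labels}; expected one of {list(VALID_LABELS)}"
            )
        bad_genders = sorted(set(df["gender"]) - set(VALID_GENDERS))
        if bad_genders:
            raise ValidationError(
                f"unknown genders {bad_genders}; expected one of {list(VALID_GENDERS)}"
            )
        if (df["age"] <= 0).any():
            raise ValidationError("ages must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def labels(self) -> np.ndarray:
        """Binary label vector: 1 for MDD (positive class), 0 for HC."""
        return (self.table["label"] == "MDD").to_numpy(dtype=int)

    def class_counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV.

    The file must have a header row with at least the columns
    ``subject_id,label,age,gender,series_path``.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "label": str, "gender": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} is missing required columns: {missing}")
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(int)
    return CohortManifest(df[list(MANIFEST_COLUMNS)].reset_index(drop=True))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, index=False)


def _sniff_delimiter(line: str) -> str:
    return "," if line.count(",") >= line.count("\t") and "," in line else "\t"


def read_timeseries(
    path: str | Path,
    tr_seconds: float,
    subject_id: str | None = None,
    header: bool = False,
) -> RoiTimeSeries:
    """Read a delimited numeric text file as a ``T x R`` ROI time-series.

    Rows are time points, columns are ROIs.  Tab- and comma-delimited files
    are both accepted; set ``header=True`` to skip one header row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if header:
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows: list[list[float]] = []
    width = None
    for i, ln in enumerate(lines):
        cells = [c for c in ln.split(delim)]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(
                f"{path}: ragged row {i + 1} has {len(cells)} cells, expected {width}"
            )
        parsed = []
        for j, cell in enumerate(cells):
            try:
                val = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: {cell!r}"
                ) from None
            if not np.isfinite(val):
                raise FormatError(
                    f"{path}: non-finite value at row {i + 1}, column {j + 1}"
                )
            parsed.append(val)
        rows.append(parsed)
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < 2:
        raise ValidationError(f"{path}: need at least 2 ROI columns, got {data.shape[1]}")
    return RoiTimeSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        data=data,
        tr_seconds=tr_seconds,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.10g")


def read_atlas(path: str | Path) -> pd.DataFrame:
    """Read a ROI atlas label table (TSV: index, roi_name, hemisphere, network_id)."""
    df = pd.read_csv(path, sep="\t")
    required = ["index", "roi_name", "hemisphere", "network_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"atlas table is missing columns: {missing}")
    return df


def load_cohort_series(
    manifest: CohortManifest,
    tr_seconds: float,
    root: str | Path | None = None,
    header: bool = False,
) -> list[RoiTimeSeries]:
    """Load every subject's series referenced in a manifest, in manifest order."""
    out = []
    for row in manifest.table.itertuples():
        p = Path(row.series_path)
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        out.append(read_timeseries(p, tr_seconds, subject_id=row.subject_id, header=header))
    return out


def regress_confounds(data: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Replace each column with its OLS residual against [confounds, intercept]."""
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if confounds.shape[0] != data.shape[0]:
        raise ValidationError(
            f"confounds have {confounds.shape[0]} rows, series has {data.shape[0]}"
        )
    design = np.column_stack([confounds, np.ones(data.shape[0])])
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def bandpass_filter(
    data: np.ndarray, low_hz: float, high_hz: float, tr_seconds: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied independently to each column."""
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 < low_hz < high_hz):
        raise ValidationError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValidationError(
            f"high cutoff {high_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    sos = sp_signal.butter(
        order, [low_hz, high_hz], btype="band", fs=1.0 / tr_seconds, output="sos"
    )
    return sp_signal.sosfiltfilt(sos, data, axis=0)


def standardize_columns(data: np.ndarray) -> np.ndarray:
    """Rescale each column to mean 0 and sample (ddof=1) standard deviation 1."""
    sd = data.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValidationError(f"cannot standardize constant columns: {zero.tolist()}")
    return (data - data.mean(axis=0)) / sd


def preprocess_series(
    ts: RoiTimeSeries,
    band: tuple[float, float] | None = (0.01, 0.1),
    confounds: np.ndarray | None = None,
    standardize: bool = True,
) -> RoiTimeSeries:
    """Apply ROI-level preprocessing: confound regression, band-pass, standardise.

    Steps run in that fixed order; each is optional.  The band-pass is a
    4th-order Butterworth applied forward-backward (zero phase) so that
    temporal structure feeding causal estimates is not phase-shifted.
    """
    data = ts.data.copy()
    if confounds is not None:
        data = regress_confounds(data, confounds)
    if band is not None:
        data = bandpass_filter(data, band[0], band[1], ts.tr_seconds)
    if standardize:
        data = standardize_columns(data)
    return RoiTimeSeries(ts.subject_id, data, ts.tr_seconds, ts.roi_names)
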