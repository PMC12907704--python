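"""Methylation matrix I/O and value-scale transforms.

Matrices are probe-major pandas DataFrames throughout: rows are CpG probes,
columns are samples, matching the tab-separated files written by array
preprocessing pipelines. Beta-values are methylation proportions in [0, 1];
M-values are their base-2 logit, preferred for differential testing because
they are approximately homoscedastic across the methylation range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cfdeconv.errors import (
    AlignmentError,
    EmptySelectionError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_BETA_OFFSET = 100.0
DEFAULT_DETECTION_P = 0.01
DEFAULT_LOGIT_EPS = 1e-6


@dataclass(frozen=True)
class IntensitySet:
    """Raw methylated/unmethylated probe intensities with detection p-values.

    All three frames must share identical probe (row) and sample (column)
    indexes; intensities must be nonnegative and detection p-values in [0, 1].
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detect_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame in (("unmeth", self.unmeth), ("detect_p", self.detect_p)):
            if not frame.index.equals(self.meth.index) or not frame.columns.equals(
                self.meth.columns
            ):
                raise AlignmentError(
                    f"'{name}' is not aligned with 'meth': indexes/columns differ"
                )
        if (self.meth.to_numpy() < 0).any() or (self.unmeth.to_numpy() < 0).any():
            raise ValidationError("intensities must be nonnegative")
        p = self.detect_p.to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("detection p-values must lie in [0, 1]")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what}: {dups[:10]}")


def validate_beta(beta: pd.DataFrame) -> None:
    """Raise unless ``beta`` is a valid beta-value matrix.

    Entries may be missing (NaN); present entries must lie in [0, 1], and
    probe/sample identifiers must be unique.
    """
    _check_unique(beta.index, "probe IDs")
    _check_unique(beta.columns, "sample IDs")
    values = beta.to_numpy(dtype=float)
    present = ~np.isnan(values)
    if ((values[present] < 0) | (values[present] > 1)).any():
        raise ValidationError("beta-values must lie in [0, 1]")


def beta_from_signals(
    signals: IntensitySet, offset: float = DEFAULT_BETA_OFFSET
) -> pd.DataFrame:
    """Compute beta-values ``M / (M + U + offset)`` from raw intensities.

    The offset (typically 100) regularizes probes where both channels are
    dim; any positive offset keeps the result strictly below 1.
    """
    if offset < 0:
        raise ValidationError(f"offset must be nonnegative, got {offset}")
    meth = signals.meth.to_numpy(dtype=float)
    unmeth = signals.unmeth.to_numpy(dtype=float)
    denom = meth + unmeth + offset
    if (denom == 0).any():
        raise ValidationError(
            "zero denominator: offset=0 with both intensities zero is undefined"
        )
    beta = pd.DataFrame(
        meth / denom, index=signals.meth.index, columns=signals.meth.columns
    )
    return beta


def detection_filter(
    beta: pd.DataFrame,
    detect_p: pd.DataFrame,
    threshold: float = DEFAULT_DETECTION_P,
) -> pd.DataFrame:
    """Drop probes whose detection p-value is >= ``threshold`` in ANY sample.

    A high detection p-value means the probe signal is indistinguishable from
    background in that sample, so the probe is unreliable array-wide. The
    comparison is inclusive: a probe with p exactly at the threshold is
    dropped. Surviving probes keep their order and values.
    """
    if not detect_p.index.equals(beta.index) or not detect_p.columns.equals(
        beta.columns
    ):
        raise AlignmentError("detect_p is not aligned with the beta matrix")
    keep = (detect_p.to_numpy() < threshold).all(axis=1)
    if not keep.any():
        raise EmptySelectionError(
            f"no probes survive the detection filter at threshold {threshold}"
        )
    return beta.loc[keep]


def drop_incomplete_probes(matrices: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Restrict all matrices to probes complete (no missing value) in every one.

    The surviving probe set is the intersection across matrices of probes with
    no NaN in any sample; all outputs share the same probe order (the order of
    the first matrix).
    """
    if not matrices:
        raise ValidationError("at least one matrix is required")
    complete_sets = [m.index[m.notna().all(axis=1)] for m in matrices]
    keep = complete_sets[0]
    for probes in complete_sets[1:]:
        keep = keep.intersection(probes, sort=False)
    if len(keep) == 0:
        raise EmptySelectionError("no probe is complete in every matrix")
    # preserve first matrix's probe order
    keep = complete_sets[0][complete_sets[0].isin(keep)]
    return [m.loc[keep] for m in matrices]


def beta_to_m(beta: pd.DataFrame, eps: float = DEFAULT_LOGIT_EPS) -> pd.DataFrame:
    """Base-2 logit transform: ``M = log2(beta / (1 - beta))``.

    Beta-values are clipped to [eps, 1-eps] first so boundary values map to
    finite M-values.
    """
    if not 0 < eps < 0.5:
        raise ValidationError(f"eps must lie in (0, 0.5), got {eps}")
    validate_beta(beta)
    clipped = np.clip(beta.to_numpy(dtype=float), eps, 1 - eps)
    return pd.DataFrame(
        np.log2(clipped / (1 - clipped)), index=beta.index, columns=beta.columns
    )


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m`: ``beta = 2**M / (1 + 2**M)``."""
    values = m.to_numpy(dtype=float)
    # expit formulation avoids overflow for large |M|
    from scipy.special import expit

    return pd.DataFrame(
        expit(values * np.log(2)), index=m.index, columns=m.columns
    )


def read_matrix(path: str | Path, validate: bool = False) -> pd.DataFrame:
    """Read a tab-separated probe-by-sample matrix.

    First column holds probe IDs, the header row sample IDs. ``NA`` and empty
    cells become missing values. Duplicate probe IDs and ragged rows are
    rejected with informative errors.
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline()
        if not header:
            raise ParseError(f"{path}: empty file")
        n_fields = len(header.rstrip("\n").split("\t"))
        for lineno, line in enumerate(handle, start=2):
            row_fields = len(line.rstrip("\n").split("\t"))
            if row_fields != n_fields:
                raise ParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({row_fields} fields, expected {n_fields})"
                )
    frame = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=["NA", ""],
        keep_default_na=False,
    )
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix entry ({exc})") from exc
    frame.index = frame.index.astype(str)
    _check_unique(frame.index, f"probe IDs in {path}")
    _check_unique(frame.columns, f"sample IDs in {path}")
    if validate:
        validate_beta(frame)
    return frame


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a probe-by-sample matrix as tab-separated text (missing -> NA)."""
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


METADATA_COLUMNS = ["sample_id", "patient_id", "phenotype", "timepoint"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (sample_id, patient_id, phenotype, timepoint)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_id: {dups[:10]}")
    meta["timepoint"] = pd.to_numeric(meta["timepoint"])
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)
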