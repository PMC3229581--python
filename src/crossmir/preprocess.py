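"""Ct-matrix ingestion, detection filtering, mean-centering and NRQ.

qPCR arrays report a cycle threshold (Ct) per miRNA per sample; lower Ct
means higher abundance and one cycle is a two-fold change.  The
preprocessing chain implemented here is:

1. detection threshold — Ct strictly greater than 35 (the single-molecule
   limit) is treated as not expressed; Ct = 35.0 itself remains detected;
2. detection filter — keep miRNAs detected in at least ``min_samples``
   samples (default 10);
3. global-mean centering — subtract each sample's mean Ct (computed over
   detected entries only) from all of that sample's Cts, removing global
   loading/efficiency shifts;
4. NRQ — per miRNA, the normalized relative quantity
   ``NRQ = 2**(Ctmax - Ct)`` where Ctmax is that miRNA's maximum centered
   Ct across samples, so every NRQ >= 1 and each miRNA's minimum is exactly 1.

Undetected entries that survive the filter are, by default, imputed at the
detection limit (Ct = 35) before centering — a conservative
limit-of-detection floor that keeps two-group tests defined for miRNAs
detected in only a subset of samples.  The imputed mask is carried through.
The stage order threshold → filter → center → NRQ is enforced by
:func:`preprocess` and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "NormalizedMatrix",
    "read_ct_matrix",
    "write_ct_matrix",
    "apply_detection_threshold",
    "filter_by_detection",
    "mean_center",
    "compute_nrq",
    "preprocess",
    "DETECTION_LIMIT",
]

logger = logging.getLogger(__name__)

DETECTION_LIMIT = 35.0
UNDETERMINED = "Undetermined"


@dataclass
class CtMatrix:
    """Raw cycle-threshold values (miRNA rows x sample columns) with metadata.

    ``values`` holds Ct in cycles (NaN where the instrument reported
    ``Undetermined``); ``detected`` is a same-shape boolean mask; ``samples``
    is a metadata frame indexed by sample id (species, tissue_class,
    genotype, study ... whatever the sidecar provides).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate miRNA identifiers in Ct matrix")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample identifiers in Ct matrix")
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detected masks differ in shape")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        with np.errstate(invalid="ignore"):
            bad = self.detected.to_numpy() & ~np.isfinite(self.values.to_numpy())
        if bad.any():
            raise ValueError("non-finite Ct value flagged as detected")

    @property
    def mirnas(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class NormalizedMatrix:
    """Mean-centered Ct and NRQ on a shared miRNA x sample index.

    ``centered_ct`` is Ct with the per-sample detected-mean removed (cycles);
    ``ctmax`` is the per-miRNA maximum centered Ct (cycles); ``nrq`` is
    ``2**(ctmax - centered_ct)`` (dimensionless, >= 1, per-miRNA minimum 1).
    ``imputed`` flags entries filled at the detection limit before centering.
    """

    centered_ct: pd.DataFrame
    samples: pd.DataFrame
    imputed: pd.DataFrame
    nrq: pd.DataFrame | None = None
    ctmax: pd.Series | None = None

    @property
    def mirnas(self) -> pd.Index:
        return self.centered_ct.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.centered_ct.columns


def read_ct_matrix(
    path: str | Path,
    metadata_path: str | Path,
    *,
    sep: str = "\t",
) -> CtMatrix:
    """Read a delimited Ct matrix plus its sample-metadata sidecar.

    The matrix file has a header row of sample ids and a first column of
    miRNA names; cells are numeric, empty, or the literal ``Undetermined``
    (the latter two become not-detected).  The metadata file must key every
    sample id in the matrix.

    Raises
    ------
    ValueError
        For a non-numeric cell other than the sentinel (naming row and
        column) or a sample absent from the metadata.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    detected = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        for row, cell in raw[col].items():
            cell = cell.strip()
            if cell == "" or cell == UNDETERMINED:
                continue
            try:
                values.loc[row, col] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric Ct cell {cell!r} at miRNA {row!r}, sample {col!r}"
                ) from exc
            detected.loc[row, col] = True

    meta = pd.read_csv(metadata_path, sep=sep, index_col=0, dtype=str)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata file: {missing}")
    return CtMatrix(values=values, detected=detected, samples=meta.loc[values.columns])


def write_ct_matrix(
    m: CtMatrix,
    path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    sep: str = "\t",
) -> None:
    """Write a Ct matrix (and optionally its metadata) as delimited text.

    Undetected entries are written as ``Undetermined``; detected values use
    Python's shortest round-tripping float representation so that
    write → read reproduces the matrix bit-exactly.
    """
    vals = m.values.to_numpy()
    det = m.detected.to_numpy()
    cells = np.where(det, np.vectorize(lambda v: repr(float(v)))(np.nan_to_num(vals)), UNDETERMINED)
    out = pd.DataFrame(cells, index=m.values.index, columns=m.values.columns)
    # repr() of detected Cts round-trips bit-exactly; undetected cells carry the sentinel
    out.to_csv(path, sep=sep)
    if metadata_path is not None:
        m.samples.to_csv(metadata_path, sep=sep)


def apply_detection_threshold(m: CtMatrix, threshold: float = DETECTION_LIMIT) -> CtMatrix:
    """Mark Ct values strictly greater than ``threshold`` as not expressed.

    The boundary value (Ct = threshold exactly) remains detected.  Ct values
    are preserved; only the mask changes.
    """
    with np.errstate(invalid="ignore"):
        over = m.values > threshold
    return replace(m, detected=m.detected & ~over)


def filter_by_detection(m: CtMatrix, min_samples: int = 10) -> CtMatrix:
    """Keep miRNAs detected in at least ``min_samples`` samples (row order kept)."""
    n_samples = m.values.shape[1]
    if min_samples > n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of samples ({n_samples})"
        )
    keep = m.detected.sum(axis=1) >= min_samples
    return replace(m, values=m.values.loc[keep], detected=m.detected.loc[keep])


def mean_center(
    m: CtMatrix,
    *,
    undetected: Literal["impute", "drop"] = "impute",
    detection_limit: float = DETECTION_LIMIT,
) -> NormalizedMatrix:
    """Subtract each sample's mean detected Ct from all of its Ct values.

    The sample mean is computed over detected entries only — censored
    values would bias the global mean upward.  Undetected entries are
    either imputed at the detection limit before centering (default,
    flagged in ``imputed``) or left missing (``undetected="drop"``).

    Raises
    ------
    ValueError
        If any sample has zero detected entries.
    """
    det = m.detected
    n_det = det.sum(axis=0)
    empty = n_det[n_det == 0]
    if len(empty):
        raise ValueError(f"samples with zero detected entries: {list(empty.index)}")
    sample_mean = m.values.where(det).mean(axis=0)
    if undetected == "impute":
        work = m.values.where(det, detection_limit)
    else:
        work = m.values.where(det)
    centered = work.sub(sample_mean, axis=1)
    return NormalizedMatrix(
        centered_ct=centered,
        samples=m.samples,
        imputed=~det,
    )


def compute_nrq(n: NormalizedMatrix) -> NormalizedMatrix:
    """Derive NRQ = 2**(Ctmax - Ct) from the centered matrix.

    Ctmax is each miRNA's maximum centered Ct across all samples in the
    analysis set, so the lowest-expressing sample gets NRQ exactly 1 and
    every NRQ is >= 1.
    """
    ctmax = n.centered_ct.max(axis=1)
    nrq = np.power(2.0, n.centered_ct.rsub(ctmax, axis=0))
    return replace(n, nrq=nrq, ctmax=ctmax)


def preprocess(
    m: CtMatrix,
    *,
    threshold: float = DETECTION_LIMIT,
    min_samples: int = 10,
    undetected: Literal["impute", "drop"] = "impute",
) -> NormalizedMatrix:
    """Run the full ordered chain: threshold → filter → center → NRQ."""
    logger.info("detection threshold: Ct > %g set to not expressed", threshold)
    m = apply_detection_threshold(m, threshold)
    logger.info("detection filter: keeping miRNAs detected in >= %d samples", min_samples)
    m = filter_by_detection(m, min_samples)
    logger.info("retained %d miRNAs x %d samples", *m.values.shape)
    n = mean_center(m, undetected=undetected, detection_limit=threshold)
    return compute_nrq(n)
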