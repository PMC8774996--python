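"""Covariance-determinant (Cov–Det) reduction and statistical descriptors.

The reduction treats the ``m × k`` sub-segment matrix of a segment as *m*
variables observed over *k* time points, forms the sample covariance matrix

    H[i, j] = (1 / (k - 1)) * sum_t (row_i[t] - mean_i) (row_j[t] - mean_j),

and summarises it through its eigendecomposition ``H = V Λ Vᵀ``: since the
determinant of the orthonormal eigenvector factors cancels, ``|H|`` equals
the product of the eigenvalues.  Ten statistical descriptors (mean, maximum,
minimum, mode, median, range, variance, standard deviation, skewness,
kurtosis) are then computed per covariance-matrix row, giving an ``m × 10``
feature grid per segment — with the defaults, 1024 raw samples shrink to
320 features and a 4097-sample channel (four segments) to 1280.

Descriptor conventions: variance uses the n−1 divisor (matching the
covariance); skewness and kurtosis are the standardised third and fourth
central moments (kurtosis is *not* excess — a Gaussian scores 3); both are
defined as 0 for constant input so downstream screening never sees
non-finite values; the mode of continuous data is taken after
Freedman–Diaconis binning (see :func:`stat_descriptors`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .io import RawChannel
from .segmentation import (DEFAULT_M_SUBSEGMENTS, DEFAULT_N_SEGMENTS, Segment,
                           SegmentMatrix, segment_channel, to_subsegment_matrix)

logger = logging.getLogger("covdet")

#: Ordered descriptor names; the flattening of the feature grid is
#: descriptor-major (all m means first, then all m maxima, ...).
DESCRIPTOR_NAMES = ("mean", "maximum", "minimum", "mode", "median", "range",
                    "variance", "standard_deviation", "skewness", "kurtosis")

#: Non-descriptor columns of a feature table.
META_COLUMNS = ("det", "label", "channel_id", "subject_id", "segment_index")

#: Eigenvalues in [-PSD_TOL, 0) are treated as numerical noise and clipped.
PSD_TOL = 1e-10


@dataclass
class CovarianceMatrix:
    """Sample covariance of a sub-segment matrix (rows = variables)."""

    H: np.ndarray
    mean_vector: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)

    @property
    def size(self) -> int:
        return self.H.shape[0]


@dataclass
class EigenDecomposition:
    """Eigenvalues (descending) and matching orthonormal eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class StatDescriptorSet:
    """The ten named descriptors of one real sequence."""

    mean: float
    maximum: float
    minimum: float
    mode: float
    median: float
    range: float
    variance: float
    standard_deviation: float
    skewness: float
    kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_NAMES])


@dataclass
class FeatureRecord:
    """Flattened descriptor grid of one segment plus the Cov–Det scalar."""

    values: np.ndarray
    names: list[str]
    det: float
    label: str = ""
    channel_id: str = ""
    subject_id: str = ""
    segment_index: int = 0


def covariance_matrix(M: SegmentMatrix) -> CovarianceMatrix:
    """Sample covariance of *M*'s rows over the time (column) axis."""
    if M.m < 2:
        raise InvalidArgumentError("need at least 2 rows (variables)")
    if M.k < 2:
        raise InvalidArgumentError("need at least 2 observations per row")
    H = np.cov(M.rows, rowvar=True, ddof=1)
    return CovarianceMatrix(H=np.atleast_2d(H), mean_vector=M.rows.mean(axis=1))


def eigen_determinant(C: CovarianceMatrix) -> tuple[EigenDecomposition, float]:
    """Eigendecomposition of a symmetric matrix and its eigenvalue-product
    determinant.

    Eigenvalues in ``[-1e-10, 0)`` are clipped to 0 (numerical PSD repair,
    logged); the determinant is their product, which matches a direct LU
    determinant on well-conditioned input.
    """
    H = C.H
    if not np.all(np.isfinite(H)):
        raise InvalidArgumentError("covariance matrix has non-finite entries")
    if not np.allclose(H, H.T, rtol=1e-8, atol=1e-10):
        raise InvalidArgumentError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh(H)
    clip = (vals < 0) & (vals >= -PSD_TOL)
    if clip.any():
        logger.debug("clipped %d eigenvalue(s) in [-%g, 0) to 0", clip.sum(), PSD_TOL)
        vals = np.where(clip, 0.0, vals)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    det = float(np.prod(vals))
    return EigenDecomposition(eigenvalues=vals, eigenvectors=vecs), det


def _mode(x: np.ndarray, binning: str = "fd-value") -> float:
    """Mode of a real sequence.

    ``"fd-value"`` (default): Freedman–Diaconis histogram, fullest bin
    (ties → leftmost), mode = the smallest most-frequent sample value in
    that bin.  ``"fd-midpoint"``: midpoint of the fullest bin.
    ``"exact"``: most frequent exact value, ties → smallest.
    """
    if np.ptp(x) == 0:
        return float(x[0])
    if binning == "exact":
        vals, counts = np.unique(x, return_counts=True)
        return float(vals[np.argmax(counts)])
    if binning not in ("fd-value", "fd-midpoint"):
        raise InvalidArgumentError(f"unknown mode binning {binning!r}")
    edges = np.histogram_bin_edges(x, bins="fd")
    counts, edges = np.histogram(x, bins=edges)
    i = int(np.argmax(counts))  # argmax keeps the leftmost of tied bins
    if binning == "fd-midpoint":
        return float(0.5 * (edges[i] + edges[i + 1]))
    hi_edge = edges[i + 1]
    in_bin = (x >= edges[i]) & ((x <= hi_edge) if i == len(counts) - 1 else (x < hi_edge))
    vals, cnts = np.unique(x[in_bin], return_counts=True)
    return float(vals[np.argmax(cnts)])


def stat_descriptors(x, mode_binning: str = "fd-value") -> StatDescriptorSet:
    """Compute the ten descriptors of a finite real sequence (length ≥ 2)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InvalidArgumentError("x must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("x must be finite")
    if x.size < 2:
        raise InvalidArgumentError("variance undefined for n < 2")
    mn, mx = float(np.min(x)), float(np.max(x))
    var = float(np.var(x, ddof=1))
    d = x - x.mean()
    m2 = float(np.mean(d ** 2))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(d ** 3) / m2 ** 1.5)
        kurt = float(np.mean(d ** 4) / m2 ** 2)
    return StatDescriptorSet(
        mean=float(np.mean(x)),
        maximum=mx,
        minimum=mn,
        mode=_mode(x, mode_binning),
        median=float(np.median(x)),
        range=mx - mn,
        variance=var,
        standard_deviation=float(np.sqrt(var)),
        skewness=skew,
        kurtosis=kurt,
    )


def feature_names(m: int = DEFAULT_M_SUBSEGMENTS, append_det: bool = False) -> list[str]:
    """Descriptor-major column names of the flattened ``m × 10`` grid."""
    names = [f"{desc}_r{i:02d}" for desc in DESCRIPTOR_NAMES for i in range(m)]
    if append_det:
        names.append("det")
    return names


def segment_feature_record(seg: Segment, m: int = DEFAULT_M_SUBSEGMENTS, *,
                           feature_source: str = "cov_rows",
                           append_det: bool = False,
                           mode_binning: str = "fd-value",
                           overlap: int = 0,
                           label: str = "", channel_id: str = "",
                           subject_id: str = "") -> FeatureRecord:
    """Full Cov–Det reduction of one segment to an ``m × 10`` feature vector.

    ``feature_source`` picks the rows the descriptors summarise:
    ``"cov_rows"`` (default) uses the rows of the covariance matrix,
    ``"raw_rows"`` the raw sub-segment rows.  Either way the output length
    is ``m × 10`` (+1 if ``append_det``).
    """
    M = to_subsegment_matrix(seg, m, overlap=overlap)
    C = covariance_matrix(M)
    _, det = eigen_determinant(C)
    if feature_source == "cov_rows":
        rows = C.H
    elif feature_source == "raw_rows":
        rows = M.rows
    else:
        raise InvalidArgumentError(f"unknown feature_source {feature_source!r}")
    grid = np.stack([stat_descriptors(row, mode_binning).as_array() for row in rows])
    values = grid.T.reshape(-1)  # descriptor-major
    names = feature_names(m, append_det)
    if append_det:
        values = np.append(values, det)
    return FeatureRecord(values=values, names=names, det=det, label=label,
                         channel_id=channel_id, subject_id=subject_id,
                         segment_index=seg.index)


def channel_feature_records(channel: RawChannel,
                            n_segments: int = DEFAULT_N_SEGMENTS,
                            m: int = DEFAULT_M_SUBSEGMENTS,
                            **kwargs) -> list[FeatureRecord]:
    """Feature records of every segment of one channel."""
    return [segment_feature_record(seg, m, label=channel.label,
                                   channel_id=channel.channel_id,
                                   subject_id=channel.subject_id, **kwargs)
            for seg in segment_channel(channel, n_segments)]


def extract_features(channels, n_segments: int = DEFAULT_N_SEGMENTS,
                     m: int = DEFAULT_M_SUBSEGMENTS, **kwargs) -> pd.DataFrame:
    """Feature table over many channels: one row per segment.

    Columns are the descriptor grid (:func:`feature_names`) followed by
    ``det`` and provenance columns.
    """
    rows = []
    for ch in channels:
        for rec in channel_feature_records(ch, n_segments, m, **kwargs):
            row = dict(zip(rec.names, rec.values))
            row.update(det=rec.det, label=rec.label, channel_id=rec.channel_id,
                       subject_id=rec.subject_id, segment_index=rec.segment_index)
            rows.append(row)
    if not rows:
        raise InvalidArgumentError("no channels given")
    return pd.DataFrame(rows)


def descriptor_columns(table: pd.DataFrame) -> list[str]:
    """The descriptor-grid columns of a feature table (meta columns excluded)."""
    return [c for c in table.columns
            if any(c.startswith(d + "_r") for d in DESCRIPTOR_NAMES)]


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
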