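"""Raw-signal handling and the observation-level descriptor matrix.

A recording is split into fixed-length windows; each window is summarised by
six descriptors (mean, variance, skewness, excess kurtosis, sample entropy,
permutation entropy) to form an observations x features table.  Columns are
z-scored so downstream mixture modelling sees normalised data points, and
every observation carries an *intensity* (mean absolute amplitude of its
source window) used later to down-weight faint epochs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("biosigfusion")

#: Sentinel for descriptors undefined on the given window (e.g. skewness of
#: a constant signal).  Rows containing it are dropped by
#: :func:`build_feature_matrix` with a logged reason.
UNDEFINED = float("nan")

DEFAULT_DESCRIPTORS = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "sample_entropy",
    "permutation_entropy",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SignalRecord:
    """A sampled biosignal segment.

    Parameters
    ----------
    samples : array-like of float
        The raw samples, arbitrary amplitude units.  Must be non-empty and
        finite.
    sampling_rate : float, optional
        Sampling rate in Hz; metadata only.
    channel_id : str
        Channel label.
    label : str or None
        Class label of the segment (e.g. ``"healthy"``, ``"ictal"``).
    """

    samples: np.ndarray
    sampling_rate: float | None = None
    channel_id: str = "ch0"
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class FeatureMatrix:
    """Observations x features descriptor table with normalisation metadata.

    ``values`` holds the z-scored descriptors; ``normalization`` stores the
    per-feature (location, scale) pairs estimated on the rows this matrix was
    built from, so held-out data can be normalised with *training* constants.
    """

    values: np.ndarray
    feature_names: list[str]
    intensities: np.ndarray
    labels: list[str | None]
    normalization: list[tuple[float, float]]
    raw_values: np.ndarray | None = field(default=None, repr=False)
    #: boolean mask over the input segments marking rows that survived
    #: descriptor computation (dropped rows had undefined descriptors)
    source_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Write values as CSV plus a JSON sidecar with metadata."""
        path = Path(path)
        pd.DataFrame(self.values, columns=self.feature_names).to_csv(
            path, index=False
        )
        meta = {
            "feature_names": self.feature_names,
            "normalization": [list(p) for p in self.normalization],
            "intensities": self.intensities.tolist(),
            "labels": list(self.labels),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        values = pd.read_csv(path).to_numpy(dtype=float)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        return cls(
            values=values,
            feature_names=list(meta["feature_names"]),
            intensities=np.asarray(meta["intensities"], dtype=float),
            labels=list(meta["labels"]),
            normalization=[tuple(p) for p in meta["normalization"]],
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_bonn_txt(
    path: str | Path,
    label: str | None = None,
    channel_id: str | None = None,
    sampling_rate: float | None = None,
) -> SignalRecord:
    """Read a Bonn-style plain-text segment: one numeric sample per line."""
    path = Path(path)
    samples = np.loadtxt(path, dtype=float, ndmin=1)
    return SignalRecord(
        samples=samples,
        sampling_rate=sampling_rate,
        channel_id=channel_id or path.stem,
        label=label,
    )


def read_csv_signals(
    path: str | Path,
    label: str | None = None,
    sampling_rate: float | None = None,
) -> list[SignalRecord]:
    """Read a CSV matrix (rows = samples, columns = channels) into one
    record per channel.  A header row of channel names is optional."""
    df = pd.read_csv(path, header="infer" if _has_header(path) else None)
    records = []
    for col in df.columns:
        records.append(
            SignalRecord(
                samples=df[col].to_numpy(dtype=float),
                sampling_rate=sampling_rate,
                channel_id=str(col),
                label=label,
            )
        )
    return records


def _has_header(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for tok in first.replace(",", " ").split():
        try:
            float(tok)
        except ValueError:
            return True
    return False


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_signal(
    record: SignalRecord,
    window_length: int,
    overlap_fraction: float = 0.0,
) -> list[SignalRecord]:
    """Split a record into fixed-length windows, left to right.

    The stride is ``window_length * (1 - overlap_fraction)`` rounded to the
    nearest sample; a trailing partial window is dropped.
    """
    if window_length < 8:
        raise ValueError("window_length must be >= 8")
    if window_length > len(record):
        raise ValueError(
            f"window_length {window_length} exceeds signal length {len(record)}"
        )
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    stride = max(1, int(round(window_length * (1.0 - overlap_fraction))))
    windows = []
    for start in range(0, len(record) - window_length + 1, stride):
        windows.append(
            SignalRecord(
                samples=record.samples[start : start + window_length],
                sampling_rate=record.sampling_rate,
                channel_id=f"{record.channel_id}[{start}]",
                label=record.label,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def compute_moments(x: Sequence[float]) -> tuple[float, float, float, float]:
    """Mean, unbiased variance, skewness and *excess* kurtosis of ``x``.

    A constant input has zero variance; its skewness and kurtosis are
    undefined and reported as NaN sentinels rather than raising.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for moment descriptors")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        return mean, 0.0, UNDEFINED, UNDEFINED
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return mean, var, skew, kurt


def sample_entropy(x: Sequence[float], m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with template matches under Chebyshev
    distance <= r, self-matches excluded.

    ``B`` counts matching template pairs of length ``m`` and ``A`` of length
    ``m + 1``.  ``r`` defaults to 0.2 x sample SD.  A zero count in either
    tally yields ``inf`` (maximal irregularity) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        # constant signal: every template matches at any nonnegative r
        r = 1e-12
    n = x.size
    if n < m + 2:
        raise ValueError("sequence too short for the requested embedding")

    def _count(length: int) -> int:
        # both tallies use the same n - m leading templates (standard
        # definition), so a constant signal gives A/B = 1 exactly
        templ = np.lib.stride_tricks.sliding_window_view(x, length)[: n - m]
        # pairwise Chebyshev distances between all templates
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=-1)
        within = d <= r
        # exclude self-matches on the diagonal
        return int((within.sum() - within.shape[0]) // 2)

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


def permutation_entropy(
    x: Sequence[float], order: int = 3, delay: int = 1
) -> float:
    """Shannon entropy (natural log) of the ordinal-pattern distribution.

    Patterns are the argsort permutations of windows
    ``(x[t], x[t+delay], ..., x[t+(order-1)*delay])``; ties break by
    position (stable sort).  The maximum is ``ln(order!)``.
    """
    x = np.asarray(x, dtype=float)
    n_patterns = x.size - (order - 1) * delay
    if n_patterns < 1:
        raise ValueError("sequence too short for the requested order/delay")
    idx = np.arange(n_patterns)[:, None] + delay * np.arange(order)[None, :]
    windows = x[idx]
    ranks = np.argsort(windows, axis=1, kind="stable")
    codes = (ranks * (order ** np.arange(order))[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


_DESCRIPTOR_FNS: dict[str, Callable[[np.ndarray], float]] = {
    "mean": lambda x: compute_moments(x)[0],
    "variance": lambda x: compute_moments(x)[1],
    "skewness": lambda x: compute_moments(x)[2],
    "kurtosis": lambda x: compute_moments(x)[3],
    "sample_entropy": lambda x: sample_entropy(x),
    "permutation_entropy": lambda x: permutation_entropy(x),
}


# ---------------------------------------------------------------------------
# Feature matrix construction
# ---------------------------------------------------------------------------

def compute_descriptors(
    segments: Sequence[SignalRecord],
    descriptors: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> np.ndarray:
    """Raw (un-normalised) descriptor rows for each segment."""
    if len(segments) == 0 or len(descriptors) == 0:
        raise ValueError("need at least one segment and one descriptor")
    unknown = set(descriptors) - set(_DESCRIPTOR_FNS)
    if unknown:
        raise KeyError(f"unknown descriptors: {sorted(unknown)}")
    rows = np.empty((len(segments), len(descriptors)), dtype=float)
    for i, seg in enumerate(segments):
        # moments are shared between four descriptors; compute once
        moments = dict(
            zip(("mean", "variance", "skewness", "kurtosis"),
                compute_moments(seg.samples))
        )
        for j, name in enumerate(descriptors):
            if name in moments:
                rows[i, j] = moments[name]
            else:
                rows[i, j] = _DESCRIPTOR_FNS[name](seg.samples)
    return rows


def build_feature_matrix(
    segments: Sequence[SignalRecord],
    descriptors: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> FeatureMatrix:
    """Descriptor matrix with z-scored columns (the normalised data points
    the mixture model consumes).

    Rows on which any descriptor is undefined (NaN/inf) are excluded with a
    logged reason.  Normalisation uses the unbiased SD of the surviving
    rows; a single surviving row makes the scale undefined and raises.
    """
    raw = compute_descriptors(segments, descriptors)
    ok = np.all(np.isfinite(raw), axis=1)
    for i in np.flatnonzero(~ok):
        logger.warning(
            "dropping segment %d (%s): undefined descriptor value",
            i, segments[i].channel_id,
        )
    raw = raw[ok]
    kept = [seg for seg, keep in zip(segments, ok) if keep]
    if raw.shape[0] < 2:
        raise ValueError(
            "need at least 2 valid segments to normalise feature columns"
        )
    loc = raw.mean(axis=0)
    scale = raw.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)  # constant column -> centred zeros
    values = (raw - loc) / scale
    intensities = np.array([np.mean(np.abs(s.samples)) for s in kept])
    return FeatureMatrix(
        values=values,
        feature_names=list(descriptors),
        intensities=intensities,
        labels=[s.label for s in kept],
        normalization=[(float(l), float(s)) for l, s in zip(loc, scale)],
        raw_values=raw,
        source_mask=ok,
    )


def apply_normalization(
    segments: Sequence[SignalRecord],
    reference: FeatureMatrix,
) -> FeatureMatrix:
    """Descriptor matrix for new segments normalised with *reference*
    (training-derived) constants — no statistics leak from these rows."""
    raw = compute_descriptors(segments, reference.feature_names)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    loc = np.array([p[0] for p in reference.normalization])
    scale = np.array([p[1] for p in reference.normalization])
    values = (raw - loc) / scale
    intensities = np.array([np.mean(np.abs(s.samples)) for s in segments])
    return FeatureMatrix(
        values=values,
        feature_names=list(reference.feature_names),
        intensities=intensities,
        labels=[s.label for s in segments],
        normalization=list(reference.normalization),
        raw_values=raw,
        source_mask=np.ones(len(segments), dtype=bool),
    )


def preprocess_identity(records: Sequence[SignalRecord]) -> list[SignalRecord]:
    """No-op preprocessing hook (artifact removal such as ICA would slot in
    here; none is performed)."""
    return list(records)
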