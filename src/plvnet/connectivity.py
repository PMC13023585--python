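"""Band-limited phase-locking-value (PLV) connectivity.

The pipeline implemented here turns region-level time series into symmetric
PLV matrices: zero-phase bandpass filtering, segmentation into fixed-length
epochs, instantaneous phase extraction via the analytic signal, and the
modulus of the time-averaged unit phasor of the phase difference, averaged
over segments.

PLV between two phase series ``x`` and ``y`` of length ``T`` is

    PLV = | (1/T) * sum_t exp(i * (x_t - y_t)) |

which is 1 for perfectly phase-locked signals and decays to a finite-sample
floor of order ``1/sqrt(T_eff)`` for unrelated signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "BandDefinition",
    "THETA",
    "ALPHA",
    "BETA",
    "DEFAULT_BANDS",
    "RegionTimeSeries",
    "ConnectivityMatrix",
    "bandpass",
    "segment",
    "instantaneous_phase",
    "plv",
    "connectivity_matrix",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with lower and upper edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges: lo={self.lo}, hi={self.hi}")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 14.0)
BETA = BandDefinition("beta", 14.0, 30.0)
DEFAULT_BANDS: tuple[BandDefinition, ...] = (THETA, ALPHA, BETA)

#: default sampling rate (Hz) of the analysis pipeline
DEFAULT_FS = 256.0
#: default epoch length in seconds
DEFAULT_SEG_SECONDS = 6.0
#: fraction of each segment's samples discarded at both ends before PLV
#: averaging, to suppress analytic-signal edge transients
EDGE_FRACTION = 0.05


def band_by_name(name: str) -> BandDefinition:
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: theta, alpha, beta")


@dataclass
class RegionTimeSeries:
    """A block of real-valued signals, one row per region.

    Parameters
    ----------
    labels
        Ordered, unique region names.
    data
        Array of shape ``(n_regions, n_samples)``.
    fs
        Sampling rate in Hz.
    """

    labels: list[str]
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ConnectivityMatrix:
    """A symmetric PLV matrix with region labels and provenance.

    ``values`` lie in [0, 1], the diagonal is stored as 1 by convention and
    is always excluded from downstream statistics.
    """

    labels: list[str]
    values: np.ndarray
    band: BandDefinition
    n_segments: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity values must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("PLV values must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("diagonal must be 1 (self-connection convention)")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries as a flat vector (self-connections excluded)."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]

    # -- plain-text round trip -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as labeled CSV plus a JSON sidecar with band metadata."""
        path = Path(path)
        header = ",".join(self.labels)
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")
        sidecar = {
            "labels": self.labels,
            "band": {"name": self.band.name, "lo": self.band.lo, "hi": self.band.hi},
            "n_segments": self.n_segments,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = np.loadtxt(path, delimiter=",", skiprows=1)
        band = BandDefinition(**sidecar["band"])
        return cls(sidecar["labels"], values, band, sidecar["n_segments"])


def write_timeseries_csv(ts: RegionTimeSeries, path: str | Path) -> None:
    """Write signals as CSV (one row per region) plus a JSON sidecar (labels, fs)."""
    path = Path(path)
    np.savetxt(path, ts.data, delimiter=",")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"labels": ts.labels, "fs": ts.fs})
    )


def read_timeseries_csv(path: str | Path) -> RegionTimeSeries:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return RegionTimeSeries(sidecar["labels"], data, sidecar["fs"])


def bandpass(
    ts: RegionTimeSeries, band: BandDefinition, order: int = 4
) -> RegionTimeSeries:
    """Zero-phase Butterworth bandpass filter.

    Forward-backward filtering (``sosfiltfilt``) removes group delay; the
    default order meets a >= 20 dB stopband attenuation one band away at the
    analysis sampling rates.
    """
    if band.hi >= ts.fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.hi} Hz >= Nyquist ({ts.fs / 2} Hz)"
        )
    sos = butter(order, [band.lo, band.hi], btype="bandpass", fs=ts.fs, output="sos")
    filtered = sosfiltfilt(sos, ts.data, axis=-1)
    return RegionTimeSeries(ts.labels, filtered, ts.fs)


def segment(
    ts: RegionTimeSeries, seg_seconds: float = DEFAULT_SEG_SECONDS
) -> list[RegionTimeSeries]:
    """Cut into non-overlapping segments of ``seg_seconds``; remainder dropped."""
    n_per = int(round(seg_seconds * ts.fs))
    if n_per < 2:
        raise ValueError("segment length must cover at least 2 samples")
    n_seg = ts.n_samples // n_per
    if n_seg == 0:
        raise ValueError(
            f"duration {ts.duration:.3f} s shorter than one {seg_seconds} s segment"
        )
    return [
        RegionTimeSeries(ts.labels, ts.data[:, k * n_per : (k + 1) * n_per], ts.fs)
        for k in range(n_seg)
    ]


def instantaneous_phase(ts: RegionTimeSeries) -> np.ndarray:
    """Per-region instantaneous phase (radians in (-pi, pi]) via the analytic signal."""
    amplitude = np.abs(ts.data).max(axis=1)
    if np.any(amplitude == 0):
        bad = ts.labels[int(np.argmax(amplitude == 0))]
        raise ValueError(f"phase undefined for all-zero signal in region {bad!r}")
    return np.angle(hilbert(ts.data, axis=-1))


def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase locking value between two phase series.

    Symmetric in its arguments, invariant to a constant phase offset on
    either series, and bounded in [0, 1].
    """
    phase_x = np.asarray(phase_x, dtype=float).ravel()
    phase_y = np.asarray(phase_y, dtype=float).ravel()
    if phase_x.shape != phase_y.shape:
        raise ValueError(
            f"phase series lengths differ: {phase_x.size} vs {phase_y.size}"
        )
    if phase_x.size < 2:
        raise ValueError("need at least 2 phase samples")
    value = np.abs(np.mean(np.exp(1j * (phase_x - phase_y))))
    return float(min(value, 1.0))


def _segment_plv_matrix(phases: np.ndarray, edge_fraction: float) -> np.ndarray:
    """PLV matrix of one segment from its (regions x samples) phase array."""
    n = phases.shape[1]
    trim = int(np.floor(edge_fraction * n))
    core = phases[:, trim : n - trim] if trim > 0 else phases
    z = np.exp(1j * core)
    m = np.abs(z @ z.conj().T) / core.shape[1]
    return np.minimum(m, 1.0)


def connectivity_matrix(
    ts: RegionTimeSeries,
    band: BandDefinition,
    seg_seconds: float = DEFAULT_SEG_SECONDS,
    edge_fraction: float = EDGE_FRACTION,
) -> ConnectivityMatrix:
    """Full PLV pipeline: bandpass -> segment -> phase -> per-segment PLV -> average.

    The first and last ``edge_fraction`` of each segment's samples are
    excluded from the average to suppress filter/Hilbert edge transients.
    The diagonal is set to 1 by convention.
    """
    filtered = bandpass(ts, band)
    segments = segment(filtered, seg_seconds)
    acc = np.zeros((ts.n_regions, ts.n_regions))
    for seg in segments:
        phases = instantaneous_phase(seg)
        acc += _segment_plv_matrix(phases, edge_fraction)
    values = acc / len(segments)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(ts.labels, np.clip(values, 0.0, 1.0), band, len(segments))
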