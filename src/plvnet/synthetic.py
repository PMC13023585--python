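"""Synthetic phase-coupled region signals and group datasets.

The generator emulates the resting-state recordings behind the study design
it is built for: 34 subjects, a 2 (without/with music) x 2 (pre/post)
within-subject crossover, and 78 source-space regions grouped into five
resting-state networks, with band-limited oscillatory signals whose pairwise
phase locking is controlled.

Signal model
------------
Each region's signal is a narrowband oscillation ``x_i(t) = Re[c_i(t)
exp(i 2 pi f_c t)]`` whose complex envelope ``c_i`` is a lowpass-filtered
complex Gaussian process.  Envelopes are correlated across regions through a
matrix factor, so that the pairwise envelope coherence ``rho_ij`` is set
freely for any positive-semidefinite target pattern -- including a uniform
background plus planted cliques.  Because the pairwise marginal of a jointly
Gaussian process depends only on ``rho_ij``, the empirical PLV of a pair is
a monotone function of its coherence alone; that map is calibrated
numerically against the package's own connectivity pipeline and inverted to
turn target PLV matrices into coherence matrices.

Targets at or below the finite-sample PLV floor (the expected PLV of
uncoupled signals) are mapped to zero coherence; a target coupling matrix
whose implied coherence matrix is not positive semidefinite is rejected with
an error naming an offending region triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .connectivity import (
    ALPHA,
    DEFAULT_BANDS,
    DEFAULT_FS,
    DEFAULT_SEG_SECONDS,
    BandDefinition,
    ConnectivityMatrix,
    RegionTimeSeries,
    connectivity_matrix,
)
from .dataset import GroupDataset

__all__ = [
    "CouplingInfeasibleError",
    "OscillatorSpec",
    "PlantedEffect",
    "GroupDesign",
    "uniform_coupling",
    "clique_edges",
    "calibrate_coupling",
    "coupling_floor",
    "simulate_region_signals",
    "simulate_group",
    "simulate_group_plv",
]

logger = logging.getLogger(__name__)


class CouplingInfeasibleError(ValueError):
    """Raised when a target PLV matrix cannot be realized by the mixing model."""


def uniform_coupling(n_regions: int, value: float) -> np.ndarray:
    """Coupling matrix with one common off-diagonal target and unit diagonal."""
    C = np.full((n_regions, n_regions), float(value))
    np.fill_diagonal(C, 1.0)
    return C


def clique_edges(nodes: list[int]) -> list[tuple[int, int]]:
    """All unordered edges among ``nodes``."""
    return [(min(a, b), max(a, b)) for a, b in combinations(nodes, 2)]


@dataclass
class OscillatorSpec:
    """Specification of one band-limited, phase-coupled signal block."""

    n_regions: int = 78
    band: BandDefinition = ALPHA
    fs: float = DEFAULT_FS
    duration: float = 300.0
    coupling: np.ndarray | None = None
    seed: int = 0
    labels: list[str] | None = None
    seg_seconds: float = DEFAULT_SEG_SECONDS

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if self.fs <= 2 * self.band.hi:
            raise ValueError(
                f"fs={self.fs} must exceed twice the band upper edge ({self.band.hi} Hz)"
            )
        if self.coupling is None:
            self.coupling = np.eye(self.n_regions)
        self.coupling = np.asarray(self.coupling, dtype=float)
        C = self.coupling
        if C.shape != (self.n_regions, self.n_regions):
            raise ValueError("coupling matrix shape does not match n_regions")
        if not np.allclose(C, C.T):
            raise ValueError("coupling matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("coupling diagonal must be exactly 1")
        off = C[~np.eye(self.n_regions, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal coupling targets must lie in [0, 1]")
        if self.labels is None:
            width = max(3, len(str(self.n_regions)))
            self.labels = [f"R{k:0{width}d}" for k in range(self.n_regions)]

    @property
    def n_segments(self) -> int:
        return int(self.duration // self.seg_seconds)


# --------------------------------------------------------------------------
# coupling -> coherence calibration
# --------------------------------------------------------------------------

_CAL_SEED = 987_654  # fixed internal seed for calibration simulations
_pair_cache: dict[tuple, float] = {}
_curve_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _envelopes(
    factor: np.ndarray,
    n_samples: int,
    band: BandDefinition,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated lowpass complex-Gaussian envelopes, one row per region."""
    n_regions = factor.shape[0]
    xi = rng.standard_normal((n_regions, n_samples)) + 1j * rng.standard_normal(
        (n_regions, n_samples)
    )
    mixed = factor @ xi
    cutoff = max(band.width / 2.0, 0.25)
    sos = butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, mixed.real, axis=-1) + 1j * sosfiltfilt(
        sos, mixed.imag, axis=-1
    )


def _coherence_factor(rho: np.ndarray, labels: list[str]) -> np.ndarray:
    """Matrix square root of a coherence matrix; rejects non-PSD targets.

    Uses an eigendecomposition rather than Cholesky so that exactly locked
    pairs (coherence 1, a singular but valid matrix) are accepted.
    """
    eigval, eigvec = np.linalg.eigh(rho)
    if eigval.min() < -1e-8:
        for i, j, k in combinations(range(rho.shape[0]), 3):
            sub = rho[np.ix_((i, j, k), (i, j, k))]
            if np.linalg.det(sub) < -1e-10:
                raise CouplingInfeasibleError(
                    "coupling targets are not jointly realizable; offending "
                    f"region triple: ({labels[i]}, {labels[j]}, {labels[k]}) "
                    f"with pairwise targets {sub[0, 1]:.3f}, {sub[0, 2]:.3f}, "
                    f"{sub[1, 2]:.3f}"
                )
        raise CouplingInfeasibleError(
            "coupling targets are not jointly realizable "
            f"(minimum eigenvalue {eigval.min():.3e})"
        )
    return eigvec * np.sqrt(np.clip(eigval, 0.0, None))


def _pair_plv(
    weight: float,
    n_segments: int,
    band: BandDefinition,
    fs: float,
    seg_seconds: float,
) -> float:
    """Simulated empirical PLV of a two-region pair at envelope coherence ``weight``."""
    key = (round(weight, 6), n_segments, band.name, band.lo, band.hi, fs, seg_seconds)
    if key in _pair_cache:
        return _pair_cache[key]
    rho = np.array([[1.0, weight], [weight, 1.0]])
    spec = OscillatorSpec(
        n_regions=2,
        band=band,
        fs=fs,
        duration=n_segments * seg_seconds,
        coupling=None,
        seed=_CAL_SEED,
        seg_seconds=seg_seconds,
    )
    ts = _simulate_from_coherence(rho, spec)
    cm = connectivity_matrix(ts, band, seg_seconds)
    value = float(cm.values[0, 1])
    _pair_cache[key] = value
    return value


def coupling_floor(
    n_segments: int,
    band: BandDefinition = ALPHA,
    fs: float = DEFAULT_FS,
    seg_seconds: float = DEFAULT_SEG_SECONDS,
) -> float:
    """Expected empirical PLV of an uncoupled pair (the finite-sample floor)."""
    return _pair_plv(0.0, n_segments, band, fs, seg_seconds)


def calibrate_coupling(
    target_plv: float,
    n_segments: int,
    band: BandDefinition = ALPHA,
    fs: float = DEFAULT_FS,
    seg_seconds: float = DEFAULT_SEG_SECONDS,
    tol: float = 0.01,
) -> float:
    """Envelope-coherence mixing weight whose expected empirical PLV hits the target.

    Found by monotone bisection against the simulation oracle (the package's
    own signal -> PLV pipeline); results are cached.  The weight is
    nondecreasing in the target.  A target below the finite-sample floor
    raises with the floor in the message.
    """
    if not (0.0 <= target_plv <= 1.0):
        raise ValueError("target PLV must lie in [0, 1]")
    floor = coupling_floor(n_segments, band, fs, seg_seconds)
    if target_plv >= 1.0:
        return 1.0
    if target_plv <= floor:
        if target_plv >= floor - tol:
            return 0.0
        raise ValueError(
            f"target PLV {target_plv:.3f} is below the finite-sample floor "
            f"{floor:.3f} for {n_segments} segments in band {band.name}"
        )
    lo, hi = 0.0, 1.0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        value = _pair_plv(mid, n_segments, band, fs, seg_seconds)
        if abs(value - target_plv) <= tol:
            return mid
        if value < target_plv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibration_curve(
    n_segments: int, band: BandDefinition, fs: float, seg_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone (plv_grid, weight_grid) table for inverting targets elementwise."""
    key = (n_segments, band.name, band.lo, band.hi, fs, seg_seconds)
    if key in _curve_cache:
        return _curve_cache[key]
    weights = np.array(
        [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98, 1.0]
    )
    plvs = np.array(
        [_pair_plv(w, n_segments, band, fs, seg_seconds) for w in weights]
    )
    plvs[-1] = 1.0
    plvs = np.maximum.accumulate(plvs)  # guard monotonicity against MC noise
    _curve_cache[key] = (plvs, weights)
    return plvs, weights


def _coupling_to_coherence(coupling: np.ndarray, spec: OscillatorSpec) -> np.ndarray:
    """Invert the calibration curve elementwise: target PLV -> envelope coherence.

    Targets at or below the floor map to coherence 0 (uncoupled); targets of
    1 map to coherence 1 (exact locking).
    """
    plvs, weights = _calibration_curve(
        spec.n_segments, spec.band, spec.fs, spec.seg_seconds
    )
    rho = np.interp(coupling, plvs, weights)
    np.fill_diagonal(rho, 1.0)
    return rho


def _simulate_from_coherence(rho: np.ndarray, spec: OscillatorSpec) -> RegionTimeSeries:
    factor = _coherence_factor(rho, spec.labels)
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.fs * spec.duration))
    env = _envelopes(factor, n_samples, spec.band, spec.fs, rng)
    t = np.arange(n_samples) / spec.fs
    carrier = np.exp(1j * 2 * np.pi * spec.band.center * t)
    x = (env * carrier).real
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return RegionTimeSeries(spec.labels, x / sd, spec.fs)


def simulate_region_signals(spec: OscillatorSpec) -> RegionTimeSeries:
    """Generate region signals whose empirical band PLV approaches the targets.

    Deterministic given ``spec.seed``.  Raises
    :class:`CouplingInfeasibleError` when the coupling targets are not
    jointly realizable by the mixing model.
    """
    if spec.duration < spec.seg_seconds:
        raise ValueError("duration must cover at least one segment")
    rho = _coupling_to_coherence(spec.coupling, spec)
    return _simulate_from_coherence(rho, spec)


# --------------------------------------------------------------------------
# group designs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEffect:
    """A condition x time x band connectivity offset.

    ``edges`` lists region index pairs; ``None`` applies the delta to every
    off-diagonal pair (a diffuse, global shift).  ``delta`` is additive on
    the target PLV and results are clipped to [0, 1] (clipping is logged).
    """

    condition: str
    time: str
    band: str
    delta: float
    edges: list[tuple[int, int]] | None = None


@dataclass
class GroupDesign:
    """A 2-condition x 2-time within-subject crossover design."""

    n_subjects: int = 34
    conditions: tuple[str, str] = ("without_music", "with_music")
    times: tuple[str, str] = ("pre", "post")
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    n_regions: int = 78
    labels: list[str] | None = None
    base_coupling: float | dict[str, float | np.ndarray] = 0.3
    duration: float = 300.0
    fs: float = DEFAULT_FS
    seg_seconds: float = DEFAULT_SEG_SECONDS
    subject_sd: float = 0.03
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.labels is None:
            width = max(3, len(str(self.n_regions)))
            self.labels = [f"R{k:0{width}d}" for k in range(self.n_regions)]
        band_names = {b.name for b in self.bands}
        for eff in self.planted_effects:
            if eff.condition not in self.conditions:
                raise ValueError(f"unknown condition {eff.condition!r} in planted effect")
            if eff.time not in self.times:
                raise ValueError(f"unknown time {eff.time!r} in planted effect")
            if eff.band not in band_names:
                raise ValueError(f"unknown band {eff.band!r} in planted effect")
            for i, j in eff.edges or []:
                if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                    raise ValueError(f"planted edge ({i}, {j}) out of range")

    def base_matrix(self, band: BandDefinition) -> np.ndarray:
        base = self.base_coupling
        if isinstance(base, dict):
            base = base[band.name]
        if np.isscalar(base):
            return uniform_coupling(self.n_regions, float(base))
        return np.asarray(base, dtype=float).copy()


def _cell_target(
    design: GroupDesign,
    band: BandDefinition,
    condition: str,
    time: str,
    jitter: np.ndarray,
) -> np.ndarray:
    target = design.base_matrix(band)
    off = ~np.eye(design.n_regions, dtype=bool)
    target[off] += jitter[off]
    for eff in design.planted_effects:
        if (eff.condition, eff.time, eff.band) != (condition, time, band.name):
            continue
        if eff.edges is None:
            target[off] += eff.delta
        else:
            for i, j in eff.edges:
                target[i, j] += eff.delta
                target[j, i] += eff.delta
    clipped = np.clip(target, 0.0, 1.0)
    n_clipped = int((clipped != target)[off].sum()) // 2
    if n_clipped:
        logger.warning(
            "planted effects clipped %d edge targets to [0, 1] in cell (%s, %s, %s)",
            n_clipped,
            condition,
            time,
            band.name,
        )
    np.fill_diagonal(clipped, 1.0)
    return clipped


def _subject_jitter(
    design: GroupDesign, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject global coupling offset, normal truncated at +/- 3 sd.

    The offset is shared by all edges of a band rather than drawn per edge:
    independent per-edge perturbations of a large coupling matrix push its
    implied coherence matrix off the positive-semidefinite cone (the
    perturbation's extreme eigenvalues grow like sd * sqrt(n_regions)), so
    subject heterogeneity is modeled as a shift of the subject's overall
    coupling level.
    """
    n = design.n_regions
    delta = float(
        np.clip(
            rng.normal(0.0, design.subject_sd),
            -3 * design.subject_sd,
            3 * design.subject_sd,
        )
    )
    j = np.full((n, n), delta)
    np.fill_diagonal(j, 0.0)
    return j


def simulate_group(design: GroupDesign) -> GroupDataset:
    """Simulate a full group dataset through the signal -> PLV pipeline.

    One connectivity matrix per subject x condition x time x band.  Subject
    heterogeneity is a per-subject, per-band coupling jitter shared across
    the four cells (a subject trait); cell-to-cell variability then arises
    from finite-segment PLV estimation noise.  Fully reproducible from
    ``design.seed``.
    """
    subjects = list(range(design.n_subjects))
    ds = GroupDataset(
        subjects,
        list(design.conditions),
        list(design.times),
        [b.name for b in design.bands],
    )
    root = np.random.SeedSequence(design.seed)
    jitter_rng = np.random.default_rng(root.spawn(1)[0])
    n_cells = (
        design.n_subjects * len(design.bands) * len(design.conditions) * len(design.times)
    )
    cell_seeds = iter(root.spawn(n_cells))
    for s in subjects:
        for band in design.bands:
            jitter = _subject_jitter(design, jitter_rng)
            for condition in design.conditions:
                for time in design.times:
                    target = _cell_target(design, band, condition, time, jitter)
                    seed = int(next(cell_seeds).generate_state(1, np.uint32)[0])
                    spec = OscillatorSpec(
                        n_regions=design.n_regions,
                        band=band,
                        fs=design.fs,
                        duration=design.duration,
                        coupling=target,
                        seed=seed,
                        labels=design.labels,
                        seg_seconds=design.seg_seconds,
                    )
                    ts = simulate_region_signals(spec)
                    cm = connectivity_matrix(ts, band, design.seg_seconds)
                    ds.put(s, condition, time, band.name, cm)
    return ds


def simulate_group_plv(
    design: GroupDesign, noise_sd: float = 0.03, seed: int | None = None
) -> GroupDataset:
    """Matrix-level surrogate of :func:`simulate_group` for large calibration runs.

    Draws each cell's PLV matrix directly as ``base + subject jitter +
    independent cell noise + planted deltas`` clipped to [0.001, 0.999],
    skipping signal synthesis.  ``noise_sd`` stands in for finite-segment
    PLV estimation noise.  Intended for simulation studies that need
    hundreds of group datasets (type-I calibration, power curves); it shares
    the design semantics but not the signal path of the full generator.
    """
    subjects = list(range(design.n_subjects))
    ds = GroupDataset(
        subjects,
        list(design.conditions),
        list(design.times),
        [b.name for b in design.bands],
    )
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_regions
    off = ~np.eye(n, dtype=bool)
    for s in subjects:
        for band in design.bands:
            jitter = _subject_jitter(design, rng)
            for condition in design.conditions:
                for time in design.times:
                    target = _cell_target(design, band, condition, time, jitter)
                    noise = rng.normal(0.0, noise_sd, size=(n, n))
                    noise = np.triu(noise, k=1)
                    noise += noise.T
                    values = np.clip(target + noise, 0.001, 0.999)
                    values[~off] = 1.0
                    cm = ConnectivityMatrix(design.labels, values, band, n_segments=0)
                    ds.put(s, condition, time, band.name, cm)
    return ds
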