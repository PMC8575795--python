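"""Temporal preprocessing of BOLD node timeseries.

The cleaning step is a single least-squares projection implementing
*simultaneous* bandpass filtering (0.009-0.08 Hz by default) and nuisance
regression: the design matrix stacks an intercept, a linear trend, a
cosine (DCT) basis spanning every stop-band frequency, externally supplied
nuisance regressors (motion parameters, tissue PCs), and one indicator
column per flagged spike frame ("scrubbing" by regression, which keeps the
series length constant for the DCC stage).  Spike frames are flagged when
the global signal exceeds |z| > 5 against the scan's own mean/SD or the
framewise displacement exceeds 0.9 mm.

Parcellation averages voxels within a 10-mm sphere of each node center,
honoring a per-voxel quality mask; node-level QC retains a node only if its
in-sphere coverage is at least 75% in *every* scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import static_fc, edge_vectorize

__all__ = [
    "PreprocessConfig",
    "ParcellationConfig",
    "DesignMatrix",
    "detect_spikes",
    "build_design",
    "clean_timeseries",
    "parcellate",
    "node_qc",
    "split_half_reliability",
]


@dataclass(frozen=True)
class PreprocessConfig:
    band_low: float = 0.009             # Hz
    band_high: float = 0.08             # Hz
    tr_seconds: float = 2.0
    global_z_threshold: float = 5.0
    motion_mm_threshold: float = 0.9
    include_linear_trend: bool = True
    n_csf_pcs: int = 5
    n_wm_pcs: int = 5
    n_motion_params: int = 24

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 < self.band_low < self.band_high < nyquist):
            raise ValueError(
                f"need 0 < band_low < band_high < Nyquist ({nyquist:g} Hz)")
        if self.global_z_threshold <= 0 or self.motion_mm_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ParcellationConfig:
    radius_mm: float = 10.0
    min_coverage_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not 0 < self.min_coverage_fraction <= 1:
            raise ValueError("min_coverage_fraction must be in (0, 1]")


@dataclass
class DesignMatrix:
    """T x K design with named columns; full column rank, K < T."""

    matrix: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        x = np.asarray(self.matrix, dtype=float)
        t, k = x.shape
        if k >= t:
            raise ValueError(f"over-parameterized design: {k} columns, {t} rows")
        if len(self.names) != k:
            raise ValueError("one name per column required")
        if np.linalg.matrix_rank(x) < k:
            raise ValueError(
                f"rank-deficient design; collinear columns among: "
                f"{_collinear_columns(x, self.names)}")
        self.matrix = x

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns whose removal restores full rank (QR diagnostic)."""
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def detect_spikes(global_signal: np.ndarray,
                  framewise_displacement: np.ndarray,
                  config: PreprocessConfig | None = None) -> set[int]:
    """Frames with |global-signal z| > threshold or FD above the mm cutoff.

    The z-score uses the scan's own mean and SD.  A zero-variance global
    signal falls back to the motion criterion alone, with a warning.
    """
    config = config or PreprocessConfig()
    gs = np.asarray(global_signal, dtype=float).ravel()
    fd = np.asarray(framewise_displacement, dtype=float).ravel()
    if gs.size != fd.size:
        raise ValueError("global signal and displacement lengths differ")
    sd = gs.std()
    if sd == 0:
        warnings.warn("zero-variance global signal; motion criterion only",
                      stacklevel=2)
        z_flags = np.zeros(gs.size, dtype=bool)
    else:
        z_flags = np.abs((gs - gs.mean()) / sd) > config.global_z_threshold
    fd_flags = fd > config.motion_mm_threshold
    return set(np.flatnonzero(z_flags | fd_flags).tolist())


# ---------------------------------------------------------------------------
# design construction and projection
# ---------------------------------------------------------------------------

def stopband_frequencies(t: int, config: PreprocessConfig) -> list[int]:
    """DCT basis orders k whose frequency k/(2*T*TR) lies outside the band."""
    ks = []
    for k in range(1, t):
        f_k = k / (2.0 * t * config.tr_seconds)
        if f_k < config.band_low or f_k > config.band_high:
            ks.append(k)
    return ks


def build_design(t: int, config: PreprocessConfig | None = None,
                 nuisance_regressors: pd.DataFrame | np.ndarray | None = None,
                 spike_indices: set[int] | None = None) -> DesignMatrix:
    """Intercept + trend + stop-band DCT basis + nuisance + spike indicators."""
    config = config or PreprocessConfig()
    cols = [np.ones(t)]
    names = ["intercept"]
    if config.include_linear_trend:
        cols.append(np.linspace(-1.0, 1.0, t))
        names.append("trend")

    time = np.arange(t)
    for k in stopband_frequencies(t, config):
        cols.append(np.cos(np.pi * k * (2 * time + 1) / (2.0 * t)))
        names.append(f"dct{k:04d}")

    if nuisance_regressors is not None:
        nr = nuisance_regressors
        if isinstance(nr, pd.DataFrame):
            nr_names = [str(c) for c in nr.columns]
            nr = nr.to_numpy(dtype=float)
        else:
            nr = np.asarray(nr, dtype=float)
            if nr.ndim == 1:
                nr = nr[:, None]
            nr_names = [f"nuisance{i}" for i in range(nr.shape[1])]
        if nr.shape[0] != t:
            raise ValueError("nuisance length does not match T")
        cols.extend(nr.T)
        names.extend(nr_names)

    for s in sorted(spike_indices or ()):
        if not 0 <= s < t:
            raise ValueError(f"spike index {s} out of range")
        ind = np.zeros(t)
        ind[s] = 1.0
        cols.append(ind)
        names.append(f"spike{s:04d}")

    return DesignMatrix(np.column_stack(cols), names)


def clean_timeseries(y: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Least-squares residuals of Y against the design (idempotent)."""
    y = np.asarray(y, dtype=float)
    one_d = y.ndim == 1
    if one_d:
        y = y[:, None]
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError("row counts of data and design differ")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid.ravel() if one_d else resid


# ---------------------------------------------------------------------------
# parcellation and node QC
# ---------------------------------------------------------------------------

def parcellate(voxel_array: np.ndarray, voxel_coords: np.ndarray,
               node_centers: np.ndarray,
               voxel_quality_mask: np.ndarray | None = None,
               config: ParcellationConfig | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Average in-sphere voxels passing the quality mask per node.

    Sphere membership is Euclidean distance <= radius in continuous mm.
    Returns (T x n_nodes node signals, per-node coverage fractions); a node
    with no usable voxels gets coverage 0 and NaN signal (an explicit
    missing-signal marker, never silent zeros).
    """
    config = config or ParcellationConfig()
    v = np.asarray(voxel_array, dtype=float)
    coords = np.asarray(voxel_coords, dtype=float)
    centers = np.asarray(node_centers, dtype=float)
    mask = (np.ones(coords.shape[0], dtype=bool) if voxel_quality_mask is None
            else np.asarray(voxel_quality_mask, dtype=bool))
    t = v.shape[0]
    n = centers.shape[0]
    signals = np.full((t, n), np.nan)
    coverage = np.zeros(n)
    for k in range(n):
        d = np.linalg.norm(coords - centers[k], axis=1)
        inside = d <= config.radius_mm
        n_inside = int(inside.sum())
        if n_inside == 0:
            continue
        usable = inside & mask
        coverage[k] = usable.sum() / n_inside
        if usable.any():
            signals[:, k] = v[:, usable].mean(axis=1)
    return signals, coverage


def node_qc(coverage_table: pd.DataFrame | np.ndarray,
            config: ParcellationConfig | None = None) -> list:
    """Nodes whose coverage is >= the threshold in every scan (inclusive).

    ``coverage_table`` is scans x nodes; columns name the nodes when a
    DataFrame is given.
    """
    config = config or ParcellationConfig()
    if isinstance(coverage_table, pd.DataFrame):
        table = coverage_table.to_numpy(dtype=float)
        node_ids = list(coverage_table.columns)
    else:
        table = np.asarray(coverage_table, dtype=float)
        node_ids = list(range(table.shape[1])) if table.ndim == 2 else []
    if table.size == 0:
        raise ValueError("empty coverage table")
    keep = np.all(table >= config.min_coverage_fraction, axis=0)
    return [node_ids[i] for i in np.flatnonzero(keep)]


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def split_half_reliability(node_ts: np.ndarray) -> float:
    """Correlation across edges between first-half and second-half sFC.

    Constant nodes in either half are excluded (with a warning) before the
    per-half connectivity matrices are compared.
    """
    y = np.asarray(getattr(node_ts, "values", node_ts), dtype=float)
    t = y.shape[0]
    if t < 4:
        raise ValueError("need at least 4 timepoints for split halves")
    half = t // 2
    first, second = y[:half], y[half:]
    ok = (first.std(axis=0) > 0) & (second.std(axis=0) > 0)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} constant node(s) excluded from "
                      "reliability", stacklevel=2)
    first, second = first[:, ok], second[:, ok]
    if first.shape[1] < 2:
        raise ValueError("fewer than 2 usable nodes")
    z1 = edge_vectorize(static_fc(first).values)
    z2 = edge_vectorize(static_fc(second).values)
    return float(np.corrcoef(z1, z2)[0, 1])
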