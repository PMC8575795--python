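"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates an open-label pre/post psilocybin-therapy study
design: ~24 participants split into immediate and delayed-treatment groups,
a baseline and a 1-week-post resting-state scan per participant (355 TRs at
TR = 2 s), and integer-scored behavior (HAMD-like depression severity,
PCET-like perseverative errors) at baseline, week 1 and week 4, plus a
behavior-only pre-delay timepoint for the delayed group.

Node signals are heteroskedastic GARCH(1,1) processes.  A configurable set
of "active" edges carries a genuinely time-varying correlation path driven
by the DCC recursion; all other node pairs share a constant background
correlation.  The generator records the true correlation path of every
active edge, so the true dFC of an edge is simply the variance of its
recorded path — the quantity the estimation stage tries to recover.

Planted structure:

* pre->post standardized shifts on each behavior (treatment effects),
* a standardized pre->post increase in one target edge's dFC,
* linear couplings from a participant's baseline edge feature (sFC level or
  dFC amplitude) to a behavior score or to its pre->post change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GarchParams",
    "DccParams",
    "BaselineCoupling",
    "CohortConfig",
    "GroundTruth",
    "CohortDataset",
    "simulate_garch_series",
    "simulate_dcc_edge",
    "simulate_cohort",
    "simulate_voxel_scene",
    "write_cohort",
]

TIMEPOINTS = ("pre_delay", "baseline", "week1", "week4")
HAMD_RANGE = (0, 52)
PCET_RANGE = (0, 30)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GarchParams:
    """GARCH(1,1) conditional-variance parameters.

    omega is the variance intercept (signal units squared); alpha weights the
    previous squared innovation and beta the previous variance.  Covariance
    stationarity requires alpha + beta < 1, giving long-run variance
    omega / (1 - alpha - beta).
    """

    omega: float = 0.05
    alpha: float = 0.10
    beta: float = 0.85

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError("omega must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if not self.alpha + self.beta < 1:
            raise ValueError("alpha + beta must be < 1 (stationarity)")

    @property
    def long_run_variance(self) -> float:
        return self.omega / (1.0 - self.alpha - self.beta)


@dataclass(frozen=True)
class DccParams:
    """DCC(1,1) correlation-dynamics parameters.

    a weights the innovation outer product, b the previous pseudo-correlation
    state; rho_bar is the unconditional correlation target.  a = b = 0
    degenerates to a constant correlation at rho_bar.
    """

    a: float = 0.05
    b: float = 0.90
    rho_bar: float = 0.30

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be >= 0")
        if not self.a + self.b < 1:
            raise ValueError("a + b must be < 1 (stationarity)")
        if not abs(self.rho_bar) < 1:
            raise ValueError("|rho_bar| must be < 1")


@dataclass(frozen=True)
class BaselineCoupling:
    """Planted linear coupling from a baseline edge feature to behavior.

    ``feature_kind`` selects the sFC level or the dFC amplitude of ``edge``
    at baseline; ``behavior`` names the coupled score (``hamd`` or
    ``pcet_persev``); ``target`` says whether the coupling acts on the
    baseline score itself or on the baseline->week1 change; ``sign`` and
    ``strength`` give the direction and magnitude (in score SD units per
    feature SD).
    """

    edge: tuple[int, int]
    feature_kind: str = "dfc"           # "sfc" | "dfc"
    behavior: str = "pcet_persev"       # "hamd" | "pcet_persev"
    target: str = "change"              # "baseline" | "change"
    sign: int = 1
    strength: float = 0.8

    def __post_init__(self) -> None:
        if self.feature_kind not in ("sfc", "dfc"):
            raise ValueError("feature_kind must be 'sfc' or 'dfc'")
        if self.behavior not in ("hamd", "pcet_persev"):
            raise ValueError("behavior must be 'hamd' or 'pcet_persev'")
        if self.target not in ("baseline", "change"):
            raise ValueError("target must be 'baseline' or 'change'")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated study: 24 participants (13 immediate / 11
    delayed), 355 TRs at TR = 2 s, pre/post scans, moderate-to-large planted
    treatment effects on both behaviors and on the target edge's dFC, and a
    positive baseline-dFC -> less-improvement coupling.
    """

    n_participants: int = 24
    n_nodes: int = 16
    n_trs: int = 355
    tr_seconds: float = 2.0
    n_immediate: int | None = None      # default: ceil(n/2) + 1 -> 13 for 24
    effect_behavior_hamd: float = 1.5   # standardized pre->post decrease
    effect_behavior_pcet: float = 0.8
    target_edge: tuple[int, int] = (0, 1)
    effect_target_dfc: float = 0.8      # standardized amplitude increase
    baseline_coupling: list[BaselineCoupling] = field(default_factory=list)
    noise_sd_hamd: float | None = 4.0   # score units; None -> from retest corr
    noise_sd_pcet: float | None = 4.0
    hamd_baseline_mean: float = 23.0
    pcet_baseline_mean: float = 14.0
    hamd_between_sd: float = 4.0
    pcet_between_sd: float = 4.0
    retest_correlation: float = 0.5     # within-participant behavior corr
    garch: GarchParams = field(default_factory=GarchParams)
    dcc: DccParams = field(default_factory=DccParams)
    background_rho: float = 0.10
    amplitude_sd: float = 0.35          # between-participant dFC amplitude SD
    amplitude_shared: bool = False      # one dynamics factor across active edges
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_nodes, self.n_trs) <= 0:
            raise ValueError("counts must be positive")
        i, j = self.target_edge
        if i == j or not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
            raise ValueError("target_edge indices must be valid and distinct")
        for c in self.baseline_coupling:
            a, b = c.edge
            if a == b or not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                raise ValueError(f"invalid coupling edge {c.edge}")
        for name in ("effect_behavior_hamd", "effect_behavior_pcet",
                     "effect_target_dfc"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_immediate is None:
            self.n_immediate = min(self.n_participants,
                                   self.n_participants // 2 + 1)


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery checks."""

    rho_paths: dict = field(default_factory=dict)
    # {(participant, session): {edge: rho_path array}}
    true_dfc: dict = field(default_factory=dict)
    # {(participant, session): {edge: variance of that rho path}}
    amplitudes: dict = field(default_factory=dict)
    # {(participant, session): {edge: amplitude multiplier}}
    coupling_coefficients: list = field(default_factory=list)
    latent_behavior: pd.DataFrame | None = None
    config: CohortConfig | None = None


@dataclass
class CohortDataset:
    """Participants x sessions of node timeseries plus a long behavior table."""

    timeseries: dict                    # {(participant_id, session): T x N array}
    behavior: pd.DataFrame              # participant_id, group, timepoint, scores
    node_labels: list[str]
    node_coords: pd.DataFrame           # label, x, y, z (mm)
    tr_seconds: float
    config: CohortConfig

    @property
    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.timeseries})


# ---------------------------------------------------------------------------
# elementary simulators
# ---------------------------------------------------------------------------

def simulate_garch_series(params: GarchParams, n_trs: int,
                          seed: int | np.random.Generator = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a GARCH(1,1) series with standard normal innovations.

    Returns the series and the true conditional-variance path.  sigma2_1 is
    the long-run variance omega/(1-alpha-beta).
    """
    if n_trs < 2:
        raise ValueError("n_trs must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n_trs)
    sigma2 = np.empty(n_trs)
    eps = np.empty(n_trs)
    sigma2[0] = params.long_run_variance
    eps[0] = np.sqrt(sigma2[0]) * z[0]
    for t in range(1, n_trs):
        sigma2[t] = (params.omega + params.alpha * eps[t - 1] ** 2
                     + params.beta * sigma2[t - 1])
        eps[t] = np.sqrt(sigma2[t]) * z[t]
    return eps, sigma2


def _simulate_dcc_standardized(dcc: DccParams, n_trs: int,
                               rng: np.random.Generator
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate standardized innovations with a DCC correlation path.

    Returns (z, rho) where z is (T, 2) and rho the generating conditional
    correlation at each t (rho_1 = rho_bar).
    """
    a, b, rho_bar = dcc.a, dcc.b, dcc.rho_bar
    z = np.empty((n_trs, 2))
    rho = np.empty(n_trs)
    q11 = q22 = 1.0
    q12 = rho_bar
    raw = rng.standard_normal((n_trs, 2))
    for t in range(n_trs):
        rho_t = q12 / np.sqrt(q11 * q22)
        rho_t = float(np.clip(rho_t, -0.999999, 0.999999))
        rho[t] = rho_t
        z[t, 0] = raw[t, 0]
        z[t, 1] = rho_t * raw[t, 0] + np.sqrt(1.0 - rho_t ** 2) * raw[t, 1]
        q11 = (1 - a - b) * 1.0 + a * z[t, 0] ** 2 + b * q11
        q22 = (1 - a - b) * 1.0 + a * z[t, 1] ** 2 + b * q22
        q12 = (1 - a - b) * rho_bar + a * z[t, 0] * z[t, 1] + b * q12
    return z, rho


def simulate_dcc_edge(garch1: GarchParams, garch2: GarchParams,
                      dcc: DccParams, n_trs: int,
                      seed: int | np.random.Generator = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a node pair whose correlation follows the DCC recursion.

    Returns (series_pair, true_rho_path) with series_pair of shape (T, 2).
    The variance of true_rho_path is the edge's true dFC.
    """
    if n_trs < 2:
        raise ValueError("n_trs must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z, rho = _simulate_dcc_standardized(dcc, n_trs, rng)
    pair = np.empty((n_trs, 2))
    for k, params in enumerate((garch1, garch2)):
        sigma2 = np.empty(n_trs)
        sigma2[0] = params.long_run_variance
        pair[0, k] = np.sqrt(sigma2[0]) * z[0, k]
        for t in range(1, n_trs):
            sigma2[t] = (params.omega + params.alpha * pair[t - 1, k] ** 2
                         + params.beta * sigma2[t - 1])
            pair[t, k] = np.sqrt(sigma2[t]) * z[t, k]
    return pair, rho


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _nearest_psd_corr(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, v = np.linalg.eigh(r)
    if w.min() >= 1e-10:
        return r
    w = np.clip(w, 1e-10, None)
    r2 = (v * w) @ v.T
    d = np.sqrt(np.diag(r2))
    return r2 / np.outer(d, d)


def _scan_timeseries(cfg: CohortConfig, active: dict, rng: np.random.Generator
                     ) -> tuple[np.ndarray, dict]:
    """One scan's T x N matrix given {edge: (rho_bar_p, amplitude_p)}.

    Each active edge's correlation path is a DCC-generated path whose
    deviations from its mean are scaled by the participant's amplitude;
    inactive pairs sit at the constant background correlation.  Node signals
    are the correlated innovations scaled by independent GARCH variance
    paths.
    """
    n, t = cfg.n_nodes, cfg.n_trs
    base = np.full((n, n), cfg.background_rho)
    np.fill_diagonal(base, 1.0)

    paths = {}
    for edge, (rho_bar_p, amp) in active.items():
        dcc_p = DccParams(cfg.dcc.a, cfg.dcc.b, rho_bar_p)
        _, rho_raw = _simulate_dcc_standardized(dcc_p, t, rng)
        rho = rho_bar_p + amp * (rho_raw - np.mean(rho_raw))
        paths[edge] = np.clip(rho, -0.95, 0.95)

    # innovations drawn from the (possibly time-varying) correlation matrix
    raw = rng.standard_normal((t, n))
    z = np.empty((t, n))
    if paths:
        for ti in range(t):
            r = base.copy()
            for (i, j), rho in paths.items():
                r[i, j] = r[j, i] = rho[ti]
            r = _nearest_psd_corr(r)
            z[ti] = np.linalg.cholesky(r) @ raw[ti]
    else:
        chol = np.linalg.cholesky(_nearest_psd_corr(base))
        z = raw @ chol.T

    y = np.empty((t, n))
    g = cfg.garch
    for k in range(n):
        sigma2 = np.empty(t)
        sigma2[0] = g.long_run_variance
        y[0, k] = np.sqrt(sigma2[0]) * z[0, k]
        for ti in range(1, t):
            sigma2[ti] = (g.omega + g.alpha * y[ti - 1, k] ** 2
                          + g.beta * sigma2[ti - 1])
            y[ti, k] = np.sqrt(sigma2[ti]) * z[ti, k]
    return y, paths


def simulate_cohort(config: CohortConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a full synthetic cohort and its ground-truth record.

    Every participant gets a ``baseline`` and ``week1`` scan; behavior rows
    cover baseline/week1/week4 (plus a zero-change ``pre_delay`` row for the
    delayed group).  Planted effects: standardized pre->post decreases on
    both behaviors, a standardized dFC-amplitude increase on the target
    edge, and the configured baseline-feature -> behavior couplings.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    pids = [f"sub-{k + 1:02d}" for k in range(n)]
    groups = ["immediate" if k < cfg.n_immediate else "delayed"
              for k in range(n)]

    active_edges = {tuple(sorted(cfg.target_edge))}
    for c in cfg.baseline_coupling:
        active_edges.add(tuple(sorted(c.edge)))
    active_edges = sorted(active_edges)

    # per-participant latent edge properties
    rho_bars = {e: np.clip(rng.normal(cfg.dcc.rho_bar, 0.10, n), -0.8, 0.8)
                for e in active_edges}
    if cfg.amplitude_shared:
        # one per-participant dynamics factor common to all active edges,
        # emulating a node whose overall correlation dynamics scale together
        shared = np.clip(rng.normal(1.0, cfg.amplitude_sd, n), 0.05, None)
        amps = {e: shared for e in active_edges}
    else:
        amps = {e: np.clip(rng.normal(1.0, cfg.amplitude_sd, n), 0.05, None)
                for e in active_edges}

    gt = GroundTruth(config=cfg)
    ts = {}
    target = tuple(sorted(cfg.target_edge))
    for k, pid in enumerate(pids):
        for session in ("baseline", "week1"):
            active = {}
            for e in active_edges:
                amp = amps[e][k]
                if e == target and session == "week1":
                    amp = amp + cfg.effect_target_dfc * cfg.amplitude_sd
                active[e] = (rho_bars[e][k], amp)
            y, paths = _scan_timeseries(cfg, active, rng)
            key = (pid, session)
            ts[key] = y
            gt.rho_paths[key] = paths
            gt.true_dfc[key] = {e: float(np.var(p, ddof=1))
                                for e, p in paths.items()}
            gt.amplitudes[key] = {e: active[e][1] for e in active}

    behavior, latent = _simulate_behavior(cfg, pids, groups, rho_bars, amps,
                                          rng)
    gt.latent_behavior = latent
    gt.coupling_coefficients = [
        {"edge": list(c.edge), "feature_kind": c.feature_kind,
         "behavior": c.behavior, "target": c.target,
         "beta": c.sign * c.strength} for c in cfg.baseline_coupling
    ]

    labels = [f"node{k:03d}" for k in range(cfg.n_nodes)]
    coords = pd.DataFrame({
        "label": labels,
        "x": rng.uniform(-70, 70, cfg.n_nodes).round(1),
        "y": rng.uniform(-100, 70, cfg.n_nodes).round(1),
        "z": rng.uniform(-50, 80, cfg.n_nodes).round(1),
    })
    dataset = CohortDataset(timeseries=ts, behavior=behavior,
                            node_labels=labels, node_coords=coords,
                            tr_seconds=cfg.tr_seconds, config=cfg)
    return dataset, gt


def _simulate_behavior(cfg, pids, groups, rho_bars, amps, rng):
    """Integer behavior scores with planted effects and couplings.

    A participant's score at a timepoint is a latent between-participant
    mean plus independent measurement noise, rounded and clipped to the
    instrument's range.  The planted treatment effect is standardized
    against the SD of a pre/post difference (sqrt(2) * noise SD), so a
    planted effect of 0.8 is recovered as a paired Cohen's d of about 0.8.
    The implied test-retest correlation is b_sd^2 / (b_sd^2 + n_sd^2)
    (0.5 at the default equal SDs); `retest_correlation`, when set, derives
    the noise SD from the between-participant SD instead.
    """
    n = len(pids)
    rows = []
    latent_rows = []

    def standardize(v):
        sd = np.std(v)
        return (v - np.mean(v)) / sd if sd > 0 else np.zeros_like(v)

    # coupling contributions per participant, in score units
    specs = {("hamd", "baseline"): np.zeros(n),
             ("hamd", "change"): np.zeros(n),
             ("pcet_persev", "baseline"): np.zeros(n),
             ("pcet_persev", "change"): np.zeros(n)}
    scale = {"hamd": cfg.hamd_between_sd, "pcet_persev": cfg.pcet_between_sd}
    for c in cfg.baseline_coupling:
        e = tuple(sorted(c.edge))
        feat = rho_bars[e] if c.feature_kind == "sfc" else amps[e]
        specs[(c.behavior, c.target)] = (specs[(c.behavior, c.target)]
                                         + c.sign * c.strength
                                         * standardize(feat)
                                         * scale[c.behavior])

    for name, mean0, b_sd, n_sd, effect, lo, hi in (
            ("hamd", cfg.hamd_baseline_mean, cfg.hamd_between_sd,
             cfg.noise_sd_hamd, cfg.effect_behavior_hamd, *HAMD_RANGE),
            ("pcet_persev", cfg.pcet_baseline_mean, cfg.pcet_between_sd,
             cfg.noise_sd_pcet, cfg.effect_behavior_pcet, *PCET_RANGE)):
        if n_sd is None:
            r = cfg.retest_correlation
            n_sd = b_sd * np.sqrt((1.0 - r) / r)
        latent = rng.normal(mean0, b_sd, n)
        eff_units = effect * np.sqrt(2.0) * n_sd  # paired-d scaling
        for k, pid in enumerate(pids):
            base_mean = latent[k] + specs[(name, "baseline")][k]
            change_mean = eff_units + specs[(name, "change")][k]
            tps = {"baseline": base_mean,
                   "week1": base_mean - change_mean,
                   "week4": base_mean - change_mean}
            if groups[k] == "delayed":
                tps["pre_delay"] = base_mean  # zero planted change
            for tp, mu in tps.items():
                score = int(np.clip(round(rng.normal(mu, n_sd)), lo, hi))
                rows.append({"participant_id": pid, "group": groups[k],
                             "timepoint": tp, "measure": name,
                             "score": score})
            latent_rows.append({"participant_id": pid, "measure": name,
                                "latent_baseline": base_mean,
                                "latent_change": change_mean})

    long = pd.DataFrame(rows)
    wide = long.pivot_table(index=["participant_id", "group", "timepoint"],
                            columns="measure", values="score",
                            aggfunc="first").reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={"hamd": "hamd", "pcet_persev": "pcet_persev"})
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    wide = wide.sort_values(["participant_id", "timepoint"],
                            key=lambda s: s.map(order) if s.name == "timepoint" else s
                            ).reset_index(drop=True)
    return wide, pd.DataFrame(latent_rows)


# ---------------------------------------------------------------------------
# voxel scene fixture
# ---------------------------------------------------------------------------

def simulate_voxel_scene(node_centers: np.ndarray, radius_mm: float,
                         grid_spec: tuple[tuple[int, int, int], float],
                         dropout_fraction: float = 0.0,
                         seed: int = 0, n_trs: int = 100,
                         voxel_noise_sd: float = 0.1):
    """Voxel-level 4D fixture for parcellation and coverage-QC tests.

    ``grid_spec`` is ((nx, ny, nz), spacing_mm) with the grid origin at 0.
    Voxels within ``radius_mm`` of a node center carry that node's latent
    standard-normal signal plus voxel noise; a ``dropout_fraction`` of each
    sphere's voxels is replaced by low-SNR noise and marked bad in the
    returned quality mask.  Spheres must be disjoint and fit inside the
    grid so the ground truth stays unambiguous.

    Returns (voxels [T x V], voxel_coords [V x 3 mm], quality_mask [V bool],
    latent_signals [T x n_nodes]).
    """
    centers = np.asarray(node_centers, dtype=float)
    (nx, ny, nz), spacing = grid_spec
    rng = np.random.default_rng(seed)
    if np.any(np.asarray(dropout_fraction) < 0) or np.any(np.asarray(dropout_fraction) > 1):
        raise ValueError("dropout_fraction must be in [0, 1]")

    extent = np.array([nx, ny, nz]) * spacing - spacing
    for c in centers:
        if np.any(c - radius_mm < 0) or np.any(c + radius_mm > extent):
            raise ValueError("sphere does not fit inside the grid")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) <= 2 * radius_mm:
                raise ValueError(f"spheres {i} and {j} overlap")

    grid = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                indexing="ij"), axis=-1).reshape(-1, 3)
    coords = grid * spacing
    v = coords.shape[0]

    latent = rng.standard_normal((n_trs, len(centers)))
    voxels = rng.standard_normal((n_trs, v)) * voxel_noise_sd
    quality = np.ones(v, dtype=bool)

    drop_frac = (list(dropout_fraction) if np.ndim(dropout_fraction)
                 else [dropout_fraction] * len(centers))
    for k, c in enumerate(centers):
        inside = np.flatnonzero(np.linalg.norm(coords - c, axis=1) <= radius_mm)
        voxels[:, inside] += latent[:, [k]]
        n_drop = int(round(drop_frac[k] * inside.size))
        if n_drop:
            dropped = rng.choice(inside, size=n_drop, replace=False)
            voxels[:, dropped] = rng.standard_normal((n_trs, n_drop)) * voxel_noise_sd
            quality[dropped] = False
    return voxels, coords, quality, latent


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, gt: GroundTruth, outdir: str | Path
                 ) -> Path:
    """Write a cohort directory: cohort.json, behavior.csv, nodes.tsv,
    ts/<participant>_<session>.tsv and ground_truth.json."""
    out = Path(outdir)
    (out / "ts").mkdir(parents=True, exist_ok=True)
    cfg = dataset.config

    def _jsonable(obj):
        if isinstance(obj, (GarchParams, DccParams)):
            return vars(obj)
        if isinstance(obj, BaselineCoupling):
            return {**vars(obj), "edge": list(obj.edge)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    cfg_dict = {k: _jsonable(v) for k, v in vars(cfg).items()
                if k != "baseline_coupling"}
    cfg_dict["baseline_coupling"] = [_jsonable(c) for c in cfg.baseline_coupling]
    (out / "cohort.json").write_text(json.dumps(cfg_dict, indent=2))

    dataset.behavior.to_csv(out / "behavior.csv", index=False)
    dataset.node_coords.to_csv(out / "nodes.tsv", sep="\t", index=False)
    for (pid, session), y in dataset.timeseries.items():
        pd.DataFrame(y, columns=dataset.node_labels).to_csv(
            out / "ts" / f"{pid}_{session}.tsv", sep="\t", index=False)

    gt_dict = {
        "true_dfc": {f"{p}_{s}": {f"{i}-{j}": v for (i, j), v in d.items()}
                     for (p, s), d in gt.true_dfc.items()},
        "amplitudes": {f"{p}_{s}": {f"{i}-{j}": v for (i, j), v in d.items()}
                       for (p, s), d in gt.amplitudes.items()},
        "coupling_coefficients": gt.coupling_coefficients,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_dict, indent=2))
    return out
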