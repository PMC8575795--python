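"""Plain-text readers/writers and the end-to-end pipeline driver.

All interchange is diffable delimited text: node timeseries as TSV with a
node-label header, behavior as long-format CSV, connectivity matrices as
labeled TSV, edge vectors and QC tables as CSV.  Every file the pipeline
writes starts with a provenance comment (package version, config hash,
seed) so a results tree can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity, cpm, stats
from .preprocess import PreprocessConfig, build_design, clean_timeseries
from .synthetic import (TIMEPOINTS, CohortConfig, simulate_cohort,
                        write_cohort)

__all__ = [
    "NodeTimeseries",
    "PipelineConfig",
    "read_timeseries",
    "write_timeseries",
    "read_behavior",
    "write_matrix",
    "read_matrix",
    "run_pipeline",
]

__version__ = "0.1.0"
log = logging.getLogger("dynafc")

REQUIRED_BEHAVIOR_COLUMNS = ("participant_id", "group", "timepoint",
                             "hamd", "pcet_persev")


@dataclass
class NodeTimeseries:
    """One scan's T x N node signal matrix with TR and node labels."""

    values: np.ndarray
    node_labels: list[str]
    tr_seconds: float = 2.0
    scan_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("timeseries must be 2-D (T x N)")
        if len(self.node_labels) != v.shape[1]:
            raise ValueError("one label per node column required")
        self.values = v

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class PipelineConfig:
    cohort_dir: str | Path = ""
    output_dir: str | Path = "dynafc_out"
    simulate: CohortConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cpm: "cpm.CpmConfig" = field(default_factory=lambda: cpm.CpmConfig())
    seed: int = 0
    verbosity: int = 1

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis rerun into a different directory hashes identically)."""
        def default(o):
            if hasattr(o, "__dict__"):
                return vars(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            return str(o)
        payload = {k: v for k, v in vars(self).items()
                   if k not in ("cohort_dir", "output_dir")}
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config_hash: str, seed: int) -> str:
    return (f"# dynafc v{__version__} | config={config_hash} | seed={seed}\n")


# ---------------------------------------------------------------------------
# timeseries
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, tr_seconds: float = 2.0
                    ) -> NodeTimeseries:
    """Read a TSV with a node-label header row and numeric body.

    Ragged rows, non-numeric cells and duplicate labels raise a parse
    error naming the offending line (1-based, counting the header).
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate node labels {dupes}")
    n = len(header)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n:
            raise ValueError(f"{path}:{lineno}: expected {n} columns, "
                             f"got {len(cells)}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})"
                             ) from None
    return NodeTimeseries(np.array(rows, dtype=float), header,
                          tr_seconds=tr_seconds, scan_id=path.stem)


def write_timeseries(ts: NodeTimeseries, path: str | Path,
                     provenance: str = "") -> Path:
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(provenance)
        fh.write("\t".join(ts.node_labels) + "\n")
        for row in ts.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def read_behavior(path: str | Path) -> pd.DataFrame:
    """Validated long-format behavior table.

    Requires participant_id, group, timepoint, hamd, pcet_persev columns;
    timepoints outside the study design are rejected; blank score cells
    become missing values, never zeros.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(REQUIRED_BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns {sorted(missing)}")
    bad = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad:
        raise ValueError(f"unknown timepoint labels {sorted(bad)}; "
                         f"allowed: {list(TIMEPOINTS)}")
    for col in ("hamd", "pcet_persev"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


# ---------------------------------------------------------------------------
# matrices and edge vectors
# ---------------------------------------------------------------------------

def write_matrix(mat: connectivity.ConnectivityMatrix, path: str | Path,
                 provenance: str = "") -> Path:
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(provenance)
        fh.write("label\t" + "\t".join(mat.node_labels) + "\n")
        for lab, row in zip(mat.node_labels, mat.values):
            fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_matrix(path: str | Path, kind: str) -> connectivity.ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = df.to_numpy(dtype=float)
    np.fill_diagonal(values, 0.0)
    return connectivity.ConnectivityMatrix(values, kind=kind,
                                           node_labels=list(df.columns),
                                           scan_id=Path(path).stem)


def write_edge_vector(vec: np.ndarray, n_nodes: int, path: str | Path,
                      provenance: str = "") -> Path:
    iu = np.triu_indices(n_nodes, k=1)
    df = pd.DataFrame({"node_i": iu[0], "node_j": iu[1], "value": vec})
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            fh.write(provenance)
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """simulate (optional) -> preprocess -> FC -> CPM -> stats.

    Writes a results tree under ``config.output_dir``; every file carries a
    provenance header and the log records per-stage counts.  Any stage
    error aborts with the stage named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(config.config_hash(), config.seed)
    if config.verbosity:
        logging.basicConfig(level=logging.INFO, format="%(message)s")

    stage = "simulate"
    try:
        if config.simulate is not None:
            cohort_dir = out / "cohort"
            dataset, _ = simulate_cohort(config.simulate)
            write_cohort(dataset, _, cohort_dir)
        else:
            cohort_dir = Path(config.cohort_dir)
            if not cohort_dir.is_dir():
                raise FileNotFoundError(f"cohort dir {cohort_dir} not found")
        behavior = read_behavior(cohort_dir / "behavior.csv")
        ts_files = sorted((cohort_dir / "ts").glob("*.tsv"))
        log.info("[simulate] %d scans, %d behavior rows",
                 len(ts_files), len(behavior))

        stage = "preprocess"
        scans: dict[tuple[str, str], NodeTimeseries] = {}
        pp = config.preprocess
        for f in ts_files:
            ts = read_timeseries(f, tr_seconds=pp.tr_seconds)
            design = build_design(ts.n_trs, pp)
            cleaned = clean_timeseries(ts.values, design)
            pid, session = f.stem.rsplit("_", 1)
            scans[(pid, session)] = NodeTimeseries(
                cleaned, ts.node_labels, ts.tr_seconds, scan_id=f.stem)
        log.info("[preprocess] cleaned %d scans (%d design columns)",
                 len(scans), design.shape[1])

        stage = "fc"
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        sfc_vecs: dict[tuple[str, str], np.ndarray] = {}
        dfc_vecs: dict[tuple[str, str], np.ndarray] = {}
        for key, ts in scans.items():
            s = connectivity.static_fc(ts.values, ts.node_labels,
                                       scan_id=ts.scan_id)
            d, qc = connectivity.dynamic_fc(ts.values, ts.node_labels,
                                            scan_id=ts.scan_id)
            sfc_vecs[key] = connectivity.edge_vectorize(s.values)
            dfc_vecs[key] = connectivity.edge_vectorize(d.values)
            write_matrix(s, fc_dir / f"{ts.scan_id}_sfc.tsv", header)
            write_matrix(d, fc_dir / f"{ts.scan_id}_dfc.tsv", header)
            with (fc_dir / f"{ts.scan_id}_dfc_qc.csv").open("w") as fh:
                fh.write(header)
                qc.to_csv(fh, index=False)
        n_nodes = next(iter(scans.values())).n_nodes
        log.info("[fc] %d scans x %d edges", len(scans),
                 connectivity.n_edges(n_nodes))

        stage = "stats"
        stats_report = _stats_stage(behavior, sfc_vecs, dfc_vecs, config)
        with (out / "stats.json").open("w") as fh:
            fh.write(header)
            json.dump(stats_report, fh, indent=2)

        stage = "cpm"
        _cpm_stage(behavior, sfc_vecs, dfc_vecs, n_nodes, config, out, header)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "pipeline.json").write_text(
        header + json.dumps({"stages": ["simulate", "preprocess", "fc",
                                        "stats", "cpm"],
                             "n_scans": len(scans),
                             "n_nodes": n_nodes}, indent=2))
    return out


def _stats_stage(behavior, sfc_vecs, dfc_vecs, config) -> dict:
    report: dict = {}
    for measure in ("hamd", "pcet_persev"):
        wide = behavior.pivot_table(index="participant_id",
                                    columns="timepoint", values=measure,
                                    aggfunc="first")
        if {"baseline", "week1"} <= set(wide.columns):
            pair = wide[["baseline", "week1"]].dropna()
            res = stats.paired_t(pair["baseline"], pair["week1"])
            report[f"{measure}_baseline_vs_week1"] = res.summary()
        cols = [c for c in ("baseline", "week1", "week4") if c in wide.columns]
        if len(cols) == 3:
            complete = wide[cols].dropna()
            if len(complete) >= 2:
                res = stats.rm_anova_oneway(complete)
                report[f"{measure}_rm_anova"] = res.summary()
    return report


def _cpm_stage(behavior, sfc_vecs, dfc_vecs, n_nodes, config, out, header):
    pids = sorted({p for p, s in sfc_vecs if (p, "baseline") in sfc_vecs})
    delta = stats.delta_scores(behavior, "baseline", "week1", "pcet_persev")
    pids = [p for p in pids if p in delta.index]
    if len(pids) < 5:
        log.info("[cpm] skipped (fewer than 5 complete participants)")
        return
    sfc = np.vstack([sfc_vecs[(p, "baseline")] for p in pids])
    dfc = np.vstack([dfc_vecs[(p, "baseline")] for p in pids])
    y = delta.loc[pids].to_numpy(dtype=float)
    result = cpm.threshold_sweep(sfc, dfc, y, config.cpm, n_nodes=n_nodes)
    curve = result.performance_curve()
    with (out / "cpm_performance.csv").open("w") as fh:
        fh.write(header)
        curve.to_csv(fh, index=False)
    stable = cpm.stable_edges(result, result.best)
    with (out / "cpm_stable_edges.csv").open("w") as fh:
        fh.write(header)
        stable.to_csv(fh, index=False)
    log.info("[cpm] n=%d, best p<%.3f, r=%s, %d stable edges", len(pids),
             result.best_threshold,
             None if result.best.performance_r is None
             else round(result.best.performance_r, 3), len(stable))
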