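"""Connectome-based predictive modeling (CPM) with leave-one-out CV.

CPM predicts a behavioral score from baseline connectivity: within each
training fold, edges whose Pearson correlation with behavior passes a
p-value threshold are selected and split by correlation sign; each
participant's feature is the sum over positively selected edges minus the
sum over negatively selected edges; an ordinary least-squares line maps
that summary onto behavior; the model is applied to the held-out
participant.  Performance is the Pearson r between observed and
out-of-fold predicted scores across all participants.  Because n is small
and the edge pool large, the selection threshold is swept over a grid
(p < 0.010 to 0.050) and edges selected in at least 75% of folds are
reported as the model's stable features.

Feature spaces: static FC edges, dynamic FC edges, or both concatenated
(selection is correlation-based and thus scale-free, so no rescaling is
applied).  Node-subset models keep only edges with at least one endpoint
in the subset (e.g., "edges emanating from the ACC").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import edge_nodes, n_edges

__all__ = [
    "CpmConfig",
    "ThresholdResult",
    "CpmResult",
    "select_edges",
    "summarize_features",
    "cpm_loocv",
    "threshold_sweep",
    "stable_edges",
    "node_subset_features",
    "sign_reversal_report",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.010, 0.0501, 0.005), 4))


@dataclass
class CpmConfig:
    p_thresholds: tuple = DEFAULT_THRESHOLDS
    feature_space: str = "both"          # "sfc" | "dfc" | "both"
    node_subset: list | str = "full"
    stability_fraction: float = 0.75
    behavior_name: str = ""
    direction: str = "baseline->change"  # bookkeeping label
    combine: str = "difference"          # "difference" | "two-predictor"

    def __post_init__(self) -> None:
        for p in self.p_thresholds:
            if not 0 < p <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        if not 0 < self.stability_fraction <= 1:
            raise ValueError("stability_fraction must lie in (0, 1]")
        if self.feature_space not in ("sfc", "dfc", "both"):
            raise ValueError("feature_space must be sfc, dfc or both")
        if self.combine not in ("difference", "two-predictor"):
            raise ValueError("combine must be 'difference' or 'two-predictor'")


@dataclass
class ThresholdResult:
    """LOO-CV outcome at a single selection threshold."""

    p_thresh: float
    predictions: np.ndarray              # one out-of-fold value per participant
    observed: np.ndarray
    performance_r: float | None          # None when undefined (constant preds)
    selection_frequency: np.ndarray      # per edge column, in [0, 1]
    dominant_sign: np.ndarray            # +1 / -1 / 0 per edge column
    fold_edges: list                     # per fold: (pos_idx, neg_idx)
    flagged_folds: list                  # folds that selected zero edges


@dataclass
class CpmResult:
    config: CpmConfig
    column_space: np.ndarray             # "sfc"/"dfc" label per feature column
    column_edge: list                    # (i, j) node pair per feature column
    per_threshold: dict = field(default_factory=dict)  # p -> ThresholdResult
    best_threshold: float | None = None

    @property
    def best(self) -> ThresholdResult:
        return self.per_threshold[self.best_threshold]

    def performance_curve(self) -> pd.DataFrame:
        rows = [{"p_thresh": p, "r": tr.performance_r,
                 "n_flagged_folds": len(tr.flagged_folds)}
                for p, tr in sorted(self.per_threshold.items())]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# selection and summarization
# ---------------------------------------------------------------------------

def _edge_behavior_r(features: np.ndarray, behavior: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r and two-tailed p against behavior."""
    n = behavior.size
    xc = features - features.mean(axis=0)
    yc = behavior - behavior.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(sx == 0, np.nan, p)  # constant edges never selected
    return r, p


def select_edges(features: np.ndarray, behavior: np.ndarray, p_thresh: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Edges whose correlation with behavior passes p < p_thresh, by sign.

    Returns (positive edge indices, negative edge indices).  Constant edge
    columns are skipped with a warning; constant behavior is an error.
    """
    features = np.asarray(features, dtype=float)
    behavior = np.asarray(behavior, dtype=float).ravel()
    if features.shape[0] != behavior.size:
        raise ValueError("features and behavior are not row-aligned")
    if behavior.size < 4:
        raise ValueError("need at least 4 participants")
    if behavior.std() == 0:
        raise ValueError("constant behavior")
    if np.any(features.std(axis=0) == 0):
        warnings.warn("constant edge column(s) skipped in selection",
                      stacklevel=2)
    r, p = _edge_behavior_r(features, behavior)
    selected = p < p_thresh  # NaN p (constant column) compares False
    pos = np.flatnonzero(selected & (r > 0))
    neg = np.flatnonzero(selected & (r < 0))
    return pos, neg


def summarize_features(features_row: np.ndarray, positive: np.ndarray,
                       negative: np.ndarray) -> float:
    """Sum over positive edges minus sum over negative edges (empty -> 0)."""
    positive = np.asarray(positive, dtype=int)
    negative = np.asarray(negative, dtype=int)
    if np.intersect1d(positive, negative).size:
        raise ValueError("positive and negative edge sets must be disjoint")
    row = np.asarray(features_row, dtype=float)
    return float(row[positive].sum() - row[negative].sum())


# ---------------------------------------------------------------------------
# LOO-CV
# ---------------------------------------------------------------------------

def _assemble_features(sfc: np.ndarray | None, dfc: np.ndarray | None,
                       config: CpmConfig, n_nodes: int | None
                       ) -> tuple[np.ndarray, np.ndarray, list]:
    """Concatenate the requested feature spaces and resolve edge labels."""
    blocks, spaces, edges = [], [], []
    wanted = (("sfc", sfc), ("dfc", dfc))
    for name, block in wanted:
        if config.feature_space not in (name, "both"):
            continue
        if block is None:
            raise ValueError(f"feature space {config.feature_space!r} "
                             f"requires a {name} table")
        block = np.asarray(block, dtype=float)
        if n_nodes is not None and block.shape[1] != n_edges(n_nodes):
            raise ValueError(f"{name} table has {block.shape[1]} columns; "
                             f"{n_edges(n_nodes)} expected for {n_nodes} nodes")
        cols = block.shape[1]
        if n_nodes is not None:
            pair = [edge_nodes(c, n_nodes) for c in range(cols)]
        else:
            pair = [(-1, c) for c in range(cols)]
        if config.node_subset != "full" and n_nodes is not None:
            keep = _subset_columns(pair, config.node_subset)
            block, pair = block[:, keep], [pair[k] for k in keep]
        blocks.append(block)
        spaces.extend([name] * block.shape[1])
        edges.extend(pair)
    return np.column_stack(blocks), np.asarray(spaces), edges


def _subset_columns(pairs: list, node_subset) -> np.ndarray:
    subset = set(node_subset)
    if not subset:
        raise ValueError("empty node subset")
    return np.flatnonzero([i in subset or j in subset for i, j in pairs])


def _fit_fold(x_train: np.ndarray, y_train: np.ndarray, p_thresh: float,
              combine: str):
    """Selection + linear fit on a training fold; returns a predictor."""
    pos, neg = select_edges(x_train, y_train, p_thresh)
    if pos.size + neg.size == 0:
        mean = float(y_train.mean())
        return pos, neg, (lambda row: mean), True
    if combine == "difference":
        s = np.array([summarize_features(r, pos, neg) for r in x_train])
        if s.std() == 0:
            mean = float(y_train.mean())
            return pos, neg, (lambda row: mean), True
        slope, intercept = np.polyfit(s, y_train, 1)
        return pos, neg, (lambda row, a=slope, b=intercept:
                          float(a * summarize_features(row, pos, neg) + b)), False
    # two-predictor variant: separate positive and negative sums
    sp = x_train[:, pos].sum(axis=1) if pos.size else np.zeros(len(y_train))
    sn = x_train[:, neg].sum(axis=1) if neg.size else np.zeros(len(y_train))
    design = np.column_stack([np.ones_like(y_train), sp, sn])
    coef, *_ = np.linalg.lstsq(design, y_train, rcond=None)

    def predict(row, c=coef, pos=pos, neg=neg):
        return float(c[0] + c[1] * row[pos].sum() + c[2] * row[neg].sum())
    return pos, neg, predict, False


def cpm_loocv(sfc: np.ndarray | None, dfc: np.ndarray | None,
              behavior: np.ndarray, config: CpmConfig | None = None,
              p_thresh: float | None = None, n_nodes: int | None = None
              ) -> ThresholdResult:
    """Leave-one-participant-out CPM at a single selection threshold.

    Selection and fitting use only the n-1 training rows of each fold; the
    held-out row never influences its own fold's model.  Folds selecting
    zero edges predict the training mean and are flagged.
    """
    config = config or CpmConfig()
    if p_thresh is None:
        p_thresh = config.p_thresholds[0]
    x, spaces, edges = _assemble_features(sfc, dfc, config, n_nodes)
    y = np.asarray(behavior, dtype=float).ravel()
    n = y.size
    if x.shape[0] != n:
        raise ValueError("feature tables not row-aligned with behavior")
    if n < 5:
        raise ValueError("need at least 5 participants for LOO-CV")

    preds = np.empty(n)
    counts = np.zeros(x.shape[1])
    sign_votes = np.zeros(x.shape[1])
    fold_edges, flagged = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n):
            keep = np.arange(n) != i
            pos, neg, predict, is_flagged = _fit_fold(
                x[keep], y[keep], p_thresh, config.combine)
            preds[i] = predict(x[i])
            counts[pos] += 1
            counts[neg] += 1
            sign_votes[pos] += 1
            sign_votes[neg] -= 1
            fold_edges.append((pos, neg))
            if is_flagged:
                flagged.append(i)

    if np.ptp(preds) == 0 or np.ptp(y) == 0:
        performance = None  # undefined, not silently 0
    else:
        performance = float(np.corrcoef(y, preds)[0, 1])
    return ThresholdResult(
        p_thresh=float(p_thresh), predictions=preds, observed=y,
        performance_r=performance, selection_frequency=counts / n,
        dominant_sign=np.sign(sign_votes).astype(int),
        fold_edges=fold_edges, flagged_folds=flagged)


def threshold_sweep(sfc: np.ndarray | None, dfc: np.ndarray | None,
                    behavior: np.ndarray, config: CpmConfig | None = None,
                    n_nodes: int | None = None) -> CpmResult:
    """Run LOO-CV per threshold on the grid and declare a best model.

    Best = maximal performance r; ties (and all-undefined grids) break
    toward the stricter (smaller) threshold.
    """
    config = config or CpmConfig()
    _, spaces, edges = _assemble_features(sfc, dfc, config, n_nodes)
    result = CpmResult(config=config, column_space=spaces, column_edge=edges)
    for p in config.p_thresholds:
        result.per_threshold[float(p)] = cpm_loocv(
            sfc, dfc, behavior, config, p_thresh=p, n_nodes=n_nodes)

    def sort_key(p):
        r = result.per_threshold[p].performance_r
        return (-(r if r is not None else -np.inf), p)
    result.best_threshold = min(result.per_threshold, key=sort_key)
    return result


# ---------------------------------------------------------------------------
# stability and reversal reporting
# ---------------------------------------------------------------------------

def stable_edges(result: CpmResult, threshold_result: ThresholdResult,
                 stability_fraction: float | None = None) -> pd.DataFrame:
    """Edges selected in at least ``stability_fraction`` of folds.

    Labeled by feature space (sfc/dfc) and the dominant sign of their
    correlation with behavior across folds.
    """
    frac = (result.config.stability_fraction if stability_fraction is None
            else stability_fraction)
    keep = np.flatnonzero(threshold_result.selection_frequency >= frac)
    rows = [{"column": int(k),
             "node_i": result.column_edge[k][0],
             "node_j": result.column_edge[k][1],
             "feature_space": str(result.column_space[k]),
             "sign": ("positive" if threshold_result.dominant_sign[k] > 0
                      else "negative"),
             "frequency": float(threshold_result.selection_frequency[k])}
            for k in keep]
    return pd.DataFrame(rows, columns=["column", "node_i", "node_j",
                                       "feature_space", "sign", "frequency"])


def node_subset_features(edge_table: np.ndarray, node_subset, n_nodes: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Restrict an edge table to edges with an endpoint in the subset.

    Returns (restricted table, kept column indices).
    """
    table = np.asarray(edge_table, dtype=float)
    if table.shape[1] != n_edges(n_nodes):
        raise ValueError("edge table width does not match node count")
    subset = set(node_subset)
    if not subset:
        raise ValueError("empty node subset")
    if not subset <= set(range(n_nodes)):
        raise ValueError("node subset contains invalid ids")
    pairs = [edge_nodes(c, n_nodes) for c in range(table.shape[1])]
    keep = np.flatnonzero([i in subset or j in subset for i, j in pairs])
    return table[:, keep], keep


def sign_reversal_report(baseline_models: CpmResult,
                         change_models: CpmResult) -> dict:
    """Compare edge-behavior correlation signs across prediction directions.

    For edges stable (at each result's stability fraction, best threshold)
    in *both* the baseline-predicting and the change-predicting models,
    tabulate the (sign_baseline, sign_change) cells.  An edge whose signs
    differ sits in a "reversed" cell — the signature of features that track
    better baseline behavior but smaller treatment-related change.
    """
    sb = stable_edges(baseline_models, baseline_models.best)
    sc = stable_edges(change_models, change_models.best)
    eb = {(r.node_i, r.node_j, r.feature_space): r.sign
          for r in sb.itertuples()}
    ec = {(r.node_i, r.node_j, r.feature_space): r.sign
          for r in sc.itertuples()}
    common = sorted(set(eb) & set(ec))
    cells = {("positive", "positive"): 0, ("positive", "negative"): 0,
             ("negative", "positive"): 0, ("negative", "negative"): 0}
    rows = []
    for key in common:
        cells[(eb[key], ec[key])] += 1
        rows.append({"node_i": key[0], "node_j": key[1],
                     "feature_space": key[2], "sign_baseline": eb[key],
                     "sign_change": ec[key],
                     "reversed": eb[key] != ec[key]})
    n_rev = cells[("positive", "negative")] + cells[("negative", "positive")]
    return {
        "edges": pd.DataFrame(rows, columns=["node_i", "node_j",
                                             "feature_space", "sign_baseline",
                                             "sign_change", "reversed"]),
        "cells": cells,
        "n_common": len(common),
        "n_reversed": n_rev,
        "note": ("no stable edges shared between directions"
                 if not common else ""),
    }
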