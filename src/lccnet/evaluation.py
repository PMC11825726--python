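"""Scoring of estimates against ground truth: matrix correlations,
confusion counts and ROC-style threshold scans, connected-component
diagnostics, and the method x density sweep."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .estimators import estimate_with
from .hopf_sim import HopfParams, simulate_hopf
from .linear_sim import LinearParams, build_linear_gt, simulate_linear
from .netgen import generate_network

__all__ = [
    "EvaluationReport",
    "ROCCurve",
    "SweepResult",
    "matrix_correlation",
    "binarize",
    "confusion_counts",
    "evaluate",
    "roc_scan",
    "connected_component_counts",
    "method_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Pearson score plus confusion counts at one binarization threshold."""

    pearson_gt_est: float
    confusion: dict
    threshold: float


@dataclass
class ROCCurve:
    """Confusion counts as the binarization threshold varies (ascending)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    tp_counts: np.ndarray
    fp_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp_counts,
                "fp": self.fp_counts,
                "tpr": self.tpr,
                "fpr": self.fpr,
            }
        )


@dataclass
class SweepResult:
    """Mean GT-vs-estimate scores on a (method x connection probability) grid."""

    methods: list[str]
    p_grid: np.ndarray
    mean_r: np.ndarray
    n_realizations: int
    n_failures: int = 0

    def to_frame(self, round_to: int = 2) -> pd.DataFrame:
        """Tabulate like the published comparison matrices (2 decimals)."""
        return pd.DataFrame(
            np.round(self.mean_r, round_to),
            index=self.methods,
            columns=[f"{p:g}" for p in self.p_grid],
        )


def _offdiag(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return m[~np.eye(m.shape[0], dtype=bool)]


def matrix_correlation(
    gt: np.ndarray, est: np.ndarray, include_diagonal: bool = False
) -> float:
    """Pearson correlation of the flattened (off-diagonal) entries.

    The diagonal is excluded by default: it is structurally zero in both
    ground truth and estimates and would inflate the score.
    """
    gt = np.asarray(gt, dtype=float)
    est = np.asarray(est, dtype=float)
    if gt.shape != est.shape:
        raise ValueError("shape mismatch")
    a, b = (gt.ravel(), est.ravel()) if include_diagonal else (_offdiag(gt), _offdiag(est))
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    return float(pearsonr(a, b).statistic)


def binarize(m: np.ndarray, thr: float) -> np.ndarray:
    """Entries strictly above ``thr`` become 1, everything else 0; diagonal 0.

    The strict ``>`` mirrors the clamping rule of
    :func:`~lccnet.estimators.threshold_matrix` (which zeroes values *lower
    than* its threshold), so the two are consistent at the boundary.
    """
    if not np.isfinite(thr):
        raise ValueError("thr must be finite")
    b = (np.asarray(m, dtype=float) > thr).astype(int)
    np.fill_diagonal(b, 0)
    return b


def confusion_counts(gt_binary: np.ndarray, est_binary: np.ndarray) -> dict:
    """TP/FP/FN/TN over off-diagonal positions of two binary matrices."""
    gt_binary = np.asarray(gt_binary)
    est_binary = np.asarray(est_binary)
    if gt_binary.shape != est_binary.shape:
        raise ValueError("shape mismatch")
    for name, m in (("gt", gt_binary), ("est", est_binary)):
        if not np.isin(_offdiag(m), (0, 1)).all():
            raise ValueError(f"{name} matrix is not binary")
    g = _offdiag(gt_binary).astype(bool)
    e = _offdiag(est_binary).astype(bool)
    return {
        "TP": int(np.sum(g & e)),
        "FP": int(np.sum(~g & e)),
        "FN": int(np.sum(g & ~e)),
        "TN": int(np.sum(~g & ~e)),
    }


def evaluate(gt: np.ndarray, est: np.ndarray, threshold: float = 0.0) -> EvaluationReport:
    """Score an estimate: off-diagonal Pearson plus confusion at a threshold."""
    return EvaluationReport(
        pearson_gt_est=matrix_correlation(gt, est),
        confusion=confusion_counts(binarize(gt, 0.0), binarize(est, threshold)),
        threshold=threshold,
    )


def roc_scan(
    gt_binary: np.ndarray, est_weighted: np.ndarray, thresholds: np.ndarray
) -> ROCCurve:
    """Confusion counts at every binarization threshold (sorted ascending).

    TP and FP counts (hence TPR and FPR) are non-increasing in the
    threshold.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    gt_b = binarize(gt_binary, 0.0)
    tp, fp = [], []
    for thr in thresholds:
        c = confusion_counts(gt_b, binarize(est_weighted, thr))
        tp.append(c["TP"])
        fp.append(c["FP"])
    tp = np.array(tp)
    fp = np.array(fp)
    pos = max(int(np.sum(_offdiag(gt_b))), 1)
    neg = max(gt_b.shape[0] * (gt_b.shape[0] - 1) - pos, 1)
    return ROCCurve(thresholds, tp / pos, fp / neg, tp, fp)


def connected_component_counts(gt: np.ndarray) -> dict:
    """Weakly and strongly connected component counts of the nonzero digraph."""
    gt = np.asarray(gt)
    if gt.ndim != 2 or gt.shape[0] != gt.shape[1]:
        raise ValueError("gt must be square")
    n = gt.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(gt)
    # weights[i, j] is j -> i, so the edge runs from the column to the row
    g.add_edges_from(zip(cols.tolist(), rows.tolist()))
    return {
        "weak": nx.number_weakly_connected_components(g),
        "strong": nx.number_strongly_connected_components(g),
    }


def method_sweep(
    model: str,
    n_nodes: int,
    p_grid,
    methods,
    n_realizations: int = 100,
    master_seed: int = 0,
    hopf_params: HopfParams | None = None,
    linear_params: LinearParams | None = None,
    method_kwargs: dict | None = None,
) -> SweepResult:
    """Mean GT-vs-estimate Pearson over a (method x density) grid.

    For each cell: generate a network, simulate the chosen model, run every
    requested estimator on the same realization, and score against the
    ground truth; realization seeds are spawned reproducibly from
    ``master_seed``.  Individual realization failures are logged and
    excluded, with the total failure count reported.
    """
    if model not in ("hopf", "linear"):
        raise ValueError(f"model must be 'hopf' or 'linear', got {model!r}")
    p_grid = np.asarray(list(p_grid), dtype=float)
    methods = list(methods)
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    method_kwargs = method_kwargs or {}
    hopf_params = hopf_params or HopfParams()
    linear_params = linear_params or LinearParams()

    seed_grid = np.random.SeedSequence(master_seed).generate_state(
        p_grid.size * n_realizations
    ).reshape(p_grid.size, n_realizations) % (2**31)

    scores = np.full((len(methods), p_grid.size, n_realizations), np.nan)
    failures = 0
    for pi, p in enumerate(p_grid):
        for k in range(n_realizations):
            seed = int(seed_grid[pi, k])
            try:
                if model == "hopf":
                    net = generate_network(n_nodes, p, seed=seed)
                    gt = net.weights
                    ts = simulate_hopf(hopf_params, net, seed=seed)
                else:
                    C = build_linear_gt(n_nodes, p, seed=seed)
                    gt = C.copy()
                    np.fill_diagonal(gt, 0.0)
                    ts = simulate_linear(
                        C, LinearParams(
                            sigma=linear_params.sigma,
                            dt=linear_params.dt,
                            duration=linear_params.duration,
                            seed=seed,
                        )
                    )
                for mi, method in enumerate(methods):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = estimate_with(method, ts, **dict(method_kwargs.get(method, {})))
                    scores[mi, pi, k] = matrix_correlation(gt, est.weights)
            except Exception:  # noqa: BLE001 -- a cell failure must not kill the sweep
                failures += 1
                logger.exception("realization failed (p=%g, seed=%d)", p, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = np.nanmean(scores, axis=2)
    return SweepResult(methods, p_grid, mean_r, n_realizations, failures)
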