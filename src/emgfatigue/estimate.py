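"""sEMG-to-grasp-force estimation and the three-method comparison.

Three feature configurations are compared on the same windows:

* TMLM — time-domain only: one RMS column per muscle channel;
* CMLM — combined: RMS columns plus MNF/ARV columns per channel;
* FMLM — fatigue-augmented: RMS columns plus one MFL column.

Each drives a three-layer feed-forward network (single hidden layer with
log-sigmoid units, linear output) regressing windowed mean grasp force, with
a hidden-node sweep, repeated retraining, blocked k-fold cross-validation and
R^2 = 1 - SSE/SST scoring, followed by percent-improvement arithmetic and
paired t-tests between methods.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import MinMaxScaler

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["MethodKind", "NetworkSpec", "CVSpec", "EstimationResult",
           "ComparisonReport", "assemble", "ScalerPair", "log_sigmoid",
           "train_net", "r2", "blocked_folds", "run_cv", "percent_increase",
           "compare", "evaluate_methods"]


class MethodKind(str, enum.Enum):
    TMLM = "TMLM"   # time-domain (RMS) only
    CMLM = "CMLM"   # RMS + MNF/ARV
    FMLM = "FMLM"   # RMS + MFL


@dataclass(frozen=True)
class NetworkSpec:
    """Three-layer network: hidden log-sigmoid units, linear output."""

    hidden_nodes: int = 10
    max_epochs: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")


@dataclass(frozen=True)
class CVSpec:
    folds: int = 4
    retrains: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.retrains < 1:
            raise ValueError("retrains must be >= 1")


def log_sigmoid(x):
    """Hidden-unit transfer function S(x) = 1/(1 + e^-x)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def assemble(method: MethodKind | str, fm: FeatureMatrix
             ) -> tuple[np.ndarray, np.ndarray]:
    """Build the design matrix and force target for one method."""
    method = MethodKind(method)
    y = fm.mean_force
    if method is MethodKind.TMLM:
        X = fm.rms.copy()
    elif method is MethodKind.CMLM:
        X = np.hstack([fm.rms, fm.mnf_arv])
    else:  # FMLM
        if np.isnan(fm.mfl).any():
            raise ValueError(
                "FMLM needs the fatigue column filled: assign MFL from the "
                "session's MVC probes before assembling")
        X = np.hstack([fm.rms, fm.mfl[:, None]])
    return X, y.copy()


class ScalerPair:
    """Min-max scaling of inputs and target, fitted on training data only.

    Columns and the target are mapped to [0, 1] using training-set ranges;
    test values outside the training range scale outside [0, 1] (no clipping).
    A zero-range column maps to constant 0.  Predictions are inverse-mapped
    back to newtons before scoring.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ScalerPair":
        self._xs = MinMaxScaler(clip=False).fit(X)
        zero = self._xs.data_range_ == 0
        if zero.any():
            logger.info("ScalerPair: %d zero-range column(s) mapped to 0",
                        int(zero.sum()))
        self._ys = MinMaxScaler(clip=False).fit(y.reshape(-1, 1))
        return self

    def transform(self, X: np.ndarray, y: np.ndarray | None = None):
        Xs = self._xs.transform(X)
        if y is None:
            return Xs
        return Xs, self._ys.transform(y.reshape(-1, 1)).ravel()

    def inverse_y(self, y_scaled: np.ndarray) -> np.ndarray:
        return self._ys.inverse_transform(
            np.asarray(y_scaled).reshape(-1, 1)).ravel()


@dataclass
class TrainedNet:
    model: MLPRegressor
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def train_net(X: np.ndarray, y: np.ndarray, spec: NetworkSpec = NetworkSpec(),
              seed: int = 0) -> TrainedNet:
    """Train the single-hidden-layer log-sigmoid network on scaled data.

    Full-batch gradient-based training (L-BFGS over the backpropagated
    gradient); deterministic for a fixed (seed, data) pair.  Non-convergence
    within the epoch budget is flagged, not raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3 * spec.hidden_nodes:
        raise ValueError(
            f"{X.shape[0]} training rows is too few for {spec.hidden_nodes} "
            "hidden nodes (need >= 3x)")
    model = MLPRegressor(hidden_layer_sizes=(spec.hidden_nodes,),
                         activation="logistic", solver="lbfgs",
                         max_iter=spec.max_epochs, tol=spec.tol,
                         random_state=seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence handled via flag
        model.fit(X, y)
    converged = model.n_iter_ < spec.max_epochs
    if not converged:
        logger.debug("train_net: epoch budget exhausted (loss %.3g)",
                     model.loss_)
    return TrainedNet(model, converged)


def r2(actual, predicted) -> float:
    """Coefficient of determination, 1 - SSE/SST.

    May be negative for fits worse than the mean; NaN when the actual values
    have zero variance.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("actual and predicted must be equal-length, n >= 2")
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0:
        return float("nan")
    sse = float(np.sum((a - p) ** 2))
    return 1.0 - sse / sst


def blocked_folds(n_rows: int, folds: int,
                  groups: np.ndarray | None = None) -> list[np.ndarray]:
    """Contiguous-block fold assignment, stratified over groups.

    Within each group (session) the rows are split into ``folds`` contiguous
    time blocks; fold j tests on block j of every group.  Adjacent windows
    overlap in time, so contiguous blocks avoid train/test leakage that random
    shuffling would cause.
    """
    if groups is None:
        groups = np.zeros(n_rows, dtype=int)
    groups = np.asarray(groups)
    test_idx: list[list[int]] = [[] for _ in range(folds)]
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        for j, chunk in enumerate(np.array_split(idx, folds)):
            test_idx[j].extend(chunk.tolist())
    return [np.sort(np.array(t, dtype=int)) for t in test_idx]


@dataclass
class EstimationResult:
    method: MethodKind
    per_node: dict[int, tuple[float, float, np.ndarray]]  # mean, sd, raw R^2s
    best_node: int
    best_mean_r2: float
    best_sd_r2: float
    predictions: tuple[np.ndarray, np.ndarray]  # (actual, predicted) at best

    def per_node_frame(self) -> pd.DataFrame:
        rows = [{"nodes": k, "r2_mean": m, "r2_sd": s}
                for k, (m, s, _) in sorted(self.per_node.items())]
        return pd.DataFrame(rows)


def run_cv(X: np.ndarray, y: np.ndarray, cv: CVSpec = CVSpec(),
           node_range=range(2, 21), seed: int | None = None,
           groups: np.ndarray | None = None,
           method: MethodKind = MethodKind.TMLM,
           network: NetworkSpec = NetworkSpec()) -> EstimationResult:
    """Node sweep with retrains and blocked k-fold cross-validation.

    For each hidden-node count the network is retrained ``cv.retrains`` times
    per fold with fresh initialisation seeds; R^2 is computed on each held-out
    fold in newtons, and mean +/- sd pooled over all retrain-fold values.
    Scalers are fitted on training folds only.  Fully deterministic under the
    seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    root = np.random.SeedSequence(cv.seed if seed is None else seed)
    folds = blocked_folds(X.shape[0], cv.folds, groups)
    node_list = list(node_range)
    seeds = iter(root.generate_state(len(node_list) * cv.retrains * cv.folds))
    per_node: dict[int, tuple[float, float, np.ndarray]] = {}
    best = (None, -np.inf, np.nan, None)
    for nodes in node_list:
        spec = NetworkSpec(hidden_nodes=nodes, max_epochs=network.max_epochs,
                           tol=network.tol)
        scores = []
        fold_preds: list[tuple[np.ndarray, np.ndarray]] = []
        for r in range(cv.retrains):
            for j, test in enumerate(folds):
                train = np.setdiff1d(np.arange(X.shape[0]), test)
                init_seed = int(next(seeds) % (2**31 - 1))
                scaler = ScalerPair().fit(X[train], y[train])
                Xtr, ytr = scaler.transform(X[train], y[train])
                net = train_net(Xtr, ytr, spec, seed=init_seed)
                pred = scaler.inverse_y(net.predict(scaler.transform(X[test])))
                score = r2(y[test], pred)
                if np.isnan(score):
                    logger.info("run_cv: fold %d has zero target variance; "
                                "R^2 excluded", j)
                else:
                    scores.append(score)
                if r == 0:
                    fold_preds.append((y[test], pred))
        arr = np.array(scores)
        mean = float(arr.mean()) if arr.size else float("nan")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
        per_node[nodes] = (mean, sd, arr)
        if arr.size and mean > best[1]:
            actual = np.concatenate([a for a, _ in fold_preds])
            predicted = np.concatenate([p for _, p in fold_preds])
            best = (nodes, mean, sd, (actual, predicted))
    if best[0] is None:
        raise ValueError("no fold produced a defined R^2")
    return EstimationResult(MethodKind(method), per_node, best[0], best[1],
                            best[2], best[3])


def percent_increase(r2_a: float, r2_b: float) -> float:
    """Relative R^2 increase of b over a, in percent; NaN when r2_a <= 0."""
    if r2_a <= 0:
        return float("nan")
    return (r2_b - r2_a) / r2_a * 100.0


def _paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired t-test needs equal-length, aligned samples")
    if np.allclose(a, b):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonReport:
    """Cross-method summary: means, percent increases, paired t-tests."""

    means: dict[str, float]
    sds: dict[str, float]
    increases: dict[str, float]           # "A_vs_B": percent increase of B over A
    ttests: dict[str, tuple[float, float]]
    significant: dict[str, bool]
    table: pd.DataFrame                   # per-subject (or per-fold) values
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {"means": self.means, "sds": self.sds,
                "increases": self.increases,
                "ttests": {k: {"t": t, "p": p}
                           for k, (t, p) in self.ttests.items()},
                "significant": self.significant, "alpha": self.alpha}


def compare(per_method: dict[str, np.ndarray], alpha: float = 0.05
            ) -> ComparisonReport:
    """Compare methods on paired R^2 samples (per subject or per fold).

    ``per_method`` maps method name to an aligned vector of R^2 values.
    Percent increases are computed between sample means; significance is a
    two-sided paired t-test at the given alpha.
    """
    names = list(per_method)
    if len(names) < 2:
        raise ValueError("need at least two methods to compare")
    vals = {k: np.asarray(v, dtype=float) for k, v in per_method.items()}
    n = {len(v) for v in vals.values()}
    if len(n) != 1:
        raise ValueError("method sample vectors must be aligned (equal length)")
    means = {k: float(v.mean()) for k, v in vals.items()}
    sds = {k: float(v.std(ddof=1)) if v.size > 1 else float("nan")
           for k, v in vals.items()}
    increases, ttests, signif = {}, {}, {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            key = f"{a}_vs_{b}"
            increases[key] = percent_increase(means[a], means[b])
            t, p = _paired_ttest(vals[a], vals[b])
            ttests[key] = (t, p)
            signif[key] = bool(p < alpha)
    table = pd.DataFrame(vals)
    table.insert(0, "unit", np.arange(1, len(table) + 1))
    return ComparisonReport(means, sds, increases, ttests, signif, table,
                            alpha)


def evaluate_methods(fm: FeatureMatrix, cv: CVSpec = CVSpec(),
                     node_range=range(2, 21),
                     methods=(MethodKind.TMLM, MethodKind.CMLM,
                              MethodKind.FMLM),
                     groups: np.ndarray | None = None,
                     network: NetworkSpec = NetworkSpec(),
                     ) -> dict[MethodKind, EstimationResult]:
    """Run the full node-sweep CV for each requested method on one matrix."""
    out: dict[MethodKind, EstimationResult] = {}
    for m in methods:
        m = MethodKind(m)
        X, y = assemble(m, fm)
        out[m] = run_cv(X, y, cv, node_range, groups=groups, method=m,
                        network=network)
    return out
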