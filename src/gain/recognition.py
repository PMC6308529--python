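"""Low-latency context-window activity and intention recognition.

A recognition module scores the last ``K`` frames of a feature stream
against per-class Gaussian-mixture emission densities and picks

    s_hat(t) = argmax_s  sum_{k=0}^{K-1} log P(v_{t-k} | s)

i.e. a product of per-frame class likelihoods over a short context window,
with uniform class priors.  Mixtures are fitted per class by
Expectation-Maximization on labeled training frames.  For intention
detection (stand-up, sit-down) the windowed log-likelihood ratio of the
intention class against the best competing class is additionally compared
with a decision threshold calibrated for a target event-level precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

#: Per-class Gaussian component counts for each recognition module.
DEFAULT_COMPONENTS = {
    "standing_up": {"intention": 10, "sitting": 1},
    "sitting_down": {"intention": 5, "other": 2},
    "sitting_standing_moving": {"sitting": 1, "standing": 1, "moving": 1},
}

#: Context-window length in frames, shared by all recognition modules.
DEFAULT_WINDOW = 20


@dataclass
class ClassMixture:
    """Parameters of one class-conditional Gaussian mixture."""

    weights: np.ndarray  # (n_components,)
    means: np.ndarray  # (n_components, d)
    covariances: np.ndarray  # (n_components, d, d)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("mixture weights must be nonnegative")


@dataclass
class GmmModelBank:
    """Per-class mixtures plus decision metadata for one recognition module."""

    module_kind: str
    classes: list[str]
    mixtures: dict[str, ClassMixture]
    K: int = DEFAULT_WINDOW  # context-window length in frames
    threshold: float | None = None
    intention_class: str | None = None
    feature_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def dim(self) -> int:
        return self.mixtures[self.classes[0]].means.shape[1]


def fit_gmm(
    X: np.ndarray,
    n_components: int,
    seed: int = 0,
    reg_covar: float = 1e-6,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[ClassMixture, np.ndarray]:
    """Fit a full-covariance Gaussian mixture by EM with k-means init.

    Runs EM one iteration at a time so the per-iteration mean
    log-likelihood trace can be returned alongside the parameters;
    stops when the gain drops below ``tol`` or after ``max_iter``
    iterations.  Returns ``(mixture, loglik_trace)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if n_components > len(X):
        raise ValueError(f"n_components={n_components} exceeds {len(X)} samples")
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        reg_covar=reg_covar,
        init_params="kmeans",
        random_state=seed,
        warm_start=True,
        max_iter=1,
        tol=0.0,
    )
    trace: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(X)
            trace.append(float(gm.score(X)))
            if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
                break
    mixture = ClassMixture(
        weights=gm.weights_.copy(), means=gm.means_.copy(), covariances=gm.covariances_.copy()
    )
    return mixture, np.asarray(trace)


def mixture_loglik(mixture: ClassMixture, V: np.ndarray) -> np.ndarray:
    """Log mixture density at each row of ``V``, via log-sum-exp over components."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    d = mixture.means.shape[1]
    if V.shape[1] != d:
        raise ValueError(f"feature dimension {V.shape[1]} != model dimension {d}")
    parts = np.empty((len(V), len(mixture.weights)))
    for j, (w, mu, cov) in enumerate(zip(mixture.weights, mixture.means, mixture.covariances)):
        chol = cho_factor(cov, lower=True)
        dev = V - mu
        maha = np.sum(dev * cho_solve(chol, dev.T).T, axis=1)
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        log_norm = -0.5 * (d * np.log(2 * np.pi) + logdet)
        with np.errstate(divide="ignore"):
            parts[:, j] = np.log(w) + log_norm - 0.5 * maha
    return logsumexp(parts, axis=1)


def class_loglik(bank: GmmModelBank, cls: str, v: np.ndarray) -> np.ndarray | float:
    """Log-density of frame(s) ``v`` under the class-conditional mixture."""
    v = np.asarray(v, dtype=float)
    scalar = v.ndim == 1
    out = mixture_loglik(bank.mixtures[cls], v)
    return float(out[0]) if scalar else out


def classify_window(bank: GmmModelBank, window: np.ndarray) -> tuple[str, dict[str, float]]:
    """Argmax of the summed per-frame log-densities over the context window.

    ``window`` holds the most recent frames, at most ``bank.K`` of them
    (fewer are allowed at the start of a stream).  Ties break by class
    order.  Returns ``(class, scores)``.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if len(window) == 0:
        raise ValueError("empty context window")
    if len(window) > bank.K:
        raise ValueError(f"window of {len(window)} frames exceeds K={bank.K}")
    scores = {cls: float(np.sum(class_loglik(bank, cls, window))) for cls in bank.classes}
    best = max(bank.classes, key=lambda c: scores[c])  # max is stable: first wins ties
    return best, scores


def _window_sums(per_frame: np.ndarray, window: int, lengths: list[int] | None) -> np.ndarray:
    """Trailing sums over ``window`` frames, restarted at sequence boundaries."""
    n = len(per_frame)
    if lengths is None:
        lengths = [n]
    out = np.empty_like(per_frame, dtype=float)
    start = 0
    for length in lengths:
        seg = per_frame[start : start + length]
        csum = np.concatenate([[0.0], np.cumsum(seg)])
        t = np.arange(length)
        lo = np.maximum(t + 1 - window, 0)
        out[start : start + length] = csum[t + 1] - csum[lo]
        start += length
    return out


class ContextWindowGmmClassifier(BaseEstimator, ClassifierMixin):
    """Sliding context-window classifier with GMM emissions.

    Parameters
    ----------
    n_components : dict mapping class name -> component count, or int
        applied to every class.
    window : context-window length K in frames.
    module_kind : optional tag; when given and ``n_components`` is None the
        module's default component counts are used.
    """

    def __init__(
        self,
        n_components=None,
        window: int = DEFAULT_WINDOW,
        module_kind: str | None = None,
        reg_covar: float = 1e-6,
        tol: float = 1e-4,
        max_iter: int = 200,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.window = window
        self.module_kind = module_kind
        self.reg_covar = reg_covar
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _components_for(self, cls: str) -> int:
        spec = self.n_components
        if spec is None and self.module_kind in DEFAULT_COMPONENTS:
            spec = DEFAULT_COMPONENTS[self.module_kind]
        if spec is None:
            return 1
        if isinstance(spec, dict):
            return int(spec.get(cls, spec.get("other", 1)))
        return int(spec)

    def fit(self, X, y, lengths=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray([str(v) for v in np.asarray(y)])
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = sorted(np.unique(y).tolist())
        mixtures = {}
        self.em_traces_ = {}
        for cls in self.classes_:
            rows = X[y == cls]
            mixtures[cls], self.em_traces_[cls] = fit_gmm(
                rows,
                self._components_for(cls),
                seed=self.random_state,
                reg_covar=self.reg_covar,
                tol=self.tol,
                max_iter=self.max_iter,
            )
        self.bank_ = GmmModelBank(
            module_kind=self.module_kind or "custom",
            classes=self.classes_,
            mixtures=mixtures,
            K=self.window,
        )
        return self

    def frame_logliks(self, X) -> np.ndarray:
        """Per-frame log-density under each class, shape (n, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([class_loglik(self.bank_, c, X) for c in self.classes_])

    def window_scores(self, X, lengths=None) -> np.ndarray:
        """Context-window summed log-likelihood per class, shape (n, n_classes)."""
        ll = self.frame_logliks(X)
        return np.column_stack(
            [_window_sums(ll[:, j], self.window, lengths) for j in range(ll.shape[1])]
        )

    def predict(self, X, lengths=None) -> np.ndarray:
        scores = self.window_scores(X, lengths)
        return np.asarray(self.classes_, dtype=object)[np.argmax(scores, axis=1)]

    def decision_score(self, X, positive_class: str, lengths=None) -> np.ndarray:
        """Windowed log-likelihood ratio of ``positive_class`` vs best other."""
        scores = self.window_scores(X, lengths)
        pos = self.classes_.index(positive_class)
        others = [j for j in range(len(self.classes_)) if j != pos]
        return scores[:, pos] - scores[:, others].max(axis=1)


def event_decisions_metrics(
    decisions: np.ndarray, spans: list[tuple[int, int]], slack: int = 0
) -> tuple[int, int, int]:
    """Event-level (TP, FP, FN) of per-frame boolean decisions.

    A true event (half-open frame span) counts detected if any positive
    decision falls inside it, extended by ``slack`` trailing frames to
    credit the recognizer's context-window lag; each maximal positive run
    entirely outside all (extended) true spans is one false positive.
    """
    decisions = np.asarray(decisions, dtype=bool)
    inside = np.zeros(len(decisions), dtype=bool)
    tp = fn = 0
    for start, end in spans:
        end = min(len(decisions), end + slack)
        inside[start:end] = True
        if decisions[start:end].any():
            tp += 1
        else:
            fn += 1
    # count maximal runs of positives that never touch a true span
    d = decisions.astype(np.int8)
    run_starts = np.flatnonzero(np.diff(np.concatenate([[0], d])) == 1)
    run_ends = np.flatnonzero(np.diff(np.concatenate([d, [0]])) == -1)
    fp = sum(1 for s, e in zip(run_starts, run_ends) if not inside[s : e + 1].any())
    return tp, fp, fn


def calibrate_threshold(
    scores: list[np.ndarray],
    spans: list[list[tuple[int, int]]],
    target_precision: float = 0.99,
    max_candidates: int = 2000,
    slack: int = 0,
) -> float:
    """Smallest decision threshold achieving event-level precision >= target.

    ``scores`` are per-sequence intention log-likelihood-ratio traces and
    ``spans`` the true intention event frame spans per sequence.  The
    sweep descends from the top of the score range while event precision
    stays at or above the target, and returns the largest threshold that
    achieves the best recall seen along that descent: the most
    conservative decision rule attaining it (precision is bought at the
    expense of recall and latency).  Descending past that point only
    loosens the rule without detecting more events, and on continuous
    score traces eventually degenerates into an always-on decision.  If
    the target is unattainable at every threshold, returns ``inf`` with a
    warning (recall collapses to zero by construction).
    """
    if not scores or all(len(s) == 0 for s in scores):
        raise ValueError("empty calibration set")
    n_events = sum(len(sp) for sp in spans)
    if n_events == 0:
        raise ValueError("calibration set contains no positive events")
    allscores = np.concatenate([np.asarray(s, dtype=float) for s in scores])
    candidates = np.unique(allscores[np.isfinite(allscores)])
    if len(candidates) > max_candidates:
        idx = np.linspace(0, len(candidates) - 1, max_candidates).round().astype(int)
        span_maxima = [
            np.asarray(s)[lo:hi].max()
            for s, sp in zip(scores, spans)
            for lo, hi in sp
            if hi > lo
        ]
        candidates = np.unique(np.concatenate([candidates[idx], span_maxima]))
    best = np.inf
    best_recall = -1
    for thr in candidates[::-1]:
        tp = fp = 0
        for s, sp in zip(scores, spans):
            t, f, _ = event_decisions_metrics(np.asarray(s) >= thr, sp, slack=slack)
            tp += t
            fp += f
        if tp + fp == 0:
            continue
        if tp / (tp + fp) < target_precision:
            break
        if tp > best_recall:
            best_recall = tp
            best = float(thr)
        if tp == n_events:
            break
    if not np.isfinite(best):
        warnings.warn(
            f"target precision {target_precision} unattainable; returning inf threshold"
        )
    return best


def save_bank(bank: GmmModelBank, path: str | Path) -> None:
    """Serialize a model bank to a portable JSON file."""
    payload = {
        "module_kind": bank.module_kind,
        "classes": bank.classes,
        "K": bank.K,
        "threshold": bank.threshold,
        "intention_class": bank.intention_class,
        "feature_bounds": {k: list(v) for k, v in bank.feature_bounds.items()},
        "mixtures": {
            cls: {
                "weights": m.weights.tolist(),
                "means": m.means.tolist(),
                "covariances": m.covariances.tolist(),
            }
            for cls, m in bank.mixtures.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_bank(path: str | Path) -> GmmModelBank:
    payload = json.loads(Path(path).read_text())
    mixtures = {
        cls: ClassMixture(
            weights=np.array(m["weights"]),
            means=np.array(m["means"]),
            covariances=np.array(m["covariances"]),
        )
        for cls, m in payload["mixtures"].items()
    }
    return GmmModelBank(
        module_kind=payload["module_kind"],
        classes=payload["classes"],
        mixtures=mixtures,
        K=payload["K"],
        threshold=payload["threshold"],
        intention_class=payload["intention_class"],
        feature_bounds={k: tuple(v) for k, v in payload["feature_bounds"].items()},
    )
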