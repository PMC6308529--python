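"""Independent reference implementations used as test oracles.

Everything here is written directly from the defining formulas, using a
different code path (scipy densities, explicit loops) from the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import multivariate_normal


def lstm_reference_step(weights: dict, x, h, c):
    """Equation-by-equation LSTM cell evaluation with explicit loops."""
    H = len(weights["b_f"])

    def sigmoid(v):
        return 1.0 / (1.0 + math.exp(-v))

    vh = list(x) + list(h)
    f = [sigmoid(sum(weights["W_f"][j][k] * vh[k] for k in range(len(vh))) + weights["b_f"][j])
         for j in range(H)]
    i = [sigmoid(sum(weights["W_i"][j][k] * vh[k] for k in range(len(vh))) + weights["b_i"][j])
         for j in range(H)]
    g = [math.tanh(sum(weights["W_g"][j][k] * vh[k] for k in range(len(vh))) + weights["b_g"][j])
         for j in range(H)]
    c_next = [f[j] * c[j] + i[j] * g[j] for j in range(H)]
    o = [sigmoid(sum(weights["W_o"][j][k] * vh[k] for k in range(len(vh))) + weights["b_o"][j])
         for j in range(H)]
    h_next = [o[j] * math.tanh(c_next[j]) for j in range(H)]
    O = len(weights["b_y"])
    y = [math.tanh(sum(weights["W_y"][m][j] * h_next[j] for j in range(H)) + weights["b_y"][m])
         for m in range(O)]
    return np.array(h_next), np.array(c_next), np.array(y)


def mixture_density(weights, means, covs, v) -> float:
    """Direct weighted sum of Gaussian densities (no log domain)."""
    return float(
        sum(w * multivariate_normal.pdf(v, mean=m, cov=S)
            for w, m, S in zip(weights, means, covs))
    )


def brute_force_window_class(mixtures: dict, window: np.ndarray, class_order: list[str]) -> str:
    """Argmax over classes of the product of per-frame mixture densities."""
    best_cls, best_val = None, -1.0
    for cls in class_order:
        w, m, S = mixtures[cls]
        val = 1.0
        for frame in window:
            val *= mixture_density(w, m, S, frame)
        if val > best_val:
            best_cls, best_val = cls, val
    return best_cls


def trailing_mean(series, window):
    """Direct per-frame loop for the causal moving average."""
    out = []
    for t in range(len(series)):
        lo = max(0, t - window + 1)
        out.append(sum(series[lo : t + 1]) / (t - lo + 1))
    return np.array(out)


def population_std(values) -> float:
    values = list(values)
    mu = sum(values) / len(values)
    return math.sqrt(sum((v - mu) ** 2 for v in values) / len(values))


def emg_grad_std_loop(emg, w):
    """Direct formula: STD of the last w+1 backward differences."""
    emg = list(map(float, emg))
    out = [0.0] * len(emg)
    for t in range(w + 1, len(emg)):
        diffs = [emg[t - i] - emg[t - i - 1] for i in range(w + 1)]
        out[t] = population_std(diffs)
    return np.array(out)


def paired_diff_std_loop(left, right, w):
    out = [0.0] * len(left)
    for t in range(w, len(left)):
        vals = [abs(left[t - i] - right[t - i]) for i in range(w + 1)]
        out[t] = population_std(vals)
    return np.array(out)
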