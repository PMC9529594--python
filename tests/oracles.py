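"""Independent straight-loop re-implementations used as test oracles.

Deliberately naive: plain Python loops, no vectorisation tricks, no shared
code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import math


def hjorth_naive(x) -> tuple[float, float, float]:
    n = len(x)
    mean = sum(x) / n
    var_x = sum((v - mean) ** 2 for v in x) / n
    if var_x == 0:
        return 0.0, 0.0, 0.0
    dx = [x[i + 1] - x[i] for i in range(n - 1)]
    mdx = sum(dx) / len(dx)
    var_dx = sum((v - mdx) ** 2 for v in dx) / len(dx)
    mobility = math.sqrt(var_dx / var_x)
    if var_dx == 0:
        return var_x, 0.0, 0.0
    ddx = [dx[i + 1] - dx[i] for i in range(len(dx) - 1)]
    mddx = sum(ddx) / len(ddx)
    var_ddx = sum((v - mddx) ** 2 for v in ddx) / len(ddx)
    mobility_dx = math.sqrt(var_ddx / var_dx)
    return var_x, mobility, mobility_dx / mobility


def abs_amplitude_naive(x) -> tuple[float, float]:
    return max(abs(v) for v in x), sum(abs(v) for v in x)


def petrosian_naive(x) -> float:
    n = len(x)
    dx = [x[i + 1] - x[i] for i in range(n - 1)]
    signs = [1 if v > 0 else -1 for v in dx if v != 0]
    n_delta = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    if n_delta == 0:
        return 1.0
    log_n = math.log10(n)
    return log_n / (log_n + math.log10(n / (n + 0.4 * n_delta)))


def higuchi_naive(x, k_max: int = 10) -> float:
    n = len(x)
    if max(x) == min(x):
        return 1.0
    ln_l, ln_inv_k = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(1, k + 1):
            n_intervals = (n - m) // k
            if n_intervals < 1:
                continue
            total = 0.0
            for i in range(1, n_intervals + 1):
                total += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            lengths.append(total * (n - 1) / (n_intervals * k * k))
        ln_l.append(math.log(sum(lengths) / len(lengths)))
        ln_inv_k.append(math.log(1.0 / k))
    # least-squares slope
    mx = sum(ln_inv_k) / len(ln_inv_k)
    my = sum(ln_l) / len(ln_l)
    sxx = sum((v - mx) ** 2 for v in ln_inv_k)
    sxy = sum((a - mx) * (b - my) for a, b in zip(ln_inv_k, ln_l))
    return sxy / sxx


def mean_center_naive(x) -> list[float]:
    mean = sum(x) / len(x)
    return [v - mean for v in x]


def features_naive(x, k_max: int = 10) -> list[float]:
    """The 7 features in package order, on the mean-centered signal."""
    xc = mean_center_naive(list(x))
    act, mob, comp = hjorth_naive(xc)
    amax, asum = abs_amplitude_naive(xc)
    return [act, comp, mob, amax, asum, higuchi_naive(xc, k_max), petrosian_naive(xc)]


def nlms_naive(primary, reference, taps: int, mu: float, eps: float):
    """Per-sample NLMS with explicit index arithmetic."""
    n = len(primary)
    w = [0.0] * taps
    estimate = [0.0] * n
    for i in range(taps, n):
        window = [reference[i - j] for j in range(taps)]
        y = sum(w[j] * window[j] for j in range(taps))
        e = primary[i] - y
        estimate[i] = y
        norm = sum(v * v for v in window) + eps
        for j in range(taps):
            w[j] += mu * e * window[j] / norm
    cleaned = [primary[i] - estimate[i] for i in range(n)]
    return cleaned, estimate


def metrics_naive(tp: int, fp: int, fn: int, tn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "mcc": mcc}
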