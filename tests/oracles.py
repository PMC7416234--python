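"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's fast code paths: the S-transform
oracle is a literal double loop over output time and input time, and the
confusion oracle counts pairs one by one.
"""

from __future__ import annotations

import numpy as np


def direct_stockwell(
    x: np.ndarray, fs: float, freqs: np.ndarray, p: float = 1.0, q: float = 1.0
) -> np.ndarray:
    """Double-loop discretisation of the S-transform integral.

    S(tau_j, f) = sum_t x[t] g(tau_j - t, f) exp(-i 2 pi f t) dt with the
    Gaussian window summed over periodic images of the trial window.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    dt = 1.0 / fs
    period = n * dt
    t = np.arange(n) * dt
    out = np.empty((len(freqs), n), dtype=np.complex128)
    for k, f in enumerate(freqs):
        sigma = p / f**q
        n_wrap = int(np.ceil(9.0 * sigma / period)) + 1
        for j in range(n):
            acc = 0.0 + 0.0j
            for m in range(n):
                lag = t[j] - t[m]
                g = 0.0
                for ell in range(-n_wrap, n_wrap + 1):
                    u = lag + ell * period
                    g += np.exp(-0.5 * (u / sigma) ** 2)
                g /= sigma * np.sqrt(2.0 * np.pi)
                acc += x[m] * g * np.exp(-2j * np.pi * f * t[m]) * dt
            out[k, j] = acc
    return out


def fourier_coefficient(x: np.ndarray, fs: float, f: float) -> complex:
    """Riemann-sum Fourier coefficient X(f) = sum x(t) exp(-i 2 pi f t) dt."""
    t = np.arange(len(x)) / fs
    return np.sum(x * np.exp(-2j * np.pi * f * t)) / fs


def brute_confusion(y_true, y_pred) -> dict:
    """Pairwise confusion counts, no vectorisation."""
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            counts["tp"] += 1
        elif t == -1 and p == -1:
            counts["tn"] += 1
        elif t == -1 and p == 1:
            counts["fp"] += 1
        else:
            counts["fn"] += 1
    return counts
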