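"""Minimal orthogonal discrete wavelet decomposition (circular convolution).

Supports the Daubechies family (db1/db2/db4).  Odd-length inputs are
zero-padded to even length at each level, which adds no energy, so for these
orthonormal filters the decomposition conserves energy exactly:
``sum(detail**2 over levels) + sum(approx**2) == sum(x**2)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wavedec", "FILTERS"]

# scaling (lowpass) filters, normalized so sum(h**2) == 1 and sum(h) == sqrt(2)
FILTERS: dict[str, np.ndarray] = {
    "db1": np.array([0.7071067811865476, 0.7071067811865476]),
    "db2": np.array(
        [
            0.48296291314469025,
            0.8365163037378079,
            0.22414386804185735,
            -0.12940952255092145,
        ]
    ),
    "db4": np.array(
        [
            0.23037781330885523,
            0.7148465705525415,
            0.6308807679295904,
            -0.02798376941698385,
            -0.18703481171888114,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


def _analysis_step(x: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One circular-convolution analysis level -> (approx, detail)."""
    n = len(x)
    if n % 2 == 1:
        x = np.concatenate([x, [0.0]])
        n += 1
    L = len(g)
    h = ((-1) ** np.arange(L)) * g[::-1]  # quadrature mirror highpass
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :]) % n
    windows = x[idx]
    return windows @ g, windows @ h


def wavedec(x: np.ndarray, wavelet: str = "db4", levels: int = 4) -> tuple[np.ndarray, list[np.ndarray]]:
    """Decompose ``x`` into (final approximation, [detail_1 ... detail_k]).

    The depth is capped so every level keeps at least 2 approximation
    samples; the achieved depth may therefore be lower than requested for
    short inputs.
    """
    if wavelet not in FILTERS:
        raise ValueError(f"unsupported wavelet {wavelet!r}; choose from {sorted(FILTERS)}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    g = FILTERS[wavelet]
    a = np.asarray(x, dtype=float)
    details: list[np.ndarray] = []
    for _ in range(levels):
        if len(a) < 2:
            break
        a, d = _analysis_step(a, g)
        details.append(d)
    return a, details
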