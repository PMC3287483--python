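"""Moving-average smoothing of per-base tag start counts."""

from __future__ import annotations

import numpy as np


def smooth_counts(t: np.ndarray, b: int = 20) -> np.ndarray:
    """Centered moving average of width ``b``.

    The window covering position ``n`` spans ``[n - b//2, n + b - b//2)``;
    at the edges it is truncated and the divisor is the actual number of
    positions averaged, so a constant input maps to itself everywhere.
    """
    if b < 1:
        raise ValueError("smoothing width must be >= 1")
    t = np.asarray(t, dtype=float)
    n = t.size
    if n == 0:
        return t.copy()
    cs = np.concatenate([[0.0], np.cumsum(t)])
    idx = np.arange(n)
    lo = np.clip(idx - b // 2, 0, n)
    hi = np.clip(idx + (b - b // 2), 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)
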