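"""False-discovery-rate q-values from a p-value distribution.

Two estimators of the null proportion pi0 are offered:

* ``"bh"`` — Benjamini-Hochberg step-up (pi0 = 1);
* ``"storey"`` — Storey's point estimate pi0 = min(1, mean(p > lambda) /
  (1 - lambda)) at lambda = 0.5, followed by the same step-up.

q_i = min over thresholds t >= p_(i) of pi0 * m * t / rank(t), so q is
monotone nondecreasing in p and bounded by pi0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["qvalues", "storey_pi0"]


def storey_pi0(p: np.ndarray, lam: float = 0.5) -> float:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return 1.0
    return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))


def qvalues(p, method: str = "storey", lam: float = 0.5) -> np.ndarray:
    """FDR q-values in the input order; empty input gives empty output."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        pi0 = 1.0
    elif method == "storey":
        pi0 = storey_pi0(p, lam)
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
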