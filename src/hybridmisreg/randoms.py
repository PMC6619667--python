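"""Shared random-variate helpers."""
from __future__ import annotations

import numpy as np

from .containers import ValidationError


def betabinom_rvs(
    rng: np.random.Generator,
    n,
    p: float,
    rho: float,
    size=None,
) -> np.ndarray:
    """Beta-binomial draws parameterized by mean *p* and intraclass
    correlation *rho* in [0, 1).

    rho = 0 degenerates to the binomial. For rho > 0 the underlying Beta
    has a + b = (1 - rho) / rho, giving Var = n p (1-p) (1 + (n-1) rho).
    """
    if not 0.0 <= rho < 1.0:
        raise ValidationError("rho must lie in [0, 1)")
    p = np.asarray(p, dtype=float)
    if not ((p > 0.0) & (p < 1.0)).all():
        raise ValidationError("allelic ratio must lie strictly in (0, 1)")
    n = np.asarray(n)
    if size is None:
        size = np.broadcast_shapes(n.shape, p.shape) or None
    if rho == 0.0:
        return rng.binomial(n, p, size=size)
    s = (1.0 - rho) / rho
    probs = rng.beta(p * s, (1.0 - p) * s, size=size)
    return rng.binomial(n, probs, size=size)
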