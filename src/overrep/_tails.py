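"""Shared upper-tail hypergeometric machinery (internal)."""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

#: smallest positive double; p-values are floored here so -log10 stays finite
P_FLOOR = float(np.nextafter(0.0, 1.0))


def tail_array(N, K, n, k) -> np.ndarray:
    """P(X >= k) for X ~ Hypergeom(N, K, n), vectorized with broadcasting.

    Computed as the survival function at k-1; values are clipped into
    (0, 1] so downstream log transforms are finite.
    """
    k = np.asarray(k)
    p = hypergeom.sf(k - 1, N, K, n)
    return np.clip(p, P_FLOOR, 1.0)
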