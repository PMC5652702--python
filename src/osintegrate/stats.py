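"""Small shared statistics helpers."""

from __future__ import annotations

from scipy.stats import hypergeom


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for overlap X of an n-draw with a K-subset of an N-universe.

    Upper-tail with P(X >= 0) = 1; used by both pathway enrichment and
    kinase-target deconvolution.
    """
    if k <= 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))
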