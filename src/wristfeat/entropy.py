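"""Approximate entropy (ApEn) of a scalar time series.

ApEn(m, r, K) quantifies the (ir)regularity of a series x = {x_1 ... x_K}:
form the K-m+1 overlapping template vectors u_i = (x_i, ..., x_{i+m-1}),
count for each template the fraction C_i^m(r) of templates within Chebyshev
distance r (self-matches included, which keeps the logarithm defined), let
Phi^m(r) be the mean natural log of those fractions, and report

    ApEn = Phi^m(r) - Phi^{m+1}(r).

Predictable series (constants, slow trends) score near zero; irregular
series score higher.  The conventional physiological parameterization is
m = 2 with tolerance r = 0.2 * sd(x).
"""

from __future__ import annotations

import numpy as np

from .config import ApEnParams

__all__ = ["apen", "apen_normalized"]


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Mean log fraction of template matches at embedding length m."""
    n = x.size - m + 1
    # templates as an (n, m) strided view; pairwise Chebyshev via broadcasting
    u = np.lib.stride_tricks.sliding_window_view(x, m)
    d = np.abs(u[:, None, :] - u[None, :, :]).max(axis=2)
    c = np.count_nonzero(d <= r, axis=1) / n
    return float(np.mean(np.log(c)))


def apen(x, params: ApEnParams | None = None) -> float:
    """Approximate entropy of ``x`` under ``params`` (default m=2, r=0.2*sd).

    Raises ``ValueError`` if the series is shorter than m + 2, the minimum
    length for which Phi^{m+1} is defined on at least one template pair.
    Under the relative tolerance mode a constant series (sd = 0) returns 0.
    """
    params = params or ApEnParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("apen expects a 1-D series")
    if not np.all(np.isfinite(x)):
        raise ValueError("apen input contains non-finite values")
    k = x.size
    if k < params.m + 2:
        raise ValueError(f"series of length {k} too short for m={params.m} (need >= {params.m + 2})")
    sd = float(np.std(x, ddof=1))
    if params.r_mode == "relative_sd" and sd == 0.0:
        return 0.0
    r = params.tolerance(sd)
    return _phi(x, params.m, r) - _phi(x, params.m + 1, r)


def apen_normalized(x, params: ApEnParams | None = None) -> float:
    """ApEn divided by the series length K.

    Normalization compensates for the length dependence of ApEn so that
    nights (or days) with more temperature points do not automatically score
    higher.
    """
    x = np.asarray(x, dtype=float)
    return apen(x, params) / x.size
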