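"""Safe noncentral-t density evaluation.

scipy's boost-backed ``nct.pdf`` can return NaN (with a quadrature
warning) deep in the tail for large degrees of freedom, where the true
density has underflowed to essentially zero.  These helpers clamp such
non-finite values to 0 so that quadrature and grid construction stay
well defined.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["nct_pdf"]


def nct_pdf(x, df, nc):
    """Noncentral-t density, with non-finite tail values clamped to 0.

    Deep in the tail the backend can return NaN or raise an overflow;
    there the true density has underflowed, so 0 is the correct value.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            val = stats.nct.pdf(x, df, nc)
        except (OverflowError, FloatingPointError):
            if np.ndim(nc) == 0:
                return 0.0
            val = np.array([_scalar(x, df, a) for a in np.asarray(nc).ravel()])
            val = val.reshape(np.shape(nc))
    if np.isscalar(val) or np.ndim(val) == 0:
        return float(val) if np.isfinite(val) else 0.0
    return np.nan_to_num(val, nan=0.0, posinf=0.0, neginf=0.0)


def _scalar(x, df, nc):
    try:
        v = stats.nct.pdf(x, df, nc)
    except (OverflowError, FloatingPointError):
        return 0.0
    return float(v) if np.isfinite(v) else 0.0
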