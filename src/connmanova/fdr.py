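"""Benjamini-Hochberg false discovery rate control (step-up procedure)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError

__all__ = ["bh_fdr"]


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up adjusted p-values and reject mask at level ``alpha``.

    Returns ``(p_adj, reject)`` in the input order; ``reject[i]`` is True iff
    ``p_adj[i] <= alpha``. Adjusted p-values are monotone nondecreasing in the
    raw-p ranks.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or p.size == 0:
        raise DegenerateDataError("p-values must be a non-empty 1-d sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DegenerateDataError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject
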