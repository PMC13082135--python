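"""Multiple-testing adjustments (BH step-up FDR, Bonferroni)."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def adjust_bonferroni(pvals) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, m*p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return np.minimum(1.0, p * p.size)
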