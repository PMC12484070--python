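"""Small shared statistical helpers."""
from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_qvalues", "by_qvalues", "pearson_r"]


def _check_p(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any((p < 0) | (p > 1)) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone-enforced)."""
    p = _check_p(p_values)
    if p.size == 0:
        return p.copy()
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]


def by_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted q-values (FDR under arbitrary dependence)."""
    p = _check_p(p_values)
    if p.size == 0:
        return p.copy()
    return multipletests(p, alpha=0.05, method="fdr_by")[1]


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; raises on constant input instead of returning NaN."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt(ac @ ac)
    nb = np.sqrt(bc @ bc)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((ac @ bc) / (na * nb))
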