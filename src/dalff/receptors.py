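"""Spatial association of a regional statistic map with receptor density maps.

Each receptor/transporter density profile (regions x maps, e.g. a PET
panel parcel-averaged on the same atlas as the statistic map) is
correlated with the group-difference t profile. Each map gets a Pearson
r, a parametric two-tailed p (t distribution, n_regions - 2 df), a
spin-permutation p sharing one spatial null across the panel, and
Benjamini-Hochberg q-values across maps for both p families; a map is
flagged significant only if both corrected families fall below the
threshold (symmetric multiple-comparison control across the panel).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, by_qvalues, pearson_r
from .transcriptomics import SpinNull, spin_p

__all__ = ["correlate_panel", "fdr_bh"]

TABLE_COLUMNS = ["map", "r", "p", "p_spin", "q", "q_spin", "significant"]


def fdr_bh(p_values: np.ndarray, threshold: float = 0.05):
    """Benjamini-Hochberg step-up q-values and rejection set."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    q = bh_qvalues(p)
    return q, q < threshold


def correlate_panel(
    tvec: pd.Series,
    panel: pd.DataFrame,
    null: SpinNull,
    fdr_threshold: float = 0.05,
    correction: str = "by",
) -> pd.DataFrame:
    """Correlate a regional t profile with every map of a receptor panel.

    ``tvec`` and ``panel`` must share the region index (>= 4 regions).
    Constant maps are reported with NaN statistics and excluded from the
    FDR family. Receptor/transporter densities within one panel share
    strong spatial gradients, so the default correction is the
    dependence-robust Benjamini-Yekutieli variant (``correction='bh'``
    selects plain Benjamini-Hochberg).
    """
    if correction not in ("by", "bh"):
        raise ValueError("correction must be 'by' or 'bh'")
    adjust = by_qvalues if correction == "by" else bh_qvalues
    if len(tvec) < 4:
        raise ValueError("need at least 4 regions")
    if panel.shape[1] == 0:
        raise ValueError("empty receptor panel")
    if not tvec.index.equals(panel.index):
        panel = panel.loc[tvec.index]
    t = tvec.to_numpy(dtype=float)
    n = len(t)
    rows = []
    for name in panel.columns:
        dens = panel[name].to_numpy(dtype=float)
        try:
            r = pearson_r(t, dens)
        except ValueError:
            warnings.warn(f"map {name!r} is constant; excluded from FDR family")
            rows.append(
                {"map": name, "r": np.nan, "p": np.nan, "p_spin": np.nan}
            )
            continue
        # two-tailed parametric p via the exact t transform of r
        tstat = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(tstat), n - 2)
        ps = spin_p(t, dens, null)
        rows.append({"map": name, "r": r, "p": p, "p_spin": ps})
    table = pd.DataFrame(rows).set_index("map")
    defined = table["p"].notna()
    q = np.full(len(table), np.nan)
    q[defined.to_numpy()] = adjust(table.loc[defined, "p"].to_numpy())
    table["q"] = q
    q_spin = np.full(len(table), np.nan)
    q_spin[defined.to_numpy()] = adjust(table.loc[defined, "p_spin"].to_numpy())
    table["q_spin"] = q_spin
    table["significant"] = (
        defined & (table["q"] < fdr_threshold) & (table["q_spin"] < fdr_threshold)
    )
    return table
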