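"""Immune-infiltration scoring and FPI-infiltration correlation.

Infiltration of each immune cell type is approximated by the ssGSEA
enrichment of its surface-marker gene set (relative enrichment, not a cell
proportion).  Association with the ferroptosis index is quantified by plain
Pearson correlation, or by partial Pearson correlation when numeric
confounders are supplied, with Benjamini-Hochberg adjustment across cell
types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, GeneSetCollection, InputError
from .enrichment import ScoreMatrix, bh_adjust, ssgsea_scores
from .fpi import FPIVector

__all__ = ["infiltration_scores", "correlate_fpi_infiltration", "network_edges"]


def infiltration_scores(
    expr: ExpressionMatrix,
    marker_sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """Per-sample ssGSEA infiltration scores, one row per cell type."""
    try:
        return ssgsea_scores(expr, marker_sets, alpha=alpha, normalize=normalize)
    except InputError as exc:
        raise InputError(f"infiltration scoring failed: {exc}") from exc


def _partial_residuals(x: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), controls])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def correlate_fpi_infiltration(
    fpi: FPIVector,
    infil: ScoreMatrix,
    controls: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlate FPI with each cell type's (z-standardized) infiltration score.

    Returns a DataFrame with columns cell_type, r, pvalue, padj, n sorted by
    |r| descending.  With ``controls``, both FPI and each score row are
    residualized on the controls (plus intercept) and the Pearson correlation
    of residuals is used, with t-based p on n - 2 - k degrees of freedom;
    with no controls this reduces exactly to plain Pearson correlation.
    """
    shared = [s for s in fpi.sample_ids if s in set(infil.sample_ids)]
    if len(shared) < 5:
        raise InputError("need at least 5 shared samples for correlation")
    fpi_idx = [fpi.sample_ids.index(s) for s in shared]
    inf_idx = [infil.sample_ids.index(s) for s in shared]
    x = fpi.fpi[fpi_idx]
    n = len(shared)

    k = 0
    ctrl = None
    if controls is not None:
        ctrl = np.asarray(controls, dtype=float)
        if ctrl.ndim == 1:
            ctrl = ctrl[:, None]
        if ctrl.shape[0] != n:
            raise InputError("controls must have one row per shared sample")
        if not np.all(np.isfinite(ctrl)):
            raise InputError("controls must be numeric with no missing values")
        k = ctrl.shape[1]
        x = _partial_residuals(x, ctrl)

    rows = []
    pvals = []
    for i, cell_type in enumerate(infil.set_names):
        y = infil.scores[i, inf_idx].astype(float)
        sd = y.std(ddof=1)
        if sd == 0:
            raise InputError(f"infiltration score for {cell_type!r} is constant")
        y = (y - y.mean()) / sd
        if ctrl is not None:
            y = _partial_residuals(y, ctrl)
        r = float(np.corrcoef(x, y)[0, 1])
        df = n - 2 - k
        r_clamped = min(max(r, -1.0), 1.0)
        if abs(r_clamped) >= 1.0:
            p = 0.0
        else:
            t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append({"cell_type": cell_type, "r": r, "pvalue": p, "n": n})
        pvals.append(p)

    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(np.array(pvals))
    table = table[["cell_type", "r", "pvalue", "padj", "n"]]
    return table.reindex(table["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def network_edges(table: pd.DataFrame, padj_cutoff: float = 0.05) -> pd.DataFrame:
    """FPI-centred edge list (source, target, weight) for significant cell types.

    Rows with padj < ``padj_cutoff`` become edges weighted by r, sorted by
    |r| descending — ready for generic network tools.
    """
    if table.empty:
        return pd.DataFrame(columns=["source", "target", "weight"])
    kept = table[table["padj"] < padj_cutoff]
    edges = pd.DataFrame(
        {"source": "FPI", "target": kept["cell_type"], "weight": kept["r"]}
    )
    return edges.reindex(edges["weight"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
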