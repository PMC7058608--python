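"""Population-specific expression analysis (PSEA).

Cell-type-adjusted differential expression: marker genes are chosen from a
sorted-cell reference panel by a fold rule (a gene marks the one cell type
in which its reference expression is at least ``fold`` times the mean of the
other types), per-sample cell-type signals are the mean expression of the
present markers, and each gene is regressed on one cell-type signal plus a
signal-by-group interaction without intercept.  The interaction coefficient
is the cell-type-specific fold change ("slope change"); its two-sided
t-test answers whether expression differs between groups beyond what the
cell type's abundance explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .braak import _as_frame
from .stats import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_CELL_TYPES = (
    "neurons", "astrocytes", "oligodendrocytes", "microglia", "endothelial",
)

__all__ = [
    "DEFAULT_CELL_TYPES",
    "select_markers",
    "celltype_signals",
    "psea_test",
    "PSEATestResult",
    "PSEAModel",
    "PSEAResults",
]


def select_markers(reference: pd.DataFrame, fold: float = 20.0) -> dict[str, list[str]]:
    """Markers per cell type from a linear-scale reference panel (genes x types).

    Gene g marks type c iff ref(g, c) >= fold * mean over the other types.
    With fold > 1 a gene can mark at most one type.  A zero numerator over a
    zero denominator is not a marker; a positive numerator over a zero
    denominator is (infinite ratio).
    """
    if reference.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    if (reference.to_numpy() < 0).any():
        raise ValueError("reference panel must be non-negative (linear scale)")
    x = reference.to_numpy(dtype=float)
    n_types = x.shape[1]
    total = x.sum(axis=1, keepdims=True)
    other_mean = (total - x) / (n_types - 1)
    is_marker = np.where(
        other_mean > 0, x >= fold * other_mean, x > 0
    )
    markers = {
        str(ct): list(reference.index[is_marker[:, j]])
        for j, ct in enumerate(reference.columns)
    }
    logger.info(
        "select_markers (fold=%g): %s", fold,
        ", ".join(f"{ct}={len(g)}" for ct, g in markers.items()),
    )
    return markers


def celltype_signals(
    expr, markers: dict[str, list[str]], scale: str = "linear"
) -> pd.DataFrame:
    """Per-sample cell-type signals: mean expression of each type's markers.

    ``scale='linear'`` (default) converts log2 expression to linear (2^x)
    before averaging; ``'log'`` averages the values as given.  Markers
    absent from the expression matrix are dropped with a warning; a type
    with no present markers is an error.
    """
    frame = _as_frame(expr)
    values = np.exp2(frame) if scale == "linear" else frame
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    signals = {}
    for ct, genes in markers.items():
        present = [g for g in genes if g in frame.index]
        if len(present) < len(genes):
            logger.warning(
                "celltype_signals: %d of %d %s markers absent from expression",
                len(genes) - len(present), len(genes), ct,
            )
        if not present:
            raise ValueError(f"no markers of cell type {ct!r} present in expression")
        signals[ct] = values.loc[present].mean(axis=0)
    return pd.DataFrame(signals)


@dataclass(frozen=True)
class PSEATestResult:
    slope: float
    slope_change: float
    t: float
    p: float
    df: int
    status: str = "ok"  # or "untestable"


def _design(signal: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    return np.column_stack([signal, signal * group_b])


def psea_test(gene_expr, signal, group_b) -> PSEATestResult:
    """Regression of one gene on one cell-type signal with a group interaction.

    Model (no intercept): y = b1 * s + b2 * s * 1[group B].  ``slope`` is b1
    (group A slope), ``slope_change`` is b2 (the cell-type-specific fold
    change), tested two-sided with n - 2 residual degrees of freedom.
    Collinear designs are flagged untestable rather than raising.
    """
    y = np.asarray(gene_expr, dtype=float)
    s = np.asarray(signal, dtype=float)
    g = np.asarray(group_b, dtype=bool)
    if not (len(y) == len(s) == len(g)):
        raise ValueError("gene_expr, signal and group must have equal length")
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    x = _design(s, g)
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx) < 2 or len(y) <= 2:
        return PSEATestResult(np.nan, np.nan, np.nan, np.nan, 0, "untestable")
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    df = len(y) - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(cov[1, 1])
    if se == 0:
        t = 0.0 if beta[1] == 0 else np.inf * np.sign(beta[1])
        p = 1.0 if beta[1] == 0 else 0.0
    else:
        t = float(beta[1] / se)
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PSEATestResult(float(beta[0]), float(beta[1]), t, p, df)


class PSEAModel:
    """Cell-type-adjusted two-group differential expression over all genes.

    Parameters
    ----------
    expr
        Log2 expression (genes x samples); converted to linear scale for the
        regression when ``scale='linear'`` (default).
    samples
        Annotations with ``sample_id`` and the grouping column.
    panel
        Linear-scale reference (genes x cell types) from which markers are
        derived by the fold rule.
    contrast
        Pair (a, b) of values of ``group_col``; b is the "treated" group
        whose slope change is estimated.
    group_col
        Column of ``samples`` holding the group labels (default
        ``braak_region`` so the default contrast is region R1 vs R6).
    """

    def __init__(
        self,
        expr,
        samples: pd.DataFrame,
        panel: pd.DataFrame,
        contrast=(1, 6),
        group_col: str = "braak_region",
        fold: float = 20.0,
        scale: str = "linear",
    ):
        self.expr = _as_frame(expr)
        self.samples = samples
        self.panel = panel
        self.contrast = tuple(contrast)
        self.group_col = group_col
        self.fold = fold
        self.scale = scale

    def fit(self) -> "PSEAResults":
        markers = select_markers(self.panel, fold=self.fold)
        group = self.samples.set_index("sample_id")[self.group_col]
        group = group.reindex(self.expr.columns)
        a, b = self.contrast
        in_a = (group == a).to_numpy()
        in_b = (group == b).to_numpy()
        use = in_a | in_b
        if in_a.sum() == 0 or in_b.sum() == 0:
            raise ValueError(f"contrast groups {a!r}/{b!r} must both be non-empty")
        expr_ab = self.expr.loc[:, use]
        group_b = in_b[use]
        signals = celltype_signals(expr_ab, markers, scale=self.scale)
        y_all = (np.exp2(expr_ab) if self.scale == "linear" else expr_ab).to_numpy()

        rows = []
        for ct in signals.columns:
            s = signals[ct].to_numpy()
            x = _design(s, group_b)
            xtx = x.T @ x
            if np.linalg.matrix_rank(xtx) < 2:
                for gene in expr_ab.index:
                    rows.append((gene, ct, np.nan, np.nan, np.nan, np.nan, "untestable"))
                continue
            xtx_inv = np.linalg.inv(xtx)
            betas = y_all @ (x @ xtx_inv)  # genes x 2
            resid = y_all - betas @ x.T
            df = x.shape[0] - 2
            sigma2 = (resid**2).sum(axis=1) / df
            se = np.sqrt(sigma2 * xtx_inv[1, 1])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = betas[:, 1] / se
            p = 2.0 * sps.t.sf(np.abs(t), df)
            p[se == 0] = np.where(betas[se == 0, 1] == 0, 1.0, 0.0)
            for i, gene in enumerate(expr_ab.index):
                rows.append((gene, ct, betas[i, 0], betas[i, 1], t[i], p[i], "ok"))

        table = pd.DataFrame(
            rows,
            columns=["gene_id", "cell_type", "slope", "slope_change", "t", "p", "status"],
        )
        table["contrast"] = f"{a}:{b}"
        table["q"] = np.nan
        for ct in signals.columns:
            mask = (table["cell_type"] == ct) & (table["status"] == "ok")
            if mask.any():
                table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
        return PSEAResults(self, table, markers, signals)


@dataclass
class PSEAResults:
    """Per-gene, per-cell-type slope changes with BH-adjusted p-values."""

    model: PSEAModel
    table: pd.DataFrame = field(repr=False)
    markers: dict[str, list[str]] = field(repr=False)
    signals: pd.DataFrame = field(repr=False)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]

    def summary(self, alpha: float = 0.05) -> str:
        a, b = self.model.contrast
        lines = [
            "PSEA: cell-type-adjusted differential expression",
            "=" * 48,
            f"genes tested:     {self.table['gene_id'].nunique()}",
            f"contrast:         {a} vs {b} ({self.model.group_col})",
            f"marker fold rule: {self.model.fold:g}x",
        ]
        for ct in self.signals.columns:
            sub = self.table[(self.table["cell_type"] == ct) & (self.table["status"] == "ok")]
            n_sig = int((sub["q"] < alpha).sum())
            lines.append(
                f"  {ct}: markers={len(self.markers[ct])}, "
                f"significant={n_sig}/{len(sub)} at q<{alpha:g}"
            )
        return "\n".join(lines)
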