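"""Braak stage-related gene (BRG) analysis.

For each donor separately, every gene's expression is (i) correlated with
the ordinal region labels 1-6 and (ii) contrasted between two regions
(default R1 vs R6, fold change = difference of mean log2 expression).
Effect sizes are pooled across donors by DerSimonian-Laird random-effects
meta-analysis — correlations in Fisher-z space with sampling variance
1/(n-3), fold changes with their non-pooled variance — and tested with a
two-sided t-test on k-1 degrees of freedom.  BRGs are the intersection of
the top deciles by |r|, |FC| and smallest BH-corrected fold-change p-value,
split into negatively and positively correlated sets by the sign of the
summary correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_io import ExpressionMatrix
from .stats import bh_adjust, inverse_fisher, pool_effects, welch_contrast

logger = logging.getLogger(__name__)

__all__ = [
    "stage_correlation",
    "region_fold_change",
    "summarize_genes",
    "BRGSelection",
    "select_brgs",
    "BraakGeneModel",
    "BraakGeneResults",
]


def _as_frame(expr) -> pd.DataFrame:
    return expr.data if isinstance(expr, ExpressionMatrix) else expr


def _labels_for(expr_frame: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    labels = samples.set_index("sample_id")["braak_region"]
    labels = labels.reindex(expr_frame.columns).dropna().astype(int)
    return labels


def stage_correlation(expr_donor, samples: pd.DataFrame) -> pd.Series:
    """Pearson correlation of each gene with the region labels 1-6.

    Only the donor's labeled samples enter; genes with zero expression
    variance get NaN (excluded from the meta-analysis downstream).
    """
    frame = _as_frame(expr_donor)
    labels = _labels_for(frame, samples)
    if len(labels) < 4:
        raise ValueError(
            f"need >= 4 labeled samples for a usable correlation, got {len(labels)}"
        )
    x = frame[labels.index].to_numpy()
    y = labels.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = math.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r[sx == 0] = np.nan
    return pd.Series(r, index=frame.index, name="r")


def region_fold_change(
    expr_donor, samples: pd.DataFrame, region_a: int = 1, region_b: int = 6
) -> pd.DataFrame:
    """Per-gene contrast between two regions within one donor.

    fc = mean(region_b) - mean(region_a) on the log2 scale, so genes rising
    along the staging axis have positive fold change for the default R1->R6
    contrast.  Returns columns fc, var_fc (non-pooled) and p (Welch t-test).
    """
    frame = _as_frame(expr_donor)
    labels = _labels_for(frame, samples)
    ids_a = labels.index[labels == region_a]
    ids_b = labels.index[labels == region_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"regions R{region_a}/R{region_b} need >= 2 samples each "
            f"(got {len(ids_a)}, {len(ids_b)})"
        )
    fc, var_fc, p = welch_contrast(frame[ids_a].to_numpy(), frame[ids_b].to_numpy())
    return pd.DataFrame(
        {"fc": fc, "var_fc": var_fc, "p": p,
         "n_a": len(ids_a), "n_b": len(ids_b)},
        index=frame.index,
    )


def summarize_genes(
    donor_expr: dict[str, object],
    samples: pd.DataFrame,
    contrast: tuple[int, int] = (1, 6),
    min_donors: int = 2,
) -> pd.DataFrame:
    """Per-donor statistics pooled across donors into one row per gene.

    Correlations are pooled in Fisher-z space with variance 1/(n-3) and the
    summary is back-transformed to r; fold changes are pooled with their
    non-pooled variances.  BH correction is applied separately to the
    correlation and fold-change p-value columns, across all retained genes.
    Genes with usable effects in fewer than ``min_donors`` donors are
    dropped (and counted in the log).
    """
    donors = sorted(donor_expr)
    genes = _as_frame(donor_expr[donors[0]]).index
    k = len(donors)
    z = np.full((len(genes), k), np.nan)
    var_z = np.full((len(genes), k), np.nan)
    fc = np.full((len(genes), k), np.nan)
    var_fc = np.full((len(genes), k), np.nan)

    for j, donor in enumerate(donors):
        frame = _as_frame(donor_expr[donor])
        if not frame.index.equals(genes):
            raise ValueError("all donors must share the same gene set and order")
        sub = samples[samples["donor_id"] == donor]
        labels = _labels_for(frame, sub)
        n = len(labels)
        r = stage_correlation(frame, sub).to_numpy()
        usable = np.isfinite(r) & (np.abs(r) < 1.0 - 1e-12)
        z[usable, j] = np.arctanh(r[usable])
        var_z[usable, j] = 1.0 / (n - 3)
        table = region_fold_change(frame, sub, *contrast)
        ok = table["var_fc"].to_numpy() > 0
        fc[ok, j] = table["fc"].to_numpy()[ok]
        var_fc[ok, j] = table["var_fc"].to_numpy()[ok]

    n_r = np.isfinite(z).sum(axis=1)
    n_fc = np.isfinite(fc).sum(axis=1)
    keep = (n_r >= min_donors) & (n_fc >= min_donors)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("summarize_genes: dropped %d genes with < %d usable donors",
                    dropped, min_donors)

    z_sum, z_se, z_tau2, z_t, z_p, _ = pool_effects(z[keep], var_z[keep])
    f_sum, f_se, f_tau2, f_t, f_p, _ = pool_effects(fc[keep], var_fc[keep])
    out = pd.DataFrame(
        {
            "r": inverse_fisher(z_sum),
            "se_r": z_se,
            "tau2_r": z_tau2,
            "p_r": z_p,
            "q_r": bh_adjust(z_p),
            "fc": f_sum,
            "se_fc": f_se,
            "tau2_fc": f_tau2,
            "p_fc": f_p,
            "q_fc": bh_adjust(f_p),
            "n_donors_r": n_r[keep],
            "n_donors_fc": n_fc[keep],
        },
        index=genes[keep],
    )
    out.index.name = "gene_id"
    return out


@dataclass(frozen=True)
class BRGSelection:
    """Triple top-decile intersection, split by sign of the summary correlation."""

    fraction: float
    r_cut: float
    fc_cut: float
    p_cut: float
    negative_genes: tuple[str, ...]
    positive_genes: tuple[str, ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.negative_genes + self.positive_genes))

    def __len__(self) -> int:
        return len(self.negative_genes) + len(self.positive_genes)


def select_brgs(summary: pd.DataFrame, fraction: float = 0.10) -> BRGSelection:
    """Intersect the top ``fraction`` of genes by |r|, |FC| and smallest q_FC.

    Each list takes exactly floor(fraction * G) genes, boundary ties broken
    by gene id; the reported thresholds are the boundary values of each top
    set (the least extreme included value).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if summary.empty:
        raise ValueError("empty gene summary")
    n_top = int(math.floor(fraction * len(summary)))
    if n_top == 0:
        raise ValueError("fraction selects zero genes")

    by_id = summary.sort_index()
    top_r = by_id.reindex(
        by_id["r"].abs().sort_values(ascending=False, kind="mergesort").index
    ).index[:n_top]
    top_fc = by_id.reindex(
        by_id["fc"].abs().sort_values(ascending=False, kind="mergesort").index
    ).index[:n_top]
    top_q = by_id.reindex(
        by_id["q_fc"].sort_values(ascending=True, kind="mergesort").index
    ).index[:n_top]

    selected = set(top_r) & set(top_fc) & set(top_q)
    sign = summary.loc[sorted(selected), "r"]
    return BRGSelection(
        fraction=fraction,
        r_cut=float(summary.loc[top_r, "r"].abs().min()),
        fc_cut=float(summary.loc[top_fc, "fc"].abs().min()),
        p_cut=float(summary.loc[top_q, "q_fc"].max()),
        negative_genes=tuple(sign.index[sign < 0]),
        positive_genes=tuple(sign.index[sign >= 0]),
    )


class BraakGeneModel:
    """Meta-analytic gene-stage model over a multi-donor expression atlas.

    Parameters
    ----------
    donor_expr
        Mapping donor id -> log2 expression (genes x samples), all donors
        sharing one gene index.
    samples
        Sample annotations with ``sample_id``, ``donor_id`` and an assigned
        ``braak_region`` column (unassigned samples are ignored).
    contrast
        Pair of region labels for the fold-change contrast; default (1, 6).
    """

    def __init__(self, donor_expr, samples: pd.DataFrame,
                 contrast: tuple[int, int] = (1, 6)):
        self.donor_expr = dict(donor_expr)
        self.samples = samples
        self.contrast = tuple(contrast)

    @classmethod
    def from_directory(cls, expr_dir, samples: pd.DataFrame, **kwargs):
        """Load one ``expr_<donor>.tsv`` per donor from a directory."""
        from pathlib import Path

        from .atlas_io import read_expression

        donor_expr = {
            p.stem.removeprefix("expr_"): read_expression(p)
            for p in sorted(Path(expr_dir).glob("expr_*.tsv"))
        }
        if not donor_expr:
            raise FileNotFoundError(f"no expr_*.tsv files in {expr_dir}")
        return cls(donor_expr, samples, **kwargs)

    def fit(self, min_donors: int = 2) -> "BraakGeneResults":
        summary = summarize_genes(
            self.donor_expr, self.samples, contrast=self.contrast,
            min_donors=min_donors,
        )
        return BraakGeneResults(self, summary)


@dataclass
class BraakGeneResults:
    """Fitted gene-level summaries with BRG selection and reporting."""

    model: BraakGeneModel
    gene_summary: pd.DataFrame = field(repr=False)

    def select_brgs(self, fraction: float = 0.10) -> BRGSelection:
        return select_brgs(self.gene_summary, fraction=fraction)

    def summary(self, fraction: float = 0.10) -> str:
        sel = self.select_brgs(fraction)
        a, b = self.model.contrast
        lines = [
            "Braak stage-related gene analysis",
            "=" * 40,
            f"genes analyzed:        {len(self.gene_summary)}",
            f"donors:                {len(self.model.donor_expr)}",
            f"contrast:              R{a} vs R{b}",
            f"selection fraction:    {fraction:.2f}",
            f"|r| threshold:         {sel.r_cut:.3f}",
            f"|FC| threshold:        {sel.fc_cut:.3f}",
            f"q_FC threshold:        {sel.p_cut:.3g}",
            f"BRGs selected:         {len(sel)} "
            f"({len(sel.negative_genes)} negative, {len(sel.positive_genes)} positive)",
        ]
        return "\n".join(lines)
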