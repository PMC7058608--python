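"""Consensus co-expression modules and their association with Braak stages.

Per donor, gene-gene Pearson correlation matrices are computed over the
staged (R1-R6) samples and averaged element-wise into a consensus network.
Co-expression is converted to the dissimilarity d = 1 - r (so negatively
correlated genes are maximally dissimilar), hierarchically clustered
(average linkage by default) and split into modules by a bottom-up dynamic
cut of the dendrogram with a minimum module size; genes in no module get
label 0.  Each module is summarized per donor by its eigengene — the first
principal component over samples of the row-standardized module submatrix,
sign-aligned with the module's mean expression — and eigengene-stage
correlations are pooled across donors with the same random-effects
meta-analysis used for single genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .stats import bh_adjust, inverse_fisher, pool_effects
from .braak import _as_frame, _labels_for

logger = logging.getLogger(__name__)

__all__ = [
    "donor_correlation_matrix",
    "consensus",
    "cut_dendrogram",
    "cluster_modules",
    "Eigengene",
    "module_eigengene",
    "module_braak_association",
    "ConsensusModuleModel",
    "ModuleResults",
]


def donor_correlation_matrix(expr_donor, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of genes across one donor's staged samples.

    If ``samples`` is given, columns are restricted to samples with an
    assigned region.  Zero-variance genes get NaN rows/columns; callers must
    exclude them from clustering.
    """
    frame = _as_frame(expr_donor)
    if samples is not None:
        labels = _labels_for(frame, samples)
        frame = frame[labels.index]
    if frame.shape[1] < 3:
        raise ValueError("need >= 3 samples for a correlation network")
    x = frame.to_numpy()
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    n_bad = int((sd == 0).sum())
    if n_bad:
        logger.info("donor_correlation_matrix: %d zero-variance genes flagged", n_bad)
    return pd.DataFrame(r, index=frame.index, columns=frame.index)


def consensus(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-donor correlation matrices."""
    if not matrices:
        raise ValueError("no matrices given")
    first = matrices[0]
    total = first.to_numpy().copy()
    for m in matrices[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("donor matrices must share gene sets and ordering")
        total += m.to_numpy()
    return pd.DataFrame(total / len(matrices), index=first.index, columns=first.columns)


def cut_dendrogram(
    merge_heights: np.ndarray,
    merge_children: np.ndarray,
    n_leaves: int,
    min_size: int,
    split_gap: float = 0.1,
    max_height: float = 0.99,
) -> np.ndarray:
    """Bottom-up dynamic cut of an agglomerative dendrogram.

    Merges are visited in height order.  A merge is *refused* — both sides
    finalized as separate clusters — when either side already holds at least
    ``min_size`` leaves and the merge height exceeds that side's median
    internal merge height by more than ``split_gap``: a large jump above a
    grown cluster's typical height marks the boundary between a coherent
    module and whatever joins it next (the median, unlike the most recent
    merge, is robust to a stretched tail of weakly co-expressed late
    members).  Merges above the absolute ceiling ``max_height`` are always
    refused; at the default 0.99 on the d = 1 - r scale, clusters may only
    join through positive co-expression.  Finalized clusters smaller than
    ``min_size`` become unassigned (label 0); surviving modules are
    relabeled 1..m by decreasing size.
    """
    n_merges = len(merge_heights)
    members: list[list[int] | None] = [[i] for i in range(n_leaves)]
    members += [None] * n_merges
    heights: list[list[float] | None] = [[] for i in range(n_leaves)]
    heights += [None] * n_merges
    closed = np.zeros(n_leaves + n_merges, dtype=bool)

    labels = np.zeros(n_leaves, dtype=int)
    clusters: list[list[int]] = []

    def finalize(node: int) -> None:
        got = members[node]
        if got is not None and len(got) >= min_size:
            clusters.append(got)
        members[node] = None


    for i in range(n_merges):
        a, b = int(merge_children[i, 0]), int(merge_children[i, 1])
        h = float(merge_heights[i])
        node = n_leaves + i
        if closed[a] or closed[b]:
            for child in (a, b):
                if not closed[child]:
                    finalize(child)
            closed[node] = True
            continue
        size_a, size_b = len(members[a]), len(members[b])
        refuse = h > max_height or any(
            size >= min_size and (h - float(np.median(heights[child]))) > split_gap
            for child, size in ((a, size_a), (b, size_b))
        )
        if refuse:
            finalize(a)
            finalize(b)
            closed[node] = True
        else:
            members[node] = members[a] + members[b]
            members[a] = members[b] = None
            heights[node] = heights[a] + heights[b] + [h]
            heights[a] = heights[b] = None

    for node in range(n_leaves + n_merges):
        if not closed[node] and members[node] is not None:
            finalize(node)

    clusters.sort(key=lambda c: (-len(c), min(c)))
    for label, cluster in enumerate(clusters, start=1):
        labels[cluster] = label
    return labels


def cluster_modules(
    net: pd.DataFrame,
    min_size: int = 50,
    linkage: str = "average",
    split_gap: float = 0.1,
    max_height: float = 0.99,
) -> pd.Series:
    """Cluster a consensus network into modules on the dissimilarity 1 - r.

    Returns gene -> module label (0 = unassigned), labels ordered by
    decreasing module size.  ``linkage`` may be "average" (default),
    "single" or "complete".
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    genes = net.index
    if len(genes) < min_size:
        return pd.Series(0, index=genes, name="module")
    r = net.to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ValueError("network contains NaN; exclude flagged genes first")
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 2.0, out=d)
    z = scipy_linkage(squareform(d, checks=False), method=linkage)
    labels = cut_dendrogram(
        z[:, 2], z[:, :2].astype(int), len(genes),
        min_size=min_size, split_gap=split_gap, max_height=max_height,
    )
    n_mod = labels.max()
    logger.info(
        "cluster_modules: %d modules, %d of %d genes assigned",
        n_mod, int((labels > 0).sum()), len(genes),
    )
    return pd.Series(labels, index=genes, name="module")


@dataclass(frozen=True)
class Eigengene:
    """First principal component of a module within one donor."""

    donor_id: str
    module: int
    vector: pd.Series
    explained_variance: float


def module_eigengene(
    expr_donor, module_genes, donor_id: str = "", module: int = 0
) -> Eigengene:
    """Unit-norm first principal component over samples of a module.

    Genes are standardized (zero mean, unit variance across the donor's
    samples) before the decomposition; genes constant in this donor are
    dropped.  The sign is flipped, if needed, so that the eigengene
    correlates positively with the module's mean expression.
    """
    frame = _as_frame(expr_donor).loc[list(module_genes)]
    x = frame.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    usable = sd > 0
    if usable.sum() < 2:
        raise ValueError("module needs >= 2 genes with nonzero variance")
    xs = (x[usable] - x[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    _, s, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]
    mean_expr = x.mean(axis=0)
    mc = mean_expr - mean_expr.mean()
    if float(eig @ mc) < 0:
        eig = -eig
    return Eigengene(
        donor_id=donor_id,
        module=int(module),
        vector=pd.Series(eig, index=frame.columns, name=f"ME{module}"),
        explained_variance=float(s[0] ** 2 / (s**2).sum()),
    )


def module_braak_association(
    eigengenes: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Meta-analyze eigengene-stage correlations across donors.

    ``eigengenes`` maps donor -> (samples x modules) eigengene table.  Each
    module's per-donor Pearson correlation with the region labels is pooled
    in Fisher-z space (variance 1/(n-3)) by DerSimonian-Laird, and BH
    correction runs across all modules.  Modules with q < ``alpha`` are
    flagged significant.
    """
    donors = sorted(eigengenes)
    modules = sorted(set().union(*(eigengenes[d].columns for d in donors)))
    k = len(donors)
    z = np.full((len(modules), k), np.nan)
    var_z = np.full((len(modules), k), np.nan)
    for j, donor in enumerate(donors):
        table = eigengenes[donor]
        labels = samples.set_index("sample_id")["braak_region"]
        labels = labels.reindex(table.index).dropna().astype(int)
        if len(labels) < 4:
            raise ValueError(f"donor {donor}: need >= 4 labeled samples")
        y = labels.to_numpy(dtype=float)
        for i, module in enumerate(modules):
            if module not in table.columns:
                continue
            e = table.loc[labels.index, module].to_numpy(dtype=float)
            if e.std() == 0:
                continue
            r = float(np.corrcoef(e, y)[0, 1])
            if abs(r) >= 1.0 - 1e-12:
                raise ValueError(
                    f"module {module}, donor {donor}: |r| = 1 is outside the "
                    "Fisher transform's domain"
                )
            z[i, j] = np.arctanh(r)
            var_z[i, j] = 1.0 / (len(labels) - 3)

    n_eff = np.isfinite(z).sum(axis=1)
    if np.any(n_eff < 2):
        bad = [m for m, n in zip(modules, n_eff) if n < 2]
        raise ValueError(f"modules with < 2 donor estimates: {bad}")
    summary, se, tau2, t, p, _ = pool_effects(z, var_z)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "r": inverse_fisher(summary),
            "se": se,
            "tau2": tau2,
            "t": t,
            "p": p,
            "q": q,
            "significant": q < alpha,
        },
        index=pd.Index(modules, name="module"),
    )
    return out


class ConsensusModuleModel:
    """Consensus co-expression module detection over a multi-donor atlas.

    Parameters mirror the staging analysis: ``donor_expr`` maps donor id to
    a log2 expression frame (shared gene index), ``samples`` carries the
    assigned region labels.  ``fit`` builds per-donor correlation networks
    on the staged samples, averages them, clusters the consensus, computes
    per-donor eigengenes and pools their stage correlations.
    """

    def __init__(
        self,
        donor_expr,
        samples: pd.DataFrame,
        min_size: int = 50,
        linkage: str = "average",
        split_gap: float = 0.1,
        max_height: float = 0.99,
        alpha: float = 1e-4,
    ):
        self.donor_expr = dict(donor_expr)
        self.samples = samples
        self.min_size = min_size
        self.linkage = linkage
        self.split_gap = split_gap
        self.max_height = max_height
        self.alpha = alpha

    def fit(self) -> "ModuleResults":
        donors = sorted(self.donor_expr)
        matrices = []
        bad_genes: set[str] = set()
        for donor in donors:
            sub = self.samples[self.samples["donor_id"] == donor]
            m = donor_correlation_matrix(self.donor_expr[donor], sub)
            bad = m.index[m.isna().any(axis=1)]
            bad_genes.update(bad)
            matrices.append(m)
        if bad_genes:
            logger.info("excluding %d zero-variance genes from clustering",
                        len(bad_genes))
            keep = matrices[0].index.difference(sorted(bad_genes))
            matrices = [m.loc[keep, keep] for m in matrices]
        net = consensus(matrices)
        partition = cluster_modules(
            net, min_size=self.min_size, linkage=self.linkage,
            split_gap=self.split_gap, max_height=self.max_height,
        )
        module_ids = sorted(set(partition[partition > 0]))
        eigengenes: dict[str, pd.DataFrame] = {}
        explained: dict[int, list[float]] = {m: [] for m in module_ids}
        for donor in donors:
            sub = self.samples[self.samples["donor_id"] == donor]
            frame = _as_frame(self.donor_expr[donor])
            labels = _labels_for(frame, sub)
            staged = frame[labels.index]
            cols = {}
            for m in module_ids:
                genes = partition.index[partition == m]
                eg = module_eigengene(staged, genes, donor_id=donor, module=m)
                cols[m] = eg.vector
                explained[m].append(eg.explained_variance)
            eigengenes[donor] = pd.DataFrame(cols)
        association = module_braak_association(
            eigengenes, self.samples, alpha=self.alpha
        )
        association["size"] = [
            int((partition == m).sum()) for m in association.index
        ]
        association["explained_variance"] = [
            float(np.mean(explained[m])) for m in association.index
        ]
        return ModuleResults(self, net, partition, eigengenes, association)


@dataclass
class ModuleResults:
    """Fitted consensus modules, eigengenes and stage associations."""

    model: ConsensusModuleModel
    network: pd.DataFrame = field(repr=False)
    partition: pd.Series = field(repr=False)
    eigengenes: dict[str, pd.DataFrame] = field(repr=False)
    association: pd.DataFrame = field(repr=False)

    @property
    def significant_modules(self) -> list[int]:
        return list(self.association.index[self.association["significant"]])

    def summary(self) -> str:
        part = self.partition
        assoc = self.association
        lines = [
            "Consensus co-expression module analysis",
            "=" * 40,
            f"genes clustered:       {len(part)}",
            f"modules found:         {int(part.max())}",
            f"genes assigned:        {int((part > 0).sum())}",
            f"largest module size:   {int(part.value_counts().drop(0, errors='ignore').max()) if part.max() > 0 else 0}",
            f"significant modules:   {len(self.significant_modules)} "
            f"(q < {self.model.alpha:g})",
        ]
        if len(assoc):
            top = assoc.reindex(assoc["r"].abs().sort_values(ascending=False).index).head(5)
            lines.append("top modules by |stage correlation|:")
            for m, row in top.iterrows():
                lines.append(
                    f"  M{m}: size={int(row['size'])} r={row['r']:+.2f} q={row['q']:.2e}"
                )
        return "\n".join(lines)
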