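"""Reading, writing and preprocessing of expression data and annotations.

Expression matrices are log2-scale, features (probes or genes) in rows and
samples in columns, stored as tab-separated text.  Sample annotations carry
the donor, the anatomical structure a sample was taken from, and — after
``assign_regions`` — the Braak stage-related region label R1–R6 used as the
ordinal stage axis throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample_id", "donor_id", "structure_name"]
PROBE_COLUMNS = ["probe_id", "gene_id", "presence_fraction"]

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_sample_table",
    "write_sample_table",
    "read_probe_table",
    "read_region_map",
    "write_region_map",
    "read_gmt",
    "write_gmt",
    "filter_probes",
    "collapse_probes",
    "assign_regions",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values, features x samples.

    Wraps a :class:`pandas.DataFrame` whose index holds unique feature ids
    (probes or genes) and whose columns hold unique sample ids.  All values
    must be finite.
    """

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        validate_expression(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def log2p1(self) -> "ExpressionMatrix":
        """Return log2(x + 1) transformed copy, for count-like inputs."""
        return ExpressionMatrix(np.log2(self.data + 1.0))


def validate_expression(frame: pd.DataFrame) -> None:
    for axis, name in ((frame.index, "feature"), (frame.columns, "sample")):
        if axis.has_duplicates:
            dup = axis[axis.duplicated()][0]
            raise ValueError(f"duplicate {name} id: {dup!r}")
    arr = frame.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    bad = ~np.isfinite(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value at feature {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )


def read_expression(path: str | Path, log2_transform: bool = False) -> ExpressionMatrix:
    """Read a features x samples TSV (header = sample ids, first column = feature ids)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad_rows = frame.index[
                pd.to_numeric(frame[col], errors="coerce").isna()
            ]
            raise ValueError(
                f"non-numeric cell in {path.name} at feature {bad_rows[0]!r}, "
                f"sample {col!r}"
            )
    if frame.isna().to_numpy().any():
        i, j = np.argwhere(frame.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {path.name} at feature {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    frame = frame.astype(float)
    em = ExpressionMatrix(frame)
    return em.log2p1() if log2_transform else em


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV with 6 significant digits (round-trip stable at that precision)."""
    expr.data.to_csv(path, sep="\t", float_format="%.6g", index_label="feature_id")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    if "braak_region" in table.columns:
        table["braak_region"] = table["braak_region"].astype("Int64")
        vals = table["braak_region"].dropna()
        if not vals.isin(range(1, 7)).all():
            raise ValueError("braak_region values must be in 1..6")
    return table


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    missing = [c for c in PROBE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    if table["probe_id"].duplicated().any():
        dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id: {dup!r}")
    pf = table["presence_fraction"].astype(float)
    if ((pf < 0) | (pf > 1)).any():
        raise ValueError("presence_fraction outside [0, 1]")
    table["presence_fraction"] = pf
    return table


def read_region_map(path: str | Path) -> dict[str, int]:
    """Two-column TSV: structure_name, braak_region (1-6)."""
    table = pd.read_csv(path, sep="\t")
    cols = list(table.columns[:2])
    mapping: dict[str, int] = {}
    for structure, region in zip(table[cols[0]].astype(str), table[cols[1]]):
        region = int(region)
        if not 1 <= region <= 6:
            raise ValueError(f"region {region} for {structure!r} outside 1..6")
        if structure in mapping and mapping[structure] != region:
            raise ValueError(f"structure {structure!r} mapped to two regions")
        mapping[structure] = region
    return mapping


def write_region_map(mapping: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"structure_name": list(mapping), "braak_region": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Gene sets in GMT: name <tab> description <tab> member ids."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name: {name!r}")
            sets[name] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, description, *sorted(members)]) + "\n")


def filter_probes(
    expr: ExpressionMatrix, probes: pd.DataFrame, min_presence: float = 0.01
) -> ExpressionMatrix:
    """Drop probes without a gene id or expressed above background too rarely.

    A probe is kept iff its ``gene_id`` is non-missing and its
    ``presence_fraction`` (fraction of samples where the detection call is
    "present") is at least ``min_presence``.  Row order is preserved.
    """
    probes = probes.set_index("probe_id")
    missing = expr.feature_ids.difference(probes.index)
    if len(missing) > 0:
        raise ValueError(f"features absent from probe table: {list(missing[:5])}")
    info = probes.loc[expr.feature_ids]
    has_gene = info["gene_id"].notna() & (info["gene_id"].astype(str) != "")
    present = info["presence_fraction"] >= min_presence
    keep = (has_gene & present).to_numpy()
    logger.info(
        "filter_probes: kept %d of %d probes (min_presence=%g)",
        int(keep.sum()), len(keep), min_presence,
    )
    return ExpressionMatrix(expr.data.loc[keep])


def _connectivity(values: np.ndarray) -> np.ndarray:
    """Summed signed correlation of each probe with the gene's other probes."""
    r = np.corrcoef(values)
    np.fill_diagonal(r, 0.0)
    return r.sum(axis=1)


def collapse_probes(expr: ExpressionMatrix, probes: pd.DataFrame) -> ExpressionMatrix:
    """Summarize probe-level expression to one representative probe per gene.

    Selection rules: a single probe represents its gene directly; of two
    probes the one with maximum variance across all samples wins; with three
    or more probes the one with the highest connectivity (summed signed
    correlation with the gene's other probes) wins.  Ties break on the
    lexicographically smallest probe id.
    """
    probe_gene = probes.set_index("probe_id")["gene_id"]
    missing = expr.feature_ids.difference(probe_gene.index)
    if len(missing) > 0:
        raise ValueError(f"probes absent from probe table: {list(missing[:5])}")
    gene_of = probe_gene.loc[expr.feature_ids]
    if gene_of.isna().any():
        raise ValueError("collapse_probes requires a gene_id for every probe")

    rows: list[str] = []
    genes: list[str] = []
    for gene, probe_ids in gene_of.groupby(gene_of).groups.items():
        probe_ids = sorted(probe_ids)
        if len(probe_ids) == 1:
            chosen = probe_ids[0]
        elif len(probe_ids) == 2:
            var = expr.data.loc[probe_ids].var(axis=1, ddof=1)
            chosen = var.loc[probe_ids].idxmax()  # idxmax keeps first (lexicographic) on ties
        else:
            conn = _connectivity(expr.data.loc[probe_ids].to_numpy())
            chosen = probe_ids[int(np.argmax(conn))]  # argmax keeps first on ties
        rows.append(chosen)
        genes.append(str(gene))
    collapsed = expr.data.loc[rows]
    collapsed.index = pd.Index(genes, name="gene_id")
    collapsed = collapsed.sort_index()
    logger.info("collapse_probes: %d probes -> %d genes", expr.shape[0], len(genes))
    return ExpressionMatrix(collapsed)


def assign_regions(samples: pd.DataFrame, region_map: dict[str, int]) -> pd.DataFrame:
    """Assign each sample a Braak stage-related region label from its structure.

    Structures absent from the map stay unassigned (missing label); this is a
    valid state, not an error.
    """
    out = samples.copy()
    out["braak_region"] = (
        out["structure_name"].map(region_map).astype("Int64")
    )
    counts = out["braak_region"].value_counts().sort_index()
    logger.info(
        "assign_regions: %d of %d samples assigned (%s)",
        int(out["braak_region"].notna().sum()),
        len(out),
        ", ".join(f"R{r}={n}" for r, n in counts.items()),
    )
    return out
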