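"""Reading, filtering and writing of count tables and result matrices.

File dialect: UTF-8 tab-separated text with one header row of ids and one
id column; the first header cell may be empty. Decimal separator is ``.``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = ["read_count_table", "filter_table", "write_results", "write_count_table"]


def read_count_table(path, orientation: str = "samples_as_rows") -> CountTable:
    """Read a tab-separated count table into canonical orientation.

    Parameters
    ----------
    path
        TSV file with a header row of ids and a leading id column.
    orientation
        ``"samples_as_rows"`` if file rows are samples, ``"components_as_rows"``
        if file rows are components; the returned table is always samples x
        components.
    """
    if orientation not in ("samples_as_rows", "components_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    col_ids = [c.strip() for c in header[1:]]
    if len(set(col_ids)) != len(col_ids):
        dupes = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise ValueError(f"duplicate column ids in {path.name}: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8")
    df.columns = col_ids
    row_ids = [str(r).strip() for r in df.index]
    mat = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        try:
            val = float(cell)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r}"
            ) from None
        if val < 0 or val != int(val):
            raise ValueError(
                f"count must be a nonnegative integer, got {cell!r} at "
                f"row {row_ids[i]!r}, column {col_ids[j]!r}"
            )
        mat[i, j] = int(val)
    if orientation == "components_as_rows":
        return CountTable(mat.T, sample_ids=col_ids, component_ids=row_ids)
    return CountTable(mat, sample_ids=row_ids, component_ids=col_ids)


def write_count_table(table: CountTable, path) -> None:
    """Write a count table as TSV, samples as rows."""
    df = pd.DataFrame(
        table.counts, index=table.sample_ids, columns=table.component_ids
    )
    df.to_csv(path, sep="\t")


def filter_table(
    table: CountTable, min_sample_reads: int = 0, min_mean_count: float = 0.0
) -> CountTable:
    """Apply sequencing-depth and rarity quality filters.

    Samples with total reads below ``min_sample_reads`` are dropped first;
    then components whose mean count per *remaining* sample falls below
    ``min_mean_count`` are dropped. Survivor order is preserved. The
    conventional thresholds for 16S survey data are 500 reads per sample and
    a mean of 2 reads per component.

    This is a single pass: component removal shrinks sample totals, so
    re-applying with both thresholds active can remove further samples.
    Each filter alone is idempotent.
    """
    if min_sample_reads < 0 or min_mean_count < 0:
        raise ValueError("thresholds must be nonnegative")
    keep_s = table.sample_totals() >= min_sample_reads
    if not keep_s.any():
        raise ValueError("all samples removed by min_sample_reads filter")
    counts = table.counts[keep_s]
    keep_c = counts.mean(axis=0) >= min_mean_count
    if not keep_c.any():
        raise ValueError("all components removed by min_mean_count filter")
    taxonomy = None
    comp_ids = [c for c, k in zip(table.component_ids, keep_c) if k]
    if table.taxonomy is not None:
        taxonomy = {c: table.taxonomy[c] for c in comp_ids if c in table.taxonomy}
    return CountTable(
        counts[:, keep_c],
        sample_ids=[s for s, k in zip(table.sample_ids, keep_s) if k],
        component_ids=comp_ids,
        taxonomy=taxonomy,
    )


def _matrix_frame(mat: np.ndarray, ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(mat, dtype=float), index=ids, columns=ids)


def write_results(
    corr,
    pvals: np.ndarray | None = None,
    threshold: float = 0.3,
    out_prefix="sparcc",
    component_ids: list[str] | None = None,
) -> list[Path]:
    """Write a correlation matrix, optional p-values, edge list and GraphML.

    The edge list contains exactly the unordered pairs ``i < j`` with
    ``|rho| > threshold`` (undefined entries excluded); the GraphML export
    carries the same edges with the correlation as edge weight.

    Returns the list of written paths.
    """
    rho = np.asarray(getattr(corr, "rho", corr), dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(rho, rho.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    D = rho.shape[0]
    if component_ids is None:
        component_ids = [f"c{i}" for i in range(D)]
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    corr_path = out_prefix.with_name(out_prefix.name + ".corr.tsv")
    _matrix_frame(rho, component_ids).to_csv(corr_path, sep="\t")
    written.append(corr_path)

    if pvals is not None:
        p_path = out_prefix.with_name(out_prefix.name + ".pvals.tsv")
        _matrix_frame(pvals, component_ids).to_csv(p_path, sep="\t")
        written.append(p_path)

    graph = nx.Graph()
    graph.add_nodes_from(component_ids)
    edges = []
    for i in range(D):
        for j in range(i + 1, D):
            r = rho[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                edges.append(
                    (component_ids[i], component_ids[j], r, "+" if r > 0 else "-")
                )
                graph.add_edge(component_ids[i], component_ids[j], weight=float(r))

    edge_path = out_prefix.with_name(out_prefix.name + ".edges.tsv")
    with open(edge_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["component_i", "component_j", "correlation", "sign"])
        for ci, cj, r, sign in edges:
            writer.writerow([ci, cj, repr(float(r)), sign])
    written.append(edge_path)

    gml_path = out_prefix.with_name(out_prefix.name + ".graphml")
    nx.write_graphml(graph, gml_path)
    written.append(gml_path)
    return written
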