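"""Readers, writers and gene-universe plumbing.

All tabular inputs are plain TSV: a genes × samples matrix with a header row
of sample identifiers and gene symbols in the first column; a two-column
(sample, group) label table; and a two- or three-column edge list (SIF-style
interaction columns are tolerated and ignored).  Gene identifiers are opaque
strings — no symbol translation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: accepted spellings for the two outcome groups in a label table
_GROUP_ALIASES = {
    "positive": POSITIVE, "lts": POSITIVE, "long": POSITIVE, "1": POSITIVE,
    "negative": NEGATIVE, "sts": NEGATIVE, "short": NEGATIVE, "0": NEGATIVE,
}


@dataclass
class OmicsMatrix:
    """Genes × samples measurements for one analyte, plus optional group labels."""

    analyte: str
    values: pd.DataFrame  # rows = genes, columns = samples
    labels: pd.Series | None = None  # sample -> "positive" | "negative"

    def __post_init__(self) -> None:
        if self.analyte not in ("expression", "methylation"):
            raise ValueError(f"unknown analyte tag {self.analyte!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene symbol: {dup!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            raise ValueError(f"duplicate sample id: {cols[cols.duplicated()][0]!r}")
        if self.values.isna().any().any():
            raise ValueError("matrix contains missing values after loading")
        if self.labels is not None:
            missing = set(self.labels.index) - set(cols)
            if missing:
                raise ValueError(
                    f"labeled sample(s) absent from matrix: {sorted(missing)}"
                )
            groups = set(self.labels)
            if not groups <= {POSITIVE, NEGATIVE}:
                raise ValueError(f"unknown group tag(s): {sorted(groups - {POSITIVE, NEGATIVE})}")
            if len(groups) < 2:
                raise ValueError("both groups must be non-empty when labels are present")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        if self.labels is None:
            raise ValueError("matrix carries no labels")
        return [s for s in self.samples if self.labels.get(s) == group]

    def restrict_genes(self, genes: Iterable[str]) -> "OmicsMatrix":
        keep = [g for g in self.genes if g in set(genes)]
        return OmicsMatrix(self.analyte, self.values.loc[keep], self.labels)

    def restrict_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        labels = self.labels.loc[[s for s in samples if s in self.labels.index]] if self.labels is not None else None
        return OmicsMatrix(self.analyte, self.values[list(samples)], labels)


def read_labels(path: str | Path) -> pd.Series:
    """Read a (sample, group) TSV; a `sample<TAB>group` header line is optional."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 columns, got {len(parts)}")
            rows.append(parts)
    if rows and [c.lower() for c in rows[0]] == ["sample", "group"]:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: empty label table")
    samples, groups = zip(*rows)
    mapped = []
    for s, g in rows:
        tag = _GROUP_ALIASES.get(g.strip().lower())
        if tag is None:
            raise ValueError(f"{path}: unknown group value {g!r} for sample {s!r}")
        mapped.append(tag)
    series = pd.Series(mapped, index=list(samples), name="group")
    if series.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample in label table")
    return series


def read_omics_matrix(
    path: str | Path,
    analyte: str,
    labels_path: str | Path | None = None,
) -> OmicsMatrix:
    """Load a genes × samples TSV, dropping genes with any missing value.

    A duplicated gene symbol or a non-numeric cell is a hard error; rows with
    missing entries are removed (the count is logged) so downstream statistics
    always see complete rows.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene symbol {dup!r}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "") \
            & (raw[col].str.strip().str.lower() != "nan")
        if bad.any():
            gene = raw.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
        values[col] = converted
    n_before = len(values)
    values = values.dropna(axis=0, how="any")
    dropped = n_before - len(values)
    if dropped:
        logger.warning("%s: dropped %d gene row(s) with missing values", path, dropped)
    labels = read_labels(labels_path) if labels_path is not None else None
    return OmicsMatrix(analyte=analyte, values=values, labels=labels)


def read_network(path: str | Path) -> nx.Graph:
    """Read a TSV/SIF edge list into an undirected simple graph.

    Two columns are an edge; three columns are SIF (`a  type  b`). Self-loops
    are discarded with a logged count; duplicate edges collapse silently.
    """
    graph = nx.Graph()
    n_loops = 0
    n_lines = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p for p in line.replace("\t", " ").split(" ") if p]
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                a, b = parts[0], parts[2]
            else:
                raise ValueError(f"{path}: malformed line {ln}: {line!r}")
            n_lines += 1
            if a == b:
                n_loops += 1
                continue
            graph.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"{path}: empty network file")
    if n_loops:
        logger.warning("%s: discarded %d self-loop(s)", path, n_loops)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def intersect_gene_universe(
    expr: OmicsMatrix, meth: OmicsMatrix, net: nx.Graph
) -> tuple[OmicsMatrix, OmicsMatrix, nx.Graph]:
    """Restrict both matrices and the network to their common gene set."""
    common = set(expr.genes) & set(meth.genes) & set(net.nodes)
    if not common:
        raise ValueError("empty gene intersection between expression, methylation and network")
    logger.info("gene universe: %d common genes", len(common))
    return (
        expr.restrict_genes(common),
        meth.restrict_genes(common),
        net.subgraph(common).copy(),
    )


def giant_connected_component(net: nx.Graph) -> nx.Graph:
    """Largest connected component; size ties go to the lexicographically
    smallest sorted node list so the backbone is reproducible."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [sorted(c) for c in nx.connected_components(net)]
    top = max(len(c) for c in comps)
    best = min(c for c in comps if len(c) == top)
    return net.subgraph(best).copy()


# ---------------------------------------------------------------------------
# module (gene set) exchange


def write_modules_gmt(modules: Sequence, path: str | Path) -> None:
    """Write modules in GMT: name, `analyte=..;score=..;p=..`, member genes.

    Duplicate module names are suffixed `.2`, `.3`, … to stay unique.
    """
    if not modules:
        raise ValueError("no modules to write")
    seen: dict[str, int] = {}
    with open(path, "w") as fh:
        for i, mod in enumerate(modules):
            name = getattr(mod, "name", None) or f"module{i + 1:03d}"
            if name in seen:
                seen[name] += 1
                name = f"{name}.{seen[name]}"
            else:
                seen[name] = 1
            score = "NA" if mod.score is None else f"{mod.score:.6g}"
            pval = "NA" if mod.pvalue is None else f"{mod.pvalue:.6g}"
            desc = f"analyte={mod.analyte};score={score};p={pval}"
            genes = "\t".join(sorted(mod.genes))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_modules_gmt(path: str | Path) -> list:
    """Read a GMT written by :func:`write_modules_gmt` back into modules."""
    from .search import Module

    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {ln}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            meta = dict(kv.split("=", 1) for kv in desc.split(";") if "=" in kv)
            score = None if meta.get("score", "NA") == "NA" else float(meta["score"])
            pval = None if meta.get("p", "NA") == "NA" else float(meta["p"])
            out.append(
                Module(
                    genes=frozenset(genes),
                    analyte=meta.get("analyte", "expression"),
                    score=score,
                    pvalue=pval,
                    name=name,
                )
            )
    return out


def write_node_attributes(
    modules: Sequence,
    path: str | Path,
    q_by_analyte: Mapping[str, Mapping[str, float]] | None = None,
) -> None:
    """TSV of (gene, module, analyte, per-analyte q) for network viewers."""
    q_by_analyte = q_by_analyte or {}
    analytes = sorted(q_by_analyte)
    with open(path, "w") as fh:
        header = ["gene", "module", "analyte"] + [f"q_{a}" for a in analytes]
        fh.write("\t".join(header) + "\n")
        for i, mod in enumerate(modules):
            name = getattr(mod, "name", None) or f"module{i + 1:03d}"
            for g in sorted(mod.genes):
                qs = [f"{q_by_analyte[a].get(g, float('nan')):.6g}" for a in analytes]
                fh.write("\t".join([g, name, mod.analyte] + qs) + "\n")


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in labels.items():
            fh.write(f"{s}\t{g}\n")


def collapse_duplicate_rows(values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Representative-row rule for symbols measured more than once (e.g. several
    promoter probes per gene): keep, per duplicated symbol, the row whose
    absolute between-group mean difference is largest.

    This is a pre-processing helper for raw tables; the default read path
    (:func:`read_omics_matrix`) expects matrices already collapsed to one row
    per gene and treats duplicates as errors.
    """
    pos = [s for s in values.columns if labels.get(s) == POSITIVE]
    neg = [s for s in values.columns if labels.get(s) == NEGATIVE]
    if not pos or not neg:
        raise ValueError("collapse requires both groups among the columns")
    diff = (values[pos].mean(axis=1) - values[neg].mean(axis=1)).abs()
    order = pd.DataFrame({"diff": diff, "pos": range(len(values))}, index=values.index)
    keep = (
        order.sort_values(["diff", "pos"], ascending=[False, True])
        .groupby(level=0, sort=False)
        .head(1)["pos"]
        .sort_values()
    )
    return values.iloc[list(keep)]
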