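"""Readers and writers for every external representation the pipeline touches.

All downstream modules operate on the in-memory domain types defined here:
:class:`InteractionRecord`, :class:`ExpressionMatrix`, and plain pandas
survival tables.  Gene identifiers are upper-cased symbols throughout;
probe-to-symbol mapping is the caller's responsibility.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as missing in expression tables.  Anything else
#: non-numeric is an error, to surface corrupt inputs early.
MISSING_TOKENS = frozenset({"", "NA", "null"})

_HEADER_WORDS = {"source", "target", "from", "to", "tf", "gene1", "gene2", "gene_a", "gene_b"}


class InteractionKind(str, enum.Enum):
    """Interaction class: protein-protein (undirected) or protein-DNA (TF -> target)."""

    PPI = "PPI"
    PDI = "PDI"


@dataclass(frozen=True)
class InteractionRecord:
    """One interaction edge between two gene symbols.

    PPIs are bidirectional, PDIs are unidirectional (transcription factor to
    target gene); the ``directed`` flag is forced by ``kind``.
    """

    source: str
    target: str
    kind: InteractionKind

    @property
    def directed(self) -> bool:
        return self.kind is InteractionKind.PDI


class ParseError(ValueError):
    """Malformed content in an input file."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample class labels.

    ``values`` is a DataFrame indexed by unique upper-case gene symbols with
    sample ids as columns; missing measurements are NaN, never silent zeros.
    ``sample_class`` maps each sample id to ``normal``/``polyp``/``tumor``/
    ``unknown``.
    """

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        self.sample_class = self.sample_class.reindex(self.values.columns).fillna("unknown")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_class(self, label: str) -> list[str]:
        return list(self.sample_class.index[self.sample_class == label])


def _open_rows(path: str | Path) -> list[list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    rows: list[list[str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append([lineno, *line.split("\t")])  # keep line number for errors
    return rows


def read_interaction_table(path: str | Path, kind: InteractionKind | str) -> list[InteractionRecord]:
    """Read a two-column TSV of gene-symbol pairs as interactions of one kind.

    Duplicates are preserved; deduplication happens at network construction.
    An optional header row (recognised by common column names) is skipped.
    """
    kind = InteractionKind(kind)
    rows = _open_rows(path)
    records: list[InteractionRecord] = []
    for i, (lineno, *fields) in enumerate(rows):
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected >=2 tab-separated columns")
        a, b = fields[0].strip(), fields[1].strip()
        if i == 0 and (a.lower() in _HEADER_WORDS or b.lower() in _HEADER_WORDS):
            continue
        records.append(InteractionRecord(a.upper(), b.upper(), kind))
    return records


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; comments and blanks skipped; upper-cased."""
    return [fields[0].strip().upper() for _, *fields in _open_rows(path)]


def _parse_cell(token: str, path, lineno: int) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: non-numeric cell {token!r} outside missing-value tokens"
        ) from None


def read_expression_matrix(
    path: str | Path, class_map: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a gene x sample TSV, or a GEO-series-matrix-style block.

    GEO series-matrix files delimit the table with
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end``; lines
    starting with ``!`` outside the block are metadata and ignored.  Duplicate
    gene symbols are collapsed by the mean of their rows (logged).  Sample
    classes come from ``class_map`` (default ``unknown``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    lines = path.read_text().splitlines()
    in_block = True
    if any(l.startswith("!series_matrix_table_begin") for l in lines):
        in_block = False
    header: list[str] | None = None
    genes: list[str] = []
    data: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("!series_matrix_table_begin"):
            in_block = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_block = False
            continue
        if not in_block or not line.strip() or line.startswith(("#", "!")):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip().strip('"') for f in fields[1:]]
            continue
        genes.append(fields[0].strip().strip('"').upper())
        data.append([_parse_cell(tok, path, lineno) for tok in fields[1:]])
    if header is None:
        raise ParseError(f"{path}: no header row found")
    df = pd.DataFrame(data, index=genes, columns=header, dtype=float)
    if df.index.duplicated().any():
        ndup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean in %s", ndup, path)
        df = df.groupby(level=0, sort=False).mean()
    classes = pd.Series(
        {s: (class_map or {}).get(s, "unknown") for s in df.columns}, dtype=object
    )
    return ExpressionMatrix(df, classes)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6f", index_label="gene", na_rep="NA")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (sample, time, event in {0,1}); returns a sample-indexed frame.

    Times are in months and must be non-negative; sample ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.lower() for c in df.columns]
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicated sample ids")
    if (df["time"] < 0).any():
        raise ParseError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event column must be 0/1")
    out = df.set_index("sample")[["time", "event"]].astype({"time": float, "event": int})
    return out


def write_survival_table(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Network serialization (dialects: edge_tsv, graphml, sif)
# ---------------------------------------------------------------------------

NETWORK_DIALECTS = ("edge_tsv", "graphml", "sif")
_SIF_TOKEN = {"PPI": "pp", "PDI": "pd"}
_SIF_KIND = {v: k for k, v in _SIF_TOKEN.items()}


def _rounded_graph(graph: nx.DiGraph) -> nx.DiGraph:
    g = graph.copy()
    for _, _, d in g.edges(data=True):
        d["distance"] = round(float(d.get("distance", 1.0)), 6)
    return g


def write_network(network, path: str | Path, dialect: str = "edge_tsv") -> None:
    """Serialize a bridge network; round trip is exact at 6-decimal distances.

    ``edge_tsv`` keeps node roles (and isolated nodes) in ``# node`` comment
    lines above the header.  ``sif`` follows the Cytoscape convention and
    stores roles / distances in ``.noa`` / ``.eda`` sidecar files next to the
    main file, since SIF lines carry only the relation token (``pp``/``pd``).
    """
    if dialect not in NETWORK_DIALECTS:
        raise ValueError(f"unknown network dialect {dialect!r}; expected one of {NETWORK_DIALECTS}")
    path = Path(path)
    g = _rounded_graph(network.graph)
    roles = {n: (network.role(n) or "intermediate") for n in g.nodes}
    if dialect == "graphml":
        for n, d in g.nodes(data=True):
            d["role"] = roles[n]
        nx.write_graphml(g, path)
        return
    if dialect == "edge_tsv":
        with path.open("w") as fh:
            for n in sorted(g.nodes):
                fh.write(f"# node\t{n}\t{roles[n]}\n")
            fh.write("source\ttarget\tkind\tdistance\n")
            for u, v, d in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d.get('kind', 'PPI')}\t{d['distance']:.6f}\n")
        return
    # sif + sidecars
    with path.open("w") as fh:
        written = set()
        for u, v, d in sorted(g.edges(data=True)):
            kind = d.get("kind", "PPI")
            if kind == "PPI" and (v, u) in written:
                continue  # one undirected sif line per antiparallel PPI pair
            fh.write(f"{u}\t{_SIF_TOKEN[kind]}\t{v}\n")
            written.add((u, v))
        for n in sorted(nx.isolates(g)):
            fh.write(f"{n}\n")
    with path.with_suffix(path.suffix + ".noa").open("w") as fh:
        fh.write("node\trole\n")
        for n in sorted(g.nodes):
            fh.write(f"{n}\t{roles[n]}\n")
    with path.with_suffix(path.suffix + ".eda").open("w") as fh:
        fh.write("source\ttarget\tkind\tdistance\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('kind', 'PPI')}\t{d['distance']:.6f}\n")


def read_network(path: str | Path, dialect: str = "edge_tsv"):
    """Inverse of :func:`write_network` for all three dialects."""
    from .network import BridgeNetwork  # local import to avoid a cycle

    if dialect not in NETWORK_DIALECTS:
        raise ValueError(f"unknown network dialect {dialect!r}; expected one of {NETWORK_DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    g = nx.DiGraph()
    if dialect == "graphml":
        raw = nx.read_graphml(path)
        for n, d in raw.nodes(data=True):
            g.add_node(str(n), role=d.get("role", "intermediate"))
        for u, v, d in raw.edges(data=True):
            g.add_edge(str(u), str(v), kind=d.get("kind", "PPI"), distance=float(d["distance"]))
        return BridgeNetwork(g)
    if dialect == "edge_tsv":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("# node\t"):
                    _, n, role = line.split("\t")
                    g.add_node(n, role=role)
                    continue
                if line.startswith("#") or line.startswith("source\t"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ParseError(f"{path}: line {lineno}: expected 4 columns")
                u, v, kind, dist = fields
                g.add_edge(u, v, kind=kind, distance=float(dist))
        return BridgeNetwork(g)
    # sif
    eda = path.with_suffix(path.suffix + ".eda")
    noa = path.with_suffix(path.suffix + ".noa")
    with path.open() as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1 and fields[0].strip():
                g.add_node(fields[0].strip())
            elif len(fields) >= 3:
                u, token, v = fields[0], fields[1], fields[2]
                kind = _SIF_KIND.get(token, "PPI")
                g.add_edge(u, v, kind=kind, distance=1.0)
                if kind == "PPI":
                    g.add_edge(v, u, kind=kind, distance=1.0)
    if eda.exists():
        edge_attrs = pd.read_csv(eda, sep="\t")
        for _, row in edge_attrs.iterrows():
            g.add_edge(row["source"], row["target"], kind=row["kind"], distance=float(row["distance"]))
    if noa.exists():
        node_attrs = pd.read_csv(noa, sep="\t")
        for _, row in node_attrs.iterrows():
            g.add_node(row["node"], role=row["role"])
    return BridgeNetwork(g)
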