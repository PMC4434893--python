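"""Readers and writers for the package's external file formats.

Formats handled here:

* regulation tables — one curated regulation per row (regulator id, regulator
  class, target id, target class, optional source database), tab-separated by
  default;
* plain ID lists — one identifier per line, ``#`` comments allowed;
* SIF and GraphML network exports (Cytoscape interchange);
* scored-path tables (TSV).

All writers emit deterministically ordered output so files are diffable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ContractError, ParseError, ValidationError

#: Node classes a regulator may carry.
REGULATOR_CLASSES = ("TF", "miRNA")
#: Node classes a target may carry.  "gene" means a non-TF target gene.
TARGET_CLASSES = ("TF", "gene", "miRNA")

_CLASS_ALIASES = {c.lower(): c for c in ("TF", "miRNA", "gene")}

PATH_TABLE_COLUMNS = (
    "path",
    "path_length",
    "n_known",
    "de_fraction",
    "coverage_ratio",
    "p_value",
)


@dataclass(frozen=True)
class RegulationRecord:
    """One directed curated regulation.

    A transcription factor may regulate genes, other TFs or miRNAs; a miRNA
    may repress genes or TFs but never another miRNA.
    """

    regulator_id: str
    regulator_class: str
    target_id: str
    target_class: str
    source_db: str = ""

    def __post_init__(self):
        object.__setattr__(self, "regulator_id", self.regulator_id.strip())
        object.__setattr__(self, "target_id", self.target_id.strip())
        object.__setattr__(self, "source_db", self.source_db.strip())
        if not self.regulator_id or not self.target_id:
            raise ValidationError("regulation with empty regulator or target id")
        if self.regulator_class not in REGULATOR_CLASSES:
            raise ValidationError(
                f"unknown regulator class {self.regulator_class!r} "
                f"(expected one of {REGULATOR_CLASSES})"
            )
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(
                f"unknown target class {self.target_class!r} "
                f"(expected one of {TARGET_CLASSES})"
            )
        if self.regulator_class == "miRNA" and self.target_class == "miRNA":
            raise ValidationError(
                f"miRNA->miRNA regulation {self.regulator_id}->{self.target_id} "
                "is not allowed"
            )


def _normalise_class(token: str, line_number: int) -> str:
    try:
        return _CLASS_ALIASES[token.strip().lower()]
    except KeyError:
        raise ParseError(f"unknown class token {token.strip()!r}", line_number) from None


def read_regulations(
    path: str | Path,
    *,
    delimiter: str = "\t",
    header: bool = False,
    uppercase_genes: bool = False,
) -> list[RegulationRecord]:
    """Read a regulation table into an ordered list of records.

    Duplicate rows are retained here (the network builder collapses them).
    Rows starting with ``#`` and blank lines are skipped.  With
    ``uppercase_genes=True`` TF/gene symbols are upper-cased while miRNA
    names keep their case (miRNA nomenclature is case-sensitive).

    Raises :class:`ParseError` on a row with fewer than 4 columns or an
    unknown class token, and :class:`ValidationError` on a miRNA->miRNA row;
    both name the offending line number.
    """
    path = Path(path)
    records: list[RegulationRecord] = []
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for line_number, row in enumerate(reader, start=1):
            if header and line_number == 1:
                continue
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if all(not field.strip() for field in row):
                continue
            if len(row) < 4:
                raise ParseError(
                    f"expected at least 4 columns, found {len(row)}", line_number
                )
            reg_id, reg_class, tgt_id, tgt_class = (field.strip() for field in row[:4])
            source_db = row[4].strip() if len(row) > 4 else ""
            reg_class = _normalise_class(reg_class, line_number)
            tgt_class = _normalise_class(tgt_class, line_number)
            if uppercase_genes:
                if reg_class != "miRNA":
                    reg_id = reg_id.upper()
                if tgt_class != "miRNA":
                    tgt_id = tgt_id.upper()
            try:
                record = RegulationRecord(reg_id, reg_class, tgt_id, tgt_class, source_db)
            except ValidationError as exc:
                raise ValidationError(f"line {line_number}: {exc}") from None
            records.append(record)
    return records


def write_regulations(
    records: Iterable[RegulationRecord],
    path: str | Path,
    *,
    delimiter: str = "\t",
    header: bool = False,
) -> None:
    """Write records in reading order; inverse of :func:`read_regulations`."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        if header:
            writer.writerow(
                ["regulator_id", "regulator_class", "target_id", "target_class", "source_db"]
            )
        for rec in records:
            writer.writerow(
                [rec.regulator_id, rec.regulator_class, rec.target_id, rec.target_class, rec.source_db]
            )


def read_id_list(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line file into a de-duplicated set.

    ``#`` comment lines and blank lines are skipped; surrounding whitespace
    is trimmed.  An empty file yields an empty set.
    """
    ids: set[str] = set()
    with Path(path).open() as handle:
        for line in handle:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            ids.add(token)
    return ids


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for token in sorted(ids):
            handle.write(f"{token}\n")


# --- network exports -------------------------------------------------------

def _relation_for(net, regulator: str) -> str:
    # miRNA edges are repressive; everything a TF does is generic regulation.
    return "inh" if net.node_class.get(regulator) == "miRNA" else "reg"


def write_sif(net, path: str | Path) -> None:
    """Write a network in SIF; edges as ``regulator <relation> target``.

    The relation token is ``reg`` for TF edges and ``inh`` for miRNA edges.
    Isolated nodes appear as single-token lines.  Edge lines come first in
    lexicographic order, then isolated nodes.
    """
    lines = []
    connected: set[str] = set()
    for u, v in sorted(net.edges):
        lines.append(f"{u} {_relation_for(net, u)} {v}")
        connected.update((u, v))
    for node in sorted(set(net.nodes) - connected):
        lines.append(node)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sif(path: str | Path):
    """Read a SIF file back into a :class:`~regpath.network.RegulatoryNetwork`.

    Node classes are inferred from relation tokens (``inh`` source = miRNA,
    ``reg`` source = TF, pure targets = gene); classes beyond that inference
    are not stored in SIF, so a GraphML round-trip is lossless where SIF is
    not.
    """
    from .network import build_network

    records = []
    isolated: list[str] = []
    with Path(path).open() as handle:
        for line_number, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 1:
                isolated.append(fields[0])
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"SIF line must have 1 or 3 tokens, found {len(fields)}", line_number
                )
            source, relation, target = fields
            if relation == "inh":
                reg_class = "miRNA"
            elif relation == "reg":
                reg_class = "TF"
            else:
                raise ParseError(f"unknown SIF relation {relation!r}", line_number)
            records.append(RegulationRecord(source, reg_class, target, "gene"))
    net = build_network(records)
    for node in isolated:
        net.add_node(node, "gene")
    return net


def write_graphml(net, path: str | Path) -> None:
    """Write a network as GraphML with node attribute ``class``, edge
    attributes ``relation`` and ``sources`` (comma-joined provenance)."""
    graph = nx.DiGraph()
    for node in sorted(net.nodes):
        graph.add_node(node, **{"class": net.node_class[node]})
    for u, v in sorted(net.edges):
        graph.add_edge(
            u,
            v,
            relation=_relation_for(net, u),
            sources=",".join(sorted(net.edge_provenance.get((u, v), set()))),
        )
    nx.write_graphml(graph, path)


def read_graphml(path: str | Path):
    """Read a GraphML file written by :func:`write_graphml`."""
    from .network import RegulatoryNetwork

    graph = nx.read_graphml(path)
    net = RegulatoryNetwork()
    for node, data in graph.nodes(data=True):
        net.add_node(str(node), data.get("class", "gene"))
    for u, v, data in graph.edges(data=True):
        sources = {s for s in data.get("sources", "").split(",") if s}
        net.add_edge(str(u), str(v), sources)
    return net


def write_paths_table(scored_paths: Sequence, path: str | Path) -> None:
    """Write scored paths as a TSV sorted by ascending p-value then path.

    Columns: path (nodes joined by ``->``), path_length, n_known,
    de_fraction, coverage_ratio, p_value.  Raises :class:`ContractError` if
    handed anything that is not a scored path.
    """
    from .pathfind import PathScore

    rows = []
    for item in scored_paths:
        if not isinstance(item, PathScore):
            raise ContractError(
                f"write_paths_table requires scored paths, got {type(item).__name__}"
            )
        rows.append(
            {
                "path": "->".join(item.path.nodes),
                "path_length": item.path.length,
                "n_known": item.n_known,
                "de_fraction": item.de_fraction,
                "coverage_ratio": item.coverage_ratio,
                "p_value": item.p_value,
            }
        )
    frame = pd.DataFrame(rows, columns=list(PATH_TABLE_COLUMNS))
    frame = frame.sort_values(["p_value", "path"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)


def read_paths_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
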