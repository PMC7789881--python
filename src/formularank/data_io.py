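"""Readers, writers and validation for every table and graph format the pipeline touches.

All inputs are plain delimited text (TSV/CSV with header, SIF, GMT). Gene and
protein identifiers are uppercased on ingestion; component names are
case-folded and whitespace-collapsed before any set comparison, so
"Berberine " and "berberine" refer to the same component.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ("mw", "alogp", "hdon", "hacc", "caco2", "ob", "dl")
#: descriptors that may be absent from a component table (the packaged
#: formula fixture prints only OB and DL)
OPTIONAL_DESCRIPTORS = ("mw", "alogp", "hdon", "hacc", "caco2")


class DataError(Exception):
    """Base class for ingestion failures."""


class SchemaError(DataError):
    """A required column or field is missing."""


class ParseError(DataError):
    """A cell could not be parsed; message cites the offending row."""


def normalize_name(name: str) -> str:
    """Canonical form of a component name: case-folded, whitespace collapsed."""
    return " ".join(name.split()).casefold()


def normalize_symbol(symbol: str) -> str:
    """Canonical form of a gene/protein symbol: stripped and uppercased."""
    return symbol.strip().upper()


@dataclass
class ComponentRecord:
    """One herb-component row with its pharmacological descriptors.

    ``ob`` (oral bioavailability, percent) and ``dl`` (drug-likeness in
    [0, 1]) are mandatory because they drive the ADME screen; the remaining
    five descriptors may be missing.
    """

    record_id: str
    name: str
    herb: str
    ob: float
    dl: float
    role_label: Optional[str] = None
    mw: Optional[float] = None
    alogp: Optional[float] = None
    hdon: Optional[int] = None
    hacc: Optional[int] = None
    caco2: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError(f"record {self.record_id!r}: empty component name")
        if not self.herb or not self.herb.strip():
            raise ValueError(f"record {self.record_id!r}: empty herb label")
        if self.ob < 0:
            raise ValueError(f"record {self.record_id!r}: ob must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"record {self.record_id!r}: dl must be in [0, 1], got {self.dl}")
        for attr in ("hdon", "hacc"):
            v = getattr(self, attr)
            if v is not None and (v != int(v) or v < 0):
                raise ValueError(f"record {self.record_id!r}: {attr} must be a nonnegative integer")
        if self.mw is not None and self.mw < 0:
            raise ValueError(f"record {self.record_id!r}: mw must be >= 0")

    @property
    def norm_name(self) -> str:
        return normalize_name(self.name)

    def descriptor(self, key: str) -> Optional[float]:
        if key not in DESCRIPTOR_COLUMNS:
            raise KeyError(key)
        return getattr(self, key)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Pathway id -> (description, uppercased gene set)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out |= gs.genes
        return frozenset(out)


@dataclass
class DiseaseGeneTable:
    """Pathogenic genes with nonnegative relevance scores, unique by symbol."""

    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, s in self.scores.items():
            if s < 0:
                raise ValueError(f"disease gene {g}: negative relevance score {s}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.scores)

    def __len__(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# component tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("name", "herb") + DESCRIPTOR_COLUMNS


def _sniff_delimiter(path: Path, explicit: Optional[str]) -> str:
    if explicit:
        return explicit
    if path.suffix.lower() in {".tsv", ".tab", ".txt"}:
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _parse_float(cell: str, column: str, row_num: int) -> Optional[float]:
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN"}:
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"row {row_num}: cannot parse {column}={cell!r} as a number") from None


def read_component_table(path: str | Path, delimiter: Optional[str] = None) -> list[ComponentRecord]:
    """Parse a component table (TSV/CSV with header) into records, row order preserved.

    The header must name ``name``, ``herb`` and the seven descriptor columns
    (case-insensitive); a ``record_id`` and a ``role`` column are optional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path, delimiter)
    records: list[ComponentRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        colmap = {c.strip().lower(): c for c in reader.fieldnames}
        for required in _REQUIRED_COLUMNS:
            if required not in colmap:
                raise SchemaError(f"{path}: missing required column {required!r}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            name = (row[colmap["name"]] or "").strip()
            herb = (row[colmap["herb"]] or "").strip()
            ob = _parse_float(row[colmap["ob"]] or "", "ob", i)
            dl = _parse_float(row[colmap["dl"]] or "", "dl", i)
            if ob is None or dl is None:
                raise ParseError(f"row {i}: ob and dl are required")
            kwargs: dict = {}
            for col in OPTIONAL_DESCRIPTORS:
                val = _parse_float(row[colmap[col]] or "", col, i)
                if col in ("hdon", "hacc") and val is not None:
                    if val != int(val):
                        raise ParseError(f"row {i}: {col}={val} is not an integer")
                    val = int(val)
                kwargs[col] = val
            rid = (row.get(colmap.get("record_id", ""), "") or "").strip() or f"row{i - 1}"
            role_col = colmap.get("role") or colmap.get("role_label")
            role = (row.get(role_col, "") or "").strip() or None if role_col else None
            try:
                records.append(
                    ComponentRecord(record_id=rid, name=name, herb=herb, ob=ob, dl=dl,
                                    role_label=role, **kwargs)
                )
            except ValueError as exc:
                raise ParseError(f"row {i}: {exc}") from None
    return records


def write_component_table(records: Iterable[ComponentRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "name", "herb", "role"] + list(DESCRIPTOR_COLUMNS))
        for r in records:
            writer.writerow(
                [r.record_id, r.name, r.herb, r.role_label or ""]
                + ["" if r.descriptor(c) is None else r.descriptor(c) for c in DESCRIPTOR_COLUMNS]
            )


def load_formula_fixture() -> list[ComponentRecord]:
    """The packaged 114-row four-herb formula component table."""
    with resources.as_file(resources.files("formularank").joinpath("data/hjd_components.tsv")) as p:
        return read_component_table(p)


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


def _add_collapsed_edge(g: nx.Graph, u: str, v: str, w: float) -> bool:
    """Add an undirected edge, collapsing duplicates by max weight.

    Returns True if the edge was a self-loop (and therefore dropped).
    """
    if w <= 0:
        raise ValueError(f"edge ({u}, {v}): weight must be > 0, got {w}")
    if u == v:
        return True
    if g.has_edge(u, v):
        g[u][v]["weight"] = max(g[u][v]["weight"], w)
    else:
        g.add_edge(u, v, weight=w)
    return False


def read_edge_list(path: str | Path, fmt: Optional[str] = None,
                   kind: str = "protein") -> nx.Graph:
    """Read a two/three-column TSV or a SIF file into an undirected graph.

    Self-loops are dropped (count logged); duplicate edges are collapsed by
    maximum weight; node ids are uppercased symbols with node attribute
    ``kind`` (default ``protein``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    g = nx.Graph()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "sif":
                if len(fields) < 3:
                    raise ParseError(f"line {line_num}: SIF needs source, relation, >=1 target")
                src = normalize_symbol(fields[0])
                for tgt in fields[2:]:
                    dropped += _add_collapsed_edge(g, src, normalize_symbol(tgt), 1.0)
            else:
                if line_num == 1 and fields[0].strip().lower() in {"source", "from", "node1"}:
                    continue  # optional header
                if len(fields) < 2:
                    raise ParseError(f"line {line_num}: need source and target columns")
                w = 1.0
                if len(fields) >= 3 and fields[2].strip():
                    w = _parse_float(fields[2], "weight", line_num)
                dropped += _add_collapsed_edge(
                    g, normalize_symbol(fields[0]), normalize_symbol(fields[1]), w
                )
    if g.number_of_nodes() == 0:
        raise DataError(f"{path}: no edges parsed (empty graph)")
    if dropped:
        logger.info("%s: dropped %d self-loop(s)", path, dropped)
    nx.set_node_attributes(g, kind, "kind")
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\tkind\n")
        for u, v, data in sorted(g.edges(data=True)):
            kinds = "{}-{}".format(g.nodes[u].get("kind", "?"), g.nodes[v].get("kind", "?"))
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0)}\t{kinds}\n")


# ---------------------------------------------------------------------------
# gene sets, disease genes, target maps, name lists
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: id, description, genes...)."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {line_num}: GMT line needs id, description, >=1 gene")
            name = fields[0].strip()
            genes = frozenset(normalize_symbol(f) for f in fields[2:] if f.strip())
            if not genes:
                raise ParseError(f"line {line_num}: gene set {name!r} is empty")
            if name in coll:
                logger.warning("duplicate gene-set id %r at line %d: last occurrence wins", name, line_num)
            coll.sets[name] = GeneSet(name=name, description=fields[1].strip(), genes=genes)
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description] + sorted(gs.genes)) + "\n")


def read_disease_genes(path: str | Path, delimiter: Optional[str] = None) -> DiseaseGeneTable:
    """Read a two-column (symbol, relevance score) table; duplicates keep max score."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    scores: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delim)
            if (line_num == 1 and fields[0].strip().lower() in {"gene", "symbol", "name"}
                    and (len(fields) < 2 or not _is_number(fields[1]))):
                continue
            if len(fields) < 2:
                raise ParseError(f"line {line_num}: need symbol and score columns")
            sym = normalize_symbol(fields[0])
            score = _parse_float(fields[1], "score", line_num)
            if score is None or score < 0:
                raise ValueError(f"line {line_num}: relevance score must be >= 0, got {fields[1]!r}")
            scores[sym] = max(scores.get(sym, 0.0), score)
    return DiseaseGeneTable(scores=scores)


def write_disease_genes(table: DiseaseGeneTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\trelevance_score\n")
        for g in sorted(table.scores):
            fh.write(f"{g}\t{table.scores[g]}\n")


def read_target_map(path: str | Path, delimiter: Optional[str] = None) -> dict[str, frozenset[str]]:
    """Read a two-column (component name, target symbol) map into
    normalized-name -> deduplicated uppercased target sets."""
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delim)
            if line_num == 1 and fields[0].strip().lower() in {"component", "name", "compound"}:
                continue
            if len(fields) < 2:
                raise ParseError(f"line {line_num}: need component and target columns")
            name = normalize_name(fields[0])
            if not name:
                raise ParseError(f"line {line_num}: empty component name")
            mapping.setdefault(name, set()).add(normalize_symbol(fields[1]))
    return {k: frozenset(v) for k, v in mapping.items()}


def write_target_map(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("component\ttarget\n")
        for name in sorted(mapping):
            for t in sorted(mapping[name]):
                fh.write(f"{name}\t{t}\n")


def read_name_list(path: str | Path) -> frozenset[str]:
    """Read a one-column list of component names (e.g. blood-absorbed components)."""
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            name = normalize_name(line.rstrip("\n"))
            if name and name not in {"component", "name"}:
                names.add(name)
    return frozenset(names)


def write_name_list(names: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in sorted(names):
            fh.write(n + "\n")
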