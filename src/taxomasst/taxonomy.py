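"""File metadata, lineage resolution, and the ranked taxonomic tree.

Every reference file carries a 10-column metadata row (the monoculture
library schema): MassIVE path, dataset-qualified unique file id, dataset id,
submitted taxon name, optional corrected name, optional NCBI id, whether the
id was assigned automatically or manually curated, a ReDU-metadata flag, and
blank/QC flags.

Taxa resolve to ranked lineages through a pre-exported lineage table (no
live NCBI queries). When a record's NCBI id is unknown, the corrected
("alternative") name is tried against a name→id fallback — the
closest-accurate-taxon rule, e.g. an unregistered strain curated to its
species. Records resolvable by neither path are generically classified to a
domain-level Bacteria/Fungi/Archaea placeholder from their submitted name.

The tree keeps the main ranks (a coarsest "domain" head, then kingdom to
strain) plus subgenus, subspecies and varietas, so lineages have comparable
depth; other ranks are dropped, their counts re-attaching to the nearest
kept ancestor. Blank, QC, and human cell-line files live under dedicated
special children of the root (negative synthetic ids) and are excluded from
the biological sample totals, so per-taxon match proportions reflect
biological files only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from skbio import TreeNode as _SkbioTree

from .exceptions import (
    InconsistentLineageError,
    MetadataValidationError,
    SchemaError,
    UnresolvableTaxonError,
)

__all__ = [
    "RANKS",
    "FileRecord",
    "LineageStep",
    "Lineage",
    "TaxonNode",
    "load_metadata",
    "write_metadata",
    "load_lineage_table",
    "write_lineage_table",
    "resolve_taxon",
    "build_tree",
    "walk",
    "export_newick",
    "parse_newick",
]

# Kept biological ranks, coarse -> fine. "domain" heads the three-domain tree
# (Bacteria / Archaea / Eukaryota-side kingdoms such as Fungi are normalised
# to this level); strain is the finest.
RANKS: tuple[str, ...] = (
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "subgenus",
    "species",
    "subspecies",
    "varietas",
    "strain",
)
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

SPECIAL_RANKS = ("root", "blank", "qc", "cell_line")

ROOT_ID = 1
BLANK_ID = -1
QC_ID = -2
CELL_LINE_ID = -3
HUMAN_TAXID = 9606

BACTERIA = (2, "Bacteria", "domain")
ARCHAEA = (2157, "Archaea", "domain")
FUNGI = (4751, "Fungi", "domain")


@dataclass(frozen=True)
class FileRecord:
    """One reference file's metadata row."""

    massive_path: str
    file_id: str
    dataset_id: str
    taxon_name_submitted: str
    taxon_name_alternative: str | None
    ncbi_id: int | None
    id_assignment: str  # "automatic" | "manual"
    has_redu_metadata: bool
    is_blank: bool
    is_qc: bool

    def __post_init__(self) -> None:
        if self.is_blank and self.is_qc:
            raise MetadataValidationError(
                f"{self.file_id}: a file cannot be both blank and QC"
            )
        if self.ncbi_id is not None and self.ncbi_id <= 0:
            raise MetadataValidationError(f"{self.file_id}: ncbi_id must be positive")
        if self.id_assignment not in ("automatic", "manual"):
            raise MetadataValidationError(
                f"{self.file_id}: id_assignment must be automatic/manual, "
                f"got {self.id_assignment!r}"
            )


METADATA_COLUMNS = (
    "massive_path",
    "file_id",
    "dataset_id",
    "taxon_name_submitted",
    "taxon_name_alternative",
    "ncbi_id",
    "id_assignment",
    "has_redu_metadata",
    "is_blank",
    "is_qc",
)

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", "", "nan", "none"}


def _parse_bool(value, column: str, row: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise MetadataValidationError(f"{row}: cannot parse {column}={value!r} as boolean")


def load_metadata(path: str | Path) -> list[FileRecord]:
    """Load and validate the per-file metadata table (CSV or TSV).

    The header must contain the 10 schema columns (order-insensitive; extra
    columns are ignored). Duplicate file ids and rows flagged both blank and
    QC are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table is missing column(s): {', '.join(missing)}")
    records: list[FileRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        file_id = row["file_id"].strip()
        if file_id in seen:
            raise MetadataValidationError(f"duplicate file_id: {file_id}")
        seen.add(file_id)
        raw_ncbi = row["ncbi_id"].strip()
        ncbi_id = int(float(raw_ncbi)) if raw_ncbi not in ("", "nan", "NA") else None
        alt = row["taxon_name_alternative"].strip() or None
        records.append(
            FileRecord(
                massive_path=row["massive_path"].strip(),
                file_id=file_id,
                dataset_id=row["dataset_id"].strip(),
                taxon_name_submitted=row["taxon_name_submitted"].strip(),
                taxon_name_alternative=alt,
                ncbi_id=ncbi_id,
                id_assignment=row["id_assignment"].strip().lower(),
                has_redu_metadata=_parse_bool(row["has_redu_metadata"], "has_redu_metadata", file_id),
                is_blank=_parse_bool(row["is_blank"], "is_blank", file_id),
                is_qc=_parse_bool(row["is_qc"], "is_qc", file_id),
            )
        )
    return records


def write_metadata(records: Iterable[FileRecord], path: str | Path) -> None:
    rows = [
        {
            "massive_path": r.massive_path,
            "file_id": r.file_id,
            "dataset_id": r.dataset_id,
            "taxon_name_submitted": r.taxon_name_submitted,
            "taxon_name_alternative": r.taxon_name_alternative or "",
            "ncbi_id": "" if r.ncbi_id is None else r.ncbi_id,
            "id_assignment": r.id_assignment,
            "has_redu_metadata": r.has_redu_metadata,
            "is_blank": r.is_blank,
            "is_qc": r.is_qc,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Lineages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineageStep:
    ncbi_id: int
    name: str
    rank: str


@dataclass(frozen=True)
class Lineage:
    """Ordered (coarse → fine) chain of kept-rank taxa down to the terminal."""

    steps: tuple[LineageStep, ...]

    def __post_init__(self) -> None:
        last = -1
        for step in self.steps:
            if step.rank not in _RANK_INDEX:
                raise ValueError(f"rank {step.rank!r} not in the kept rank set")
            idx = _RANK_INDEX[step.rank]
            if idx <= last:
                raise ValueError("lineage ranks must be strictly coarse-to-fine")
            last = idx

    def __iter__(self) -> Iterator[LineageStep]:
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def terminal(self) -> LineageStep:
        return self.steps[-1]


def make_lineage(triples: Iterable[tuple[int, str, str]]) -> Lineage:
    """Build a `Lineage` from (ncbi_id, name, rank) triples, dropping any
    rank outside the kept set (its counts re-attach to the nearest kept
    ancestor by construction)."""
    steps = tuple(
        LineageStep(int(i), str(n), str(r)) for i, n, r in triples if r in _RANK_INDEX
    )
    return Lineage(steps)


def write_lineage_table(table: Mapping[int, Lineage], path: str | Path) -> None:
    """Serialize a lineage table as TSV: ncbi_id <TAB> rank:name:id|... ."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ncbi_id\tlineage\n")
        for ncbi_id in sorted(table):
            lineage = table[ncbi_id]
            for step in lineage:
                if ":" in step.name or "|" in step.name:
                    raise ValueError(f"taxon name {step.name!r} contains reserved characters")
            text = "|".join(f"{s.rank}:{s.name}:{s.ncbi_id}" for s in lineage)
            fh.write(f"{ncbi_id}\t{text}\n")


def load_lineage_table(path: str | Path) -> dict[int, Lineage]:
    table: dict[int, Lineage] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"ncbi_id", "lineage"} <= set(df.columns):
        raise SchemaError("lineage table needs columns: ncbi_id, lineage")
    for _, row in df.iterrows():
        steps = []
        for part in row["lineage"].split("|"):
            rank, name, ncbi = part.split(":")
            steps.append((int(ncbi), name, rank))
        table[int(row["ncbi_id"])] = make_lineage(steps)
    return table


def name_fallback_from_table(lineage_table: Mapping[int, Lineage]) -> dict[str, int]:
    """Name → NCBI id map over every taxon a lineage table mentions; the
    lookup behind the closest-accurate-taxon fallback."""
    out: dict[str, int] = {}
    for lineage in lineage_table.values():
        for step in lineage:
            out[step.name] = step.ncbi_id
    return out


_GENERIC = (
    ("archae", Lineage((LineageStep(*ARCHAEA),))),
    ("fung", Lineage((LineageStep(*FUNGI),))),
    ("bacter", Lineage((LineageStep(*BACTERIA),))),
)


def resolve_taxon(
    record: FileRecord,
    lineage_table: Mapping[int, Lineage],
    fallback: Mapping[str, int] | None = None,
) -> Lineage | None:
    """Resolve a file record to its lineage.

    Resolution order: the record's NCBI id; then the corrected/submitted
    name through the name→id fallback (closest-accurate-taxon rule); then a
    generic domain-level placeholder inferred from the submitted name.
    Blank/QC records need no lineage and return None. A biological record
    with no resolution path raises `UnresolvableTaxonError`.
    """
    if record.is_blank or record.is_qc:
        return None
    if record.ncbi_id is not None and record.ncbi_id in lineage_table:
        return lineage_table[record.ncbi_id]
    fallback = fallback or {}
    for name in (record.taxon_name_alternative, record.taxon_name_submitted):
        if name and name in fallback and fallback[name] in lineage_table:
            return lineage_table[fallback[name]]
    haystack = " ".join(
        n for n in (record.taxon_name_submitted, record.taxon_name_alternative) if n
    ).lower()
    for needle, lineage in _GENERIC:
        if needle in haystack:
            return lineage
    raise UnresolvableTaxonError(
        f"{record.file_id}: no NCBI id, no fallback name, no generic "
        f"classification for {record.taxon_name_submitted!r}"
    )


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


@dataclass
class TaxonNode:
    """Node of the ranked taxonomic tree.

    ``n_samples`` counts library files in the subtree (specials count only
    under their special children); ``matched_files`` holds the distinct
    matched file ids after aggregation.
    """

    ncbi_id: int
    name: str
    rank: str
    children: list["TaxonNode"] = field(default_factory=list)
    files: list[FileRecord] = field(default_factory=list)
    n_samples: int = 0
    matched_files: set[str] = field(default_factory=set)

    @property
    def n_matched(self) -> int:
        return len(self.matched_files)

    @property
    def proportion(self) -> float:
        return self.n_matched / self.n_samples if self.n_samples else 0.0

    def child_by_name(self, name: str) -> "TaxonNode | None":
        for c in self.children:
            if c.name == name:
                return c
        return None


def walk(root: TaxonNode) -> Iterator[TaxonNode]:
    """Pre-order traversal."""
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _recount(node: TaxonNode) -> int:
    node.n_samples = len(node.files) + sum(_recount(c) for c in node.children)
    return node.n_samples


def recount_samples(root: TaxonNode) -> None:
    _recount(root)


def build_tree(
    records: Iterable[FileRecord],
    lineages: Mapping[str, Lineage | None],
) -> TaxonNode:
    """Assemble the taxonomic tree from resolved file records.

    One node per distinct NCBI id on any lineage; blank/QC files attach to
    dedicated special children of the root; human cell-line files (lineage
    terminating in Homo sapiens) form a cell_line subtree with one child per
    submitted culture name. Two lineages disagreeing on a node's parent (or
    on its name/rank) raise `InconsistentLineageError`.
    """
    root = TaxonNode(ROOT_ID, "root", "root")
    specials: dict[str, TaxonNode] = {}

    def special(rank: str, ncbi_id: int, name: str) -> TaxonNode:
        if rank not in specials:
            node = TaxonNode(ncbi_id, name, rank)
            root.children.append(node)
            specials[rank] = node
        return specials[rank]

    registry: dict[int, TaxonNode] = {ROOT_ID: root}
    parent_of: dict[int, int] = {}
    cell_children: dict[str, TaxonNode] = {}
    next_cell_id = CELL_LINE_ID - 100

    for record in records:
        if record.is_blank:
            special("blank", BLANK_ID, "blank").files.append(record)
            continue
        if record.is_qc:
            special("qc", QC_ID, "QC").files.append(record)
            continue
        lineage = lineages.get(record.file_id)
        if lineage is None or len(lineage) == 0:
            raise InconsistentLineageError(f"{record.file_id}: record has no resolved lineage")
        if any(step.ncbi_id == HUMAN_TAXID for step in lineage):
            parent = special("cell_line", CELL_LINE_ID, "cell lines")
            name = record.taxon_name_submitted or "cell line"
            if name not in cell_children:
                node = TaxonNode(next_cell_id, name, "cell_line")
                next_cell_id -= 1
                parent.children.append(node)
                cell_children[name] = node
            cell_children[name].files.append(record)
            continue
        current = root
        for step in lineage:
            node = registry.get(step.ncbi_id)
            if node is None:
                node = TaxonNode(step.ncbi_id, step.name, step.rank)
                registry[step.ncbi_id] = node
                parent_of[step.ncbi_id] = current.ncbi_id
                current.children.append(node)
            else:
                if parent_of.get(step.ncbi_id) != current.ncbi_id:
                    raise InconsistentLineageError(
                        f"taxon {step.ncbi_id} ({step.name}) appears under two parents"
                    )
                if node.name != step.name or node.rank != step.rank:
                    raise InconsistentLineageError(
                        f"taxon {step.ncbi_id} has conflicting name/rank across lineages"
                    )
            current = node
        current.files.append(record)

    recount_samples(root)
    return root


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _to_skbio(node: TaxonNode) -> _SkbioTree:
    sk = _SkbioTree(name=node.name)
    sk.extend([_to_skbio(c) for c in node.children])
    return sk


def _from_skbio(sk: _SkbioTree) -> TaxonNode:
    node = TaxonNode(0, sk.name or "", "")
    node.children = [_from_skbio(c) for c in sk.children]
    return node


def export_newick(root: TaxonNode) -> str:
    """Serialize the tree topology + names as a Newick string (counts live
    only in the JSON export). Names with metacharacters are quoted per the
    standard."""
    buf = io.StringIO()
    _to_skbio(root).write(buf)
    return buf.getvalue().strip()


def parse_newick(text: str) -> TaxonNode:
    """Inverse of `export_newick` for topology and names."""
    sk = _SkbioTree.read(io.StringIO(text), format="newick")
    return _from_skbio(sk)
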