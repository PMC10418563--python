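"""Project matches onto the taxonomic tree and emit the result artifacts.

A match found in a file is credited to every ancestor taxon of that file's
lineage ("upstream propagation"): per node, the matched-file set is the
union of its children's sets plus its directly attached matched files, and
n_matched counts DISTINCT matched files (a file matched by many scans
counts once — the only reading under which the per-taxon proportion
n_matched / n_samples is bounded by 1; per-scan detail remains available in
dataset_matches.tsv). Blank/QC/cell-line matches are recorded on their
special nodes and reported separately from the biological taxa.

Outputs mirror the tool's three result tabs — library matches (compound
annotations), dataset matches (per-scan hits), taxa matches (per-taxon
counts) — plus a nested-JSON tree and a standalone collapsible HTML tree
with all data embedded inline.
"""

from __future__ import annotations

import copy
import html as _html
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConsistencyError, ParameterError
from .search_engine import AnnotationMatch, MatchResult
from .taxonomy import (
    RANKS,
    SPECIAL_RANKS,
    TaxonNode,
    recount_samples,
    walk,
)

_RANK_SORT = {r: i for i, r in enumerate(("root",) + RANKS + ("blank", "qc", "cell_line"))}

__all__ = [
    "TreeFilter",
    "aggregate",
    "reset_matches",
    "has_cell_line_match",
    "flag_cell_line_overlap",
    "classify_domain",
    "classify_domains",
    "domain_match_counts",
    "filter_tree",
    "taxa_table",
    "tree_to_json",
    "emit_outputs",
]


@dataclass(frozen=True)
class TreeFilter:
    """Interactive-style tree filter: collapse below a rank, prune by
    minimum match count."""

    max_rank: str | None = None
    min_matches: int = 0

    def __post_init__(self) -> None:
        if self.max_rank is not None and self.max_rank not in RANKS:
            raise ParameterError(f"unknown rank {self.max_rank!r}; choose from {RANKS}")
        if self.min_matches < 0:
            raise ParameterError("min_matches must be >= 0")


def reset_matches(root: TaxonNode) -> None:
    for node in walk(root):
        node.matched_files.clear()


def aggregate(matches: Iterable[MatchResult], root: TaxonNode) -> TaxonNode:
    """Annotate the tree with distinct matched files, propagated upstream.

    Previous aggregation state is cleared first. A match referencing a file
    not attached anywhere in the tree raises `ConsistencyError`.
    """
    reset_matches(root)
    file_to_node: dict[str, TaxonNode] = {}
    for node in walk(root):
        for rec in node.files:
            file_to_node[rec.file_id] = node
    for m in matches:
        fid = m.record.file_id
        node = file_to_node.get(fid)
        if node is None:
            raise ConsistencyError(f"match references unattached file {fid!r}")
        node.matched_files.add(fid)

    def up(node: TaxonNode) -> set[str]:
        for child in node.children:
            node.matched_files |= up(child)
        return node.matched_files

    up(root)
    return root


def has_cell_line_match(root: TaxonNode) -> bool:
    """True iff >= 1 matched file lies under the cell_line special subtree."""
    for child in root.children:
        if child.rank == "cell_line":
            return child.n_matched > 0
    return False


def flag_cell_line_overlap(per_query: Mapping[str, TaxonNode]) -> dict[str, bool]:
    """Per-query cell-line overlap flags from per-query aggregated trees."""
    return {qid: has_cell_line_match(tree) for qid, tree in per_query.items()}


def domain_match_counts(root: TaxonNode) -> dict[str, int]:
    """Matched-file counts for each domain-level subtree (Bacteria, Fungi,
    Archaea, ...)."""
    return {c.name: c.n_matched for c in root.children if c.rank == "domain"}


def classify_domain(root: TaxonNode) -> str:
    """Label an aggregated query tree by matched-domain membership.

    One of ``bacteria_only``, ``fungi_only``, ``both``, ``none`` from
    matched-file presence under the Bacteria vs Fungi subtrees (Archaea
    counts are reported separately via `domain_match_counts`).
    """
    counts = domain_match_counts(root)
    bacteria = counts.get("Bacteria", 0) > 0
    fungi = counts.get("Fungi", 0) > 0
    if bacteria and fungi:
        return "both"
    if bacteria:
        return "bacteria_only"
    if fungi:
        return "fungi_only"
    return "none"


def classify_domains(per_query: Mapping[str, TaxonNode]) -> dict[str, str]:
    return {qid: classify_domain(tree) for qid, tree in per_query.items()}


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_tree(root: TaxonNode, f: TreeFilter) -> TaxonNode:
    """Collapse nodes finer than ``max_rank`` into their kept ancestor and
    prune nodes with fewer than ``min_matches`` matched files.

    Collapsing re-attaches files and matched sets upward, so counts are
    conserved; ancestors of surviving nodes are always retained. Operates on
    a deep copy — the input tree is untouched.
    """
    out = copy.deepcopy(root)
    if f.max_rank is not None:
        limit = RANKS.index(f.max_rank)

        def collapse(node: TaxonNode) -> None:
            kept: list[TaxonNode] = []
            for child in node.children:
                collapse(child)
                too_fine = (
                    child.rank in RANKS and RANKS.index(child.rank) > limit
                )
                if too_fine:
                    # child's own finer descendants were already merged into
                    # it by the recursive call (ranks only get finer downward)
                    node.files.extend(child.files)
                    node.matched_files |= child.matched_files
                else:
                    kept.append(child)
            node.children = kept

        collapse(out)
    if f.min_matches > 0:

        def prune(node: TaxonNode) -> bool:
            node.children = [c for c in node.children if prune(c)]
            return bool(node.children) or node.n_matched >= f.min_matches

        out.children = [c for c in out.children if prune(c)]
    recount_samples(out)
    return out


# ---------------------------------------------------------------------------
# Tables and exports
# ---------------------------------------------------------------------------

_TAXA_COLUMNS = ["ncbi_id", "scientific_name", "rank", "n_matched_files", "n_samples", "proportion"]


def taxa_table(
    root: TaxonNode,
    include_unmatched: bool = False,
    include_special: bool = False,
) -> pd.DataFrame:
    """Per-taxon match summary (the 'taxa matches' table).

    By default only taxa with >= 1 matched file appear; the proportion is
    computed from the integer counts at formatting time.
    """
    rows = []
    for node in walk(root):
        if node.rank == "root":
            continue
        special = node.rank in SPECIAL_RANKS
        if special and not include_special:
            continue
        if node.n_matched == 0 and not include_unmatched:
            continue
        rows.append(
            {
                "ncbi_id": node.ncbi_id,
                "scientific_name": node.name,
                "rank": node.rank,
                "n_matched_files": node.n_matched,
                "n_samples": node.n_samples,
                "proportion": node.n_matched / node.n_samples if node.n_samples else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=_TAXA_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["n_matched_files", "rank", "scientific_name"],
            ascending=[False, True, True],
            key=lambda col: col.map(_RANK_SORT) if col.name == "rank" else col,
            kind="stable",
        ).reset_index(drop=True)
    return df


def tree_to_json(root: TaxonNode) -> dict:
    """Nested per-node dict: name, ncbi_id, rank, counts, proportion,
    children."""
    return {
        "name": root.name,
        "ncbi_id": root.ncbi_id,
        "rank": root.rank,
        "n_samples": root.n_samples,
        "n_matched": root.n_matched,
        "proportion": root.n_matched / root.n_samples if root.n_samples else 0.0,
        "children": [tree_to_json(c) for c in root.children],
    }


_HTML_HEAD = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>taxomasst match tree</title>
<style>
body { font-family: sans-serif; margin: 1.5em; }
details { margin-left: 1.2em; }
summary { cursor: pointer; padding: 1px 0; }
.hit { color: #0b6623; font-weight: bold; }
.counts { color: #666; font-size: 0.9em; }
</style>
</head>
<body>
<h1>Taxonomic match tree</h1>
"""


def _node_html(node: TaxonNode) -> str:
    cls = "hit" if node.n_matched else ""
    label = (
        f'<span class="{cls}">{_html.escape(node.name)}</span> '
        f'<span class="counts">[{node.rank}, id {node.ncbi_id}] '
        f"{node.n_matched}/{node.n_samples} matched "
        f"({node.proportion:.1%})</span>"
    )
    if not node.children:
        return f"<div>{label}</div>\n"
    inner = "".join(_node_html(c) for c in node.children)
    return f"<details open><summary>{label}</summary>\n{inner}</details>\n"


def tree_to_html(root: TaxonNode) -> str:
    """Standalone collapsible HTML tree with the JSON embedded inline (no
    network assets)."""
    payload = json.dumps(tree_to_json(root), indent=1, sort_keys=True)
    return (
        _HTML_HEAD
        + _node_html(root)
        + '<script type="application/json" id="tree-data">\n'
        + payload
        + "\n</script>\n</body>\n</html>\n"
    )


def emit_outputs(
    outdir: str | Path,
    root: TaxonNode,
    matches_by_query: Mapping[str, Sequence[MatchResult]],
    annotations_by_query: Mapping[str, Sequence[AnnotationMatch]] | None = None,
    include_all_taxa: bool = False,
) -> dict[str, Path]:
    """Write the three result tables plus tree.json / tree.html.

    ``root`` must already be aggregated over the union of all queries'
    matches. Row and column order are deterministic; re-running on identical
    inputs yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    lib_rows = []
    for qid in sorted(annotations_by_query or {}):
        for a in annotations_by_query[qid]:
            lib_rows.append(
                {
                    "query_id": a.query_id,
                    "accession": a.accession,
                    "compound_name": a.compound_name,
                    "cosine": round(a.score, 6),
                    "n_matched_ions": a.n_matched,
                    "delta_mz": round(a.delta_mz, 6),
                }
            )
    lib_df = pd.DataFrame(
        lib_rows,
        columns=["query_id", "accession", "compound_name", "cosine", "n_matched_ions", "delta_mz"],
    )
    paths["library_matches"] = outdir / "library_matches.tsv"
    lib_df.to_csv(paths["library_matches"], sep="\t", index=False)

    file_to_node: dict[str, TaxonNode] = {}
    for node in walk(root):
        for rec in node.files:
            file_to_node[rec.file_id] = node
    ds_rows = []
    for qid in sorted(matches_by_query):
        for m in matches_by_query[qid]:
            node = file_to_node.get(m.record.file_id)
            ds_rows.append(
                {
                    "query_id": m.query_id,
                    "ref_usi": m.ref_source_id,
                    "scientific_name": node.name if node else "",
                    "ncbi_id": node.ncbi_id if node else "",
                    "rank": node.rank if node else "",
                    "n_matched_ions": m.n_matched,
                    "cosine": round(m.score, 6),
                    "delta_mz": round(m.delta_mz, 6),
                }
            )
    ds_df = pd.DataFrame(
        ds_rows,
        columns=[
            "query_id",
            "ref_usi",
            "scientific_name",
            "ncbi_id",
            "rank",
            "n_matched_ions",
            "cosine",
            "delta_mz",
        ],
    )
    paths["dataset_matches"] = outdir / "dataset_matches.tsv"
    ds_df.to_csv(paths["dataset_matches"], sep="\t", index=False)

    taxa = taxa_table(root, include_unmatched=include_all_taxa, include_special=True)
    taxa = taxa.copy()
    if len(taxa):
        taxa["proportion"] = taxa["proportion"].map(lambda x: f"{x:.6f}")
    paths["taxa_matches"] = outdir / "taxa_matches.tsv"
    taxa.to_csv(paths["taxa_matches"], sep="\t", index=False)

    paths["tree_json"] = outdir / "tree.json"
    with open(paths["tree_json"], "w", encoding="utf-8") as fh:
        json.dump(tree_to_json(root), fh, indent=1, sort_keys=True)
        fh.write("\n")

    paths["tree_html"] = outdir / "tree.html"
    with open(paths["tree_html"], "w", encoding="utf-8") as fh:
        fh.write(tree_to_html(root))
    return paths
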