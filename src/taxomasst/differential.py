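"""Condition-unique spectrum mining: the downstream differential pipeline.

Given a clustered feature table (consensus spectrum ids × labeled samples,
e.g. colonized SPF vs germ-free GF animals) and the molecular-network edge
list, the pipeline refines the spectrum set in four stages:

1. ``condition_unique`` — spectra present (> min abundance) in at least one
   target-condition sample and absent from every other condition.
2. ``remove_control_analogs`` — drop spectra connected by a network edge
   (cosine > 0.7 AND |Δ parent mass| <= 0.02 Da; both required) to any
   spectrum present in the control condition.
3. ``microbial_screen`` — batch search against the monoculture library;
   spectra matching under Bacteria/Fungi/Archaea are "microbial", those
   also matching human cell lines are set aside, the rest pass.
4. ``cross_dataset_persistence`` — re-find survivors in a second labeled
   dataset (e.g. antibiotics-treated vs untreated) and keep the subset whose
   matches occur only in untreated samples.

Each stage's output is a subset of its input, so cardinalities along the
chain are non-increasing (a funnel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ParameterError, SchemaError
from .aggregate_report import aggregate, classify_domain, domain_match_counts, has_cell_line_match, reset_matches
from .search_engine import LibraryEntry, LibraryIndex, MatchResult, SearchParams, DEFAULT_PARAMS, search
from .spectra_io import Spectrum
from .taxonomy import FileRecord, TaxonNode

__all__ = [
    "FeatureTable",
    "load_feature_table",
    "load_edges",
    "condition_unique",
    "remove_control_analogs",
    "ScreenResult",
    "microbial_screen",
    "PersistenceResult",
    "cross_dataset_persistence",
    "FunnelSummary",
    "run_pipeline",
]


@dataclass
class FeatureTable:
    """Consensus-spectrum presence/abundance matrix with condition labels.

    ``values``: DataFrame indexed by spectrum id, columns = sample ids.
    ``conditions``: sample id → condition label, covering every column.
    "Present" in a sample means abundance > the (default 0) floor.
    """

    values: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        unlabeled = [c for c in self.values.columns if c not in self.conditions]
        if unlabeled:
            raise SchemaError(f"samples without condition label: {unlabeled}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("feature abundances must be >= 0")

    @property
    def labels(self) -> set[str]:
        return set(self.conditions[c] for c in self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [c for c in self.values.columns if self.conditions[c] == condition]

    def present_ids(self, condition: str, min_abundance: float = 0.0) -> set[str]:
        """Spectrum ids with abundance > min_abundance in >= 1 sample of the
        condition."""
        cols = self.samples_for(condition)
        if not cols:
            return set()
        mask = (self.values[cols] > min_abundance).any(axis=1)
        return set(self.values.index[mask])


def load_feature_table(features_path: str | Path, labels_path: str | Path) -> FeatureTable:
    """Load features (TSV, first column = spectrum id) and a two-column
    sample→condition label TSV."""
    values = pd.read_csv(features_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"sample", "condition"} <= set(labels.columns):
        raise SchemaError("labels table needs columns: sample, condition")
    conditions = dict(zip(labels["sample"], labels["condition"]))
    return FeatureTable(values=values, conditions=conditions)


def load_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    needed = {"id1", "id2", "cosine", "delta_mz"}
    if not needed <= set(df.columns):
        raise SchemaError(f"edge table needs columns: {sorted(needed)}")
    return df


def condition_unique(
    table: FeatureTable, target: str, min_abundance: float = 0.0
) -> set[str]:
    """Spectrum ids present only in the target condition's samples."""
    if target not in table.labels:
        raise ParameterError(f"unknown condition {target!r}; labels: {sorted(table.labels)}")
    present = table.present_ids(target, min_abundance)
    for other in table.labels - {target}:
        present -= table.present_ids(other, min_abundance)
    return present


def remove_control_analogs(
    uniq: set[str],
    edges: pd.DataFrame,
    control_ids: set[str],
    cos_thr: float = 0.7,
    delta_thr: float = 0.02,
) -> set[str]:
    """Drop spectra with a qualifying network edge to a control spectrum.

    An edge removes its non-control endpoint iff cosine > cos_thr AND
    |delta_mz| <= delta_thr (both criteria required; edges are undirected).
    With an empty control set this is the identity.
    """
    qualifying = edges[(edges["cosine"] > cos_thr) & (edges["delta_mz"].abs() <= delta_thr)]
    removed: set[str] = set()
    for a, b in zip(qualifying["id1"], qualifying["id2"]):
        if b in control_ids:
            removed.add(a)
        if a in control_ids:
            removed.add(b)
    return set(uniq) - removed


@dataclass
class ScreenResult:
    """Partition of the screened set plus per-query detail.

    ``matched`` = microbial match, no cell-line overlap; ``matched_but_cell_line``
    = microbial match that is also found in human cell lines;
    ``unmatched`` = everything else (including cell-line-only hits).
    """

    matched: set[str] = field(default_factory=set)
    matched_but_cell_line: set[str] = field(default_factory=set)
    unmatched: set[str] = field(default_factory=set)
    domains: dict[str, str] = field(default_factory=dict)
    matches: dict[str, list[MatchResult]] = field(default_factory=dict)

    @property
    def microbial(self) -> set[str]:
        return self.matched | self.matched_but_cell_line


def microbial_screen(
    spectra: Mapping[str, Spectrum],
    idx: LibraryIndex,
    p: SearchParams,
    root: TaxonNode,
) -> ScreenResult:
    """Search each spectrum and classify it by matched-taxon location.

    "Microbial" requires >= 1 matched file under a biological domain subtree
    (Bacteria/Fungi/Archaea); matches confined to cell-line/blank/QC files do
    not count. Domain labels come from Bacteria-vs-Fungi membership.
    The tree's aggregation state is reset before returning.
    """
    out = ScreenResult()
    for sid in sorted(spectra):
        spectrum = spectra[sid]
        hits = search(spectrum, idx, p)
        out.matches[sid] = hits
        if not hits:
            out.unmatched.add(sid)
            continue
        aggregate(hits, root)
        microbial = any(n > 0 for n in domain_match_counts(root).values())
        if not microbial:
            out.unmatched.add(sid)
            continue
        out.domains[sid] = classify_domain(root)
        if has_cell_line_match(root):
            out.matched_but_cell_line.add(sid)
        else:
            out.matched.add(sid)
    reset_matches(root)
    return out


@dataclass
class PersistenceResult:
    overlapping: set[str] = field(default_factory=set)
    untreated_only: set[str] = field(default_factory=set)
    matches: dict[str, list[str]] = field(default_factory=dict)


def _dummy_record(sid: str, dataset: str) -> FileRecord:
    return FileRecord(
        massive_path="",
        file_id=sid,
        dataset_id=dataset,
        taxon_name_submitted="",
        taxon_name_alternative=None,
        ncbi_id=None,
        id_assignment="automatic",
        has_redu_metadata=False,
        is_blank=False,
        is_qc=False,
    )


def cross_dataset_persistence(
    survivors: Mapping[str, Spectrum],
    second: FeatureTable,
    second_spectra: Mapping[str, Spectrum],
    p: SearchParams = DEFAULT_PARAMS,
    treated_label: str = "treated",
    untreated_label: str = "untreated",
    min_abundance: float = 0.0,
) -> PersistenceResult:
    """Re-find surviving spectra in a second labeled dataset.

    ``overlapping``: survivors with >= 1 match (at ``p``'s thresholds) to any
    second-dataset spectrum. ``untreated_only``: overlapping members all of
    whose second-dataset matches are present exclusively in untreated
    samples.
    """
    for label in (treated_label, untreated_label):
        if label not in second.labels:
            raise ParameterError(f"condition {label!r} absent from second dataset labels")
    idx = LibraryIndex(
        [
            LibraryEntry(spec.with_source_id(sid), _dummy_record(sid, "second"))
            for sid, spec in second_spectra.items()
        ]
    )
    treated_present = second.present_ids(treated_label, min_abundance)
    out = PersistenceResult()
    for sid in sorted(survivors):
        hits = search(survivors[sid], idx, p)
        hit_ids = [h.record.file_id for h in hits]
        out.matches[sid] = hit_ids
        if not hit_ids:
            continue
        out.overlapping.add(sid)
        if all(h not in treated_present for h in hit_ids):
            out.untreated_only.add(sid)
    return out


@dataclass
class FunnelSummary:
    """Stage-by-stage id sets and their sizes."""

    total: set[str]
    unique: set[str]
    after_control_analogs: set[str]
    microbial: set[str]
    microbial_no_cell_line: set[str]
    overlapping: set[str]
    untreated_only: set[str]

    def counts(self) -> dict[str, int]:
        return {
            "total": len(self.total),
            "condition_unique": len(self.unique),
            "after_control_analog_removal": len(self.after_control_analogs),
            "microbial_matched": len(self.microbial),
            "microbial_no_cell_line": len(self.microbial_no_cell_line),
            "second_dataset_overlap": len(self.overlapping),
            "untreated_only": len(self.untreated_only),
        }

    def to_frame(self) -> pd.DataFrame:
        counts = self.counts()
        return pd.DataFrame({"stage": list(counts), "n_spectra": list(counts.values())})


def run_pipeline(
    table: FeatureTable,
    spectra: Mapping[str, Spectrum],
    edges: pd.DataFrame,
    idx: LibraryIndex,
    root: TaxonNode,
    p: SearchParams = DEFAULT_PARAMS,
    target: str = "SPF",
    control: str = "GF",
    second: FeatureTable | None = None,
    second_spectra: Mapping[str, Spectrum] | None = None,
    treated_label: str = "treated",
    untreated_label: str = "untreated",
    min_abundance: float = 0.0,
    outdir: str | Path | None = None,
) -> FunnelSummary:
    """Run the full funnel; optionally write per-stage id lists + summary.

    Without a second dataset the last two stages are empty sets.
    """
    uniq = condition_unique(table, target, min_abundance)
    control_ids = table.present_ids(control, min_abundance) if control in table.labels else set()
    survivors = remove_control_analogs(uniq, edges, control_ids)
    screen = microbial_screen({sid: spectra[sid] for sid in survivors}, idx, p, root)
    clean = screen.matched
    if second is not None and second_spectra is not None:
        persist = cross_dataset_persistence(
            {sid: spectra[sid] for sid in clean},
            second,
            second_spectra,
            p,
            treated_label=treated_label,
            untreated_label=untreated_label,
            min_abundance=min_abundance,
        )
        overlapping, untreated_only = persist.overlapping, persist.untreated_only
    else:
        overlapping, untreated_only = set(), set()
    summary = FunnelSummary(
        total=set(map(str, table.values.index)),
        unique=uniq,
        after_control_analogs=survivors,
        microbial=screen.microbial,
        microbial_no_cell_line=clean,
        overlapping=overlapping,
        untreated_only=untreated_only,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stage_sets = {
            "condition_unique": summary.unique,
            "after_control_analog_removal": summary.after_control_analogs,
            "microbial_matched": summary.microbial,
            "microbial_no_cell_line": summary.microbial_no_cell_line,
            "second_dataset_overlap": summary.overlapping,
            "untreated_only": summary.untreated_only,
        }
        for stage, ids in stage_sets.items():
            pd.DataFrame({"spectrum_id": sorted(ids)}).to_csv(
                outdir / f"{stage}.tsv", sep="\t", index=False
            )
        summary.to_frame().to_csv(outdir / "funnel_summary.tsv", sep="\t", index=False)
    return summary
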