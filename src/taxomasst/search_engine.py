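"""Precursor-indexed MS/MS library search: exact, analog, and batch modes.

The reference library is indexed by precursor m/z (a sorted array supporting
inclusive range queries), which restricts each search to the candidate
spectra that can plausibly achieve a high modified cosine. Default
thresholds: precursor and fragment ion tolerances 0.05 Th, minimum cosine
0.7, minimum 3 matching fragment ions, analog search off. Analog mode widens
the precursor window (default ±200 Th) and enables Δ-shifted peak pairing,
recovering structurally related molecules.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyQueryError, IndexBuildError, TaxomasstError
from .similarity import modified_cosine
from .spectra_io import Spectrum, SpectrumStore, UsiRef, read_mgf
from .taxonomy import FileRecord

__all__ = [
    "SearchParams",
    "DEFAULT_PARAMS",
    "format_params",
    "LibraryEntry",
    "LibraryIndex",
    "MatchResult",
    "build_index",
    "search",
    "batch_search",
    "BatchResult",
    "AnnotationEntry",
    "AnnotationMatch",
    "load_annotation_library",
    "annotate_against_reference_library",
]


@dataclass(frozen=True)
class SearchParams:
    """Search tolerances and thresholds.

    ``weighting``/``pairing`` configure the scorer (sqrt-intensity weights,
    greedy pair selection by default); everything else mirrors the search
    form: precursor/fragment tolerances in Th, minimum cosine, minimum
    matched fragment ions, analog toggle and its precursor window.
    """

    precursor_tol: float = 0.05
    frag_tol: float = 0.05
    min_cosine: float = 0.7
    min_matched_ions: int = 3
    analog: bool = False
    analog_window: float = 200.0
    weighting: object = "sqrt"
    pairing: str = "greedy"

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.frag_tol <= 0 or self.analog_window <= 0:
            raise ValueError("tolerances must be > 0")
        if not 0 <= self.min_cosine <= 1:
            raise ValueError("min_cosine must lie in [0, 1]")
        if self.min_matched_ions < 1:
            raise ValueError("min_matched_ions must be >= 1")


DEFAULT_PARAMS = SearchParams()


def format_params(p: SearchParams = DEFAULT_PARAMS) -> str:
    """Stable one-parameter-per-line dump of the search defaults."""
    return (
        f"precursor_tol={p.precursor_tol}\n"
        f"frag_tol={p.frag_tol}\n"
        f"min_cosine={p.min_cosine}\n"
        f"min_matched_ions={p.min_matched_ions}\n"
        f"analog={p.analog}\n"
        f"analog_window={p.analog_window}"
    )


class LibraryEntry(NamedTuple):
    spectrum: Spectrum
    record: FileRecord


class LibraryIndex:
    """Reference spectra sorted by precursor m/z for range queries."""

    def __init__(self, entries: Sequence[LibraryEntry]):
        seen: set[str] = set()
        for e in entries:
            sid = e.spectrum.source_id
            if sid in seen:
                raise IndexBuildError(f"duplicate reference source_id: {sid!r}")
            seen.add(sid)
        self._entries = sorted(
            entries, key=lambda e: (e.spectrum.precursor_mz, e.spectrum.source_id)
        )
        self._precursors = np.array(
            [e.spectrum.precursor_mz for e in self._entries], dtype=float
        )

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> list[LibraryEntry]:
        return list(self._entries)

    def range_query(self, lo: float, hi: float) -> list[LibraryEntry]:
        """Entries with lo <= precursor_mz <= hi (inclusive on both ends)."""
        i = int(np.searchsorted(self._precursors, lo, side="left"))
        j = int(np.searchsorted(self._precursors, hi, side="right"))
        return self._entries[i:j]


def build_index(library: Iterable[tuple[Spectrum, FileRecord]]) -> LibraryIndex:
    """Build the precursor index; duplicate spectrum provenance is an error."""
    return LibraryIndex([LibraryEntry(s, r) for s, r in library])


@dataclass(frozen=True)
class MatchResult:
    """One query↔reference hit passing the score and ion-count thresholds."""

    query_id: str
    ref_source_id: str
    record: FileRecord
    score: float
    n_matched: int
    delta_mz: float


def search(q: Spectrum, idx: LibraryIndex, p: SearchParams = DEFAULT_PARAMS) -> list[MatchResult]:
    """Search one query against the indexed library.

    Exact mode restricts candidates to |Δprecursor| <= precursor_tol; analog
    mode widens the window to analog_window and enables shifted peak
    pairing. Matches require score >= min_cosine and n_matched >=
    min_matched_ions; results sort by descending score, then |Δ|, then
    reference id.
    """
    if q.is_empty:
        raise EmptyQueryError(f"query {q.source_id!r} has no peaks")
    half = p.analog_window if p.analog else p.precursor_tol
    results: list[MatchResult] = []
    for entry in idx.range_query(q.precursor_mz - half, q.precursor_mz + half):
        if entry.spectrum.is_empty:
            continue
        sim = modified_cosine(
            q,
            entry.spectrum,
            frag_tol=p.frag_tol,
            allow_shift=p.analog,
            weighting=p.weighting,
            method=p.pairing,
        )
        if sim.score >= p.min_cosine and sim.n_matched >= p.min_matched_ions:
            results.append(
                MatchResult(
                    query_id=q.source_id,
                    ref_source_id=entry.spectrum.source_id,
                    record=entry.record,
                    score=sim.score,
                    n_matched=sim.n_matched,
                    delta_mz=sim.delta_mz,
                )
            )
    results.sort(key=lambda m: (-m.score, abs(m.delta_mz), m.ref_source_id))
    return results


@dataclass
class BatchResult:
    """Per-query match lists plus a per-query failure report."""

    results: dict[str, list[MatchResult]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def batch_search(
    queries: Iterable[Spectrum | UsiRef],
    idx: LibraryIndex,
    p: SearchParams = DEFAULT_PARAMS,
    store: SpectrumStore | None = None,
) -> BatchResult:
    """Run many queries; failures are recorded per query, never fatal.

    Queries may be spectra or USI references (resolved via ``store``).
    Per-query results are identical to individual `search` calls.
    """
    out = BatchResult()
    for ordinal, item in enumerate(queries, start=1):
        if isinstance(item, UsiRef):
            qid = str(item)
            try:
                spectrum = (store or SpectrumStore()).resolve(item)
            except TaxomasstError as exc:
                out.failures[qid] = str(exc)
                continue
        else:
            spectrum = item
            qid = spectrum.source_id or f"query#{ordinal}"
            if not spectrum.source_id:
                spectrum = spectrum.with_source_id(qid)
        try:
            out.results[qid] = search(spectrum, idx, p)
        except TaxomasstError as exc:
            out.failures[qid] = str(exc)
    return out


# ---------------------------------------------------------------------------
# Reference-library (compound) annotation
# ---------------------------------------------------------------------------


class AnnotationEntry(NamedTuple):
    spectrum: Spectrum
    compound_name: str
    accession: str


@dataclass(frozen=True)
class AnnotationMatch:
    query_id: str
    accession: str
    compound_name: str
    score: float
    n_matched: int
    delta_mz: float


def load_annotation_library(mgf_path: str | Path, tsv_path: str | Path) -> list[AnnotationEntry]:
    """Load an annotation library: MGF spectra + TSV of (accession, name).

    Spectra are matched to TSV rows by TITLE == accession, falling back to
    file order when titles are absent from the table.
    """
    spectra = read_mgf(mgf_path)
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if not {"accession", "name"} <= set(table.columns):
        raise TaxomasstError("annotation table needs columns: accession, name")
    by_accession = dict(zip(table["accession"], table["name"]))
    entries = []
    for i, s in enumerate(spectra):
        if s.source_id in by_accession:
            accession, name = s.source_id, by_accession[s.source_id]
        elif i < len(table):
            accession, name = table["accession"].iloc[i], table["name"].iloc[i]
        else:
            continue
        entries.append(AnnotationEntry(s, str(name), str(accession)))
    return entries


def annotate_against_reference_library(
    q: Spectrum,
    annots: Sequence[AnnotationEntry],
    p: SearchParams = DEFAULT_PARAMS,
) -> list[AnnotationMatch]:
    """Score a query against compound-labeled reference spectra.

    Same candidate windowing, scoring and thresholds as `search`; the
    result is the compound-labeled 'library matches' list.
    """
    if q.is_empty:
        raise EmptyQueryError(f"query {q.source_id!r} has no peaks")
    half = p.analog_window if p.analog else p.precursor_tol
    matches: list[AnnotationMatch] = []
    for entry in annots:
        if entry.spectrum.is_empty:
            continue
        if abs(q.precursor_mz - entry.spectrum.precursor_mz) > half:
            continue
        sim = modified_cosine(
            q,
            entry.spectrum,
            frag_tol=p.frag_tol,
            allow_shift=p.analog,
            weighting=p.weighting,
            method=p.pairing,
        )
        if sim.score >= p.min_cosine and sim.n_matched >= p.min_matched_ions:
            matches.append(
                AnnotationMatch(
                    query_id=q.source_id,
                    accession=entry.accession,
                    compound_name=entry.compound_name,
                    score=sim.score,
                    n_matched=sim.n_matched,
                    delta_mz=sim.delta_mz,
                )
            )
    matches.sort(key=lambda m: (-m.score, abs(m.delta_mz), m.accession))
    return matches
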