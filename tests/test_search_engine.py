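"""Precursor index, exact/analog search, batch mode, compound annotation."""

import numpy as np
import pytest

import taxomasst as tm
from taxomasst.exceptions import EmptyQueryError, IndexBuildError
from taxomasst.search_engine import AnnotationEntry, LibraryEntry

from conftest import make_spectrum, random_spectrum


def _record(file_id, ncbi_id=1008):
    return tm.FileRecord(
        massive_path=f"f.X/{file_id}",
        file_id=file_id,
        dataset_id="MSVTEST",
        taxon_name_submitted="Test taxon",
        taxon_name_alternative=None,
        ncbi_id=ncbi_id,
        id_assignment="automatic",
        has_redu_metadata=False,
        is_blank=False,
        is_qc=False,
    )


def brute_force_search(q, idx, p):
    """Linear-scan oracle: score every library entry within the precursor
    window, apply identical thresholds and sorting."""
    half = p.analog_window if p.analog else p.precursor_tol
    out = []
    for entry in idx.entries:
        if entry.spectrum.is_empty:
            continue
        if abs(q.precursor_mz - entry.spectrum.precursor_mz) > half:
            continue
        sim = tm.modified_cosine(
            q, entry.spectrum, frag_tol=p.frag_tol, allow_shift=p.analog,
            weighting=p.weighting, method=p.pairing,
        )
        if sim.score >= p.min_cosine and sim.n_matched >= p.min_matched_ions:
            out.append(
                tm.MatchResult(
                    query_id=q.source_id,
                    ref_source_id=entry.spectrum.source_id,
                    record=entry.record,
                    score=sim.score,
                    n_matched=sim.n_matched,
                    delta_mz=sim.delta_mz,
                )
            )
    out.sort(key=lambda m: (-m.score, abs(m.delta_mz), m.ref_source_id))
    return out


class TestIndex:
    def test_range_query_inclusive_bounds(self):
        entries = [
            (make_spectrum(p, [(100.0, 1.0)], source_id=f"e{p}"), _record(f"f{p}"))
            for p in (100.0, 200.0, 300.0)
        ]
        idx = tm.build_index(entries)
        got = idx.range_query(150.0, 250.0)
        assert [e.spectrum.source_id for e in got] == ["e200.0"]
        assert [e.spectrum.source_id for e in idx.range_query(200.0, 200.0)] == ["e200.0"]

    def test_empty_library(self):
        idx = tm.build_index([])
        assert len(idx) == 0 and idx.range_query(0, 1e6) == []

    def test_duplicate_source_id_rejected(self):
        s = make_spectrum(100.0, [(50.0, 1.0)], source_id="dup")
        with pytest.raises(IndexBuildError, match="dup"):
            tm.build_index([(s, _record("a")), (s, _record("b"))])

    def test_range_query_matches_linear_scan(self):
        rng = np.random.default_rng(42)
        entries = [
            (random_spectrum(rng, n_peaks=3), _record(f"f{i}"))
            for i in range(1000)
        ]
        idx = tm.build_index(entries)
        precursors = {e[0].source_id: e[0].precursor_mz for e in entries}
        for _ in range(100):
            lo = float(rng.uniform(0, 1000))
            hi = lo + float(rng.uniform(0, 200))
            expected = {sid for sid, p in precursors.items() if lo <= p <= hi}
            got = {e.spectrum.source_id for e in idx.range_query(lo, hi)}
            assert got == expected


class TestSearch:
    def test_exact_copy_returns_perfect_hit(self, repo, index):
        template = repo.molecules[0].template
        hits = tm.search(template, index)
        assert hits and hits[0].score == pytest.approx(1.0)
        assert {h.record.file_id for h in hits} == repo.truth_files("mol01")

    def test_precursor_window_membership(self):
        entries = [
            (make_spectrum(500.03, [(100.0, 1.0), (150.0, 1.0), (200.0, 1.0)], "near"),
             _record("near")),
            (make_spectrum(500.20, [(100.0, 1.0), (150.0, 1.0), (200.0, 1.0)], "far"),
             _record("far")),
        ]
        idx = tm.build_index(entries)
        q = make_spectrum(500.00, [(100.0, 1.0), (150.0, 1.0), (200.0, 1.0)], "q")
        hits = tm.search(q, idx, tm.SearchParams())
        assert [h.ref_source_id for h in hits] == ["near"]

    def test_empty_query_rejected(self, index):
        e = tm.Spectrum(precursor_mz=100.0, mz=np.array([]), intensity=np.array([]))
        with pytest.raises(EmptyQueryError):
            tm.search(e, index)

    def test_planted_analog_found_only_in_analog_mode(self, repo, index):
        # mol06 has a +14.016 analog planted in a sibling species
        template = next(m for m in repo.molecules if m.mol_id == "mol06").template
        analog_files = repo.truth_files("mol06", kinds=("analog",))
        assert analog_files
        exact_hits = {h.record.file_id for h in tm.search(template, index)}
        assert exact_hits.isdisjoint(analog_files)
        analog_params = tm.SearchParams(analog=True)
        analog_hits = {h.record.file_id for h in tm.search(template, index, analog_params)}
        assert analog_files <= analog_hits

    def test_exact_results_subset_of_analog(self, repo, index):
        for mol in repo.molecules:
            exact = {h.ref_source_id for h in tm.search(mol.template, index)}
            analog = {
                h.ref_source_id
                for h in tm.search(mol.template, index, tm.SearchParams(analog=True))
            }
            assert exact <= analog

    def test_threshold_monotonicity(self, repo, index):
        template = repo.molecules[1].template
        base = tm.search(template, index, tm.SearchParams(min_cosine=0.3, min_matched_ions=1))
        stricter_cos = tm.search(template, index, tm.SearchParams(min_cosine=0.9, min_matched_ions=1))
        stricter_ions = tm.search(template, index, tm.SearchParams(min_cosine=0.3, min_matched_ions=5))
        base_ids = {m.ref_source_id for m in base}
        assert {m.ref_source_id for m in stricter_cos} <= base_ids
        assert {m.ref_source_id for m in stricter_ions} <= base_ids
        # widening the precursor window never removes results
        widened = tm.search(
            template, index, tm.SearchParams(precursor_tol=5.0, min_cosine=0.3, min_matched_ions=1)
        )
        assert base_ids <= {m.ref_source_id for m in widened}

    def test_indexed_equals_brute_force(self, repo, index):
        rng = np.random.default_rng(77)
        queries = [m.template for m in repo.molecules]
        queries += [random_spectrum(rng) for _ in range(10)]
        picks = rng.choice(len(index.entries), size=10, replace=False)
        queries += [index.entries[i].spectrum for i in picks]
        for p in (tm.SearchParams(), tm.SearchParams(analog=True)):
            for q in queries:
                assert tm.search(q, index, p) == brute_force_search(q, index, p)

    def test_determinism(self, repo, index):
        template = repo.molecules[2].template
        assert tm.search(template, index) == tm.search(template, index)


class TestBatch:
    def test_batch_equals_sequential_loop(self, repo, index):
        rng = np.random.default_rng(3)
        queries = [m.template.with_source_id(f"q{i}") for i, m in enumerate(repo.molecules)]
        queries += [random_spectrum(rng) for _ in range(200)]
        batch = tm.batch_search(queries, index)
        assert not batch.failures
        assert len(batch.results) == len(queries)
        for q in queries:
            assert batch.results[q.source_id] == tm.search(q, index)

    def test_failure_isolation(self, repo, index):
        store = tm.SpectrumStore()
        store.add_run("C", "run1", [repo.molecules[0].template])
        good = tm.UsiRef("C", "run1", "scan", 1)
        bad = tm.UsiRef("C", "missing", "scan", 1)
        batch = tm.batch_search([good, bad], index, store=store)
        assert str(bad) in batch.failures
        assert batch.results[str(good)]  # resolved query still searched

    def test_empty_query_recorded_not_fatal(self, index):
        e = tm.Spectrum(precursor_mz=100.0, mz=np.array([]), intensity=np.array([]),
                        source_id="empty_q")
        batch = tm.batch_search([e], index)
        assert "empty_q" in batch.failures and not batch.results


class TestAnnotation:
    @pytest.fixture()
    def annots(self):
        rng = np.random.default_rng(6)
        spectra = [random_spectrum(rng, n_peaks=8, spacing=2.0) for _ in range(3)]
        return [
            AnnotationEntry(s, f"compound {i}", f"ACC{i:05d}")
            for i, s in enumerate(spectra)
        ]

    def test_identical_query_scores_one(self, annots):
        hits = tm.annotate_against_reference_library(annots[1].spectrum, annots)
        assert hits and hits[0].accession == "ACC00001"
        assert hits[0].score == pytest.approx(1.0)

    def test_empty_annotation_library(self, annots):
        assert tm.annotate_against_reference_library(annots[0].spectrum, []) == []

    def test_perturbed_peak_drops_one_matched_ion(self, annots):
        ref = annots[0].spectrum
        hits_full = tm.annotate_against_reference_library(ref, annots)
        mz = ref.mz.copy()
        mz[0] += 0.5  # beyond frag_tol, away from any other peak
        perturbed = tm.Spectrum(ref.precursor_mz, mz, ref.intensity, source_id="pert")
        hits = tm.annotate_against_reference_library(
            perturbed, annots, tm.SearchParams(min_cosine=0.1)
        )
        hit = next(h for h in hits if h.accession == "ACC00000")
        assert hit.n_matched == hits_full[0].n_matched - 1
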