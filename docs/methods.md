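# Methods

This note documents the models, algorithms, parameter choices, and
numerical conventions behind `taxomasst`, and what the synthetic fixtures
do and do not emulate.

## Spectrum model and preprocessing

A spectrum is a precursor m/z plus a fragment peak list (m/z in Th,
intensity in arbitrary units), stored sorted ascending by m/z. Intensities
are kept raw at I/O time; any weighting happens inside the scorer, so
stored libraries are transformation-agnostic.

`normalize_spectrum` offers two optional cleanups, both disabled in the
search pipeline by default so that parsed spectra are searched exactly as
written:

- **Close-peak merging** (`merge_tol`, default 0.002 Th when invoked):
  maximal runs of peaks whose consecutive gaps are ≤ merge_tol collapse to
  one peak with summed intensity at the intensity-weighted mean m/z.
  Because groups are separated by gaps > merge_tol, merged centroids stay
  more than merge_tol apart, which makes the operation idempotent (a
  property test asserts this).
- **Precursor-region removal** (`precursor_window`, default 17 Th when
  invoked): removes all peaks at or above `precursor_mz − window`, i.e.
  the residual precursor and small-neutral-loss clutter (water loss at
  −18 falls just outside, by design the window is configurable).

MGF is the canonical interchange format (read via pyteomics, written with
full `repr` precision so round trips are numerically lossless). mzML is
read-only and limited to MS2 scans with a recorded selected-ion m/z; the
reader is a small lxml streaming parser supporting 64/32-bit float arrays
and optional zlib compression. USIs (`mzspec:collection:run:scan|index:n`)
resolve against a local `SpectrumStore`; `scan` is the 1-based position in
the run, `index` the 0-based one. No network resolution is attempted.

## Modified cosine

Peak pairs are admitted **directly** when |mz_q − mz_r| ≤ τ_frag and, in
analog mode, **shifted** when |mz_q − mz_r − Δ| ≤ τ_frag with
Δ = precursor_q − precursor_r. A combination qualifying both ways counts
once, as direct (this matters only when Δ ≈ 0, where both windows
coincide). The score is

    Σ_(i,j)∈M  w_q(i) · w_r(j)  /  (‖w_q‖ · ‖w_r‖)

over a one-to-one pairing M, with norms over all peaks of both spectra —
hence score ∈ [0, 1], equality at 1 for self-comparison (Cauchy–Schwarz),
and invariance under intensity rescaling of either spectrum.

- **Weighting**: w = √intensity by default; `"raw"` and
  `(p, q)` → intensity^p · mz^q are available. Square-root weighting is
  the common molecular-networking compromise between dominant-peak
  sensitivity and noise amplification.
- **Pair selection**: greedy, descending by pair weight, ties broken by
  (query index, reference index) for determinism. An exact maximum-weight
  assignment (`method="exact"`, scipy linear-sum assignment on the
  candidate-weight matrix; zero padding is safe because all candidate
  weights are ≥ 0) exists primarily as the optimality oracle. On random
  ≤10-peak spectra at the default 0.05 Th tolerance the greedy score is
  within 1% of optimal and equal on well-separated peaks (tested); see
  Limitations for the dense regime.
- **Degenerate inputs**: two empty spectra → `UndefinedScoreError`; one
  empty spectrum or all-zero weights → score 0 with no pairs.

A scored pair list can be exported as a mirror-plot TSV
(mz_q, int_q, mz_r, int_r, pair_type).

## Search engine

The library is indexed by precursor m/z (sorted array + binary search);
`range_query(lo, hi)` is inclusive on both ends, so boundary ties are
kept. Exact search restricts candidates to |Δprecursor| ≤ τ_prec; analog
search widens the window to ±`analog_window` and enables shifted pairing.
A match requires score ≥ min_cosine AND matched ions ≥ min_matched_ions;
results sort by (−score, |Δ|, reference id), which makes output ordering
total and runs byte-reproducible.

Defaults: τ_prec = τ_frag = 0.05 Th (absolute, not ppm), min cosine 0.7,
min matched ions 3, analog off, analog window ±200 Th. The window value is
a package choice (the analog toggle itself carries no standard width);
±200 Th covers common multi-glycosylation/acylation offsets while keeping
candidate sets small. Charge is ignored for windowing — precursor m/z is
taken as given. Indexing is by precursor m/z only; any intensity-aware
candidate pruning would be an optimization that must not change result
sets (the index-vs-linear-scan equality test enforces this contract).

Batch search accepts spectra and/or USIs; per-query failures (unresolvable
USI, empty spectrum) are recorded in a report without aborting the batch,
and per-query results are identical to individual calls (tested against
the sequential loop; the equality test runs at ~200 queries — the property
is size-independent). Compound annotation against a reference library
(MGF + accession/name TSV) uses the same windowing, scoring, and
thresholds.

## Taxonomy and aggregation

Reference files carry a 10-column metadata schema: MassIVE path, unique
dataset-qualified file id, dataset id, submitted taxon name, optional
corrected name, optional NCBI id, automatic/manual id assignment, a
ReDU-metadata flag, and blank/QC flags (mutually exclusive). Lineages come
from a pre-exported table (TSV: ncbi_id → rank:name:id triplets), not live
NCBI queries — the taxize/ETE3-style lineage export is a one-time step
upstream of this package, which keeps everything testable offline.

Resolution order per record: NCBI id in the table → corrected/submitted
name through a name→id fallback (the closest-accurate-taxon rule, e.g. an
unregistered strain curated to its species) → generic domain-level
Bacteria/Fungi/Archaea placeholder inferred from the submitted name
(generic files attach at the domain node directly) → error.

Kept ranks, coarse to fine: domain, kingdom, phylum, class, order, family,
genus, subgenus, species, subspecies, varietas, strain. The "domain" head
is a normalization choice: NCBI calls Bacteria a superkingdom and Fungi a
kingdom under Eukaryota, but the tool's tree and the bacteria-vs-fungi
query classification need the three lineage heads at one level, so
Bacteria (2), Archaea (2157), and Fungi (4751) all sit at rank "domain".
Ranks outside the kept set are dropped from lineages; their files
re-attach to the nearest kept ancestor by construction.

Blank, QC, and human cell-line files live under dedicated special children
of the root with negative synthetic ids (blank −1, QC −2, cell lines −3,
one child per submitted culture name below that). Records are routed to
the cell-line subtree when their lineage contains Homo sapiens (9606) —
the metadata schema has no explicit cell-line flag. Special files are
**excluded** from biological ancestors' sample counts, so per-taxon
proportions reflect biological files only; whether a hosted tool counts
them in parent totals is unspecified upstream, and this package picks the
denominator under which "proportion of found matches" is a meaningful
fraction of comparable samples.

Aggregation credits a match to every ancestor of the matched file's
lineage: per node, the matched set is the union of its children's sets
plus directly attached matched files, and `n_matched` counts **distinct
files** (a file with many matching scans counts once). This is the only
reading under which proportion = n_matched / n_samples is bounded by 1;
per-scan detail remains in `dataset_matches.tsv`. Proportions are computed
from the integer counts at formatting time, never stored rounded.

Tree filtering mirrors an interactive viewer: `max_rank` collapses finer
biological nodes into their kept ancestor (files and matched sets merge
upward, so counts are conserved); `min_matches` prunes nodes below the
threshold while always retaining ancestors of survivors. Filtering
operates on a deep copy.

Newick export/parse (via scikit-bio) is lossless for topology and names
(metacharacters are quoted); counts live only in the JSON export. The HTML
export is a standalone file — a nested `<details>` collapsible tree plus
the full JSON embedded inline — with no network assets, so it archives
cleanly; visual fidelity to any hosted viewer is a non-goal.

## Differential pipeline

Inputs: a consensus-spectrum feature table (rows = spectrum ids, columns =
samples), a sample→condition label table, the spectra as MGF, and a
molecular-network edge list (id1, id2, cosine, delta_mz). "Present" in a
sample means abundance > a floor that defaults to 0 (exposed because
upstream gap-filling conventions vary).

1. `condition_unique`: present in ≥1 target-condition sample and in no
   sample of any other condition.
2. `remove_control_analogs`: drop ids with ≥1 edge to a control-present
   spectrum with cosine **strictly >** 0.7 and |Δ parent mass| ≤ 0.02 Da —
   both criteria required; edges are treated as undirected. Empty control
   set ⇒ identity.
3. `microbial_screen`: search every survivor; "microbial" requires ≥1
   matched file under Bacteria/Fungi/Archaea. Microbial hits that also
   match a cell-line file are set aside (`matched_but_cell_line`);
   matches confined to cell-line/blank/QC files alone do not count as
   microbial. Domain labels (bacteria_only / fungi_only / both / none)
   come from Bacteria-vs-Fungi matched-file presence; Archaea counts are
   reported separately.
4. `cross_dataset_persistence`: survivors are re-searched against a second
   labeled dataset's spectra (same engine defaults — no separate standard
   exists for this step, so the thresholds are configurable);
   `overlapping` = ≥1 match, `untreated_only` = overlapping ids all of
   whose matches are absent from treated samples.

Each stage's output is a subset of its input, so the chain forms a
non-increasing funnel; stage outputs are insensitive to row/sample order.
Compound-class prediction is out of scope — an optional user-supplied
class-label table can annotate the survivors. Consensus-spectrum
construction (clustering) is upstream; edge lists are accepted as input
rather than recomputed at repository scale.

## Synthetic fixtures

`make_repository` emulates a curated monoculture repository at desk scale.
Defaults: two domains (Bacteria, Fungi) × 2 phyla × 2 families × 2 genera
× 2 species = 32 species, 5 files per species, 10 background spectra per
file, plus 8 blank files (shared "media" template), 6 QC files, 6 human
cell-line files, and two metadata quirks exercising the fallback paths (an
unregistered strain curated to its species by name, and a generically
classified isolate) — ~182 files, ~1,800 spectra. This scale populates
every taxonomic level and keeps a full end-to-end run around a second on
one CPU.

Six template molecules (5–20 peaks over 50–1000 Th, precursors on a sparse
grid; background precursors keep ≥0.5 Th away from that grid so planted
molecules are the only true matches) are planted into all files of their
producers: a single species, a whole genus, a fungal species, a
bacterium+fungus pair, a bacterium+cell-line pair, and a species with a
+14.016 Th analog (3 of its peaks shifted) planted in a sibling species —
exercising exclusivity, genus-level propagation, domain classification,
cell-line overlap, and shifted-pair matching respectively. Every planted
occurrence is recorded in a truth table.

The noise model (defaults: fragment m/z jitter σ = 0.01 Th, per-peak
dropout 0.05 with ≥3 peaks always kept so occurrences stay findable at the
3-ion threshold, decoy-peak rate 0.1 at low intensity) represents
instrument mass error and spectrum-to-spectrum variability. It does **not**
simulate chromatography, isotopes, adducts, co-isolation chimeras, or
intensity-dependent peak detection — so passing tests certify the engine's
logic and thresholds, not real-data recall, where "data leakage" from
low-intensity precursors and condition-dependent metabolite production
remain the dominant failure modes.

`make_differential_fixture` plants the funnel 100 → 40 (condition-unique)
→ 30 (after control-analog removal) → 20 (microbial) → 15 (no cell-line
overlap) → 10 (second-dataset overlap) → 6 (untreated-only), assigning
template molecules to funnel groups so that no group's spectra can match
another group's second-dataset copies (template precursors are ≥60 Th
apart). The repository underneath is generated at zero noise, making every
funnel count exact by construction.

All generators are pure functions of the seed; identical seeds give
byte-identical written fixtures.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 1,000 random pairs for the
greedy-vs-optimal scoring check, a ~2,100-spectrum library with 100
queries for the index-vs-linear-scan equality, the default repository for
planted-producer recovery (zero noise and default noise), 50 random trees
for propagation conservation, and three seeds of the differential fixture.
These sizes are the package's validation choices; every property tested is
size-independent. All randomness flows through `numpy.random.default_rng`
seeded explicitly; search output ordering is total, and table/JSON writers
emit deterministic column order and row sort, so identical inputs produce
byte-identical outputs.

## Limitations

- Greedy pair selection is a heuristic: under dense candidate overlap
  (fragment tolerance comparable to peak spacing, e.g. τ_frag ≈ 1 Th on
  peaks packed a few Th apart) it degrades toward its 1/2-approximation
  worst case, with observed gaps of ~30% vs the optimal assignment in
  deliberately adversarial constructions. At the method's 0.05 Th
  tolerance on realistic spectra the gap is ≤1% and usually zero; use
  `method="exact"` where optimality matters more than speed.
- Bit-compatibility with any hosted search service is not promised: the
  modified-cosine variant used server-side (weighting, pairing optimality)
  is unspecified upstream.
- The package trusts the lineage table; merged/renamed NCBI ids and
  specimen misidentification upstream of metabolomics cannot be detected.
- Blank/QC/cell-line denominator semantics are a documented package choice
  (see above), isolated behind the aggregation function.
- No vendor raw-file readers, profile-data centroiding, spectral-entropy
  scores, or machine-learned similarity.
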