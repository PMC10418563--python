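"""Deterministic synthetic fixtures with planted ground truth.

`make_repository` emulates a curated monoculture reference repository at
desk scale: a two-domain (Bacteria/Fungi) taxonomy, per-species LC-MS/MS
files of random background spectra, planted "molecule" template spectra that
occur only in files of their designated producer taxa (optionally with
mass-shifted analogs in other taxa), blank/QC files carrying shared media
peaks, and human cell-line files. Every planted occurrence is recorded in a
truth table, so search, aggregation, and proportion outputs can be checked
exactly.

`make_differential_fixture` emulates a two-condition feature-table study
(e.g. colonized vs germ-free animals) plus a second treated/untreated
dataset, with the full differential funnel (condition-unique → control-
analog removal → microbial screen → cell-line exclusion → cross-dataset
persistence) planted by construction.

All outputs are pure functions of the seed: the same spec yields
byte-identical files. The noise model jitters fragment m/z (Gaussian),
drops peaks (keeping at least 3 so planted occurrences stay findable at the
default 3-ion threshold), and adds low-intensity decoy peaks; chromatography,
isotopes, and adduct chemistry are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd

from .exceptions import FixtureSpecError
from .differential import FeatureTable
from .search_engine import LibraryEntry, LibraryIndex, build_index
from .spectra_io import Spectrum, write_mgf
from .taxonomy import (
    BACTERIA,
    FUNGI,
    FileRecord,
    HUMAN_TAXID,
    Lineage,
    LineageStep,
    TaxonNode,
    build_tree,
    make_lineage,
    resolve_taxon,
    write_lineage_table,
    write_metadata,
)

__all__ = [
    "NoiseSpec",
    "ZERO_NOISE",
    "AnalogPlant",
    "PlantedMolecule",
    "FixtureSpec",
    "RepositoryFixture",
    "make_repository",
    "DifferentialFixture",
    "make_differential_fixture",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for planted spectra.

    ``jitter_sd``: Gaussian m/z jitter (Th) on fragments (and half of it on
    the precursor); must stay below frag_tol/2 for solvable defaults.
    ``drop_prob``: per-peak dropout probability (>= 3 peaks always kept).
    ``decoy_rate``: expected decoy peaks as a fraction of real peaks.
    """

    jitter_sd: float = 0.01
    drop_prob: float = 0.05
    decoy_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.drop_prob <= 1 and 0 <= self.decoy_rate <= 1):
            raise FixtureSpecError("drop_prob and decoy_rate must lie in [0, 1]")
        if self.jitter_sd < 0 or self.jitter_sd >= 0.025:
            raise FixtureSpecError("jitter_sd must lie in [0, frag_tol/2 = 0.025)")


ZERO_NOISE = NoiseSpec(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class AnalogPlant:
    """A mass-shifted analog of a molecule planted in another taxon."""

    taxon: str
    delta: float
    n_shifted_peaks: int


@dataclass(frozen=True)
class PlantedMolecule:
    mol_id: str
    template: Spectrum
    producers: tuple[str, ...]
    analogs: tuple[AnalogPlant, ...] = ()


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and noise of the synthetic repository.

    The default scale (~200 files, ~2,000 spectra) keeps a full end-to-end
    run fast on one CPU while leaving every taxonomic level populated.
    """

    seed: int = 0
    phyla_per_domain: int = 2
    families_per_phylum: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    files_per_species: int = 5
    spectra_per_file: int = 10
    n_blank_files: int = 8
    n_qc_files: int = 6
    n_cell_line_files: int = 6
    planted_molecules: tuple[PlantedMolecule, ...] | None = None
    noise: NoiseSpec = ZERO_NOISE

    def __post_init__(self) -> None:
        for name in (
            "phyla_per_domain",
            "families_per_phylum",
            "genera_per_family",
            "species_per_genus",
            "files_per_species",
            "spectra_per_file",
        ):
            if getattr(self, name) < 1:
                raise FixtureSpecError(f"{name} must be >= 1")


# Template precursors sit on a sparse grid; background precursors are kept
# away from it so planted molecules are the only true matches.
_TEMPLATE_GRID_START = 200.0
_TEMPLATE_GRID_STEP = 60.0
_EXCLUSION = 0.5


def _template_spectrum(rng: np.random.Generator, slot: int, mol_id: str) -> Spectrum:
    n_peaks = int(rng.integers(5, 21))
    precursor = _TEMPLATE_GRID_START + _TEMPLATE_GRID_STEP * slot + float(rng.uniform(-5, 5))
    mz = np.sort(rng.uniform(50, min(precursor - 20, 1000), n_peaks))
    while np.any(np.diff(mz) < 1.0):  # well-separated fragments
        mz = np.sort(rng.uniform(50, min(precursor - 20, 1000), n_peaks))
    intensity = rng.lognormal(mean=4.0, sigma=0.7, size=n_peaks)
    return Spectrum(precursor_mz=precursor, mz=mz, intensity=intensity, source_id=mol_id)


def _background_spectrum(
    rng: np.random.Generator, forbidden: np.ndarray, source_id: str
) -> Spectrum:
    n_peaks = int(rng.integers(5, 21))
    for _ in range(100):
        precursor = float(rng.uniform(120, 980))
        if forbidden.size == 0 or np.min(np.abs(forbidden - precursor)) > _EXCLUSION:
            break
    mz = np.sort(rng.uniform(50, 1000, n_peaks))
    intensity = rng.lognormal(mean=4.0, sigma=1.0, size=n_peaks)
    return Spectrum(precursor_mz=precursor, mz=mz, intensity=intensity, source_id=source_id)


def _noisy_copy(template: Spectrum, noise: NoiseSpec, rng: np.random.Generator, source_id: str) -> Spectrum:
    mz = template.mz.copy()
    intensity = template.intensity.copy()
    if noise.jitter_sd > 0:
        mz = mz + rng.normal(0, noise.jitter_sd, mz.size)
    if noise.drop_prob > 0 and mz.size > 3:
        keep = rng.random(mz.size) > noise.drop_prob
        if keep.sum() < 3:  # keep planted occurrences findable at >= 3 ions
            keep[np.argsort(intensity)[-3:]] = True
        mz, intensity = mz[keep], intensity[keep]
    if noise.decoy_rate > 0:
        n_decoys = rng.binomial(template.mz.size, noise.decoy_rate)
        if n_decoys:
            d_mz = rng.uniform(50, 1000, n_decoys)
            d_int = rng.uniform(0.02, 0.2, n_decoys) * float(np.median(intensity))
            mz = np.concatenate([mz, d_mz])
            intensity = np.concatenate([intensity, d_int])
    precursor = template.precursor_mz
    if noise.jitter_sd > 0:
        precursor += float(rng.normal(0, noise.jitter_sd / 2))
    return Spectrum(precursor_mz=precursor, mz=mz, intensity=intensity, source_id=source_id)


def _shifted_template(template: Spectrum, plant: AnalogPlant, rng: np.random.Generator) -> Spectrum:
    n_shift = min(plant.n_shifted_peaks, len(template))
    idx = rng.choice(len(template), size=n_shift, replace=False)
    mz = template.mz.copy()
    mz[idx] = mz[idx] + plant.delta
    return Spectrum(
        precursor_mz=template.precursor_mz + plant.delta,
        mz=mz,
        intensity=template.intensity.copy(),
        source_id=f"{template.source_id}+{plant.delta:.3f}",
    )


@dataclass
class RepositoryFixture:
    """A generated reference repository plus its ground truth."""

    spec: FixtureSpec
    entries: list[LibraryEntry]
    records: list[FileRecord]
    lineage_table: dict[int, Lineage]
    fallback: dict[str, int]
    lineages_by_file: dict[str, Lineage | None]
    truth: pd.DataFrame  # mol_id, file_id, scan, taxon, kind, ref_usi
    molecules: tuple[PlantedMolecule, ...]

    def build_index(self) -> LibraryIndex:
        return build_index([(e.spectrum, e.record) for e in self.entries])

    def build_tree(self) -> TaxonNode:
        return build_tree(self.records, self.lineages_by_file)

    def truth_files(self, mol_id: str, kinds: Sequence[str] = ("direct",)) -> set[str]:
        mask = (self.truth["mol_id"] == mol_id) & self.truth["kind"].isin(kinds)
        return set(self.truth.loc[mask, "file_id"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the repository in its on-disk formats (MGF library dir,
        metadata TSV, lineage TSV, truth TSV)."""
        outdir = Path(outdir)
        libdir = outdir / "library"
        libdir.mkdir(parents=True, exist_ok=True)
        by_file: dict[str, list[Spectrum]] = {}
        for e in self.entries:
            by_file.setdefault(e.record.file_id, []).append(e.spectrum)
        for record in self.records:
            run = record.file_id.split("/", 1)[1]
            write_mgf(by_file.get(record.file_id, []), libdir / f"{run}.mgf")
        paths = {
            "library": libdir,
            "metadata": outdir / "metadata.tsv",
            "lineages": outdir / "lineages.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_metadata(self.records, paths["metadata"])
        write_lineage_table(self.lineage_table, paths["lineages"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _default_molecules(
    rng: np.random.Generator, species: list[str], genera: dict[str, list[str]]
) -> tuple[PlantedMolecule, ...]:
    """Six planted molecules exercising species/genus producers, fungal and
    dual-domain production, a cell-line co-producer, and a +14.016 analog."""
    bacterial = [s for s in species if s.startswith("Bac")]
    fungal = [s for s in species if s.startswith("Fun")]
    bac_genus = sorted(g for g in genera if g.startswith("Bac"))[1]
    analog_host, analog_sibling = bacterial[2], bacterial[3]
    defs = [
        ("mol01", (bacterial[0],), ()),
        ("mol02", (bac_genus,), ()),
        ("mol03", (fungal[0],), ()),
        ("mol04", (bacterial[1], fungal[1]), ()),
        ("mol05", (bacterial[4], "cell_line"), ()),
        ("mol06", (analog_host,), (AnalogPlant(analog_sibling, 14.016, 3),)),
    ]
    return tuple(
        PlantedMolecule(
            mol_id=mid,
            template=_template_spectrum(rng, slot, mid),
            producers=prod,
            analogs=analogs,
        )
        for slot, (mid, prod, analogs) in enumerate(defs)
    )


def make_repository(spec: FixtureSpec = FixtureSpec()) -> RepositoryFixture:
    """Generate the synthetic reference repository (see module docstring)."""
    rng = np.random.default_rng(spec.seed)

    # --- taxonomy -----------------------------------------------------------
    next_id = 1000
    lineage_table: dict[int, Lineage] = {}
    fallback: dict[str, int] = {}
    species_names: list[str] = []
    genera: dict[str, list[str]] = {}
    species_lineage: dict[str, Lineage] = {}

    for domain in (BACTERIA, FUNGI):
        pref = "Bac" if domain is BACTERIA else "Fun"
        head = LineageStep(*domain)
        for p in range(spec.phyla_per_domain):
            phylum = LineageStep(next_id, f"{pref}_phylum{p + 1}", "phylum")
            next_id += 1
            klass = LineageStep(next_id, f"{pref}_class{p + 1}", "class")
            next_id += 1
            order = LineageStep(next_id, f"{pref}_order{p + 1}", "order")
            next_id += 1
            for f in range(spec.families_per_phylum):
                family = LineageStep(next_id, f"{pref}_family{p + 1}_{f + 1}", "family")
                next_id += 1
                for g in range(spec.genera_per_family):
                    genus_name = f"{pref}genus{p + 1}{f + 1}{g + 1}"
                    genus = LineageStep(next_id, genus_name, "genus")
                    next_id += 1
                    genus_lineage = Lineage((head, phylum, klass, order, family, genus))
                    lineage_table[genus.ncbi_id] = genus_lineage
                    fallback[genus_name] = genus.ncbi_id
                    genera[genus_name] = []
                    for s in range(spec.species_per_genus):
                        sp_name = f"{genus_name} sp{s + 1}"
                        sp = LineageStep(next_id, sp_name, "species")
                        next_id += 1
                        lineage = Lineage(genus_lineage.steps + (sp,))
                        lineage_table[sp.ncbi_id] = lineage
                        fallback[sp_name] = sp.ncbi_id
                        species_names.append(sp_name)
                        genera[genus_name].append(sp_name)
                        species_lineage[sp_name] = lineage
    lineage_table[HUMAN_TAXID] = Lineage(
        (LineageStep(HUMAN_TAXID, "Homo sapiens", "species"),)
    )

    molecules = spec.planted_molecules
    if molecules is None:
        molecules = _default_molecules(rng, species_names, genera)
    known_taxa = set(species_names) | set(genera) | {"cell_line"}
    for mol in molecules:
        for producer in mol.producers:
            if producer not in known_taxa:
                raise FixtureSpecError(f"{mol.mol_id}: producer {producer!r} not in the taxa set")
        for plant in mol.analogs:
            if plant.taxon not in known_taxa:
                raise FixtureSpecError(f"{mol.mol_id}: analog taxon {plant.taxon!r} not in the taxa set")

    def producer_species(mol: PlantedMolecule) -> list[str]:
        out: list[str] = []
        for producer in mol.producers:
            if producer in genera:
                out.extend(genera[producer])
            elif producer in species_lineage:
                out.append(producer)
        return out

    plants_by_species: dict[str, list[tuple[PlantedMolecule, Spectrum, str]]] = {}
    forbidden = [m.template.precursor_mz for m in molecules]
    for mol in molecules:
        for sp_name in producer_species(mol):
            plants_by_species.setdefault(sp_name, []).append((mol, mol.template, "direct"))
        for plant in mol.analogs:
            shifted = _shifted_template(mol.template, plant, rng)
            forbidden.append(shifted.precursor_mz)
            targets = genera.get(plant.taxon, [plant.taxon] if plant.taxon in species_lineage else [])
            for sp_name in targets:
                plants_by_species.setdefault(sp_name, []).append((mol, shifted, "analog"))
    forbidden_arr = np.asarray(forbidden)

    # --- files and spectra --------------------------------------------------
    datasets = [f"MSV{800001 + d:06d}" for d in range(4)]
    entries: list[LibraryEntry] = []
    records: list[FileRecord] = []
    truth_rows: list[dict] = []
    lineages_by_file: dict[str, Lineage | None] = {}

    def add_file(
        record: FileRecord,
        backgrounds: int,
        plants: Sequence[tuple[PlantedMolecule, Spectrum, str]] = (),
        taxon_label: str = "",
        media_template: Spectrum | None = None,
    ) -> None:
        run = record.file_id.split("/", 1)[1]
        scan = 0
        spectra: list[Spectrum] = []
        if media_template is not None:
            scan += 1
            sid = f"mzspec:{record.dataset_id}:{run}:scan:{scan}"
            spectra.append(_noisy_copy(media_template, spec.noise, rng, sid))
        for _ in range(backgrounds):
            scan += 1
            sid = f"mzspec:{record.dataset_id}:{run}:scan:{scan}"
            spectra.append(_background_spectrum(rng, forbidden_arr, sid))
        for mol, template, kind in plants:
            scan += 1
            sid = f"mzspec:{record.dataset_id}:{run}:scan:{scan}"
            spectra.append(_noisy_copy(template, spec.noise, rng, sid))
            truth_rows.append(
                {
                    "mol_id": mol.mol_id,
                    "file_id": record.file_id,
                    "scan": scan,
                    "taxon": taxon_label,
                    "kind": kind,
                    "ref_usi": sid,
                }
            )
        records.append(record)
        for s in spectra:
            entries.append(LibraryEntry(s, record))

    def biological_record(sp_name: str, k: int, dataset: str) -> FileRecord:
        slug = sp_name.replace(" ", "_")
        run = f"{slug}_r{k + 1}.mzML"
        return FileRecord(
            massive_path=f"f.{dataset}/peak/{run}",
            file_id=f"{dataset}/{run}",
            dataset_id=dataset,
            taxon_name_submitted=sp_name,
            taxon_name_alternative=None,
            ncbi_id=species_lineage[sp_name].terminal.ncbi_id,
            id_assignment="automatic",
            has_redu_metadata=True,
            is_blank=False,
            is_qc=False,
        )

    for i, sp_name in enumerate(species_names):
        dataset = datasets[i % len(datasets)]
        for k in range(spec.files_per_species):
            record = biological_record(sp_name, k, dataset)
            add_file(
                record,
                backgrounds=spec.spectra_per_file,
                plants=plants_by_species.get(sp_name, ()),
                taxon_label=sp_name,
            )
            lineages_by_file[record.file_id] = species_lineage[sp_name]

    # Closest-taxon fallback exercise: an unregistered strain curated to its
    # species via the alternative name, and a generically classified isolate.
    curated_species = species_names[0]
    quirks = [
        FileRecord(
            massive_path=f"f.{datasets[0]}/peak/curated_strain.mzML",
            file_id=f"{datasets[0]}/curated_strain.mzML",
            dataset_id=datasets[0],
            taxon_name_submitted=f"{curated_species} strain XQ-9",
            taxon_name_alternative=curated_species,
            ncbi_id=None,
            id_assignment="manual",
            has_redu_metadata=False,
            is_blank=False,
            is_qc=False,
        ),
        FileRecord(
            massive_path=f"f.{datasets[1]}/peak/generic_isolate.mzML",
            file_id=f"{datasets[1]}/generic_isolate.mzML",
            dataset_id=datasets[1],
            taxon_name_submitted="unclassified bacterium isolate A1",
            taxon_name_alternative=None,
            ncbi_id=None,
            id_assignment="manual",
            has_redu_metadata=False,
            is_blank=False,
            is_qc=False,
        ),
    ]
    for record in quirks:
        add_file(record, backgrounds=spec.spectra_per_file)
        lineages_by_file[record.file_id] = resolve_taxon(record, lineage_table, fallback)

    media = _template_spectrum(rng, len(molecules) + 1, "media")
    qc_mix = _template_spectrum(rng, len(molecules) + 2, "qc_mix")
    forbidden_arr = np.append(forbidden_arr, [media.precursor_mz, qc_mix.precursor_mz])

    for b in range(spec.n_blank_files):
        dataset = datasets[b % len(datasets)]
        run = f"blank_{b + 1}.mzML"
        record = FileRecord(
            massive_path=f"f.{dataset}/peak/{run}",
            file_id=f"{dataset}/{run}",
            dataset_id=dataset,
            taxon_name_submitted="culture medium blank",
            taxon_name_alternative=None,
            ncbi_id=None,
            id_assignment="automatic",
            has_redu_metadata=False,
            is_blank=True,
            is_qc=False,
        )
        add_file(record, backgrounds=2, media_template=media)
        lineages_by_file[record.file_id] = None

    for q in range(spec.n_qc_files):
        dataset = datasets[q % len(datasets)]
        run = f"qc_{q + 1}.mzML"
        record = FileRecord(
            massive_path=f"f.{dataset}/peak/{run}",
            file_id=f"{dataset}/{run}",
            dataset_id=dataset,
            taxon_name_submitted="quality control mix",
            taxon_name_alternative=None,
            ncbi_id=None,
            id_assignment="automatic",
            has_redu_metadata=False,
            is_blank=False,
            is_qc=True,
        )
        add_file(record, backgrounds=2, media_template=qc_mix)
        lineages_by_file[record.file_id] = None

    cell_plants = [
        (mol, mol.template, "direct") for mol in molecules if "cell_line" in mol.producers
    ]
    cell_names = ("HeLa", "HEK293")
    for c in range(spec.n_cell_line_files):
        dataset = datasets[c % len(datasets)]
        run = f"cellline_{c + 1}.mzML"
        record = FileRecord(
            massive_path=f"f.{dataset}/peak/{run}",
            file_id=f"{dataset}/{run}",
            dataset_id=dataset,
            taxon_name_submitted=cell_names[c % len(cell_names)],
            taxon_name_alternative="Homo sapiens",
            ncbi_id=HUMAN_TAXID,
            id_assignment="manual",
            has_redu_metadata=False,
            is_blank=False,
            is_qc=False,
        )
        add_file(record, backgrounds=spec.spectra_per_file, plants=cell_plants, taxon_label="cell_line")
        lineages_by_file[record.file_id] = lineage_table[HUMAN_TAXID]

    truth = pd.DataFrame(
        truth_rows, columns=["mol_id", "file_id", "scan", "taxon", "kind", "ref_usi"]
    )
    return RepositoryFixture(
        spec=spec,
        entries=entries,
        records=records,
        lineage_table=lineage_table,
        fallback=fallback,
        lineages_by_file=lineages_by_file,
        truth=truth,
        molecules=tuple(molecules),
    )


# ---------------------------------------------------------------------------
# Differential fixture
# ---------------------------------------------------------------------------


@dataclass
class DifferentialFixture:
    """A planted two-condition study plus second treated/untreated dataset."""

    repo: RepositoryFixture
    table: FeatureTable
    spectra: dict[str, Spectrum]
    edges: pd.DataFrame
    second_table: FeatureTable
    second_spectra: dict[str, Spectrum]
    truth_sets: dict[str, set[str]]
    funnel: dict[str, int]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def dump_table(tag: str, table: FeatureTable, spectra: Mapping[str, Spectrum]):
            feats = outdir / f"{tag}features.tsv"
            table.values.rename_axis("spectrum_id").to_csv(feats, sep="\t")
            labels = outdir / f"{tag}labels.tsv"
            pd.DataFrame(
                {
                    "sample": list(table.values.columns),
                    "condition": [table.conditions[c] for c in table.values.columns],
                }
            ).to_csv(labels, sep="\t", index=False)
            mgf = outdir / f"{tag}spectra.mgf"
            write_mgf([spectra[sid] for sid in sorted(spectra)], mgf)
            paths[f"{tag}features"] = feats
            paths[f"{tag}labels"] = labels
            paths[f"{tag}spectra"] = mgf

        dump_table("", self.table, self.spectra)
        dump_table("second_", self.second_table, self.second_spectra)
        paths["edges"] = outdir / "edges.tsv"
        self.edges.to_csv(paths["edges"], sep="\t", index=False)
        paths["truth"] = outdir / "truth_funnel.json"
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "funnel": self.funnel,
                    "sets": {k: sorted(v) for k, v in self.truth_sets.items()},
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        return paths


def make_differential_fixture(
    seed: int = 0,
    repo: RepositoryFixture | None = None,
) -> DifferentialFixture:
    """Plant the funnel 100 → 40 → 30 → 20 → 15 → 10 → 6 (see module doc).

    Stage membership by construction: 100 consensus spectra; 40 unique to
    the SPF condition; 10 of those carry a qualifying network edge to a
    GF-present spectrum (removed); of the 30 survivors 20 are copies of
    repository molecules (microbial match) of which 5 co-occur in cell
    lines; of the 15 clean spectra 10 are re-found in the second dataset
    and 6 only in untreated animals. The repository is generated at zero
    noise so the funnel is exact.
    """
    rng = np.random.default_rng(seed + 7919)
    if repo is None:
        repo = make_repository(FixtureSpec(seed=seed, noise=ZERO_NOISE))
    by_id = {m.mol_id: m for m in repo.molecules}
    required = {"mol01", "mol02", "mol03", "mol04", "mol05", "mol06"}
    if not required <= set(by_id):
        raise FixtureSpecError(
            "differential fixture needs the default planted molecules mol01..mol06"
        )

    ids = [f"s{i:03d}" for i in range(100)]
    untreated_templates = ["mol01", "mol02"]
    treated_templates = ["mol03", "mol06"]
    nonoverlap_templates = ["mol04"]

    groups: dict[str, list[str]] = {
        "overlap_untreated": ids[0:6],
        "overlap_treated": ids[6:10],
        "non_overlap": ids[10:15],
        "cell_line": ids[15:20],
        "unmatched": ids[20:30],
        "edge_removed": ids[30:40],
        "non_unique": ids[40:100],
    }
    template_of: dict[str, str] = {}
    for k, sid in enumerate(groups["overlap_untreated"]):
        template_of[sid] = untreated_templates[k % 2]
    for k, sid in enumerate(groups["overlap_treated"]):
        template_of[sid] = treated_templates[k % 2]
    for sid in groups["non_overlap"]:
        template_of[sid] = nonoverlap_templates[0]
    for sid in groups["cell_line"]:
        template_of[sid] = "mol05"

    forbidden = np.asarray([m.template.precursor_mz for m in repo.molecules])
    spectra: dict[str, Spectrum] = {}
    for sid in ids:
        if sid in template_of:
            template = by_id[template_of[sid]].template
            spectra[sid] = replace(
                template, mz=template.mz.copy(), intensity=template.intensity.copy(), source_id=sid
            )
        else:
            spectra[sid] = _background_spectrum(rng, forbidden, sid)

    spf_samples = [f"SPF{i + 1}" for i in range(6)]
    gf_samples = [f"GF{i + 1}" for i in range(6)]
    samples = spf_samples + gf_samples
    values = pd.DataFrame(0.0, index=pd.Index(ids, name="spectrum_id"), columns=samples)
    spf_unique = set(ids[:40])
    for sid in ids:
        if sid in spf_unique:
            cols = list(rng.choice(spf_samples, size=int(rng.integers(1, 4)), replace=False))
        else:
            cols = list(rng.choice(gf_samples, size=int(rng.integers(1, 4)), replace=False))
            if rng.random() < 0.5:  # half of the non-unique also occur in SPF
                cols += list(rng.choice(spf_samples, size=int(rng.integers(1, 3)), replace=False))
        for c in cols:
            values.loc[sid, c] = float(rng.integers(10_000, 1_000_000))
    table = FeatureTable(
        values=values,
        conditions={**{s: "SPF" for s in spf_samples}, **{s: "GF" for s in gf_samples}},
    )

    gf_present = sorted(table.present_ids("GF"))
    edge_rows = []
    for k, sid in enumerate(groups["edge_removed"]):
        partner = gf_present[k % len(gf_present)]
        edge_rows.append(
            {
                "id1": sid,
                "id2": partner,
                "cosine": round(float(rng.uniform(0.75, 0.95)), 4),
                "delta_mz": round(float(rng.uniform(-0.02, 0.02)), 4),
            }
        )
    # decoy edges that must NOT remove anything: one criterion fails each
    edge_rows.append({"id1": ids[0], "id2": gf_present[0], "cosine": 0.9, "delta_mz": 0.5})
    edge_rows.append({"id1": ids[1], "id2": gf_present[1], "cosine": 0.5, "delta_mz": 0.01})
    edge_rows.append({"id1": ids[2], "id2": ids[3], "cosine": 0.95, "delta_mz": 0.001})
    edges = pd.DataFrame(edge_rows, columns=["id1", "id2", "cosine", "delta_mz"])

    # --- second dataset -----------------------------------------------------
    second_ids = []
    second_spectra: dict[str, Spectrum] = {}
    untreated_only_ids = []
    treated_ids = []
    for k, mol in enumerate(untreated_templates):
        sid = f"t{k:03d}"
        second_ids.append(sid)
        untreated_only_ids.append(sid)
        template = by_id[mol].template
        second_spectra[sid] = replace(
            template, mz=template.mz.copy(), intensity=template.intensity.copy(), source_id=sid
        )
    for k, mol in enumerate(treated_templates):
        sid = f"t{k + 10:03d}"
        second_ids.append(sid)
        treated_ids.append(sid)
        template = by_id[mol].template
        second_spectra[sid] = replace(
            template, mz=template.mz.copy(), intensity=template.intensity.copy(), source_id=sid
        )
    for k in range(20):
        sid = f"t{k + 50:03d}"
        second_ids.append(sid)
        second_spectra[sid] = _background_spectrum(rng, forbidden, sid)

    treated_samples = [f"T{i + 1}" for i in range(4)]
    untreated_samples = [f"U{i + 1}" for i in range(4)]
    second_values = pd.DataFrame(
        0.0,
        index=pd.Index(second_ids, name="spectrum_id"),
        columns=treated_samples + untreated_samples,
    )
    for sid in second_ids:
        if sid in untreated_only_ids:
            pool = untreated_samples
        elif sid in treated_ids:
            pool = treated_samples + untreated_samples
        else:
            pool = treated_samples + untreated_samples
        cols = list(rng.choice(pool, size=int(rng.integers(1, 3)), replace=False))
        if sid in treated_ids and not any(c in treated_samples for c in cols):
            cols.append(treated_samples[0])
        for c in cols:
            second_values.loc[sid, c] = float(rng.integers(10_000, 1_000_000))
    second_table = FeatureTable(
        values=second_values,
        conditions={
            **{s: "treated" for s in treated_samples},
            **{s: "untreated" for s in untreated_samples},
        },
    )

    truth_sets = {
        "total": set(ids),
        "condition_unique": spf_unique,
        "after_control_analog_removal": set(ids[:30]),
        "microbial_matched": set(ids[:20]),
        "microbial_no_cell_line": set(ids[:15]),
        "second_dataset_overlap": set(ids[:10]),
        "untreated_only": set(ids[:6]),
    }
    funnel = {k: len(v) for k, v in truth_sets.items()}
    return DifferentialFixture(
        repo=repo,
        table=table,
        spectra=spectra,
        edges=edges,
        second_table=second_table,
        second_spectra=second_spectra,
        truth_sets=truth_sets,
        funnel=funnel,
    )
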