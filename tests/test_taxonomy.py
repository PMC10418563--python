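"""Metadata validation, lineage resolution, tree construction, Newick I/O."""

import pytest

import taxomasst as tm
from taxomasst.exceptions import (
    InconsistentLineageError,
    MetadataValidationError,
    SchemaError,
    UnresolvableTaxonError,
)
from taxomasst.taxonomy import HUMAN_TAXID, name_fallback_from_table


def _record(file_id, **kw):
    base = dict(
        massive_path=f"f.MSVX/{file_id}",
        file_id=file_id,
        dataset_id="MSVX",
        taxon_name_submitted="Examplea testii",
        taxon_name_alternative=None,
        ncbi_id=5001,
        id_assignment="automatic",
        has_redu_metadata=False,
        is_blank=False,
        is_qc=False,
    )
    base.update(kw)
    return tm.FileRecord(**base)


@pytest.fixture()
def lineage_table():
    genus = [(2, "Bacteria", "domain"), (4001, "Examplea", "genus")]
    return {
        4001: tm.make_lineage(genus),
        5001: tm.make_lineage(genus + [(5001, "Examplea testii", "species")]),
        5002: tm.make_lineage(genus + [(5002, "Examplea alterii", "species")]),
    }


class TestFileRecord:
    def test_blank_and_qc_exclusive(self):
        with pytest.raises(MetadataValidationError):
            _record("f1", is_blank=True, is_qc=True)

    def test_metadata_roundtrip(self, tmp_path):
        records = [
            _record("MSVX/a.mzML"),
            _record("MSVX/b.mzML", is_blank=True, ncbi_id=None,
                    taxon_name_submitted="blank"),
        ]
        path = tmp_path / "meta.tsv"
        tm.write_metadata(records, path)
        assert tm.load_metadata(path) == records

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "meta.tsv"
        tm.write_metadata([_record("f1")], path)
        text = path.read_text().replace("ncbi_id", "taxid")
        path.write_text(text)
        with pytest.raises(SchemaError, match="ncbi_id"):
            tm.load_metadata(path)

    def test_duplicate_file_id_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        lines = tm.write_metadata([_record("f1")], path) or path.read_text().splitlines()
        path.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(MetadataValidationError, match="duplicate"):
            tm.load_metadata(path)


class TestResolve:
    def test_known_ncbi_id(self, lineage_table):
        lin = tm.resolve_taxon(_record("f1"), lineage_table)
        assert lin.terminal.ncbi_id == 5001

    def test_closest_taxon_fallback_via_alternative_name(self, lineage_table):
        # an unregistered strain curated to its species by name
        record = _record(
            "f2",
            ncbi_id=None,
            taxon_name_submitted="Examplea testii strain CM05",
            taxon_name_alternative="Examplea testii",
        )
        fallback = name_fallback_from_table(lineage_table)
        lin = tm.resolve_taxon(record, lineage_table, fallback)
        assert lin.terminal.ncbi_id == 5001 and lin.terminal.rank == "species"

    def test_generic_domain_classification(self, lineage_table):
        record = _record("f3", ncbi_id=None, taxon_name_submitted="bacterium X")
        lin = tm.resolve_taxon(record, lineage_table)
        assert [s.name for s in lin] == ["Bacteria"]
        fungal = _record("f4", ncbi_id=None, taxon_name_submitted="unknown fungus sp.")
        assert tm.resolve_taxon(fungal, lineage_table).terminal.name == "Fungi"

    def test_blank_needs_no_lineage(self, lineage_table):
        record = _record("f5", is_blank=True, ncbi_id=None, taxon_name_submitted="blank")
        assert tm.resolve_taxon(record, lineage_table) is None

    def test_unresolvable_raises(self, lineage_table):
        record = _record("f6", ncbi_id=None, taxon_name_submitted="mystery isolate")
        with pytest.raises(UnresolvableTaxonError, match="f6"):
            tm.resolve_taxon(record, lineage_table)


class TestBuildTree:
    def test_sample_count_additivity(self, lineage_table):
        records = [
            _record("fa", ncbi_id=5001),
            _record("fb", ncbi_id=5002, taxon_name_submitted="Examplea alterii"),
        ]
        lineages = {r.file_id: lineage_table[r.ncbi_id] for r in records}
        root = tm.build_tree(records, lineages)
        by_id = {n.ncbi_id: n for n in tm.walk(root)}
        assert by_id[4001].n_samples == 2
        assert by_id[5001].n_samples == 1 and by_id[5002].n_samples == 1
        assert root.n_samples == 2

    def test_blank_only_library(self):
        records = [
            _record(f"b{i}", is_blank=True, ncbi_id=None, taxon_name_submitted="blank")
            for i in range(4)
        ]
        root = tm.build_tree(records, {r.file_id: None for r in records})
        assert len(root.children) == 1
        (blank,) = root.children
        assert blank.rank == "blank" and blank.n_samples == 4
        assert root.n_samples == 4

    def test_cell_line_subtree(self, lineage_table):
        table = dict(lineage_table)
        table[HUMAN_TAXID] = tm.make_lineage([(HUMAN_TAXID, "Homo sapiens", "species")])
        records = [
            _record("hela", ncbi_id=HUMAN_TAXID, taxon_name_submitted="HeLa"),
            _record("hek", ncbi_id=HUMAN_TAXID, taxon_name_submitted="HEK293"),
        ]
        root = tm.build_tree(records, {r.file_id: table[HUMAN_TAXID] for r in records})
        (cell,) = [c for c in root.children if c.rank == "cell_line"]
        assert {c.name for c in cell.children} == {"HeLa", "HEK293"}
        assert cell.n_samples == 2
        assert all(c.ncbi_id < 0 for c in [cell] + cell.children)

    def test_inconsistent_parent_rejected(self):
        a = tm.make_lineage([(2, "Bacteria", "domain"), (10, "G1", "genus"), (20, "S", "species")])
        b = tm.make_lineage([(2, "Bacteria", "domain"), (11, "G2", "genus"), (20, "S", "species")])
        records = [_record("fa", ncbi_id=20), _record("fb", ncbi_id=20)]
        with pytest.raises(InconsistentLineageError):
            tm.build_tree(records, {"fa": a, "fb": b})

    def test_node_counts_match_linear_scan(self, repo, tree):
        # oracle: a node's n_samples = number of biological records whose
        # lineage contains that node (specials counted separately)
        counts = {}
        for record in repo.records:
            lineage = repo.lineages_by_file[record.file_id]
            if record.is_blank or record.is_qc:
                key = "blank" if record.is_blank else "qc"
                counts[key] = counts.get(key, 0) + 1
                continue
            if any(s.ncbi_id == HUMAN_TAXID for s in lineage):
                counts["cell_line"] = counts.get("cell_line", 0) + 1
                continue
            for step in lineage:
                counts[step.ncbi_id] = counts.get(step.ncbi_id, 0) + 1
        for node in tm.walk(tree):
            if node.rank == "root":
                assert node.n_samples == len(repo.records)
            elif node.rank in ("blank", "qc", "cell_line") and node.ncbi_id in (-1, -2, -3):
                assert node.n_samples == counts[node.rank]
            elif node.ncbi_id > 0:
                assert node.n_samples == counts[node.ncbi_id], node.name

    def test_sample_conservation(self, repo, tree):
        leafish = [
            n for n in tm.walk(tree)
            if not n.children or n.files
        ]
        total = sum(len(n.files) for n in tm.walk(tree))
        assert total == len(repo.records)
        assert tree.n_samples == len(repo.records)
        assert leafish  # sanity


class TestLineage:
    def test_rank_order_enforced(self):
        with pytest.raises(ValueError):
            tm.Lineage(
                (
                    tm.LineageStep(1, "S", "species"),
                    tm.LineageStep(2, "G", "genus"),
                )
            )

    def test_unknown_ranks_dropped(self):
        lin = tm.make_lineage(
            [
                (2, "Bacteria", "domain"),
                (99, "Terrabacteria group", "clade"),  # not a kept rank
                (10, "G", "genus"),
            ]
        )
        assert [s.rank for s in lin] == ["domain", "genus"]

    def test_lineage_table_roundtrip(self, tmp_path, lineage_table):
        path = tmp_path / "lineages.tsv"
        tm.write_lineage_table(lineage_table, path)
        assert tm.load_lineage_table(path) == lineage_table


class TestNewick:
    def test_single_root(self):
        root = tm.TaxonNode(1, "root", "root")
        assert tm.export_newick(root).rstrip().endswith("root;")

    def test_roundtrip_topology_and_names(self, tree):
        nwk = tm.export_newick(tree)
        back = tm.parse_newick(nwk)

        def shape(n):
            return (n.name, tuple(sorted(shape(c) for c in n.children)))

        assert shape(back) == shape(tree)

    def test_metacharacter_names_quoted(self):
        root = tm.TaxonNode(1, "root", "root")
        root.children.append(tm.TaxonNode(2, "weird (name): x,y", "species"))
        nwk = tm.export_newick(root)
        back = tm.parse_newick(nwk)
        assert back.children[0].name == "weird (name): x,y"

    def test_nesting_depth_matches_internal_nodes(self):
        # 3-level chain: root -> genus -> species
        root = tm.TaxonNode(1, "root", "root")
        genus = tm.TaxonNode(2, "G", "genus")
        genus.children.append(tm.TaxonNode(3, "S", "species"))
        root.children.append(genus)
        nwk = tm.export_newick(root)
        assert nwk.count("(") == 2  # one per internal node
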