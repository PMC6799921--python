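"""Term registry: structure, manifest bookkeeping and exports."""

import pytest
from xml.etree import ElementTree

from ieephys.errors import TermNotFoundError, UnknownSourceError
from ieephys.ontology import (EXTERNAL_SOURCES, ROOT_LABELS,
                              build_default_registry, count_by_source,
                              empty_registry, export_minimal_owl,
                              export_term_table, manifest_totals,
                              parse_term_table, subtree)


@pytest.fixture(scope="module")
def reg():
    return build_default_registry()


class TestStructure:
    def test_six_arm_roots(self, reg):
        assert len(reg.roots) == 6
        assert {reg.terms[r].label for r in reg.roots} == set(ROOT_LABELS)

    def test_position_new_classes(self, reg):
        """cochlear turn, apical and basal are project-new position terms."""
        pos = reg.by_label("position")
        arm = {t.label: t for t in subtree(reg, pos.id)}
        for label in ("apical", "basal"):
            assert arm[label].source == "NEW"
            assert arm[label].iri == ""
        assert reg.by_label("cochlear turn").source == "NEW"

    def test_device_arm_three_new_classes(self, reg):
        dev = reg.by_label("device")
        labels = [t.label for t in subtree(reg, dev.id)]
        for expected in ("pipette pressure clamp", "patch pipette",
                         "analog camera"):
            assert expected in labels
        new = [t for t in subtree(reg, dev.id) if t.source == "NEW"]
        assert len(new) == 3

    def test_every_term_reaches_a_root(self, reg):
        roots = set(reg.roots)

        def climbs(tid, seen):
            if tid in roots:
                return True
            assert tid not in seen, "cycle detected"
            return any(climbs(p, seen | {tid})
                       for p in reg.terms[tid].parents)

        for tid in reg.terms:
            assert climbs(tid, frozenset())

    def test_multiple_parents_permitted(self, reg):
        stim = reg.by_label("intracellular electrophysiology stimulus")
        assert len(stim.parents) == 2

    def test_iri_prefix_consistent_with_source(self, reg):
        from ieephys.ontology import IRI_BASES
        for t in reg.terms.values():
            if t.source == "NEW":
                assert t.iri == ""
                assert t.id.startswith("OBI_IEE:")
            elif t.source == "OBI":
                assert t.iri.startswith("http://purl.obolibrary.org/obo/")
            else:
                assert t.iri.startswith(IRI_BASES[t.source])

    def test_anatomical_subtree_contents(self, reg):
        root = reg.by_label("anatomical entity")
        labels = {t.label for t in subtree(reg, root.id)}
        assert {"apical", "basal", "subdivision of cochlea",
                "cochlea", "cochlear turn"} <= labels

    def test_subtree_of_leaf_is_singleton(self, reg):
        leaf = reg.by_label("apical")
        assert [t.label for t in subtree(reg, leaf.id)] == ["apical"]

    def test_subtree_missing_id_raises(self, reg):
        with pytest.raises(TermNotFoundError):
            subtree(reg, "NOPE:0000000")


class TestManifest:
    @pytest.mark.parametrize("source,count", [
        ("PATO", 28), ("FMA", 12), ("CHEBI", 8), ("CL", 5), ("CNO", 2),
        ("EDAM", 2), ("GO", 6), ("MP", 5), ("NCBITaxon", 2), ("NCIT", 2),
        ("OBA", 7), ("OPB", 1), ("SBO", 1), ("SIO", 3), ("UBERON", 2),
    ])
    def test_declared_counts(self, reg, source, count):
        assert count_by_source(reg, source, "declared") == count

    def test_totals(self, reg):
        imported, new, grand, nsrc = manifest_totals(reg)
        assert (imported, new, grand, nsrc) == (86, 37, 123, 15)

    def test_zeroed_manifest_totals(self):
        assert manifest_totals(empty_registry()) == (0, 0, 0, 0)

    def test_enumerated_never_exceeds_declared(self, reg):
        for source in EXTERNAL_SOURCES:
            assert count_by_source(reg, source, "enumerated") <= \
                count_by_source(reg, source, "declared")
        assert count_by_source(reg, "NEW", "enumerated") <= \
            reg.manifest.new_count

    def test_enumerated_on_empty_registry(self):
        assert count_by_source(empty_registry(), "PATO", "enumerated") == 0

    def test_unknown_source_rejected(self, reg):
        with pytest.raises(UnknownSourceError):
            count_by_source(reg, "HPO", "declared")


class TestExports:
    def test_term_table_round_trip(self, reg):
        text = export_term_table(reg)
        reg2 = parse_term_table(text)
        assert set(reg2.terms) == set(reg.terms)
        for tid, t in reg.terms.items():
            assert reg2.terms[tid] == t
        assert reg2.roots == reg.roots
        assert manifest_totals(reg2) == manifest_totals(reg)
        assert export_term_table(reg2) == text

    def test_term_table_byte_stable(self, reg):
        assert export_term_table(reg) == export_term_table(reg)
        assert export_term_table(reg).endswith("\n")

    def test_total_comment_matches_recomputed_sums(self, reg):
        text = export_term_table(reg)
        decl_line = next(ln for ln in text.splitlines()
                         if ln.startswith("# Declared: "))
        parts = dict(p.split("=")
                     for p in decl_line[len("# Declared: "):].split(";"))
        imported = sum(int(parts[s]) for s in EXTERNAL_SOURCES)
        total_line = next(ln for ln in text.splitlines()
                          if ln.startswith("# Total: "))
        assert f"imported={imported}" in total_line
        assert f"total={imported + int(parts['NEW'])}" in total_line

    def test_empty_registry_table_has_only_root_rows(self):
        text = export_term_table(empty_registry())
        rows = [ln for ln in text.splitlines()
                if ln and not ln.startswith("#")]
        assert len(rows) == 1 + 6  # header + six roots

    def test_owl_is_wellformed_xml_with_right_axiom_count(self, reg):
        owl = export_minimal_owl(reg)
        tree = ElementTree.fromstring(owl)
        assert tree is not None
        n_links = sum(len(t.parents) for t in reg.terms.values())
        assert owl.count("subClassOf") == n_links

    def test_owl_new_terms_use_project_namespace(self, reg):
        owl = export_minimal_owl(reg)
        for t in reg.terms.values():
            if t.source == "NEW":
                local = t.id.split(":", 1)[1]
                assert f"https://w3id.org/obi-iee/OBI_IEE_{local}" in owl

    def test_single_parent_registry_one_subclass_axiom(self, reg):
        import rdflib
        reg2 = empty_registry()
        owl = export_minimal_owl(reg2)
        g = rdflib.Graph()
        g.parse(data=owl, format="xml")
        sub = list(g.triples((None, rdflib.RDFS.subClassOf, None)))
        assert sub == []
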