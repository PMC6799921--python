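"""Naming conventions and the compiled file architecture."""

import pytest
from hypothesis import given, settings, strategies as st

from ieephys.schema import (Architecture, DUAL_SINE_GROUP, IV_GROUP,
                            TRANSFORMED_GROUP, canonical_group_name,
                            default_architecture, normalize_dataset_name,
                            normalize_group_name, required_paths)
from ieephys.errors import SchemaCompileError


class TestNaming:
    @pytest.mark.parametrize("label,expected", [
        ("Anatomical Entity", "anatomical entity"),
        ("DC Conductance", "DC conductance"),
        ("cell", "cell"),
        ("Outer Hair Cell", "outer hair cell"),
        ("Solution in the Patch Pipette", "solution in the patch pipette"),
    ])
    def test_group_normalisation(self, label, expected):
        assert normalize_group_name(label) == expected

    def test_alias_table_shortens_anatomical(self):
        assert canonical_group_name("Anatomical Entity") == "anatomical"
        assert normalize_group_name("Anatomical Entity") == \
            "anatomical entity"

    @pytest.mark.parametrize("label,expected", [
        ("cell diameter", "cell_diameter"),
        ("apical-basal polarity", "apical_basal_polarity"),
        ("cell_diameter", "cell_diameter"),
        ("peak NLC", "peak_NLC"),
        ("Maximum Displacement Charge", "maximum_displacement_charge"),
    ])
    def test_dataset_normalisation(self, label, expected):
        assert normalize_dataset_name(label) == expected

    @pytest.mark.parametrize("fn", [normalize_group_name,
                                    normalize_dataset_name])
    def test_empty_label_rejected(self, fn):
        with pytest.raises(ValueError):
            fn("")
        with pytest.raises(ValueError):
            fn("   ")

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet=st.characters(
        codec="ascii", categories=("L", "N", "P", "Zs")), min_size=1))
    def test_normalisation_idempotent(self, label):
        try:
            g = normalize_group_name(label)
        except ValueError:
            g = None
        if g is not None:
            assert normalize_group_name(g) == g
        try:
            d = normalize_dataset_name(label)
        except ValueError:
            return
        assert normalize_dataset_name(d) == d
        assert " " not in d


class TestArchitecture:
    def test_six_first_level_groups(self, arch):
        assert arch.first_level_groups() == [
            "anatomical", "assay", "cell", "device", "organism",
            "transformed data set"]

    def test_assay_has_two_protocol_subgroups(self, arch):
        protos = [n for n in arch.children("assay") if n.kind == "group"
                  and n.path.split("/")[-1] in (DUAL_SINE_GROUP, IV_GROUP)]
        assert len(protos) == 2

    def test_transformed_arm_has_four_subgroups(self, arch):
        subs = [n for n in arch.children(TRANSFORMED_GROUP)]
        assert sorted(n.name for n in subs) == [
            "IV data set", "boltzmann fit", "linear data set",
            "non-linear data set"]

    def test_iv_transformed_subgroup_has_three_datasets(self, arch):
        ds = [n for n in arch.children(f"{TRANSFORMED_GROUP}/IV data set")
              if n.kind == "dataset"]
        assert sorted(n.name for n in ds) == ["I_mean", "R_b",
                                              "membrane_potential"]

    def test_morphology_paths_present(self, arch):
        for leaf in ("cell_diameter", "cochlear_outer_hair_cell_length",
                     "cochlear_outer_hair_cell_lateral_wall_length"):
            assert ("cell/outer hair cell/morphology/measurement datum/"
                    + leaf) in arch.nodes
        assert ("cell/outer hair cell/morphology/predicted data item/"
                "cell_surface_area") in arch.nodes

    def test_surface_area_units(self, arch):
        node = arch.nodes["cell/outer hair cell/morphology/"
                          "predicted data item/cell_surface_area"]
        assert node.units == "micrometer x micrometer"

    def test_every_dataset_has_description(self, arch):
        for node in arch.nodes.values():
            if node.kind == "dataset":
                assert node.description

    def test_term_ids_resolve(self, arch, registry):
        for node in arch.nodes.values():
            if node.term_id:
                assert node.term_id in registry.terms

    def test_tree_property_each_node_has_parent(self, arch):
        for path in arch.nodes:
            if "/" in path:
                assert path.rsplit("/", 1)[0] in arch.nodes

    def test_compile_fails_without_arm_root(self, registry):
        import dataclasses
        broken = dataclasses.replace(registry)
        broken.terms = {k: v for k, v in registry.terms.items()
                        if v.label != "organism"}
        broken.roots = tuple(r for r in registry.roots
                             if r in broken.terms)
        with pytest.raises((SchemaCompileError, ValueError)):
            default_architecture(broken)

    def test_json_round_trip(self, arch):
        text = arch.to_json()
        arch2 = Architecture.from_json(text)
        assert arch2.nodes == arch.nodes
        assert arch2.root_attributes == arch.root_attributes
        assert arch2.to_json() == text


class TestRequiredPaths:
    def test_both_is_superset_of_each_protocol(self, arch):
        both = set(required_paths(arch, "both"))
        assert set(required_paths(arch, "dual_sine")) <= both
        assert set(required_paths(arch, "iv")) <= both
        assert both == set(required_paths(arch, "dual_sine")) | \
            set(required_paths(arch, "iv"))

    def test_iv_requires_rb(self, arch):
        assert f"{TRANSFORMED_GROUP}/IV data set/R_b" in \
            required_paths(arch, "iv")

    def test_dual_sine_requires_admittance_at_both_frequencies(self, arch):
        req = required_paths(arch, "dual_sine")
        base = f"assay/{DUAL_SINE_GROUP}/measurement datum"
        for part in ("real", "imaginary"):
            for freq in ("f1", "f2"):
                assert f"{base}/electrical_admittance_{part}_{freq}" in req

    def test_unknown_protocol_rejected(self, arch):
        with pytest.raises(ValueError):
            required_paths(arch, "triple_sine")

    def test_deterministic_and_sorted(self, arch):
        paths = required_paths(arch, "both")
        assert paths == sorted(paths)
        assert paths == required_paths(arch, "both")
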