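"""HDF5 writing, reading and the layout conventions."""

import numpy as np
import h5py
import pytest

from ieephys.errors import SchemaError
from ieephys.h5io import (default_filename, describe_tree, read_recording,
                          tree_paths, write_recording)
from ieephys.synth import bundles_equal


class TestWrittenLayout:
    def test_six_first_level_groups(self, h5file):
        with h5py.File(h5file) as f:
            assert sorted(f.keys()) == [
                "anatomical", "assay", "cell", "device", "organism",
                "transformed data set"]

    def test_root_provenance_attributes(self, h5file, arch):
        with h5py.File(h5file) as f:
            for attr in arch.root_attributes:
                assert f.attrs[attr]

    def test_every_node_has_description(self, h5file):
        with h5py.File(h5file) as f:
            problems = []

            def visit(path, obj):
                if "description" not in obj.attrs:
                    problems.append(path)

            f.visititems(visit)
            assert problems == []

    def test_area_units_long_form_ascii(self, h5file):
        with h5py.File(h5file) as f:
            d = f["cell/outer hair cell/morphology/predicted data item/"
                  "cell_surface_area"]
            assert d.attrs["units"] == "micrometer x micrometer"

    def test_no_compound_datatypes(self, h5file):
        with h5py.File(h5file) as f:
            compound = []

            def visit(path, obj):
                if isinstance(obj, h5py.Dataset) and \
                        obj.dtype.names is not None:
                    compound.append(path)

            f.visititems(visit)
            assert compound == []

    def test_small_numeric_datasets_compact(self, h5file):
        with h5py.File(h5file) as f:
            small = f["cell/outer hair cell/morphology/measurement datum/"
                      "cell_diameter"]
            assert small.id.get_create_plist().get_layout() == \
                h5py.h5d.COMPACT
            big = f["assay/membrane current I as a function of membrane "
                    "potential V/measurement datum/membrane_current"]
            assert big.nbytes > 64 * 1024
            assert big.id.get_create_plist().get_layout() != \
                h5py.h5d.COMPACT

    def test_transformed_arm_four_subgroups(self, h5file):
        with h5py.File(h5file) as f:
            assert sorted(f["transformed data set"].keys()) == [
                "IV data set", "boltzmann fit", "linear data set",
                "non-linear data set"]

    def test_iv_subgroup_three_datasets(self, h5file):
        with h5py.File(h5file) as f:
            assert sorted(f["transformed data set/IV data set"]) == [
                "I_mean", "R_b", "membrane_potential"]

    def test_default_filename(self, bundle):
        assert default_filename(bundle) == "C0001_2016-01-01.h5"

    def test_missing_required_field_blocks_write(self, bundle, arch,
                                                 tmp_path):
        import dataclasses
        broken = dataclasses.replace(
            bundle, provenance=dataclasses.replace(bundle.provenance,
                                                   funding_source=""))
        with pytest.raises(SchemaError) as err:
            write_recording(broken, None, arch, tmp_path / "x.h5")
        assert "funding_source" in str(err.value)
        assert not (tmp_path / "x.h5").exists()


class TestRoundTrip:
    def test_read_write_identity(self, h5file, bundle, arch):
        back, td = read_recording(h5file, arch)
        assert bundles_equal(bundle, back, rtol=1e-14, atol=0.0)
        assert td is not None
        assert back.extras == {}

    def test_transformed_round_trip_values(self, h5file, transformed, arch):
        _, td = read_recording(h5file, arch)
        assert td.linear.Clin == pytest.approx(transformed.linear.Clin,
                                               rel=1e-14)
        assert td.boltzmann.params.Vpk == pytest.approx(
            transformed.boltzmann.params.Vpk, rel=1e-14)
        assert td.iv.Rb == pytest.approx(transformed.iv.Rb, rel=1e-14)
        assert np.allclose(td.nonlinear.nlc, transformed.nonlinear.nlc,
                           rtol=1e-14)

    def test_file_without_transformed_reads_as_none(self, bundle, arch,
                                                    tmp_path):
        p = tmp_path / "raw.h5"
        write_recording(bundle, None, arch, p)
        back, td = read_recording(p, arch)
        assert td is None
        assert bundles_equal(bundle, back, rtol=1e-14)

    def test_extra_dataset_tolerated_and_preserved(self, h5file, arch,
                                                   tmp_path):
        import shutil
        p = tmp_path / "extra.h5"
        shutil.copyfile(h5file, p)
        with h5py.File(p, "r+") as f:
            d = f["organism"].create_dataset("custom_note", data=3.14)
            d.attrs["description"] = "third-party addition"
        back, _ = read_recording(p, arch)
        assert back.extras == {"organism/custom_note": 3.14}

    def test_missing_arm_reported_with_path(self, h5file, arch, tmp_path):
        import shutil
        p = tmp_path / "no_organism.h5"
        shutil.copyfile(h5file, p)
        with h5py.File(p, "r+") as f:
            del f["organism"]
        with pytest.raises(SchemaError) as err:
            read_recording(p, arch)
        assert "organism" in str(err.value)
        assert any(m.startswith("organism") for m in err.value.paths)


class TestDescribeTree:
    def test_first_level_entries_fixed_order(self, h5file):
        text = describe_tree(h5file)
        top = [ln.split("/")[0] for ln in text.splitlines()
               if ln and not ln.startswith(("@", " "))]
        assert top == ["anatomical", "assay", "cell", "device", "organism",
                       "transformed data set"]

    def test_identical_across_runs(self, h5file):
        assert describe_tree(h5file) == describe_tree(h5file)

    def test_path_set_covers_required_paths(self, h5file, arch):
        from ieephys.schema import required_paths
        paths = set(tree_paths(h5file))
        for p in required_paths(arch, "both"):
            assert p in paths

    def test_units_shown_for_dimensioned_datasets(self, h5file):
        text = describe_tree(h5file)
        assert "[micrometer]" in text
        assert "[nanosiemens]" in text
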