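"""Check an HDF5 file against the architecture and its conventions.

Checks, in order per node: required groups and datasets present; group
and dataset naming rules; a ``description`` attribute on every node; a
``units`` attribute from the long-form table on physically dimensioned
datasets; the six provenance attributes at the file root; no compound
datatypes anywhere; exactly one cell per file.  Unknown extra nodes are
tolerated (reported as notes, not violations).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field

import numpy as np
import h5py

from .schema import (Architecture, is_valid_dataset_name,
                     is_valid_group_name)
from .units import is_known

CODES = (
    "MISSING_GROUP", "MISSING_DATASET", "MISSING_UNITS",
    "MISSING_DESCRIPTION", "BAD_GROUP_NAME", "BAD_DATASET_NAME",
    "COMPOUND_TYPE", "MISSING_PROVENANCE", "MULTI_CELL", "UNKNOWN_UNIT",
)


@dataclass(frozen=True)
class Violation:
    code: str
    path: str
    message: str


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    @property
    def counts(self) -> dict:
        out = {}
        for v in self.violations:
            out[v.code] = out.get(v.code, 0) + 1
        return out

    def finalize(self):
        self.violations.sort(key=lambda v: (v.path, v.code))
        return self

    def to_json(self) -> str:
        return json.dumps({
            "valid": self.valid,
            "violations": [vars(v) for v in self.violations],
            "notes": list(self.notes),
            "counts": self.counts,
        }, indent=2)

    def to_table(self) -> str:
        if self.valid:
            return "no violations\n"
        lines = [f"{v.code:22s} {v.path}  {v.message}"
                 for v in self.violations]
        return "\n".join(lines) + "\n"


def _attr_str(obj, key):
    val = obj.attrs.get(key)
    if isinstance(val, bytes):
        return val.decode("utf-8")
    return val


def validate_file(source, arch: Architecture,
                  protocol: str = "both") -> ValidationReport:
    """Validate ``source`` against ``arch`` for the given protocol set."""
    from .schema import required_paths

    report = ValidationReport()
    add = report.violations.append
    required = set(required_paths(arch, protocol))
    with h5py.File(source, "r") as f:
        # provenance attributes at root
        for attr in arch.root_attributes:
            val = _attr_str(f, attr)
            present = val is not None and \
                (np.asarray(val).size > 0 and str(val) != "")
            if not present:
                add(Violation("MISSING_PROVENANCE", "/",
                              f"root attribute {attr!r} missing or empty"))
        # one cell per file
        cell_no = f.attrs.get("cell_number")
        if cell_no is not None and np.asarray(cell_no).size > 1:
            add(Violation("MULTI_CELL", "/",
                          "cell_number attribute holds multiple values; "
                          "files must describe exactly one cell"))

        # required nodes; a missing group subsumes its descendants
        missing = {p for p in required if p not in f}
        for path in sorted(missing):
            if any(path.startswith(anc + "/") for anc in missing
                   if anc != path):
                continue
            node = arch.nodes[path]
            code = "MISSING_GROUP" if node.kind == "group" \
                else "MISSING_DATASET"
            add(Violation(code, "/" + path, f"required {node.kind} absent"))

        # per-node conventions on everything actually present
        def visit(path, obj):
            name = path.rsplit("/", 1)[-1]
            known = path in arch.nodes
            if isinstance(obj, h5py.Group):
                if not is_valid_group_name(name):
                    add(Violation("BAD_GROUP_NAME", "/" + path,
                                  f"group name {name!r} violates the "
                                  f"lower-case phrase rule"))
            else:
                if not is_valid_dataset_name(name):
                    add(Violation("BAD_DATASET_NAME", "/" + path,
                                  f"dataset name {name!r} violates the "
                                  f"underscore rule"))
                if obj.dtype.names is not None:
                    add(Violation("COMPOUND_TYPE", "/" + path,
                                  "compound datatypes are not permitted"))
                units = _attr_str(obj, "units")
                node = arch.nodes.get(path)
                if units is None:
                    needs_units = node is not None and bool(node.units)
                    if needs_units:
                        add(Violation("MISSING_UNITS", "/" + path,
                                      "physically dimensioned dataset "
                                      "lacks a units attribute"))
                elif not is_known(units):
                    add(Violation("UNKNOWN_UNIT", "/" + path,
                                  f"units {units!r} not in the long-form "
                                  f"table"))
            if _attr_str(obj, "description") in (None, ""):
                add(Violation("MISSING_DESCRIPTION", "/" + path,
                              "node lacks a description attribute"))
            if not known and "/concentration/" not in path:
                report.notes.append(f"extra node not in architecture: "
                                    f"/{path}")

        f.visititems(visit)
    return report.finalize()


# ---------------------------------------------------------------------------
# defect injection (test support)
# ---------------------------------------------------------------------------

_MUTATIONS = {}


def _mutation(code):
    def deco(fn):
        _MUTATIONS[code] = fn
        return fn
    return deco


@_mutation("MISSING_GROUP")
def _mut_missing_group(f):
    del f["organism"]


@_mutation("MISSING_DATASET")
def _mut_missing_dataset(f):
    del f["cell/outer hair cell/morphology/measurement datum/cell_diameter"]


@_mutation("MISSING_UNITS")
def _mut_missing_units(f):
    d = f["cell/outer hair cell/morphology/measurement datum/cell_diameter"]
    del d.attrs["units"]


@_mutation("MISSING_DESCRIPTION")
def _mut_missing_description(f):
    del f["organism/species"].attrs["description"]


@_mutation("BAD_GROUP_NAME")
def _mut_bad_group_name(f):
    # copy (not move) so no required-path violation is co-injected
    f.copy("device/analog camera", "device/Analog Camera")


@_mutation("BAD_DATASET_NAME")
def _mut_bad_dataset_name(f):
    base = "cell/outer hair cell/morphology/measurement datum"
    f.copy(f"{base}/cell_diameter", f"{base}/Cell Diameter")


@_mutation("COMPOUND_TYPE")
def _mut_compound(f):
    dt = np.dtype([("re", "f8"), ("im", "f8")])
    d = f["organism"].create_dataset("compound_probe", shape=(2,), dtype=dt)
    d.attrs["description"] = "injected compound dataset"


@_mutation("MISSING_PROVENANCE")
def _mut_missing_provenance(f):
    del f.attrs["funding_source"]


@_mutation("MULTI_CELL")
def _mut_multi_cell(f):
    first = f.attrs["cell_number"]
    if isinstance(first, bytes):
        first = first.decode("utf-8")
    f.attrs["cell_number"] = np.array([first, "C9999"],
                                      dtype=h5py.string_dtype())


@_mutation("UNKNOWN_UNIT")
def _mut_unknown_unit(f):
    d = f["cell/outer hair cell/morphology/predicted data item/"
          "cell_surface_area"]
    d.attrs["units"] = "µm^2"


def mutate_for_test(source, destination, defect: str):
    """Copy ``source`` to ``destination`` and inject exactly one defect.

    Each supported code has one targeted mutation, so the test suite can
    prove that every detector fires.  Unknown codes raise ValueError.
    """
    if defect not in _MUTATIONS:
        raise ValueError(f"unknown defect code: {defect!r}")
    shutil.copyfile(source, destination)
    with h5py.File(destination, "r+") as f:
        _MUTATIONS[defect](f)
    return destination
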