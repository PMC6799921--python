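"""Read and write the six-group HDF5 layout.

Conventions enforced on write:

* exactly the six first-level groups of the architecture, one cell per
  file;
* every group and dataset carries a ``description`` attribute, every
  physically dimensioned dataset a long-form ``units`` attribute;
* the six provenance attributes sit on the file root;
* values live exclusively in plain (never compound) datasets, stored
  with the *compact* layout when the payload fits in the object header
  (<= 64 KiB), so small datasets travel with their metadata;
* complex admittance is stored as separate real and imaginary datasets.
"""

from __future__ import annotations

import numpy as np
import h5py

from . import units as units_mod
from .biophysics import StimulusSpec, cell_surface_area
from .errors import SchemaError, UnknownUnitError
from .schema import (ACQUISITION_FIELDS, Architecture, DUAL_SINE_GROUP,
                     IV_GROUP, TRANSFORMED_GROUP)
from .synth import (AdmittanceRecord, Anatomy, Conditions, Devices,
                    IVProtocol, Morphology, Organism, Provenance,
                    RecordingBundle, Solution)

COMPACT_LIMIT = 64 * 1024  # HDF5 compact-layout ceiling, bytes

_STR = h5py.string_dtype(encoding="utf-8")


def default_filename(bundle: RecordingBundle) -> str:
    return (f"{bundle.provenance.cell_number}_"
            f"{bundle.provenance.experiment_date}.h5")


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _create_numeric(parent: h5py.Group, name: str, data) -> h5py.Dataset:
    """Create a float64 dataset, compact when it fits the object header."""
    arr = np.asarray(data, dtype="f8")
    dcpl = h5py.h5p.create(h5py.h5p.DATASET_CREATE)
    if arr.nbytes <= COMPACT_LIMIT:
        dcpl.set_layout(h5py.h5d.COMPACT)
    if arr.shape == ():
        space = h5py.h5s.create(h5py.h5s.SCALAR)
    else:
        space = h5py.h5s.create_simple(arr.shape)
    did = h5py.h5d.create(parent.id, name.encode("utf-8"),
                          h5py.h5t.NATIVE_DOUBLE, space, dcpl=dcpl)
    dset = h5py.Dataset(did)
    dset[()] = arr
    return dset


def _write_dataset(parent, name, data, description, units=""):
    if isinstance(data, str):
        dset = parent.create_dataset(name, data=data, dtype=_STR)
    else:
        dset = _create_numeric(parent, name, data)
    dset.attrs["description"] = description
    if units:
        units_mod.factor(units)  # raises UnknownUnitError on bad strings
        dset.attrs["units"] = units
    return dset


def _make_group(parent, name, description):
    grp = parent.create_group(name)
    grp.attrs["description"] = description
    return grp


class _Writer:
    """Architecture-driven writer for one bundle."""

    def __init__(self, f: h5py.File, arch: Architecture):
        self.f = f
        self.arch = arch

    def group(self, path):
        node = self.arch.nodes[path]
        parent = self.f if "/" not in path else \
            self.f[path.rsplit("/", 1)[0]]
        return _make_group(parent, node.name, node.description)

    def dataset(self, path, value, internal=True):
        """Write the node at ``path``; numeric values arrive in internal
        units and are converted to the node's display unit."""
        node = self.arch.nodes[path]
        parent = self.f[path.rsplit("/", 1)[0]]
        if node.units and not isinstance(value, str) and internal:
            value = units_mod.from_internal(np.asarray(value, dtype=float),
                                            node.units)
        _write_dataset(parent, node.name, value, node.description,
                       node.units)


def _check_required_bundle(bundle: RecordingBundle):
    problems = []
    for attr in ("provenance", "organism", "anatomy", "morphology",
                 "bath_solution", "pipette_solution", "devices",
                 "conditions", "stimulus", "admittance", "iv"):
        if getattr(bundle, attr, None) is None:
            problems.append(attr)
    if problems:
        raise SchemaError("bundle missing required sections: "
                          + ", ".join(problems), paths=problems)
    for name, _r, _u in ACQUISITION_FIELDS:
        if name not in bundle.aux:
            raise SchemaError(f"bundle missing required field: {name}",
                              paths=[name])
    for fieldname in ("experiment_date", "cell_number", "researcher",
                      "responsible_person", "data_curator",
                      "funding_source"):
        if not getattr(bundle.provenance, fieldname):
            raise SchemaError(f"empty provenance field: {fieldname}",
                              paths=[fieldname])


def write_recording(bundle: RecordingBundle, transformed, arch: Architecture,
                    destination) -> None:
    """Write one cell to ``destination`` in the six-group layout.

    ``transformed`` is a :class:`~ieephys.pipeline.TransformedData` or
    ``None``; when absent the four transformed sub-groups are still
    created (the arm always exists) but their datasets are not.
    Schema-required content is checked before any byte is written.
    """
    _check_required_bundle(bundle)
    b = bundle
    with h5py.File(destination, "w") as f:
        for attr in arch.root_attributes:
            f.attrs[attr] = getattr(b.provenance, attr)
        w = _Writer(f, arch)
        DS, IVG, TR = DUAL_SINE_GROUP, IV_GROUP, TRANSFORMED_GROUP

        # anatomical arm
        w.group("anatomical")
        w.group("anatomical/subdivision of bony labyrinth")
        sub = "anatomical/subdivision of bony labyrinth/" \
              "subdivision of cochlea"
        w.group(sub)
        w.dataset(f"{sub}/cochlear_turn", b.anatomy.cochlear_turn)
        w.dataset(f"{sub}/cochlea", b.anatomy.cochlea_side)
        w.group("anatomical/position")
        w.dataset("anatomical/position/apical_basal_polarity",
                  b.anatomy.apical_basal_polarity)
        w.dataset("anatomical/position/best_frequency",
                  b.anatomy.best_frequency_hz)

        # assay arm: dual-sine protocol
        w.group("assay")
        w.group(f"assay/{DS}")
        stim_g = f"assay/{DS}/intracellular electrophysiology stimulus"
        w.group(stim_g)
        w.dataset(f"{stim_g}/sine_frequency",
                  np.array([b.stimulus.f1, b.stimulus.f2]))
        w.dataset(f"{stim_g}/sine_amplitude",
                  np.array([b.stimulus.a1, b.stimulus.a2]))
        w.dataset(f"{stim_g}/command_potential", b.admittance.Vdc)
        w.dataset(f"{stim_g}/hold_time", b.stimulus.hold_time)
        meas = f"assay/{DS}/measurement datum"
        w.group(meas)
        w.dataset(f"{meas}/electrical_admittance_real_f1",
                  b.admittance.Y1.real)
        w.dataset(f"{meas}/electrical_admittance_imaginary_f1",
                  b.admittance.Y1.imag)
        w.dataset(f"{meas}/electrical_admittance_real_f2",
                  b.admittance.Y2.real)
        w.dataset(f"{meas}/electrical_admittance_imaginary_f2",
                  b.admittance.Y2.imag)
        pred = f"assay/{DS}/predicted data item"
        w.group(pred)
        if transformed is not None and transformed.per_potential is not None:
            pp = transformed.per_potential
            w.dataset(f"{pred}/membrane_capacitance_f1", pp.Cm_f1)
            w.dataset(f"{pred}/membrane_capacitance_f2", pp.Cm_f2)
            w.dataset(f"{pred}/membrane_resistance", pp.Rm)
            w.dataset(f"{pred}/series_resistance", pp.Rs)
            w.dataset(f"{pred}/reported_capacitance_estimate", pp.reported)
        ctrl = f"assay/{DS}/study design control variable"
        w.group(ctrl)
        w.dataset(f"{ctrl}/temperature", b.conditions.temperature_c)
        w.dataset(f"{ctrl}/pipette_pressure",
                  b.conditions.pipette_pressure_mmhg)
        for gname, sol in (("extracellular solution", b.bath_solution),
                           ("solution in the patch pipette",
                            b.pipette_solution)):
            base = f"assay/{DS}/{gname}"
            w.group(base)
            conc = w.group(f"{base}/concentration")
            for comp in sorted(sol.components):
                from .schema import normalize_dataset_name
                _write_dataset(conc, normalize_dataset_name(comp),
                               sol.components[comp] / 1e-3,
                               f"Molarity of {comp} in the solution.",
                               "millimolar")
            w.dataset(f"{base}/pH", sol.pH)
            w.dataset(f"{base}/osmolality", sol.osmolality)
        w.dataset(f"assay/{DS}/time_assay_started",
                  b.conditions.time_assay_started)
        w.dataset(f"assay/{DS}/time_interval_from_death",
                  b.conditions.time_interval_from_death_s)

        # assay arm: voltage-step protocol
        w.group(f"assay/{IVG}")
        ivstim = f"assay/{IVG}/intracellular electrophysiology stimulus"
        w.group(ivstim)
        w.dataset(f"{ivstim}/command_potential", b.iv.Vc)
        w.dataset(f"{ivstim}/hold_time", b.iv.hold_time)
        w.dataset(f"{ivstim}/sample_rate", b.iv.sample_rate)
        ivmeas = f"assay/{IVG}/measurement datum"
        w.group(ivmeas)
        w.dataset(f"{ivmeas}/membrane_current", b.iv.traces)

        # acquisition metadata (filler fields)
        w.group("assay/acquisition metadata")
        for name, _role, _u in ACQUISITION_FIELDS:
            w.dataset(f"assay/acquisition metadata/{name}", b.aux[name],
                      internal=False)

        # cell arm
        w.group("cell")
        w.group("cell/outer hair cell")
        w.group("cell/outer hair cell/morphology")
        mm = "cell/outer hair cell/morphology/measurement datum"
        w.group(mm)
        w.dataset(f"{mm}/cell_diameter", b.morphology.diameter_m)
        w.dataset(f"{mm}/cochlear_outer_hair_cell_length",
                  b.morphology.length_m)
        w.dataset(f"{mm}/cochlear_outer_hair_cell_lateral_wall_length",
                  b.morphology.lateral_wall_length_m)
        mp = "cell/outer hair cell/morphology/predicted data item"
        w.group(mp)
        area_um2 = cell_surface_area(b.morphology.length_m / 1e-6,
                                     b.morphology.diameter_m / 1e-6)
        w.dataset(f"{mp}/cell_surface_area", area_um2 * 1e-12)

        # device arm
        w.group("device")
        for gname, model in (
                ("pipette pressure clamp", b.devices.pipette_pressure_clamp),
                ("patch pipette", b.devices.patch_pipette),
                ("analog camera", b.devices.analog_camera)):
            w.group(f"device/{gname}")
            w.dataset(f"device/{gname}/model", model)

        # organism arm
        w.group("organism")
        w.dataset("organism/species", b.organism.species)
        w.dataset("organism/sex", b.organism.sex)
        w.dataset("organism/age", b.organism.age_days)
        w.dataset("organism/weight", b.organism.weight_grams)
        w.dataset("organism/phenotype", b.organism.phenotype)

        # transformed arm
        w.group(TR)
        for sub_name in ("linear data set", "non-linear data set",
                         "boltzmann fit", "IV data set"):
            w.group(f"{TR}/{sub_name}")
        if transformed is not None:
            _write_transformed(w, transformed)


def _write_transformed(w: _Writer, td):
    TR = TRANSFORMED_GROUP
    if td.linear is not None:
        lin = f"{TR}/linear data set"
        w.dataset(f"{lin}/linear_capacitance", td.linear.Clin)
        w.dataset(f"{lin}/membrane_resistance", td.linear.Rm)
        w.dataset(f"{lin}/series_resistance", td.linear.Rs)
        w.dataset(f"{lin}/membrane_voltage", td.linear.Vm)
    if td.nonlinear is not None:
        non = f"{TR}/non-linear data set"
        w.dataset(f"{non}/non_linear_capacitance", td.nonlinear.nlc)
        w.dataset(f"{non}/peak_NLC", td.nonlinear.peak_nlc)
        w.dataset(f"{non}/displacement_charge", td.nonlinear.charge)
        w.dataset(f"{non}/maximum_displacement_charge",
                  td.nonlinear.max_charge)
        w.dataset(f"{non}/voltage_sensitivity", td.nonlinear.alpha)
        w.dataset(f"{non}/potential_of_maximum_sensitivity",
                  td.nonlinear.Vpk)
    if td.boltzmann is not None:
        bol = f"{TR}/boltzmann fit"
        w.dataset(f"{bol}/Q_max", td.boltzmann.params.Qmax)
        w.dataset(f"{bol}/V_pk", td.boltzmann.params.Vpk)
        if td.boltzmann.Vpk_command is not None:
            w.dataset(f"{bol}/V_pk_command", td.boltzmann.Vpk_command)
        w.dataset(f"{bol}/alpha", td.boltzmann.params.alpha)
        w.dataset(f"{bol}/linear_capacitance", td.boltzmann.Clin)
        w.dataset(f"{bol}/residual_norm", td.boltzmann.residual_norm)
    if td.iv is not None:
        ivt = f"{TR}/IV data set"
        w.dataset(f"{ivt}/I_mean",
                  np.vstack([td.iv.I_mean, td.iv.I_sd]))
        w.dataset(f"{ivt}/R_b", td.iv.Rb)
        w.dataset(f"{ivt}/membrane_potential", td.iv.Vm)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_value(dset: h5py.Dataset, node):
    val = dset[()]
    if isinstance(val, bytes):
        return val.decode("utf-8")
    if node is not None and node.units:
        return units_mod.to_internal(val, node.units)
    return val


def read_recording(source, arch: Architecture):
    """Read a conformant file back into (bundle, transformed-or-None).

    Traversal follows the architecture; nodes present in the file but
    absent from the architecture are collected verbatim into
    ``bundle.extras`` (a path -> value map) rather than rejected.
    Numeric values are converted to internal SI via the units table; an
    out-of-table ``units`` attribute raises :class:`UnknownUnitError`.
    """
    from .pipeline import (BoltzmannFitSet, IVSet, LinearSet, NonlinearSet,
                           PerPotentialSet, TransformedData)
    with h5py.File(source, "r") as f:
        # transformed-arm datasets are derived content: their absence is a
        # valid state on read (the pipeline can always recompute them)
        missing = [p for p, n in arch.nodes.items()
                   if n.required and p not in f
                   and not (n.kind == "dataset"
                            and p.startswith(TRANSFORMED_GROUP + "/"))]
        if missing:
            raise SchemaError("file missing required node(s): "
                              + ", ".join(sorted(missing)),
                              paths=sorted(missing))

        def get(path, default=None):
            if path not in f:
                return default
            dset = f[path]
            node = arch.nodes.get(path)
            if node is None and "units" in dset.attrs:
                u = dset.attrs["units"]
                if not units_mod.is_known(u):
                    raise UnknownUnitError(u)
            return _read_value(dset, node)

        DS, IVG, TR = DUAL_SINE_GROUP, IV_GROUP, TRANSFORMED_GROUP
        stim_g = f"assay/{DS}/intracellular electrophysiology stimulus"
        f1, f2 = get(f"{stim_g}/sine_frequency")
        a1, a2 = get(f"{stim_g}/sine_amplitude")
        Vdc = np.asarray(get(f"{stim_g}/command_potential"))
        stim = StimulusSpec(f1=float(f1), f2=float(f2), a1=float(a1),
                            a2=float(a2), Vdc=tuple(Vdc),
                            hold_time=float(get(f"{stim_g}/hold_time")))
        meas = f"assay/{DS}/measurement datum"
        Y1 = np.asarray(get(f"{meas}/electrical_admittance_real_f1")) + \
            1j * np.asarray(get(f"{meas}/electrical_admittance_imaginary_f1"))
        Y2 = np.asarray(get(f"{meas}/electrical_admittance_real_f2")) + \
            1j * np.asarray(get(f"{meas}/electrical_admittance_imaginary_f2"))
        sub = ("anatomical/subdivision of bony labyrinth/"
               "subdivision of cochlea")
        solutions = {}
        for key, gname in (("bath", "extracellular solution"),
                           ("pipette", "solution in the patch pipette")):
            base = f"assay/{DS}/{gname}"
            conc_grp = f[f"{base}/concentration"]
            comps = {}
            for name in sorted(conc_grp):
                label = _component_label(conc_grp[name])
                comps[label] = float(conc_grp[name][()]) * 1e-3
            solutions[key] = Solution(
                components=comps, pH=float(get(f"{base}/pH")),
                osmolality=float(get(f"{base}/osmolality")))
        ivstim = f"assay/{IVG}/intracellular electrophysiology stimulus"
        aux = {}
        for name, role, _u in ACQUISITION_FIELDS:
            raw = f[f"assay/acquisition metadata/{name}"][()]
            aux[name] = raw.decode("utf-8") if isinstance(raw, bytes) \
                else float(raw)
        mm = "cell/outer hair cell/morphology/measurement datum"
        bundle = RecordingBundle(
            provenance=Provenance(**{a: f.attrs[a]
                                     for a in arch.root_attributes}),
            organism=Organism(
                species=get("organism/species"),
                sex=get("organism/sex"),
                age_days=float(get("organism/age")),
                weight_grams=float(get("organism/weight")),
                phenotype=get("organism/phenotype")),
            anatomy=Anatomy(
                cochlea_side=get(f"{sub}/cochlea"),
                cochlear_turn=get(f"{sub}/cochlear_turn"),
                apical_basal_polarity=get(
                    "anatomical/position/apical_basal_polarity"),
                best_frequency_hz=float(get(
                    "anatomical/position/best_frequency", np.nan))),
            morphology=Morphology(
                length_m=float(get(f"{mm}/cochlear_outer_hair_cell_length")),
                diameter_m=float(get(f"{mm}/cell_diameter")),
                lateral_wall_length_m=float(get(
                    f"{mm}/cochlear_outer_hair_cell_lateral_wall_length"))),
            bath_solution=solutions["bath"],
            pipette_solution=solutions["pipette"],
            devices=Devices(
                pipette_pressure_clamp=get(
                    "device/pipette pressure clamp/model"),
                patch_pipette=get("device/patch pipette/model"),
                analog_camera=get("device/analog camera/model")),
            conditions=Conditions(
                temperature_c=float(get(
                    f"assay/{DS}/study design control variable/temperature")),
                pipette_pressure_mmhg=float(get(
                    f"assay/{DS}/study design control variable/"
                    f"pipette_pressure")),
                time_assay_started=get(f"assay/{DS}/time_assay_started"),
                time_interval_from_death_s=float(get(
                    f"assay/{DS}/time_interval_from_death"))),
            stimulus=stim,
            admittance=AdmittanceRecord(Vdc=Vdc, Y1=Y1, Y2=Y2),
            iv=IVProtocol(
                Vc=np.asarray(get(f"{ivstim}/command_potential")),
                traces=np.asarray(get(
                    f"assay/{IVG}/measurement datum/membrane_current")),
                sample_rate=float(get(f"{ivstim}/sample_rate")),
                hold_time=float(get(f"{ivstim}/hold_time"))),
            aux=aux,
        )

        transformed = _read_transformed(f, get, TR, BoltzmannFitSet, IVSet,
                                        LinearSet, NonlinearSet,
                                        PerPotentialSet, TransformedData,
                                        DS)
        bundle.extras = _collect_extras(f, arch)
    return bundle, transformed


def _component_label(dset):
    descr = dset.attrs.get("description", "")
    if isinstance(descr, bytes):
        descr = descr.decode("utf-8")
    if descr.startswith("Molarity of ") and descr.endswith(
            " in the solution."):
        return descr[len("Molarity of "):-len(" in the solution.")]
    return dset.name.rsplit("/", 1)[-1]


def _read_transformed(f, get, TR, BoltzmannFitSet, IVSet, LinearSet,
                      NonlinearSet, PerPotentialSet, TransformedData, DS):
    have_lin = f"{TR}/linear data set/linear_capacitance" in f
    have_non = f"{TR}/non-linear data set/peak_NLC" in f
    have_bol = f"{TR}/boltzmann fit/Q_max" in f
    have_iv = f"{TR}/IV data set/R_b" in f
    if not any((have_lin, have_non, have_bol, have_iv)):
        return None
    linear = nonlinear = boltzmann = iv = per_potential = None
    if have_lin:
        lin = f"{TR}/linear data set"
        linear = LinearSet(
            Clin=float(get(f"{lin}/linear_capacitance")),
            Rm=float(get(f"{lin}/membrane_resistance")),
            Rs=float(get(f"{lin}/series_resistance")),
            Vm=np.asarray(get(f"{lin}/membrane_voltage")))
    if have_non:
        non = f"{TR}/non-linear data set"
        nonlinear = NonlinearSet(
            nlc=np.asarray(get(f"{non}/non_linear_capacitance")),
            peak_nlc=float(get(f"{non}/peak_NLC")),
            charge=np.asarray(get(f"{non}/displacement_charge")),
            max_charge=float(get(f"{non}/maximum_displacement_charge")),
            alpha=float(get(f"{non}/voltage_sensitivity")),
            Vpk=float(get(f"{non}/potential_of_maximum_sensitivity")))
    if have_bol:
        from .biophysics import BoltzmannParams
        bol = f"{TR}/boltzmann fit"
        vpk_cmd = get(f"{bol}/V_pk_command")
        boltzmann = BoltzmannFitSet(
            params=BoltzmannParams(
                Qmax=float(get(f"{bol}/Q_max")),
                Vpk=float(get(f"{bol}/V_pk")),
                alpha=float(get(f"{bol}/alpha"))),
            Clin=float(get(f"{bol}/linear_capacitance")),
            residual_norm=float(get(f"{bol}/residual_norm", np.nan)),
            Vpk_command=None if vpk_cmd is None else float(vpk_cmd))
    if have_iv:
        ivt = f"{TR}/IV data set"
        imat = np.asarray(get(f"{ivt}/I_mean"))
        iv = IVSet(I_mean=imat[0], I_sd=imat[1],
                   Rb=float(get(f"{ivt}/R_b")),
                   Vm=np.asarray(get(f"{ivt}/membrane_potential")))
    pred = f"assay/{DS}/predicted data item"
    if f"{pred}/membrane_capacitance_f1" in f:
        per_potential = PerPotentialSet(
            Cm_f1=np.asarray(get(f"{pred}/membrane_capacitance_f1")),
            Cm_f2=np.asarray(get(f"{pred}/membrane_capacitance_f2")),
            Rm=np.asarray(get(f"{pred}/membrane_resistance")),
            Rs=np.asarray(get(f"{pred}/series_resistance")),
            reported=get(f"{pred}/reported_capacitance_estimate"))
    return TransformedData(linear=linear, nonlinear=nonlinear,
                           boltzmann=boltzmann, iv=iv,
                           per_potential=per_potential)


def _collect_extras(f, arch) -> dict:
    extras = {}

    def visit(path, obj):
        if path not in arch.nodes and isinstance(obj, h5py.Dataset):
            val = obj[()]
            if isinstance(val, bytes):
                val = val.decode("utf-8")
            extras[path] = val

    f.visititems(visit)
    # solution components are architecture-sanctioned dynamic nodes
    for key in list(extras):
        if "/concentration/" in key:
            del extras[key]
    return extras


# ---------------------------------------------------------------------------
# inspection
# ---------------------------------------------------------------------------

def describe_tree(source) -> str:
    """Deterministic indented listing of a file's groups and datasets."""
    lines = []
    with h5py.File(source, "r") as f:
        for attr in sorted(f.attrs):
            lines.append(f"@{attr} = {f.attrs[attr]!r}")

        def visit(group, depth):
            for name in sorted(group):
                obj = group[name]
                pad = "  " * depth
                descr = obj.attrs.get("description", "")
                if isinstance(descr, bytes):
                    descr = descr.decode("utf-8")
                first = descr.split("\n")[0] if descr else ""
                if isinstance(obj, h5py.Group):
                    lines.append(f"{pad}{name}/  -- {first}")
                    visit(obj, depth + 1)
                else:
                    units = obj.attrs.get("units", "")
                    if isinstance(units, bytes):
                        units = units.decode("utf-8")
                    shape = "scalar" if obj.shape == () else \
                        "x".join(map(str, obj.shape))
                    unit_txt = f" [{units}]" if units else ""
                    lines.append(f"{pad}{name}  ({shape}){unit_txt}"
                                 f"  -- {first}")

        visit(f, 0)
    return "\n".join(lines) + "\n"


def tree_paths(source) -> list[str]:
    """All group/dataset paths in a file (sorted)."""
    paths = []
    with h5py.File(source, "r") as f:
        f.visit(paths.append)
    return sorted(paths)
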