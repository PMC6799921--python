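"""Compile the term registry into the concrete HDF5 file architecture.

The six ontology arms become the six first-level HDF5 groups (with the
conventional shortening *anatomical entity* -> ``anatomical``); adjacent
sub-classes become sub-groups; values live exclusively in datasets, each
carrying ``description`` and (when physically dimensioned) ``units``
attributes.  Naming conventions: group and sub-group names are lower-case
words or phrases (well-known abbreviations such as DC, NLC or IV keep
their capitals); dataset names are contiguous words joined by
underscores.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict

from .errors import SchemaCompileError
from .ontology import TermRegistry, ROOT_LABELS
from .units import UNITS_TABLE

PROTOCOLS = ("dual_sine", "iv")
DUAL_SINE_GROUP = "electrical admittance dual-sine stimulus"
IV_GROUP = "membrane current I as a function of membrane potential V"
TRANSFORMED_GROUP = "transformed data set"
TRANSFORMED_SUBGROUPS = (
    "linear data set", "non-linear data set", "boltzmann fit", "IV data set",
)

ROOT_ATTRIBUTES = (
    "experiment_date", "cell_number", "researcher", "responsible_person",
    "data_curator", "funding_source",
)

#: printed labels whose conventional group name differs from the plain rule
GROUP_ALIASES = {"anatomical entity": "anatomical"}

# canonical capitalisation kept through normalisation
_ABBREVIATIONS = ("DC", "NLC", "IV", "I", "V", "Q", "R", "pH")
_ABBREV_MAP = {a.upper(): a for a in _ABBREVIATIONS}

_PUNCT_RE = re.compile(r"[^\w\s-]")
_DATASET_OK_RE = re.compile(r"^[A-Za-z0-9_]+$")


def _norm_token(token: str) -> str:
    return _ABBREV_MAP.get(token.upper(), token.lower())


def _strip_punct(label: str) -> str:
    # drop punctuation except internal hyphens; collapse whitespace
    text = _PUNCT_RE.sub(" ", label)
    words = []
    for w in text.split():
        w = w.strip("-")
        w = re.sub(r"-{2,}", "-", w)
        if w:
            words.append(w)
    return " ".join(words)


def normalize_group_name(label: str) -> str:
    """Lower-case phrase form of a printed label (abbreviations kept)."""
    if not label or not label.strip():
        raise ValueError("empty group label")
    cleaned = _strip_punct(label)
    if not cleaned:
        raise ValueError(f"label reduces to nothing: {label!r}")
    return " ".join(_norm_token(w) for w in cleaned.split())


def canonical_group_name(label: str) -> str:
    """normalize_group_name plus the explicit alias table
    (e.g. "anatomical entity" -> "anatomical")."""
    name = normalize_group_name(label)
    return GROUP_ALIASES.get(name, name)


def normalize_dataset_name(label: str) -> str:
    """Underscore-joined lower-case form of a printed label."""
    if not label or not label.strip():
        raise ValueError("empty dataset label")
    cleaned = _strip_punct(label).replace("-", " ")
    tokens = [t for part in cleaned.split() for t in part.split("_") if t]
    if not tokens:
        raise ValueError(f"label reduces to nothing: {label!r}")
    name = "_".join(_norm_token(t) for t in tokens)
    assert _DATASET_OK_RE.match(name), name
    return name


def is_valid_group_name(name: str) -> bool:
    try:
        return normalize_group_name(name) == name
    except ValueError:
        return False


def is_valid_dataset_name(name: str) -> bool:
    if not _DATASET_OK_RE.match(name or ""):
        return False
    try:
        return normalize_dataset_name(name) == name
    except ValueError:
        return False


@dataclass(frozen=True)
class SchemaNode:
    """One required-or-optional location in the file architecture."""

    path: str
    kind: str                       # "group" | "dataset"
    term_id: str = ""               # registry reference, may be empty
    required: bool = True
    units: str = ""                 # long-form unit, empty for text/groups
    description: str = ""
    value_role: str = ""            # scalar | vector | matrix | text
    protocols: frozenset = frozenset(PROTOCOLS)

    @property
    def name(self) -> str:
        return self.path.rsplit("/", 1)[-1]


@dataclass
class Architecture:
    """The compiled tree of schema nodes plus file-level conventions."""

    nodes: dict[str, SchemaNode]
    root_attributes: tuple = ROOT_ATTRIBUTES
    protocol_groups: dict = field(
        default_factory=lambda: {"dual_sine": DUAL_SINE_GROUP,
                                 "iv": IV_GROUP})

    def __post_init__(self):
        roots = self.first_level_groups()
        if len(roots) != 6:
            raise SchemaCompileError(f"expected 6 first-level groups, "
                                     f"got {roots}")
        for path, node in self.nodes.items():
            parent = path.rsplit("/", 1)[0] if "/" in path else ""
            if parent and parent not in self.nodes:
                raise SchemaCompileError(f"orphan node {path!r}")
            if node.kind == "dataset" and not node.description:
                raise SchemaCompileError(f"dataset without description: "
                                         f"{path}")

    def first_level_groups(self) -> list[str]:
        return sorted({p.split("/", 1)[0] for p in self.nodes})

    def node(self, path: str) -> SchemaNode:
        return self.nodes[path]

    def children(self, path: str) -> list[SchemaNode]:
        prefix = path + "/"
        return [n for p, n in self.nodes.items()
                if p.startswith(prefix) and "/" not in p[len(prefix):]]

    def to_json(self) -> str:
        payload = {
            "root_attributes": list(self.root_attributes),
            "protocol_groups": dict(self.protocol_groups),
            "nodes": [
                {**asdict(n), "protocols": sorted(n.protocols)}
                for _, n in sorted(self.nodes.items())
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Architecture":
        payload = json.loads(text)
        nodes = {}
        for d in payload["nodes"]:
            d = dict(d)
            d["protocols"] = frozenset(d["protocols"])
            node = SchemaNode(**d)
            nodes[node.path] = node
        return cls(nodes=nodes,
                   root_attributes=tuple(payload["root_attributes"]),
                   protocol_groups=dict(payload["protocol_groups"]))


# ---------------------------------------------------------------------------
# declarative node table
# ---------------------------------------------------------------------------

DS = DUAL_SINE_GROUP
IVG = IV_GROUP
BOTH = frozenset(PROTOCOLS)
DSP = frozenset({"dual_sine"})
IVP = frozenset({"iv"})

#: filler acquisition-metadata fields: (name, value_role, units)
#: these carry generator provenance in the flat record and are optional
#: in the file architecture
ACQUISITION_FIELDS = (
    ("rig_identifier", "text", ""),
    ("amplifier_model", "text", ""),
    ("digitizer_model", "text", ""),
    ("acquisition_software", "text", ""),
    ("acquisition_software_version", "text", ""),
    ("analysis_software", "text", ""),
    ("analysis_software_version", "text", ""),
    ("protocol_file", "text", ""),
    ("calibration_file", "text", ""),
    ("calibration_date", "text", ""),
    ("bath_perfusion_rate", "text", ""),
    ("chamber_volume", "text", ""),
    ("animal_identifier", "text", ""),
    ("anesthesia_agent", "text", ""),
    ("dissociation_enzyme", "text", ""),
    ("notes", "text", ""),
    ("operator_initials", "text", ""),
    ("record_version", "text", ""),
    ("storage_location", "text", ""),
    ("backup_location", "text", ""),
    ("run_down_flag", "text", ""),
    ("amplifier_gain", "scalar", "dimensionless"),
    ("seal_resistance", "scalar", "megaohm"),
    ("pipette_resistance", "scalar", "megaohm"),
    ("pipette_capacitance_compensation", "scalar", "picofarad"),
    ("holding_potential", "scalar", "millivolt"),
    ("liquid_junction_potential", "scalar", "millivolt"),
    ("series_resistance_compensation", "scalar", "dimensionless"),
    ("stimulus_scaling", "scalar", "dimensionless"),
    ("admittance_sample_rate", "scalar", "hertz"),
    ("sine_cycles_averaged", "scalar", "dimensionless"),
    ("segment_length", "scalar", "second"),
    ("inter_step_interval", "scalar", "second"),
    ("enzyme_exposure_time", "scalar", "second"),
    ("cell_quality_score", "scalar", "dimensionless"),
)


def _node_table():
    """(path, kind, term label, required, units, role, protocols, descr)"""
    t = []

    def g(path, term="", req=True, prot=BOTH, descr=""):
        t.append((path, "group", term, req, "", "", prot, descr))

    def d(path, units, role, term="", req=True, prot=BOTH, descr=""):
        t.append((path, "dataset", term, req, units, role, prot, descr))

    # anatomical arm
    g("anatomical", "anatomical entity")
    g("anatomical/subdivision of bony labyrinth",
      "subdivision of bony labyrinth")
    g("anatomical/subdivision of bony labyrinth/subdivision of cochlea",
      "subdivision of cochlea")
    d("anatomical/subdivision of bony labyrinth/subdivision of cochlea/"
      "cochlear_turn", "", "text", "cochlear turn")
    d("anatomical/subdivision of bony labyrinth/subdivision of cochlea/"
      "cochlea", "", "text", "cochlea",
      descr="Which cochlea (left or right) the cell came from.")
    g("anatomical/position", "position")
    d("anatomical/position/apical_basal_polarity", "", "text", "apical",
      descr="Whether the cell originated in the apical or basal region "
            "of the cochlea.")
    d("anatomical/position/best_frequency", "hertz", "scalar", req=False,
      descr="The characteristic (best) frequency of the cochlear place "
            "of origin, from the tonotopic map.")

    # assay arm: dual-sine protocol
    g("assay", "assay")
    g(f"assay/{DS}", "electrical admittance dual-sine stimulus", prot=DSP)
    g(f"assay/{DS}/intracellular electrophysiology stimulus",
      "intracellular electrophysiology stimulus", prot=DSP)
    d(f"assay/{DS}/intracellular electrophysiology stimulus/sine_frequency",
      "hertz", "vector", "frequency", prot=DSP,
      descr="The two sine frequencies (f1, f2) superposed on the DC "
            "command potential.")
    d(f"assay/{DS}/intracellular electrophysiology stimulus/sine_amplitude",
      "millivolt", "vector", "amplitude", prot=DSP,
      descr="The amplitudes of the two stimulus sines.")
    d(f"assay/{DS}/intracellular electrophysiology stimulus/"
      "command_potential", "millivolt", "vector", "membrane potential",
      prot=DSP,
      descr="The DC command potentials stepped during the protocol.")
    d(f"assay/{DS}/intracellular electrophysiology stimulus/hold_time",
      "second", "scalar", "time", prot=DSP,
      descr="The duration each command potential is held.")
    g(f"assay/{DS}/measurement datum", "measurement datum", prot=DSP)
    for freq in ("f1", "f2"):
        for part, term in (("real", "real component of electrical "
                                    "admittance"),
                           ("imaginary", "imaginary component of electrical "
                                         "admittance")):
            d(f"assay/{DS}/measurement datum/"
              f"electrical_admittance_{part}_{freq}",
              "nanosiemens", "vector", term, prot=DSP,
              descr=f"The {part} component of the complex electrical "
                    f"admittance measured at {freq}, one value per "
                    f"command potential.")
    g(f"assay/{DS}/predicted data item", "predicted data item", prot=DSP)
    d(f"assay/{DS}/predicted data item/membrane_capacitance_f1",
      "picofarad", "vector", "membrane capacitance", req=False, prot=DSP)
    d(f"assay/{DS}/predicted data item/membrane_capacitance_f2",
      "picofarad", "vector", "membrane capacitance", req=False, prot=DSP)
    d(f"assay/{DS}/predicted data item/membrane_resistance",
      "megaohm", "vector", "membrane resistance", req=False, prot=DSP)
    d(f"assay/{DS}/predicted data item/series_resistance",
      "megaohm", "vector", "series resistance", req=False, prot=DSP)
    d(f"assay/{DS}/predicted data item/reported_capacitance_estimate",
      "", "text", req=False, prot=DSP,
      descr="Which of the two frequency estimates of the membrane "
            "capacitance is reported (selected by single-frequency "
            "reconstruction residual; stand-in selection rule).")
    g(f"assay/{DS}/study design control variable",
      "study design control variable", prot=DSP)
    d(f"assay/{DS}/study design control variable/temperature",
      "degree celsius", "scalar", "temperature", prot=DSP)
    d(f"assay/{DS}/study design control variable/pipette_pressure",
      "millimeter of mercury", "scalar", "pipette pressure", prot=DSP)
    for sol, term in (("extracellular solution", "extracellular solution"),
                      ("solution in the patch pipette",
                       "solution in the patch pipette")):
        g(f"assay/{DS}/{sol}", term, prot=DSP)
        g(f"assay/{DS}/{sol}/concentration", "concentration", prot=DSP)
        d(f"assay/{DS}/{sol}/pH", "dimensionless", "scalar", "acidity",
          prot=DSP)
        d(f"assay/{DS}/{sol}/osmolality", "milliosmole per kilogram",
          "scalar", "osmolality", prot=DSP)
    d(f"assay/{DS}/time_assay_started", "", "text", prot=DSP,
      descr="The wall-clock time at which the assay commenced.")
    d(f"assay/{DS}/time_interval_from_death", "second", "scalar", prot=DSP,
      descr="The interval between the death of the animal and the "
            "commencement of the assay.")

    # assay arm: voltage-step (IV) protocol
    g(f"assay/{IVG}",
      "membrane current I as a function of membrane potential V", prot=IVP)
    g(f"assay/{IVG}/intracellular electrophysiology stimulus",
      "intracellular electrophysiology stimulus", prot=IVP)
    d(f"assay/{IVG}/intracellular electrophysiology stimulus/"
      "command_potential", "millivolt", "vector", "membrane potential",
      prot=IVP,
      descr="The DC command potentials of the voltage-step protocol.")
    d(f"assay/{IVG}/intracellular electrophysiology stimulus/hold_time",
      "second", "scalar", "time", prot=IVP,
      descr="The duration of each voltage step.")
    d(f"assay/{IVG}/intracellular electrophysiology stimulus/sample_rate",
      "hertz", "scalar", prot=IVP,
      descr="The sampling rate of the current traces.")
    g(f"assay/{IVG}/measurement datum", "measurement datum", prot=IVP)
    d(f"assay/{IVG}/measurement datum/membrane_current",
      "nanoampere", "matrix", "charge flow rate", prot=IVP,
      descr="Membrane current traces, one row per voltage step.")

    # acquisition metadata (filler provenance fields, optional)
    g("assay/acquisition metadata", req=False,
      descr="Acquisition-environment metadata carried over from the flat "
            "per-cell record (generator provenance).")
    for name, role, units_ in ACQUISITION_FIELDS:
        d(f"assay/acquisition metadata/{name}", units_, role, req=False,
          descr=f"Acquisition metadata field '{name}' "
                f"(provenance: generator).")

    # cell arm
    g("cell", "cell")
    g("cell/outer hair cell", "outer hair cell")
    g("cell/outer hair cell/morphology", "morphology")
    g("cell/outer hair cell/morphology/measurement datum",
      "measurement datum")
    d("cell/outer hair cell/morphology/measurement datum/cell_diameter",
      "micrometer", "scalar", "cell diameter")
    d("cell/outer hair cell/morphology/measurement datum/"
      "cochlear_outer_hair_cell_length", "micrometer", "scalar",
      "cochlear outer hair cell length")
    d("cell/outer hair cell/morphology/measurement datum/"
      "cochlear_outer_hair_cell_lateral_wall_length", "micrometer",
      "scalar", "cochlear outer hair cell lateral wall length")
    g("cell/outer hair cell/morphology/predicted data item",
      "predicted data item")
    d("cell/outer hair cell/morphology/predicted data item/"
      "cell_surface_area", "micrometer x micrometer", "scalar",
      "cell surface area")

    # device arm
    g("device", "device")
    for dev, term in (("pipette pressure clamp", "pipette pressure clamp"),
                      ("patch pipette", "patch pipette"),
                      ("analog camera", "analog camera")):
        g(f"device/{dev}", term)
        d(f"device/{dev}/model", "", "text",
          descr=f"Model / identifying description of the {dev}.")

    # organism arm
    g("organism", "organism")
    d("organism/species", "", "text", "Cavia porcellus",
      descr="The species of the experimental animal.")
    d("organism/sex", "", "text", "sex")
    d("organism/age", "day", "scalar", "age")
    d("organism/weight", "gram", "scalar", "weight")
    d("organism/phenotype", "", "text", "phenotype")

    # transformed data set arm
    g(TRANSFORMED_GROUP, "transformed data set")
    lin = f"{TRANSFORMED_GROUP}/linear data set"
    g(lin, "linear data set", prot=DSP)
    d(f"{lin}/linear_capacitance", "picofarad", "scalar",
      "linear membrane capacitance", prot=DSP)
    d(f"{lin}/membrane_resistance", "megaohm", "scalar",
      "membrane resistance", prot=DSP,
      descr="The mean membrane resistance over the command potentials.")
    d(f"{lin}/series_resistance", "megaohm", "scalar", "series resistance",
      prot=DSP,
      descr="The mean series resistance over the command potentials.")
    d(f"{lin}/membrane_voltage", "millivolt", "vector",
      "voltage drop across the membrane", prot=DSP)
    non = f"{TRANSFORMED_GROUP}/non-linear data set"
    g(non, "non-linear data set", prot=DSP)
    d(f"{non}/non_linear_capacitance", "picofarad", "vector",
      "non-linear membrane capacitance", prot=DSP)
    d(f"{non}/peak_NLC", "picofarad", "scalar",
      "non-linear membrane capacitance", prot=DSP,
      descr="The peak value of the non-linear membrane capacitance.")
    d(f"{non}/displacement_charge", "picocoulomb", "vector",
      "displacement charge", prot=DSP)
    d(f"{non}/maximum_displacement_charge", "picocoulomb", "scalar",
      "displacement charge", prot=DSP,
      descr="The maximum (saturating) displacement charge.")
    d(f"{non}/voltage_sensitivity", "per millivolt", "scalar",
      "sensitivity of a process to voltage", prot=DSP)
    d(f"{non}/potential_of_maximum_sensitivity", "millivolt", "scalar",
      "potential of maximum sensitivity", prot=DSP)
    bol = f"{TRANSFORMED_GROUP}/boltzmann fit"
    g(bol, "2-state Boltzmann fit data set", prot=DSP)
    d(f"{bol}/Q_max", "picocoulomb", "scalar", "displacement charge",
      prot=DSP,
      descr="Maximum displacement charge from the 2-state Boltzmann fit.")
    d(f"{bol}/V_pk", "millivolt", "scalar",
      "potential of maximum sensitivity", prot=DSP,
      descr="Potential of maximum sensitivity from the fit, against the "
            "series-resistance-corrected membrane potential.")
    d(f"{bol}/V_pk_command", "millivolt", "scalar",
      "potential of maximum sensitivity", req=False, prot=DSP,
      descr="Potential of maximum sensitivity fitted against the raw "
            "command potential (no series-resistance correction).")
    d(f"{bol}/alpha", "per millivolt", "scalar",
      "sensitivity of a process to voltage", prot=DSP,
      descr="Voltage sensitivity (alpha) from the fit.")
    d(f"{bol}/linear_capacitance", "picofarad", "scalar",
      "linear membrane capacitance", prot=DSP,
      descr="Voltage-independent capacitance offset from the fit.")
    d(f"{bol}/residual_norm", "dimensionless", "scalar", req=False,
      prot=DSP, descr="Residual norm of the capacitance-form fit.")
    ivt = f"{TRANSFORMED_GROUP}/IV data set"
    g(ivt, "IV data set", prot=IVP)
    d(f"{ivt}/I_mean", "nanoampere", "matrix", "charge flow rate", prot=IVP,
      descr="Mean (row 0) and standard deviation (row 1) of the "
            "steady-state current at each voltage step.")
    d(f"{ivt}/R_b", "megaohm", "scalar", prot=IVP,
      descr="The reciprocal of the slope conductance of the steady-state "
            "current versus membrane potential.")
    d(f"{ivt}/membrane_potential", "millivolt", "vector",
      "membrane potential", prot=IVP,
      descr="The series-resistance-corrected membrane potential at each "
            "voltage step.")
    return t


def default_architecture(registry: TermRegistry) -> Architecture:
    """Compile the default file architecture against ``registry``.

    Descriptions default to the linked term's definition; ``units``
    strings must come from the shared long-form table.
    """
    by_label = {t.label: t for t in registry.terms.values()}
    for root_label in ROOT_LABELS:
        if root_label not in by_label:
            raise SchemaCompileError(f"registry missing arm root "
                                     f"{root_label!r}")
    nodes: dict[str, SchemaNode] = {}
    for path, kind, term_label, req, units_, role, prot, descr in \
            _node_table():
        term_id = ""
        if term_label:
            if term_label not in by_label:
                raise SchemaCompileError(f"schema references unknown term "
                                         f"{term_label!r}")
            term = by_label[term_label]
            term_id = term.id
            if not descr:
                descr = term.definition
        if kind == "dataset" and units_ and units_ not in UNITS_TABLE:
            raise SchemaCompileError(f"unit not in table: {units_!r}")
        name = path.rsplit("/", 1)[-1]
        if kind == "group" and not is_valid_group_name(name):
            raise SchemaCompileError(f"bad group name: {name!r}")
        if kind == "dataset" and not is_valid_dataset_name(name):
            raise SchemaCompileError(f"bad dataset name: {name!r}")
        nodes[path] = SchemaNode(
            path=path, kind=kind, term_id=term_id, required=req,
            units=units_, description=descr, value_role=role or
            ("text" if kind == "dataset" and not units_ else role),
            protocols=prot,
        )
    return Architecture(nodes=nodes)


def required_paths(arch: Architecture, protocol: str = "both") -> list[str]:
    """Sorted list of node paths required under the chosen protocol set."""
    if protocol == "both":
        selected = set(PROTOCOLS)
    elif protocol in PROTOCOLS:
        selected = {protocol}
    else:
        raise ValueError(f"unknown protocol: {protocol!r}")
    return sorted(p for p, n in arch.nodes.items()
                  if n.required and n.protocols & selected)
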