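"""Synthetic per-cell recordings with known ground truth.

Each generated cell is a complete ``RecordingBundle``: organism, anatomy
and morphology metadata, bath and pipette solutions, device identifiers,
provenance, the dual-sine admittance sweep and the voltage-step (I-V)
protocol — everything the file architecture requires — plus the ground
truth circuit and Boltzmann parameters the data were generated from.

The admittance is produced by the forward equivalent-circuit model: at
each command potential Vdc the membrane potential is the
series-resistance-divided Vm, the total capacitance is
Clin + Cnl(Vm) (+ additive capacitance noise), and Y(omega) is evaluated
at both sine frequencies with multiplicative complex noise.  The I-V
traces are single-exponential relaxations to the ohmic steady state with
additive current noise.  At zero noise every derived quantity is exactly
recoverable, which is what makes the generator the test oracle for the
rest of the package.

A flat 82-field key->value record (the shape of the original per-cell
acquisition records) is the interchange form; the field manifest is a
documented reconstruction, not a claim of fidelity to the original
variable names.  Filler acquisition-metadata fields are flagged
provenance="generator".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .biophysics import (BoltzmannParams, CircuitParams, StimulusSpec,
                         boltzmann_nlc, forward_admittance,
                         series_resistance_divider)
from .errors import SchemaError
from .schema import ACQUISITION_FIELDS

# guinea-pig tonotopic span, kHz
BEST_FREQUENCY_RANGE_KHZ = (0.060, 43.0)

#: cochlear turn -> (length range um, best-frequency range kHz)
DEFAULT_TONOTOPY = {
    "apical": ((65.0, 90.0), (0.060, 1.0)),
    "middle": ((40.0, 65.0), (1.0, 8.0)),
    "basal": ((20.0, 40.0), (8.0, 43.0)),
}

_SOLUTION_RECIPES = {
    # component label -> millimolar
    "bath": {
        "sodium chloride": 140.0,
        "potassium chloride": 5.0,
        "calcium dichloride": 2.0,
        "magnesium dichloride": 1.0,
        "HEPES": 10.0,
        "D-glucose": 5.0,
    },
    "pipette": {
        "caesium chloride": 140.0,
        "magnesium dichloride": 2.0,
        "HEPES": 10.0,
        "EGTA": 10.0,
    },
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Ranges are uniform draws in the stated display units; all values are
    converted to SI inside the bundle.
    """

    seed: int = 0
    n_cells: int = 1
    Rs_range_mohm: tuple = (5.0, 15.0)
    Rm_range_mohm: tuple = (100.0, 500.0)
    Clin_range_pf: tuple = (15.0, 35.0)
    Qmax_range_pc: tuple = (1.5, 3.5)
    Vpk_range_mv: tuple = (-60.0, -20.0)
    alpha_range_per_mv: tuple = (0.025, 0.035)
    diameter_range_um: tuple = (8.0, 10.0)
    admittance_noise_sd: float = 0.01      # multiplicative, per component
    capacitance_noise_sd: float = 0.2e-12  # farad, additive on Cm(V)
    current_noise_sd: float = 5e-12        # ampere, additive on traces
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    iv_potentials_mv: tuple = tuple(range(-100, 101, 20))
    iv_sample_rate: float = 5000.0
    iv_hold_time: float = 0.2
    tonotopy: dict = field(default_factory=lambda: dict(DEFAULT_TONOTOPY))

    def __post_init__(self):
        for rng in (self.Rs_range_mohm, self.Rm_range_mohm,
                    self.Clin_range_pf, self.Qmax_range_pc,
                    self.alpha_range_per_mv, self.diameter_range_um):
            if not (rng[0] > 0 and rng[1] >= rng[0]):
                raise ValueError(f"invalid positive range: {rng}")
        if self.Vpk_range_mv[1] < self.Vpk_range_mv[0]:
            raise ValueError("invalid Vpk range")
        lo, hi = BEST_FREQUENCY_RANGE_KHZ
        for turn, (_lr, bf) in self.tonotopy.items():
            if not (lo <= bf[0] <= bf[1] <= hi):
                raise ValueError(f"best-frequency range for {turn!r} "
                                 f"outside the guinea-pig span {lo}-{hi} kHz")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    circuit: CircuitParams
    boltzmann: BoltzmannParams


@dataclass
class Organism:
    species: str = "Cavia porcellus"
    sex: str = "female"
    age_days: float = 180.0
    weight_grams: float = 450.0
    phenotype: str = "pigmented"


@dataclass
class Anatomy:
    cochlea_side: str = "left"
    cochlear_turn: str = "middle"
    apical_basal_polarity: str = "apical"
    best_frequency_hz: float = 1000.0


@dataclass
class Morphology:
    length_m: float = 60e-6
    diameter_m: float = 9e-6
    lateral_wall_length_m: float = 55e-6


@dataclass
class Solution:
    components: dict = field(default_factory=dict)  # label -> molar
    pH: float = 7.3
    osmolality: float = 300.0                       # mOsm/kg


@dataclass
class Devices:
    pipette_pressure_clamp: str = "custom pressure clamp"
    patch_pipette: str = "borosilicate patch pipette"
    analog_camera: str = "analog tube camera"


@dataclass
class Provenance:
    experiment_date: str = "2016-01-01"
    cell_number: str = "C0001"
    researcher: str = "synthetic generator"
    responsible_person: str = "synthetic generator"
    data_curator: str = "synthetic generator"
    funding_source: str = "none (synthetic data)"


@dataclass
class Conditions:
    temperature_c: float = 22.0
    pipette_pressure_mmhg: float = 0.0
    time_assay_started: str = "12:00:00"
    time_interval_from_death_s: float = 3600.0


@dataclass
class AdmittanceRecord:
    """Complex admittance at both frequencies, one entry per Vdc (SI)."""

    Vdc: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray


@dataclass
class IVProtocol:
    Vc: np.ndarray            # command potentials, volt
    traces: np.ndarray        # steps x samples, ampere
    sample_rate: float
    hold_time: float


@dataclass
class RecordingBundle:
    """One cell's complete data set."""

    provenance: Provenance
    organism: Organism
    anatomy: Anatomy
    morphology: Morphology
    bath_solution: Solution
    pipette_solution: Solution
    devices: Devices
    conditions: Conditions
    stimulus: StimulusSpec
    admittance: AdmittanceRecord
    iv: IVProtocol
    aux: dict = field(default_factory=dict)  # acquisition-metadata fillers
    extras: dict = field(default_factory=dict)  # unknown nodes kept on read
    ground_truth: GroundTruth | None = None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _uniform(rng, lo_hi):
    return float(rng.uniform(lo_hi[0], lo_hi[1]))


def _default_aux(index: int) -> dict:
    vals = {
        "rig_identifier": "rig-1",
        "amplifier_model": "Axon 200B (emulated)",
        "digitizer_model": "PCI DAC (emulated)",
        "acquisition_software": "synthetic acquisition",
        "acquisition_software_version": "1.0",
        "analysis_software": "ieephys",
        "analysis_software_version": "0.1.0",
        "protocol_file": "dual_sine_default.prt",
        "calibration_file": "cal_default.cal",
        "calibration_date": "2016-01-01",
        "bath_perfusion_rate": "static bath",
        "chamber_volume": "0.5 ml",
        "animal_identifier": f"GP{index // 4 + 1:03d}",
        "anesthesia_agent": "none (synthetic)",
        "dissociation_enzyme": "none (mechanical)",
        "notes": "synthetic recording",
        "operator_initials": "SG",
        "record_version": "1",
        "storage_location": "generated",
        "backup_location": "generated",
        "run_down_flag": "no",
        "amplifier_gain": 1.0,
        "seal_resistance": 2000.0,        # megaohm
        "pipette_resistance": 3.5,        # megaohm
        "pipette_capacitance_compensation": 5.0,   # picofarad
        "holding_potential": -70.0,       # millivolt
        "liquid_junction_potential": 4.0,  # millivolt
        "series_resistance_compensation": 0.0,
        "stimulus_scaling": 1.0,
        "admittance_sample_rate": 10000.0,  # hertz
        "sine_cycles_averaged": 2.0,
        "segment_length": 0.0256,         # second
        "inter_step_interval": 0.05,      # second
        "enzyme_exposure_time": 0.0,      # second
        "cell_quality_score": 1.0,
    }
    assert set(vals) == {name for name, _r, _u in ACQUISITION_FIELDS}
    return vals


def generate_recording(config: GeneratorConfig,
                       index: int = 0) -> RecordingBundle:
    """Deterministically generate cell ``index`` of the cohort.

    The stream is seeded with ``config.seed + index`` so a cohort is a
    family of independent cells and the same (seed, index) pair always
    reproduces the same bundle byte for byte.
    """
    if index >= config.n_cells:
        raise ValueError("index out of range for this config")
    rng = np.random.default_rng(config.seed + index)

    circuit = CircuitParams(
        Rs=_uniform(rng, config.Rs_range_mohm) * 1e6,
        Rm=_uniform(rng, config.Rm_range_mohm) * 1e6,
        Clin=_uniform(rng, config.Clin_range_pf) * 1e-12,
    )
    boltz = BoltzmannParams(
        Qmax=_uniform(rng, config.Qmax_range_pc) * 1e-12,
        Vpk=_uniform(rng, config.Vpk_range_mv) * 1e-3,
        alpha=_uniform(rng, config.alpha_range_per_mv) * 1e3,
    )

    turn = str(rng.choice(sorted(config.tonotopy)))
    (l_lo, l_hi), (bf_lo, bf_hi) = config.tonotopy[turn]
    length_um = float(rng.uniform(l_lo, l_hi))
    # log-uniform draw respects the roughly exponential place-frequency map
    bf_khz = float(np.exp(rng.uniform(np.log(bf_lo), np.log(bf_hi))))
    diameter_um = _uniform(rng, config.diameter_range_um)
    anatomy = Anatomy(
        cochlea_side=str(rng.choice(["left", "right"])),
        cochlear_turn=turn,
        apical_basal_polarity="apical" if turn == "apical" else "basal",
        best_frequency_hz=bf_khz * 1e3,
    )
    morphology = Morphology(
        length_m=length_um * 1e-6,
        diameter_m=diameter_um * 1e-6,
        lateral_wall_length_m=0.92 * length_um * 1e-6,
    )
    organism = Organism(
        sex=str(rng.choice(["female", "male"])),
        age_days=float(rng.uniform(90, 365)),
        weight_grams=float(rng.uniform(350, 700)),
    )
    conditions = Conditions(
        temperature_c=float(rng.uniform(21.0, 24.0)),
        time_interval_from_death_s=float(rng.uniform(1800, 7200)),
    )
    provenance = Provenance(cell_number=f"C{index + 1:04d}")

    stim = config.stimulus
    Vdc = np.asarray(stim.Vdc, dtype=float)
    Vm = series_resistance_divider(Vdc, circuit.Rs, circuit.Rm)
    Cm = circuit.Clin + boltzmann_nlc(Vm, boltz)
    if config.capacitance_noise_sd > 0:
        Cm = Cm + rng.normal(0.0, config.capacitance_noise_sd, Vdc.shape)
    w1, w2 = 2 * np.pi * stim.f1, 2 * np.pi * stim.f2
    Y1 = np.array([forward_admittance(w1, circuit.Rs, circuit.Rm, c)
                   for c in Cm])
    Y2 = np.array([forward_admittance(w2, circuit.Rs, circuit.Rm, c)
                   for c in Cm])
    if config.admittance_noise_sd > 0:
        sd = config.admittance_noise_sd
        Y1 = Y1 * (1 + rng.normal(0, sd, Y1.shape)
                   + 1j * rng.normal(0, sd, Y1.shape))
        Y2 = Y2 * (1 + rng.normal(0, sd, Y2.shape)
                   + 1j * rng.normal(0, sd, Y2.shape))
    admittance = AdmittanceRecord(Vdc=Vdc, Y1=Y1, Y2=Y2)

    Vc = np.asarray(config.iv_potentials_mv, dtype=float) * 1e-3
    n = int(round(config.iv_sample_rate * config.iv_hold_time))
    t = np.arange(n) / config.iv_sample_rate
    tau = circuit.Clin * (circuit.Rs * circuit.Rm
                          / (circuit.Rs + circuit.Rm))
    I_ss = Vc / (circuit.Rs + circuit.Rm)
    I_pk = Vc / circuit.Rs
    traces = I_ss[:, None] + (I_pk - I_ss)[:, None] * np.exp(-t / tau)
    if config.current_noise_sd > 0:
        traces = traces + rng.normal(0, config.current_noise_sd,
                                     traces.shape)
    iv = IVProtocol(Vc=Vc, traces=traces,
                    sample_rate=config.iv_sample_rate,
                    hold_time=config.iv_hold_time)

    def solution(kind):
        return Solution(
            components={k: v * 1e-3
                        for k, v in _SOLUTION_RECIPES[kind].items()},
            pH=7.3 if kind == "bath" else 7.2,
            osmolality=300.0,
        )

    return RecordingBundle(
        provenance=provenance, organism=organism, anatomy=anatomy,
        morphology=morphology, bath_solution=solution("bath"),
        pipette_solution=solution("pipette"), devices=Devices(),
        conditions=conditions, stimulus=stim, admittance=admittance,
        iv=iv, aux=_default_aux(index),
        ground_truth=GroundTruth(circuit=circuit, boltzmann=boltz),
    )


def generate_cohort(config: GeneratorConfig) -> list[RecordingBundle]:
    """All ``n_cells`` bundles of the cohort."""
    return [generate_recording(config, i) for i in range(config.n_cells)]


def cohort_summary_rows(bundles) -> list[dict]:
    """Ground-truth summary table (one dict per cell, display units)."""
    rows = []
    for b in bundles:
        gt = b.ground_truth
        rows.append({
            "cell_number": b.provenance.cell_number,
            "Rs_mohm": gt.circuit.Rs / 1e6,
            "Rm_mohm": gt.circuit.Rm / 1e6,
            "Clin_pf": gt.circuit.Clin / 1e-12,
            "Qmax_pc": gt.boltzmann.Qmax / 1e-12,
            "Vpk_mv": gt.boltzmann.Vpk / 1e-3,
            "alpha_per_mv": gt.boltzmann.alpha / 1e3,
            "cochlear_turn": b.anatomy.cochlear_turn,
            "length_um": b.morphology.length_m / 1e-6,
        })
    return rows


def write_cohort_summary(bundles, path):
    """Write the ground-truth summary CSV alongside a generated cohort."""
    import csv
    rows = cohort_summary_rows(bundles)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# flat 82-field record
# ---------------------------------------------------------------------------

_SCIENCE_FIELDS = (
    # provenance
    "experiment_date", "cell_number", "researcher", "responsible_person",
    "data_curator", "funding_source",
    # organism
    "species", "sex", "age", "weight", "phenotype",
    # anatomy
    "cochlea", "cochlear_turn", "apical_basal_polarity", "best_frequency",
    # morphology
    "cell_diameter", "cochlear_outer_hair_cell_length",
    "cochlear_outer_hair_cell_lateral_wall_length",
    # dual-sine stimulus
    "sine_frequency_1", "sine_frequency_2", "sine_amplitude_1",
    "sine_amplitude_2", "command_potential", "hold_time",
    # admittance (both frequencies, real/imaginary)
    "electrical_admittance_real_f1", "electrical_admittance_imaginary_f1",
    "electrical_admittance_real_f2", "electrical_admittance_imaginary_f2",
    # voltage-step protocol
    "iv_command_potential", "iv_membrane_current", "iv_hold_time",
    "iv_sample_rate",
    # controlled conditions
    "temperature", "pipette_pressure", "time_assay_started",
    "time_interval_from_death",
    # solutions
    "extracellular_components", "extracellular_concentrations",
    "extracellular_pH", "extracellular_osmolality",
    "pipette_components", "pipette_concentrations", "pipette_pH",
    "pipette_osmolality",
    # devices
    "pipette_pressure_clamp_model", "patch_pipette_model",
    "analog_camera_model",
)

#: the pinned flat-record manifest: exactly 82 field names
FLAT_FIELD_MANIFEST = _SCIENCE_FIELDS + tuple(
    name for name, _r, _u in ACQUISITION_FIELDS)

#: fields whose values exist only to match the original record size
GENERATOR_PROVENANCE_FIELDS = frozenset(
    name for name, _r, _u in ACQUISITION_FIELDS)

assert len(FLAT_FIELD_MANIFEST) == 82, len(FLAT_FIELD_MANIFEST)
assert len(set(FLAT_FIELD_MANIFEST)) == 82


def to_flat_record(bundle: RecordingBundle) -> dict:
    """Flatten a bundle to the pinned 82-field manifest (display units,
    JSON-serialisable values, arrays as lists)."""
    b = bundle
    bath_keys = sorted(b.bath_solution.components)
    pip_keys = sorted(b.pipette_solution.components)
    rec = {
        "experiment_date": b.provenance.experiment_date,
        "cell_number": b.provenance.cell_number,
        "researcher": b.provenance.researcher,
        "responsible_person": b.provenance.responsible_person,
        "data_curator": b.provenance.data_curator,
        "funding_source": b.provenance.funding_source,
        "species": b.organism.species,
        "sex": b.organism.sex,
        "age": b.organism.age_days,
        "weight": b.organism.weight_grams,
        "phenotype": b.organism.phenotype,
        "cochlea": b.anatomy.cochlea_side,
        "cochlear_turn": b.anatomy.cochlear_turn,
        "apical_basal_polarity": b.anatomy.apical_basal_polarity,
        "best_frequency": b.anatomy.best_frequency_hz,
        "cell_diameter": b.morphology.diameter_m / 1e-6,
        "cochlear_outer_hair_cell_length": b.morphology.length_m / 1e-6,
        "cochlear_outer_hair_cell_lateral_wall_length":
            b.morphology.lateral_wall_length_m / 1e-6,
        "sine_frequency_1": b.stimulus.f1,
        "sine_frequency_2": b.stimulus.f2,
        "sine_amplitude_1": b.stimulus.a1 / 1e-3,
        "sine_amplitude_2": b.stimulus.a2 / 1e-3,
        "command_potential": [v / 1e-3 for v in b.admittance.Vdc],
        "hold_time": b.stimulus.hold_time,
        "electrical_admittance_real_f1":
            [y / 1e-9 for y in b.admittance.Y1.real],
        "electrical_admittance_imaginary_f1":
            [y / 1e-9 for y in b.admittance.Y1.imag],
        "electrical_admittance_real_f2":
            [y / 1e-9 for y in b.admittance.Y2.real],
        "electrical_admittance_imaginary_f2":
            [y / 1e-9 for y in b.admittance.Y2.imag],
        "iv_command_potential": [v / 1e-3 for v in b.iv.Vc],
        "iv_membrane_current":
            [[i / 1e-9 for i in row] for row in b.iv.traces],
        "iv_hold_time": b.iv.hold_time,
        "iv_sample_rate": b.iv.sample_rate,
        "temperature": b.conditions.temperature_c,
        "pipette_pressure": b.conditions.pipette_pressure_mmhg,
        "time_assay_started": b.conditions.time_assay_started,
        "time_interval_from_death":
            b.conditions.time_interval_from_death_s,
        "extracellular_components": bath_keys,
        "extracellular_concentrations":
            [b.bath_solution.components[k] / 1e-3 for k in bath_keys],
        "extracellular_pH": b.bath_solution.pH,
        "extracellular_osmolality": b.bath_solution.osmolality,
        "pipette_components": pip_keys,
        "pipette_concentrations":
            [b.pipette_solution.components[k] / 1e-3 for k in pip_keys],
        "pipette_pH": b.pipette_solution.pH,
        "pipette_osmolality": b.pipette_solution.osmolality,
        "pipette_pressure_clamp_model": b.devices.pipette_pressure_clamp,
        "patch_pipette_model": b.devices.patch_pipette,
        "analog_camera_model": b.devices.analog_camera,
    }
    for name, _role, _units in ACQUISITION_FIELDS:
        if name not in b.aux:
            raise SchemaError(f"bundle missing required field: {name}",
                              paths=[name])
        rec[name] = b.aux[name]
    missing = [f for f in FLAT_FIELD_MANIFEST if f not in rec]
    if missing:
        raise SchemaError(f"bundle missing required field(s): "
                          f"{', '.join(missing)}", paths=missing)
    return {name: rec[name] for name in FLAT_FIELD_MANIFEST}


def from_flat_record(rec: dict) -> RecordingBundle:
    """Rebuild a bundle from a flat record (inverse of
    :func:`to_flat_record`; ground truth is not part of the manifest)."""
    missing = [f for f in FLAT_FIELD_MANIFEST if f not in rec]
    if missing:
        raise SchemaError(f"flat record missing required field(s): "
                          f"{', '.join(missing)}", paths=missing)
    stim = StimulusSpec(
        f1=float(rec["sine_frequency_1"]),
        f2=float(rec["sine_frequency_2"]),
        a1=float(rec["sine_amplitude_1"]) * 1e-3,
        a2=float(rec["sine_amplitude_2"]) * 1e-3,
        Vdc=tuple(np.asarray(rec["command_potential"], dtype=float) * 1e-3),
        hold_time=float(rec["hold_time"]),
    )
    Vdc = np.asarray(stim.Vdc, dtype=float)
    Y1 = (np.asarray(rec["electrical_admittance_real_f1"], dtype=float)
          + 1j * np.asarray(rec["electrical_admittance_imaginary_f1"],
                            dtype=float)) * 1e-9
    Y2 = (np.asarray(rec["electrical_admittance_real_f2"], dtype=float)
          + 1j * np.asarray(rec["electrical_admittance_imaginary_f2"],
                            dtype=float)) * 1e-9
    bundle = RecordingBundle(
        provenance=Provenance(
            experiment_date=rec["experiment_date"],
            cell_number=rec["cell_number"],
            researcher=rec["researcher"],
            responsible_person=rec["responsible_person"],
            data_curator=rec["data_curator"],
            funding_source=rec["funding_source"],
        ),
        organism=Organism(
            species=rec["species"], sex=rec["sex"],
            age_days=float(rec["age"]),
            weight_grams=float(rec["weight"]),
            phenotype=rec["phenotype"],
        ),
        anatomy=Anatomy(
            cochlea_side=rec["cochlea"],
            cochlear_turn=rec["cochlear_turn"],
            apical_basal_polarity=rec["apical_basal_polarity"],
            best_frequency_hz=float(rec["best_frequency"]),
        ),
        morphology=Morphology(
            length_m=float(rec["cochlear_outer_hair_cell_length"]) * 1e-6,
            diameter_m=float(rec["cell_diameter"]) * 1e-6,
            lateral_wall_length_m=float(
                rec["cochlear_outer_hair_cell_lateral_wall_length"]) * 1e-6,
        ),
        bath_solution=Solution(
            components={k: float(c) * 1e-3 for k, c in
                        zip(rec["extracellular_components"],
                            rec["extracellular_concentrations"])},
            pH=float(rec["extracellular_pH"]),
            osmolality=float(rec["extracellular_osmolality"]),
        ),
        pipette_solution=Solution(
            components={k: float(c) * 1e-3 for k, c in
                        zip(rec["pipette_components"],
                            rec["pipette_concentrations"])},
            pH=float(rec["pipette_pH"]),
            osmolality=float(rec["pipette_osmolality"]),
        ),
        devices=Devices(
            pipette_pressure_clamp=rec["pipette_pressure_clamp_model"],
            patch_pipette=rec["patch_pipette_model"],
            analog_camera=rec["analog_camera_model"],
        ),
        conditions=Conditions(
            temperature_c=float(rec["temperature"]),
            pipette_pressure_mmhg=float(rec["pipette_pressure"]),
            time_assay_started=rec["time_assay_started"],
            time_interval_from_death_s=float(
                rec["time_interval_from_death"]),
        ),
        stimulus=stim,
        admittance=AdmittanceRecord(Vdc=Vdc, Y1=Y1, Y2=Y2),
        iv=IVProtocol(
            Vc=np.asarray(rec["iv_command_potential"], dtype=float) * 1e-3,
            traces=np.asarray(rec["iv_membrane_current"],
                              dtype=float) * 1e-9,
            sample_rate=float(rec["iv_sample_rate"]),
            hold_time=float(rec["iv_hold_time"]),
        ),
        aux={name: rec[name] for name in GENERATOR_PROVENANCE_FIELDS},
    )
    return bundle


def save_flat_record(bundle: RecordingBundle, path):
    """Write the flat record as pretty-printed UTF-8 JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(to_flat_record(bundle), fh, indent=1)
        fh.write("\n")


def load_flat_record(path) -> RecordingBundle:
    with open(path, encoding="utf-8") as fh:
        return from_flat_record(json.load(fh))


def bundles_equal(a: RecordingBundle, b: RecordingBundle,
                  rtol=0.0, atol=0.0) -> bool:
    """Field-wise equality of two bundles, ignoring ground truth."""
    a = replace(a, ground_truth=None)
    b = replace(b, ground_truth=None)

    def eq(x, y):
        if isinstance(x, (tuple, list)) and x and \
                isinstance(x[0], (int, float, np.floating)):
            x = np.asarray(x, dtype=float)
        if isinstance(y, (tuple, list)) and y and \
                isinstance(y[0], (int, float, np.floating)):
            y = np.asarray(y, dtype=float)
        if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
            x, y = np.asarray(x), np.asarray(y)
            if x.shape != y.shape:
                return False
            if rtol == 0 and atol == 0:
                return bool(np.array_equal(x, y))
            return bool(np.allclose(x, y, rtol=rtol, atol=atol))
        if isinstance(x, dict) and isinstance(y, dict):
            return set(x) == set(y) and all(eq(x[k], y[k]) for k in x)
        if isinstance(x, float) and isinstance(y, float) and rtol:
            return bool(np.isclose(x, y, rtol=rtol, atol=atol))
        return x == y

    da, db = asdict(a), asdict(b)
    return set(da) == set(db) and all(eq(da[k], db[k]) for k in da)
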