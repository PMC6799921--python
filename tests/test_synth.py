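"""Synthetic recordings: determinism, forward-model fidelity, flat records."""

import numpy as np
import pytest

from ieephys.biophysics import solve_two_sine
from ieephys.errors import SchemaError
from ieephys.synth import (FLAT_FIELD_MANIFEST, GENERATOR_PROVENANCE_FIELDS,
                           GeneratorConfig, bundles_equal, from_flat_record,
                           generate_cohort, generate_recording,
                           cohort_summary_rows, to_flat_record)

BF_SPAN_HZ = (60.0, 43000.0)


class TestGeneration:
    def test_deterministic_given_seed_and_index(self, noisy_config):
        a = generate_recording(noisy_config, 0)
        b = generate_recording(noisy_config, 0)
        assert bundles_equal(a, b)
        assert np.array_equal(a.admittance.Y1, b.admittance.Y1)
        assert np.array_equal(a.iv.traces, b.iv.traces)

    def test_seed_changes_draws(self):
        a = generate_recording(GeneratorConfig(seed=1), 0)
        b = generate_recording(GeneratorConfig(seed=2), 0)
        assert not np.array_equal(a.admittance.Y1, b.admittance.Y1)
        assert a.ground_truth.circuit != b.ground_truth.circuit

    def test_noise_free_admittance_obeys_forward_model(self, clean_bundle):
        """At zero noise the two-sine inversion returns the generating
        circuit to closed-form accuracy at every potential."""
        b = clean_bundle
        gt = b.ground_truth.circuit
        w1 = 2 * np.pi * b.stimulus.f1
        w2 = 2 * np.pi * b.stimulus.f2
        for k in (0, 10, 25, 50):
            sol = solve_two_sine(b.admittance.Y1[k], b.admittance.Y2[k],
                                 w1, w2)
            assert sol.Rs_hat == pytest.approx(gt.Rs, rel=1e-8)
            assert sol.Rm_hat == pytest.approx(gt.Rm, rel=1e-8)
            assert sol.Cm_f1 == pytest.approx(sol.Cm_f2, rel=1e-8)

    def test_turn_constrains_length(self):
        cfg = GeneratorConfig(seed=9, n_cells=40)
        for i, b in enumerate(generate_cohort(cfg)):
            lo, hi = cfg.tonotopy[b.anatomy.cochlear_turn][0]
            assert lo <= b.morphology.length_m / 1e-6 <= hi

    def test_best_frequency_within_guinea_pig_span(self):
        cfg = GeneratorConfig(seed=13, n_cells=60)
        bfs = [b.anatomy.best_frequency_hz for b in generate_cohort(cfg)]
        assert min(bfs) >= BF_SPAN_HZ[0]
        assert max(bfs) <= BF_SPAN_HZ[1]

    def test_apical_cells_longer_than_basal_on_average(self):
        cfg = GeneratorConfig(seed=17, n_cells=60)
        cohort = generate_cohort(cfg)
        apical = [b.morphology.length_m for b in cohort
                  if b.anatomy.cochlear_turn == "apical"]
        basal = [b.morphology.length_m for b in cohort
                 if b.anatomy.cochlear_turn == "basal"]
        assert apical and basal
        assert np.mean(apical) > np.mean(basal)

    def test_cohort_distinct_cell_numbers(self):
        cohort = generate_cohort(GeneratorConfig(seed=1, n_cells=5))
        numbers = [b.provenance.cell_number for b in cohort]
        assert len(set(numbers)) == 5

    def test_cohort_summary_carries_ground_truth(self):
        cohort = generate_cohort(GeneratorConfig(seed=1, n_cells=3))
        rows = cohort_summary_rows(cohort)
        assert len(rows) == 3
        assert rows[0]["Rs_mohm"] == pytest.approx(
            cohort[0].ground_truth.circuit.Rs / 1e6)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            generate_recording(GeneratorConfig(seed=1, n_cells=1), 1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=1, n_cells=0)
        with pytest.raises(ValueError):
            GeneratorConfig(Rs_range_mohm=(-5.0, 15.0))
        with pytest.raises(ValueError):
            GeneratorConfig(tonotopy={"basal": ((20, 40), (8.0, 99.0))})


class TestFlatRecord:
    def test_exactly_82_fields(self, bundle):
        rec = to_flat_record(bundle)
        assert len(rec) == 82
        assert list(rec) == list(FLAT_FIELD_MANIFEST)

    def test_round_trip_is_identity(self, bundle):
        rec = to_flat_record(bundle)
        rec2 = to_flat_record(from_flat_record(rec))
        assert rec2 == rec

    def test_bundle_round_trip_field_wise(self, bundle):
        back = from_flat_record(to_flat_record(bundle))
        assert bundles_equal(bundle, back, rtol=1e-12)

    def test_missing_required_field_named_in_error(self, bundle):
        rec = to_flat_record(bundle)
        del rec["cell_diameter"]
        with pytest.raises(SchemaError) as err:
            from_flat_record(rec)
        assert "cell_diameter" in str(err.value)

    def test_values_json_serialisable(self, bundle):
        import json
        text = json.dumps(to_flat_record(bundle))
        assert json.loads(text)["cell_number"] == \
            bundle.provenance.cell_number

    def test_filler_fields_flagged_as_generator_provenance(self):
        assert len(GENERATOR_PROVENANCE_FIELDS) == 35
        assert GENERATOR_PROVENANCE_FIELDS < set(FLAT_FIELD_MANIFEST)
        science = set(FLAT_FIELD_MANIFEST) - GENERATOR_PROVENANCE_FIELDS
        assert "cell_diameter" in science
        assert "notes" in GENERATOR_PROVENANCE_FIELDS
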