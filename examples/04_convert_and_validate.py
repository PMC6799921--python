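"""Full round trip: recording -> transformed data -> HDF5 -> validation.

Writes one cell in the six-group layout (assay, device, cell,
anatomical, organism, transformed data set), validates it against the
compiled architecture, and reads it back losslessly.
"""

from pathlib import Path

from ieephys import (GeneratorConfig, build_default_registry,
                     default_architecture, default_filename,
                     describe_tree, generate_recording, read_recording,
                     run_pipeline, validate_file, write_recording)
from ieephys.synth import bundles_equal

arch = default_architecture(build_default_registry())
bundle = generate_recording(GeneratorConfig(seed=11, n_cells=1), 0)
td = run_pipeline(bundle)

path = Path("scratch_cohort")
path.mkdir(exist_ok=True)
h5 = path / default_filename(bundle)
write_recording(bundle, td, arch, h5)
print(f"wrote {h5}")

report = validate_file(h5, arch)
print(f"validator: {'PASS' if report.valid else 'FAIL'} "
      f"({len(report.violations)} violations)")

back, td_back = read_recording(h5, arch)
print(f"lossless read-back: {bundles_equal(bundle, back, rtol=1e-14)}")

gt = bundle.ground_truth
print(f"\nstored transformed values vs generating truth:")
print(f"  Rs   {td.linear.Rs / 1e6:8.2f} MΩ   (truth "
      f"{gt.circuit.Rs / 1e6:.2f})")
print(f"  Rm   {td.linear.Rm / 1e6:8.1f} MΩ   (truth "
      f"{gt.circuit.Rm / 1e6:.1f})")
print(f"  Clin {td.linear.Clin / 1e-12:8.2f} pF   (truth "
      f"{gt.circuit.Clin / 1e-12:.2f})")
print(f"  Vpk  {td.boltzmann.params.Vpk * 1e3:8.2f} mV   (truth "
      f"{gt.boltzmann.Vpk * 1e3:.2f})")

print("\nfirst lines of the file tree:")
for line in describe_tree(h5).splitlines()[:12]:
    print(" ", line)
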