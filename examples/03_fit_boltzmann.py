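"""Fit the two forms of the 2-state Boltzmann relation to noisy data.

The voltage-dependent membrane capacitance of an outer hair cell is
bell-shaped: Cnl(V) = dQ/dV with Q(V) = Qmax / (1 + exp(-alpha (V -
Vpk))).  The capacitance form is fitted to Cm(V); the charge form to the
integrated displacement charge; both must land on the same parameters.
"""

import numpy as np

from ieephys import (BoltzmannParams, boltzmann_charge, boltzmann_nlc,
                     fit_capacitance_boltzmann, fit_charge_boltzmann,
                     peak_nlc)

truth = BoltzmannParams(Qmax=2.5e-12, Vpk=-40e-3, alpha=30.0)
Clin = 18e-12
V = np.arange(-150, 101, 5) * 1e-3

rng = np.random.default_rng(7)
Cm = Clin + boltzmann_nlc(V, truth) + rng.normal(0, 0.2e-12, V.shape)
Q = boltzmann_charge(V, truth)

pc, clin_hat, diag = fit_capacitance_boltzmann(V, Cm)
pq, offset, _ = fit_charge_boltzmann(V, Q)

print("capacitance-form fit (0.2 pF noise):")
print(f"  Qmax = {pc.Qmax / 1e-12:.3f} pC   (truth 2.500)")
print(f"  Vpk  = {pc.Vpk * 1e3:.2f} mV    (truth -40.00)")
print(f"  alpha = {pc.alpha / 1e3:.4f} /mV (truth 0.0300)")
print(f"  Clin = {clin_hat / 1e-12:.2f} pF   (truth 18.00)")
print(f"  peak NLC = {peak_nlc(pc) / 1e-12:.2f} pF "
      f"(= Qmax*alpha/4; truth {peak_nlc(truth) / 1e-12:.2f})")
print("\ncharge-form fit (noise-free):")
print(f"  Qmax = {pq.Qmax / 1e-12:.3f} pC, Vpk = {pq.Vpk * 1e3:.2f} mV, "
      f"alpha = {pq.alpha / 1e3:.4f} /mV")
print(f"\n|Vpk difference between forms| = "
      f"{abs(pc.Vpk - pq.Vpk) * 1e3:.3f} mV")
print("\nThe two forms are the same physics; a large disagreement would "
      "flag a bad fit.")
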