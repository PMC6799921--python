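# Methods

## Scope and data model

`ieephys` implements a per-cell data architecture for whole-cell
voltage-clamp recordings of cochlear outer hair cells, together with the
computations whose outputs the architecture stores.  One cell is one
HDF5 file with six first-level groups mirroring the six arms of the
OBI_IEE application-profile ontology: `assay`, `device`, `cell`,
`anatomical` (shortened from *anatomical entity*), `organism` and
`transformed data set`.  Values live exclusively in plain datasets —
never compound datatypes, because HDF5 attributes cannot annotate
compound fields and the whole point of the layout is that every node
carries a `description` (and, when physically dimensioned, a long-form
`units`) attribute.  Numeric datasets that fit inside the object header
(≤ 64 KiB) are stored with the *compact* layout so small values travel
with their metadata; variable-length strings keep the default layout,
since compact placement would relocate only the heap pointers.  Six
provenance attributes (experiment date, cell number, researcher,
responsible person, data curator, funding source) sit on the file root,
and each file describes exactly one cell.

## Term registry and import manifest

The registry enumerates only classes that the profile names
individually, organised as six directed root trees with multiple
parents permitted.  The per-source class counts of the full profile live
in a *declared import manifest* (CHEBI 8, CL 5, CNO 2, EDAM 2, FMA 12,
GO 6, MP 5, NCBITaxon 2, NCIT 2, OBA 7, OPB 1, PATO 28, SBO 1, SIO 3,
UBERON 2 — 86 imported classes from fifteen ontologies — plus 37 new
classes, 123 in total).  Declared ≥ enumerated holds for every source by
construction: unnamed members of the profile are counted, never
fabricated.  New-class identifiers are assigned as `OBI_IEE:NNNN` in
label-sorted order, which keeps all exports byte-stable.  External
accessions are standard CURIEs where the term is unambiguous and stable
project-assigned placeholders otherwise (the profile description names
classes, not accessions).  The OWL export restricts itself to class
declarations, is-a axioms and label/definition annotations — the
registry does no reasoning.

## Units

Attribute values avoid Greek letters and superscripts, so units are
long-form ASCII strings: `millivolt`, `picofarad`, `megaohm`,
`picocoulomb`, `per millivolt`, `micrometer`, `micrometer x micrometer`
(the `x` replacing ×), `millimolar`, `degree celsius`, `millimeter of
mercury`, `second`, `hertz`, plus `nanosiemens`, `nanoampere`, `gram`,
`day` and `milliosmole per kilogram` for quantities the written files
need.  Internally the electrical and geometric quantities are SI
(volt, farad, ohm, siemens, ampere, coulomb, meter, second);
temperature, pressure, age and osmolality are carried in their display
unit, because nothing downstream does arithmetic across those
dimensions and offset conversions (°C↔K) would only add noise.

## Measurement model and estimators

The equivalent circuit is the access resistance Rs in series with
Rm ∥ Cm, giving Y(ω) = (1 + jωRmCm)/(Rs + Rm + jωRsRmCm).

**Per-pair inversion.**  With Z = 1/Y, a = Re(Z) − Rs and b = Im(Z) the
circuit implies Rm = (a² + b²)/a at each frequency; equating the two
frequencies yields a quadratic in a whose roots have opposite signs, so
the physical solution is unique and closed-form.  Four observations,
four unknowns (Rs, Rm, Cm@f1, Cm@f2): on noise-free input the generating
parameters come back to ~1e−12 relative.  The *reported* capacitance
frequency is the one whose single-frequency reconstruction has the
smaller normalised misfit (ties go to f1); this selection rule is a
stand-in for the original acquisition software's undocumented rule and
is labelled as such in the file metadata, with an override to force
either frequency.

**Sweep pooling.**  The per-pair Rm estimate divides by the small
difference of real parts and is therefore heavy-tailed under noise: a
Cramér–Rao analysis at 1% multiplicative admittance noise bounds any
dual-sine-only estimator at roughly 1.7% relative sd for Rm = 100 MΩ,
rising to ~8% at 480 MΩ.  Since Rs and Rm do not depend on the DC
potential, the pipeline refits the whole sweep jointly — one (Rs, Rm)
pair plus one Cm per potential, residuals normalised by |Y|, sparse
Jacobian — which reaches that bound.  The per-frequency capacitances
are then re-derived from each admittance with the pooled Rs via
Cm = −Im(Z−Rs)/(ω|Z−Rs|²), which leans on the large susceptive part
rather than the small real-part difference.

**Membrane resistance across protocols.**  The voltage-step protocol
measures the same Rm far more precisely (steady-state I–V slope; pA
noise against hundreds of pA of signal).  When both protocols are
present, the linear data set stores the inverse-variance-weighted
combination of the pooled dual-sine estimate and R_b, with the variances
taken from the Gauss–Newton covariance of the sweep fit and the OLS
slope variance (Rs uncertainty propagated into R_b).  With either
protocol absent the other estimate is used unchanged.  R_b itself is
always stored separately in the IV data set.

**Boltzmann fits.**  The capacitance form Cm(V) = Clin + Qmax·α·u/(1+u)²
(u = exp(−α(V−Vpk))) is fitted by least squares with data-derived
initial values: Clin from the minimum, Vpk from the argmax, Qmax from
the trapezoidal charge, α = 4·(ΔCm)/Qmax.  The charge form is fitted to
the cumulative trapezoidal integral of the NLC as a cross-check; the
two forms must agree on (Qmax, Vpk, α) to well under 0.1 mV in Vpk on
clean data.  Residuals are normalised by the data span so the optimizer
tolerances (1e−12) are meaningful at picofarad scale.  Flat curves
raise a degenerate-fit error; a peak on the boundary of the sweep sets
a warning flag.  Fits run against the series-resistance-corrected
membrane potential Vm = Vc·Rm/(Rm+Rs) by default; the fit against the
raw command potential is stored alongside (`V_pk_command`), since
whether published Vpk values are divider-corrected varies between
laboratories.

**Linear window.**  The "linear" capacitance is the mean of measured Cm
over potentials where the fitted NLC is below 1% of its fitted peak;
when no potential qualifies (very shallow α), the fit offset Clin is
used and a fallback flag is set.  The stored Rs/Rm are the pooled
estimates described above, not per-potential means.

**I–V analysis.**  Each step's steady-state current is the mean over
the trace tail (default: last 50%, when the slowest time constant
RsRmClin/(Rs+Rm) ≲ 0.4 ms has decayed by many orders of magnitude);
Vm = Vc − I·Rs; R_b is the reciprocal OLS slope of I on Vm.  For a
noise-free ohmic cell R_b = Rm to numerical precision.

**Morphology.**  The predicted cell surface area is the lateral
cylinder π·d·L (the lateral wall dominates the electromotile membrane);
an option adds the two end caps.

## Synthetic-data generator

The generator is the package's study-conditions stand-in for real
recordings and the oracle for every downstream test.  Per cell it draws
uniformly: Rs 5–15 MΩ, Rm 100–500 MΩ, Clin 15–35 pF, Qmax 1.5–3.5 pC,
Vpk −60…−20 mV, α 0.025–0.035 /mV; OHC diameter 8–10 µm and length
20–90 µm tied to the cochlear turn (apical 65–90 µm, middle 40–65,
basal 20–40), with a log-uniform best frequency inside each turn's slice
of the guinea-pig tonotopic span (0.060–43 kHz).  The dual-sine stimulus
is f1 = 390.6 Hz, f2 = 781.2 Hz, 10 mV amplitudes, Vdc −150…+100 mV in
5 mV steps; the voltage-step protocol covers −100…+100 mV in 20 mV
steps at 5 kHz for 200 ms.  Admittance is computed from the forward
model with Cm(Vm) = Clin + Cnl(Vm) evaluated at the divider-corrected
potential; noise enters as 0.2 pF additive capacitance noise, 1%
multiplicative complex admittance noise, and 5 pA additive current
noise on single-exponential step responses.  Draw streams are seeded
with `seed + index`, so a bundle is a pure function of (seed, index).

What the generator does *not* emulate: stray-capacitance and seal
artefacts, run-down and drift over the sweep, non-ohmic (rectifying)
steady-state conductances, temperature dependence, or raw time-domain
sinusoids (admittance records are the input granularity).  Passing
tests therefore demonstrate correctness of the mathematics and the
format contract under the stated noise model, not robustness to every
pathology of real recordings.

The flat 82-field record emulates the original acquisition records'
array-of-structures shape: 47 fields carry the science (provenance,
organism, anatomy, morphology, stimulus, admittance, I–V, conditions,
solutions, devices), and 35 clearly-labelled acquisition-metadata
fields (rig identifier, software versions, notes, …) are flagged
`provenance="generator"` so the count matches the original record size
without inventing scientific content.  The manifest is pinned; the
names are a documented reconstruction, not a claim of fidelity to the
original variable names.

## Validation

The validator checks a file against the compiled architecture for a
chosen protocol set: required groups/datasets, group and dataset naming
rules, description attributes everywhere, units attributes from the
long-form table on dimensioned datasets, the six root provenance
attributes, no compound datatypes, one cell per file (a multi-valued
`cell_number` attribute is the multi-cell signal, since HDF5 cannot
duplicate sibling group names).  Reports are ordered by (path, code); a
missing group subsumes its descendants.  Unknown extra nodes are
tolerated and surfaced as notes, not violations — strict writing,
tolerant reading.  `mutate_for_test` injects exactly one defect per
code, which is how the suite proves every detector fires without
spurious cross-reports.

## Problem sizes and numerical choices

Cohort-level checks use 20 cells (parameter recovery at study noise)
and 50 cells (round-trip and validator soundness); the inversion oracle
sweep uses 1000 random draws and Monte-Carlo fit checks use 200–300
replicates — sizes chosen so the full suite and the acceptance script
each run in well under a minute of CPU while leaving the medians stable
to re-seeding.  Optimizer settings are fixed (trust-region reflective,
1e−12 tolerances, data-scaled parameters); random seeds appear only in
the generator and Monte-Carlo tests.  Floats survive the HDF5 round
trip to ≤ 1 ulp (display-unit conversion is the only rounding source);
integers and strings exactly.

## Known limitations

* The registry enumerates 73 of the 123 declared classes — those the
  profile names; subtree counts on unnamed regions reflect the manifest
  only.
* The reported-capacitance selection rule is a documented stand-in (see
  above).
* No time-domain lock-in demodulation: the package starts from
  admittance records, not raw current traces, for the dual-sine arm.
* The validator checks structure and conventions, not scientific
  plausibility of stored values.
* Reading third-party files is tolerant of extras but requires the
  architecture's required nodes and table units; files from the
  originally deposited collection (whose exact dataset naming is not
  published) may need an alias pass first.
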