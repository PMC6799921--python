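"""Compute the transformed-data arm from a raw recording.

The pipeline turns the per-potential admittance pairs into circuit
estimates (closed-form two-sine inversion), partitions the capacitance
into its voltage-independent and voltage-dependent parts, fits both
forms of the two-state Boltzmann relation, and reduces the voltage-step
protocol to its steady-state I-V summary.  The four outputs mirror the
four transformed sub-groups of the file layout: linear, non-linear,
Boltzmann fit and IV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biophysics import (BoltzmannParams, FitDiagnostics, boltzmann_nlc,
                         capacitance_at_frequency, fit_capacitance_boltzmann,
                         fit_charge_boltzmann, fit_circuit_sweep,
                         iv_analysis, series_resistance_divider,
                         solve_two_sine_series)
from .errors import PipelineError
from .synth import RecordingBundle

#: fitted-NLC fraction of peak below which a potential counts as "linear"
LINEAR_WINDOW_FRACTION = 0.01


@dataclass
class PerPotentialSet:
    """Two-sine solutions at every command potential."""

    Cm_f1: np.ndarray
    Cm_f2: np.ndarray
    Rm: np.ndarray              # per-potential closed-form estimates
    Rs: np.ndarray
    reported: str               # "f1" | "f2"
    Rs_fit: float | None = None   # sweep-pooled joint estimates
    Rm_fit: float | None = None
    Rs_var: float = float("nan")  # Gauss-Newton variances of the pooled fit
    Rm_var: float = float("nan")

    @property
    def Cm_reported(self) -> np.ndarray:
        return self.Cm_f1 if self.reported == "f1" else self.Cm_f2

    @property
    def Rs_central(self) -> float:
        return self.Rs_fit if self.Rs_fit is not None \
            else float(np.nanmedian(self.Rs))

    @property
    def Rm_central(self) -> float:
        return self.Rm_fit if self.Rm_fit is not None \
            else float(np.nanmedian(self.Rm))


@dataclass
class LinearSet:
    Clin: float                 # farad
    Rm: float                   # ohm (mean over potentials)
    Rs: float                   # ohm (mean over potentials)
    Vm: np.ndarray              # volt, per command potential
    window_fallback: bool = False


@dataclass
class NonlinearSet:
    nlc: np.ndarray             # farad, per potential
    peak_nlc: float             # farad
    charge: np.ndarray          # coulomb, cumulative integral of nlc
    max_charge: float           # coulomb
    alpha: float                # 1/volt (from the fit)
    Vpk: float                  # volt (from the fit)
    interior_peak: bool = True


@dataclass
class BoltzmannFitSet:
    params: BoltzmannParams
    Clin: float
    residual_norm: float = float("nan")
    Vpk_command: float | None = None     # fit against raw Vdc
    charge_params: BoltzmannParams | None = None
    diagnostics: FitDiagnostics | None = None


@dataclass
class IVSet:
    I_mean: np.ndarray
    I_sd: np.ndarray
    Rb: float
    Vm: np.ndarray
    Rb_var: float = float("nan")


@dataclass
class TransformedData:
    """The four transformed sub-sets plus the per-potential estimates."""

    linear: LinearSet | None = None
    nonlinear: NonlinearSet | None = None
    boltzmann: BoltzmannFitSet | None = None
    iv: IVSet | None = None
    per_potential: PerPotentialSet | None = None
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def solve_admittance_sweep(bundle: RecordingBundle) -> PerPotentialSet:
    """Closed-form inversion at every command potential.

    The reported capacitance frequency is chosen once per cell: the
    frequency whose single-frequency reconstruction accumulates the
    smaller misfit over the whole sweep (ties go to f1).
    """
    adm = bundle.admittance
    w1 = 2 * np.pi * bundle.stimulus.f1
    w2 = 2 * np.pi * bundle.stimulus.f2
    Rs_pp, Rm_pp, Cm1, Cm2 = solve_two_sine_series(adm.Y1, adm.Y2, w1, w2)
    if np.all(np.isnan(Cm1)):
        raise PipelineError("two-sine inversion failed at every potential",
                            stage="two_sine")
    # pool the sweep: Rs and Rm do not depend on the DC potential, so a
    # joint fit sharpens them; the per-frequency capacitances are then
    # re-derived with the pooled resistances
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            Cm0 = np.nanmean(np.vstack([Cm1, Cm2]), axis=0)
        Rs, Rm, _, (var_Rs, var_Rm) = fit_circuit_sweep(
            adm.Y1, adm.Y2, w1, w2,
            float(np.nanmedian(Rs_pp)), float(np.nanmedian(Rm_pp)), Cm0)
        Cm1 = capacitance_at_frequency(adm.Y1, w1, Rs)
        Cm2 = capacitance_at_frequency(adm.Y2, w2, Rs)
    except Exception as exc:
        raise PipelineError(f"sweep pooling failed: {exc}",
                            stage="two_sine") from exc

    def sweep_misfit(Cm):
        # reconstruct both frequencies with the single-frequency Cm
        def pred(w):
            num = 1.0 + 1j * w * Rm * Cm
            den = (Rs + Rm) + 1j * w * Rs * Rm * Cm
            return num / den
        scale = np.abs(adm.Y1) + np.abs(adm.Y2)
        with np.errstate(invalid="ignore"):
            r = (np.abs(pred(w1) - adm.Y1) ** 2
                 + np.abs(pred(w2) - adm.Y2) ** 2) / scale ** 2
        return float(np.nansum(r))

    reported = "f1" if sweep_misfit(Cm1) <= sweep_misfit(Cm2) else "f2"
    return PerPotentialSet(Cm_f1=Cm1, Cm_f2=Cm2, Rm=Rm_pp, Rs=Rs_pp,
                           reported=reported, Rs_fit=Rs, Rm_fit=Rm,
                           Rs_var=var_Rs, Rm_var=var_Rm)


def fit_boltzmann_stage(bundle: RecordingBundle, pp: PerPotentialSet,
                        use_corrected_potential: bool = True):
    """Fit both Boltzmann forms to the reported capacitance curve."""
    Vdc = np.asarray(bundle.admittance.Vdc, dtype=float)
    Vm = series_resistance_divider(Vdc, pp.Rs_central, pp.Rm_central)
    Cm = pp.Cm_reported
    ok = ~np.isnan(Cm)
    V_fit = (Vm if use_corrected_potential else Vdc)[ok]
    params, Clin, diags = fit_capacitance_boltzmann(V_fit, Cm[ok])
    # the uncorrected-potential fit is stored alongside (the correction
    # choice is a convention, so both values are kept)
    other_V = (Vdc if use_corrected_potential else Vm)[ok]
    params_raw, _, _ = fit_capacitance_boltzmann(other_V, Cm[ok])
    vpk_cmd = params_raw.Vpk if use_corrected_potential else params.Vpk
    nlc_obs = Cm[ok] - Clin
    charge = np.concatenate(
        [[0.0], np.cumsum((nlc_obs[1:] + nlc_obs[:-1]) / 2.0
                          * np.diff(V_fit))])
    charge_params = None
    try:
        charge_params, _off, _d = fit_charge_boltzmann(V_fit, charge)
    except Exception:
        pass  # charge-form fit is a cross-check, not a required output
    fit = BoltzmannFitSet(params=params, Clin=Clin,
                          residual_norm=diags.residual_norm,
                          Vpk_command=vpk_cmd,
                          charge_params=charge_params, diagnostics=diags)
    return fit, Vm, V_fit, Cm[ok], charge


def compute_linear_set(bundle: RecordingBundle, pp: PerPotentialSet,
                       fit: BoltzmannFitSet, Vm: np.ndarray,
                       V_fit: np.ndarray, Cm: np.ndarray,
                       iv: IVSet | None = None) -> LinearSet:
    """Central Rs/Rm over all potentials; Clin averaged over the linear
    window (potentials where the fitted NLC is below 1% of its peak),
    falling back to the fit offset when the window is empty.

    The stored resistances are the sweep-pooled joint estimates (the
    per-potential closed-form values are heavy-tailed).
    """
    Rs_bar = pp.Rs_central
    Rm_bar = combine_membrane_resistance(pp, iv)
    nlc_fit = boltzmann_nlc(V_fit, fit.params)
    window = nlc_fit < LINEAR_WINDOW_FRACTION * np.max(nlc_fit)
    if np.any(window):
        Clin = float(np.mean(Cm[window]))
        fallback = False
    else:
        Clin = fit.Clin
        fallback = True
    return LinearSet(Clin=Clin, Rm=Rm_bar, Rs=Rs_bar, Vm=Vm,
                     window_fallback=fallback)


def compute_nonlinear_set(fit: BoltzmannFitSet, linear: LinearSet,
                          V_fit: np.ndarray,
                          Cm: np.ndarray) -> NonlinearSet:
    """NLC(V) = Cm(V) - Clin; displacement charge is its cumulative
    trapezoidal integral; alpha and Vpk come from the Boltzmann fit."""
    nlc = Cm - linear.Clin
    peak = float(np.max(nlc))
    ipk = int(np.argmax(nlc))
    interior = 0 < ipk < len(nlc) - 1
    charge = np.concatenate(
        [[0.0], np.cumsum((nlc[1:] + nlc[:-1]) / 2.0 * np.diff(V_fit))])
    return NonlinearSet(nlc=nlc, peak_nlc=peak, charge=charge,
                        max_charge=float(charge[-1] - charge.min()),
                        alpha=fit.params.alpha, Vpk=fit.params.Vpk,
                        interior_peak=interior)


def compute_iv_set(bundle: RecordingBundle, Rs: float) -> IVSet:
    res = iv_analysis(list(zip(bundle.iv.Vc, bundle.iv.traces)),
                      window=0.5, Rs=Rs)
    return IVSet(I_mean=res.I_mean, I_sd=res.I_sd, Rb=res.Rb, Vm=res.Vm,
                 Rb_var=res.Rb_var)


def combine_membrane_resistance(pp: PerPotentialSet,
                                iv: IVSet | None) -> float:
    """Best membrane-resistance estimate from the whole recording.

    The dual-sine sweep and the voltage-step protocol both measure the
    membrane resistance; when both are present and carry usable variance
    estimates the two are combined by inverse-variance weighting (the
    steady-state I-V slope is typically far more precise at these noise
    levels).  With either piece missing the other is returned as is.
    """
    Rm_a, va = pp.Rm_central, pp.Rm_var
    if iv is None:
        return Rm_a
    vb = iv.Rb_var + pp.Rs_var  # Rs uncertainty propagates into Rb
    if not (np.isfinite(va) and np.isfinite(vb)) or va <= 0 or vb <= 0:
        return Rm_a
    wa, wb = 1.0 / va, 1.0 / vb
    return float((wa * Rm_a + wb * iv.Rb) / (wa + wb))


def run_pipeline(bundle: RecordingBundle,
                 use_corrected_potential: bool = True) -> TransformedData:
    """Full transformation of one bundle; deterministic given its data.

    Stage failures raise :class:`PipelineError` naming the stage, with
    the partial :class:`TransformedData` attached.
    """
    td = TransformedData()
    have_ds = bundle.admittance is not None and \
        np.asarray(bundle.admittance.Vdc).size > 0
    have_iv = bundle.iv is not None and np.asarray(bundle.iv.Vc).size >= 3

    if have_ds:
        try:
            pp = solve_admittance_sweep(bundle)
            td.per_potential = pp
        except PipelineError as exc:
            exc.partial = td
            raise
        try:
            fit, Vm, V_fit, Cm, charge = fit_boltzmann_stage(
                bundle, pp, use_corrected_potential)
            td.boltzmann = fit
        except Exception as exc:
            raise PipelineError(f"boltzmann fit failed: {exc}",
                                stage="boltzmann", partial=td) from exc
    else:
        td.flags["dual_sine_absent"] = True

    if have_iv:
        Rs = td.per_potential.Rs_central \
            if td.per_potential is not None else 0.0
        try:
            td.iv = compute_iv_set(bundle, Rs)
        except Exception as exc:
            raise PipelineError(f"IV analysis failed: {exc}", stage="iv",
                                partial=td) from exc
    else:
        td.flags["iv_absent"] = True

    if have_ds:
        td.linear = compute_linear_set(bundle, pp, fit, Vm, V_fit, Cm,
                                       iv=td.iv)
        td.nonlinear = compute_nonlinear_set(fit, td.linear, V_fit, Cm)
    return td
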