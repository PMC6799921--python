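"""Equivalent-circuit and 2-state Boltzmann mathematics.

The cell under whole-cell voltage clamp is modelled as the series
(access) resistance Rs of the pipette in series with the parallel
combination of the membrane resistance Rm and the membrane capacitance
Cm, so the admittance seen by the amplifier at angular frequency omega is

    Y(omega) = (1 + j omega Rm Cm) / (Rs + Rm + j omega Rs Rm Cm).

The two-sine protocol measures Y at two frequencies (f2 = 2 f1 by
convention), giving four real observations from which Rs, Rm and the
capacitance at each frequency are solved in closed form.  The
voltage-dependent part of the capacitance follows the two-state
Boltzmann relation

    Q(V)   = Qmax / (1 + exp(-alpha (V - Vpk)))          (charge form)
    Cnl(V) = dQ/dV = Qmax alpha u / (1 + u)^2,  u = exp(-alpha (V - Vpk))

which peaks at V = Vpk with peak value Qmax alpha / 4.

All interfaces are SI: volt, farad, ohm, siemens, coulomb, ampere,
second, radian/second where noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import EstimationError, FitError

__all__ = [
    "CircuitParams", "BoltzmannParams", "StimulusSpec", "TwoSineSolution",
    "IVResult", "boltzmann_charge", "boltzmann_nlc", "peak_nlc",
    "forward_admittance", "solve_two_sine", "series_resistance_divider",
    "iv_analysis", "fit_capacitance_boltzmann", "fit_charge_boltzmann",
    "cell_surface_area",
]


@dataclass(frozen=True)
class CircuitParams:
    """Passive equivalent-circuit parameters (ohm, ohm, farad)."""

    Rs: float
    Rm: float
    Clin: float

    def __post_init__(self):
        if min(self.Rs, self.Rm, self.Clin) <= 0:
            raise ValueError("circuit parameters must be strictly positive")
        if self.Rs >= self.Rm:
            import warnings
            warnings.warn("series resistance >= membrane resistance; "
                          "check the recording", stacklevel=2)


@dataclass(frozen=True)
class BoltzmannParams:
    """Two-state Boltzmann parameters (coulomb, volt, 1/volt)."""

    Qmax: float
    Vpk: float
    alpha: float

    def __post_init__(self):
        if self.Qmax <= 0 or self.alpha <= 0:
            raise ValueError("Qmax and alpha must be strictly positive")


@dataclass(frozen=True)
class StimulusSpec:
    """Dual-sine stimulus description (hertz, volt, second)."""

    f1: float = 390.6
    f2: float = 781.2
    a1: float = 0.010
    a2: float = 0.010
    Vdc: tuple = tuple(np.arange(-150, 101, 5) * 1e-3)
    hold_time: float = 0.2

    def __post_init__(self):
        if not (self.f1 > 0 and self.f2 > self.f1):
            raise ValueError("need 0 < f1 < f2")
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("sine amplitudes must be positive")
        v = np.asarray(self.Vdc, dtype=float)
        if v.size == 0 or not np.all(np.diff(v) > 0):
            raise ValueError("Vdc must be nonempty and strictly increasing")


@dataclass(frozen=True)
class TwoSineSolution:
    """Closed-form inversion of a pair of admittances."""

    Rs_hat: float
    Rm_hat: float
    Cm_f1: float
    Cm_f2: float
    reported: str            # "f1" | "f2"
    residual: float

    @property
    def Cm_reported(self) -> float:
        return self.Cm_f1 if self.reported == "f1" else self.Cm_f2


@dataclass(frozen=True)
class IVResult:
    """Steady-state current analysis of the voltage-step protocol."""

    Vm: np.ndarray           # corrected membrane potential, volt
    I_mean: np.ndarray       # ampere
    I_sd: np.ndarray         # ampere
    Rb: float                # reciprocal slope conductance, ohm
    Rb_var: float = float("nan")   # OLS variance of Rb, ohm^2


# ---------------------------------------------------------------------------
# Boltzmann forms
# ---------------------------------------------------------------------------

def boltzmann_charge(V, p: BoltzmannParams):
    """Displacement charge Q(V) of the two-state Boltzmann relation."""
    V = np.asarray(V, dtype=float)
    out = p.Qmax / (1.0 + np.exp(-p.alpha * (V - p.Vpk)))
    return out if out.ndim else float(out)


def boltzmann_nlc(V, p: BoltzmannParams):
    """Capacitance form Cnl(V) = dQ/dV; bell-shaped, symmetric about Vpk."""
    V = np.asarray(V, dtype=float)
    # evaluate with |x| to keep exp bounded on both tails
    x = p.alpha * (V - p.Vpk)
    u = np.exp(-np.abs(x))
    out = p.Qmax * p.alpha * u / (1.0 + u) ** 2
    return out if out.ndim else float(out)


def peak_nlc(p: BoltzmannParams) -> float:
    """Peak of the capacitance form: Qmax * alpha / 4 (at V = Vpk)."""
    return p.Qmax * p.alpha / 4.0


# ---------------------------------------------------------------------------
# equivalent circuit
# ---------------------------------------------------------------------------

def forward_admittance(omega, Rs, Rm, Cm):
    """Complex admittance of the Rs + (Rm || Cm) circuit.

    omega may be scalar or array (radian/second).  At omega=0 the result
    is 1/(Rs+Rm); as omega grows it tends to 1/Rs.  Cm=0 is accepted (a
    purely resistive chain); other parameters must be positive.
    """
    if Rs <= 0 or Rm <= 0 or Cm < 0:
        raise ValueError("circuit parameters out of domain")
    omega = np.asarray(omega, dtype=float)
    num = 1.0 + 1j * omega * Rm * Cm
    den = (Rs + Rm) + 1j * omega * Rs * Rm * Cm
    out = num / den
    return out if out.ndim else complex(out)


def series_resistance_divider(Vc, Rs, Rm):
    """Steady-state membrane potential Vm = Vc * Rm / (Rm + Rs)."""
    if Rs < 0 or Rm <= 0:
        raise ValueError("resistances must be positive (Rs may be 0)")
    Vc = np.asarray(Vc, dtype=float)
    out = Vc * Rm / (Rm + Rs)
    return out if out.ndim else float(out)


def _invert_pair(Z1, Z2, omega1, omega2):
    """Solve Rs, Rm, Cm@f1, Cm@f2 from the two impedances (vectorised).

    With a_i = Re(Z_i) - Rs and b_i = Im(Z_i) the circuit gives
    Rm = (a_i^2 + b_i^2)/a_i at each frequency; equating the two yields a
    quadratic in a2 whose two roots have opposite signs, so the physical
    (positive) root is unique.
    """
    r1, b1 = np.real(Z1), np.imag(Z1)
    r2, b2 = np.real(Z2), np.imag(Z2)
    d = r1 - r2
    # quadratic d*x^2 + (d^2 - b2^2 + b1^2)*x - d*b2^2 = 0 in x = a2
    bq = d * d - b2 * b2 + b1 * b1
    disc = bq * bq + 4.0 * d * d * b2 * b2   # always >= 0
    sq = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(d > 0, (-bq + sq) / (2 * d), (-bq - sq) / (2 * d))
    a2 = x
    a1 = a2 + d
    Rs = r2 - a2
    Rm = (a1 * a1 + b1 * b1) / a1
    t1 = -b1 / a1
    t2 = -b2 / a2
    Cm1 = t1 / (omega1 * Rm)
    Cm2 = t2 / (omega2 * Rm)
    return Rs, Rm, Cm1, Cm2


def solve_two_sine(Y1, Y2, omega1, omega2,
                   report: str | None = None) -> TwoSineSolution:
    """Invert a pair of complex admittances measured at omega1 < omega2.

    Returns the jointly solved Rs and Rm and the capacitance estimate at
    each frequency.  ``reported`` is the frequency whose single-frequency
    reconstruction (using its Cm at both frequencies) has the smaller
    normalised misfit; pass ``report='f1'`` or ``'f2'`` to force one.
    Raises :class:`EstimationError` when no physical solution exists
    (e.g. the capacitive susceptance is at the noise floor, or the
    implied Rs is nonpositive).
    """
    if not (0 < omega1 < omega2):
        raise ValueError("need 0 < omega1 < omega2")
    Y1, Y2 = complex(Y1), complex(Y2)
    if Y1.real <= 0 or Y2.real <= 0:
        raise ValueError("admittance real parts must be positive")
    scale = abs(Y1) + abs(Y2)
    if abs(Y1.imag) < 1e-9 * scale or abs(Y2.imag) < 1e-9 * scale \
            or abs(Y1.real - Y2.real) < 1e-12 * scale:
        raise EstimationError(
            "capacitive signature below tolerance floor (Cm ~ 0 or "
            "identical admittances)", residual=math.inf)
    Z1, Z2 = 1.0 / Y1, 1.0 / Y2
    Rs, Rm, Cm1, Cm2 = _invert_pair(Z1, Z2, omega1, omega2)
    if not (Rs > 0 and Rm > 0 and Cm1 > 0 and Cm2 > 0):
        raise EstimationError(
            f"no physical solution (Rs={Rs:.3g}, Rm={Rm:.3g}, "
            f"Cm1={Cm1:.3g}, Cm2={Cm2:.3g})", residual=math.inf)

    def misfit(Cm):
        p1 = forward_admittance(omega1, Rs, Rm, Cm)
        p2 = forward_admittance(omega2, Rs, Rm, Cm)
        obs = np.array([Y1.real, Y1.imag, Y2.real, Y2.imag])
        pred = np.array([p1.real, p1.imag, p2.real, p2.imag])
        return float(np.sum(((pred - obs) / scale) ** 2))

    res1, res2 = misfit(Cm1), misfit(Cm2)
    if report is None:
        reported = "f1" if res1 <= res2 else "f2"
    elif report in ("f1", "f2"):
        reported = report
    else:
        raise ValueError("report must be 'f1', 'f2' or None")
    residual = res1 if reported == "f1" else res2
    return TwoSineSolution(Rs_hat=float(Rs), Rm_hat=float(Rm),
                           Cm_f1=float(Cm1), Cm_f2=float(Cm2),
                           reported=reported, residual=residual)


def fit_circuit_sweep(Y1, Y2, omega1, omega2, Rs0, Rm0, Cm0):
    """Joint fit of one (Rs, Rm) pair and a per-potential capacitance to a
    whole admittance sweep.

    The closed-form per-pair inversion treats every potential in
    isolation, so its Rm estimate rides on a small noisy difference of
    real parts; pooling the sweep under the physical constraint that the
    resistances do not change with the DC potential recovers them far
    more precisely.  Returns (Rs, Rm, Cm array).
    """
    from scipy.sparse import lil_matrix

    Y1 = np.asarray(Y1, dtype=complex)
    Y2 = np.asarray(Y2, dtype=complex)
    n = Y1.size
    obs = np.concatenate([Y1.real, Y1.imag, Y2.real, Y2.imag])
    scale = np.concatenate([np.abs(Y1), np.abs(Y1), np.abs(Y2),
                            np.abs(Y2)])

    def resid(theta):
        Rs, Rm = theta[0], theta[1]
        Cm = theta[2:]
        p1 = (1 + 1j * omega1 * Rm * Cm) / (Rs + Rm
                                            + 1j * omega1 * Rs * Rm * Cm)
        p2 = (1 + 1j * omega2 * Rm * Cm) / (Rs + Rm
                                            + 1j * omega2 * Rs * Rm * Cm)
        pred = np.concatenate([p1.real, p1.imag, p2.real, p2.imag])
        return (pred - obs) / scale

    Cm0 = np.asarray(Cm0, dtype=float).copy()
    bad = ~np.isfinite(Cm0) | (Cm0 <= 0)
    if bad.all():
        raise EstimationError("no usable capacitance initialisation")
    Cm0[bad] = np.median(Cm0[~bad])
    theta0 = np.concatenate([[Rs0, Rm0], Cm0])
    sparsity = lil_matrix((4 * n, n + 2), dtype=int)
    sparsity[:, 0] = 1
    sparsity[:, 1] = 1
    for block in range(4):
        for i in range(n):
            sparsity[block * n + i, 2 + i] = 1
    sol = least_squares(resid, theta0, x_scale=np.abs(theta0),
                        jac_sparsity=sparsity,
                        bounds=(np.zeros_like(theta0) + 1e-300, np.inf),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
    Rs, Rm = float(sol.x[0]), float(sol.x[1])
    # Gauss-Newton covariance of (Rs, Rm) with the residual variance
    # estimated from the fit itself (zero for noise-free data)
    J = sol.jac
    if hasattr(J, "toarray"):
        J = J.toarray()
    m, k = J.shape
    dof = max(m - k, 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        var_Rs, var_Rm = float(cov[0, 0]), float(cov[1, 1])
    except np.linalg.LinAlgError:
        var_Rs = var_Rm = float("nan")
    return Rs, Rm, sol.x[2:], (var_Rs, var_Rm)


def capacitance_at_frequency(Y, omega, Rs):
    """Single-frequency capacitance given a known series resistance.

    Subtracting Rs from Z = 1/Y leaves the parallel Rm || Cm branch, for
    which Im(1/(Z - Rs)) = omega * Cm, i.e.
    Cm = -Im(Z - Rs) / (omega * |Z - Rs|^2).  This leans on the (large)
    susceptive part rather than the small real-part difference, so it is
    far less noise-sensitive than the per-pair closed form.  Nonphysical
    entries come back NaN.
    """
    Z = 1.0 / np.asarray(Y, dtype=complex)
    zb = Z - Rs
    with np.errstate(divide="ignore", invalid="ignore"):
        Cm = -zb.imag / (omega * np.abs(zb) ** 2)
    Cm = np.where((zb.real > 0) & (Cm > 0), Cm, np.nan)
    return Cm


def solve_two_sine_series(Y1, Y2, omega1, omega2):
    """Vectorised inversion over arrays of admittance pairs.

    Nonphysical entries come back as NaN rather than raising, so a noisy
    sweep can be reduced with nan-aware statistics.
    """
    Y1 = np.asarray(Y1, dtype=complex)
    Y2 = np.asarray(Y2, dtype=complex)
    Rs, Rm, Cm1, Cm2 = _invert_pair(1.0 / Y1, 1.0 / Y2, omega1, omega2)
    bad = ~((Rs > 0) & (Rm > 0) & (Cm1 > 0) & (Cm2 > 0))
    for arr in (Rs, Rm, Cm1, Cm2):
        arr[bad] = np.nan
    return Rs, Rm, Cm1, Cm2


# ---------------------------------------------------------------------------
# I-V analysis
# ---------------------------------------------------------------------------

def iv_analysis(steps, window: float = 0.5, Rs: float = 0.0,
                Rm_guess: float | None = None) -> IVResult:
    """Steady-state analysis of a voltage-step family.

    ``steps`` is a sequence of (Vc, trace) pairs; the mean and standard
    deviation of each trace over its tail ``window`` fraction give the
    steady-state current, the membrane potential is corrected as
    Vm = Vc - I_mean * Rs, and Rb is the reciprocal slope of the
    least-squares line of I_mean on Vm.  For a noise-free ohmic cell
    Rb equals Rm exactly.
    """
    if len(steps) < 3:
        raise ValueError("need at least 3 voltage steps")
    if not (0 < window <= 1):
        raise ValueError("window must be in (0, 1]")
    Vc = np.array([float(v) for v, _ in steps])
    means, sds = [], []
    for _, trace in steps:
        trace = np.asarray(trace, dtype=float)
        tail = trace[int(round(len(trace) * (1 - window))):]
        if tail.size == 0:
            raise ValueError("window leaves no samples")
        means.append(tail.mean())
        sds.append(tail.std(ddof=1) if tail.size > 1 else 0.0)
    I_mean = np.array(means)
    I_sd = np.array(sds)
    Vm = Vc - I_mean * Rs
    if np.ptp(Vm) == 0:
        raise EstimationError("degenerate fit: zero voltage spread")
    slope, intercept = np.polyfit(Vm, I_mean, 1)
    if slope == 0:
        raise EstimationError("degenerate fit: zero slope conductance")
    resid = I_mean - (slope * Vm + intercept)
    dof = max(len(Vm) - 2, 1)
    var_slope = float(np.sum(resid ** 2) / dof
                      / np.sum((Vm - Vm.mean()) ** 2))
    Rb = 1.0 / slope
    order = np.argsort(Vm)
    return IVResult(Vm=Vm[order], I_mean=I_mean[order], I_sd=I_sd[order],
                    Rb=Rb, Rb_var=var_slope * Rb ** 4)


# ---------------------------------------------------------------------------
# Boltzmann fitting
# ---------------------------------------------------------------------------

@dataclass
class FitDiagnostics:
    converged: bool
    residual_norm: float
    n_points: int
    peak_at_boundary: bool = False
    message: str = ""


def _initial_capacitance_guess(V, Cm):
    Clin0 = float(np.min(Cm))
    ipk = int(np.argmax(Cm))
    Vpk0 = float(V[ipk])
    Qmax0 = float(np.trapezoid(Cm - Clin0, V))
    span = float(np.max(Cm) - np.min(Cm))
    if Qmax0 <= 0 or span <= 0:
        raise FitError("flat capacitance curve: no non-linear component",
                       residual=0.0)
    alpha0 = 4.0 * span / Qmax0
    return Qmax0, Vpk0, alpha0, Clin0


def fit_capacitance_boltzmann(V, Cm_total):
    """Least-squares fit of Cm(V) = Clin + Cnl(V; Qmax, Vpk, alpha).

    Initial values are taken from the data: Clin from the minimum, Vpk
    from the argmax, Qmax from the trapezoidal charge and alpha from the
    peak height.  Returns (BoltzmannParams, Clin, FitDiagnostics); raises
    :class:`FitError` on degenerate input or non-convergence, with the
    last iterate attached.
    """
    V = np.asarray(V, dtype=float)
    Cm = np.asarray(Cm_total, dtype=float)
    if V.size < 8:
        raise ValueError("need at least 8 points")
    if not np.all(np.diff(V) > 0):
        raise ValueError("V must be strictly increasing")
    Qmax0, Vpk0, alpha0, Clin0 = _initial_capacitance_guess(V, Cm)
    span = float(np.max(Cm) - np.min(Cm))
    if span < 1e-6 * float(np.max(np.abs(Cm))):
        raise FitError("flat capacitance curve: no non-linear component",
                       residual=0.0)

    yscale = max(span, 1e-300)   # dimensionless residuals condition gtol

    def resid(theta):
        Qmax, Vpk, alpha, Clin = theta
        p = BoltzmannParams(Qmax=abs(Qmax) + 1e-300, Vpk=Vpk,
                            alpha=abs(alpha) + 1e-300)
        return (Clin + boltzmann_nlc(V, p) - Cm) / yscale

    theta0 = np.array([Qmax0, Vpk0, alpha0, Clin0])
    scale = np.array([max(Qmax0, 1e-15), max(abs(Vpk0), 0.01),
                      max(alpha0, 1.0), max(Clin0, 1e-15)])
    sol = least_squares(resid, theta0, x_scale=scale, xtol=1e-12,
                        ftol=1e-12, gtol=1e-12, max_nfev=5000)
    Qmax, Vpk, alpha, Clin = sol.x
    Qmax, alpha = abs(Qmax), abs(alpha)
    resnorm = float(np.linalg.norm(sol.fun))
    if not sol.success or Qmax <= 0 or alpha <= 0:
        raise FitError(f"capacitance fit failed: {sol.message}",
                       residual=resnorm, last_iterate=sol.x)
    boundary = not (V[0] < Vpk < V[-1])
    diags = FitDiagnostics(converged=bool(sol.success),
                           residual_norm=resnorm, n_points=int(V.size),
                           peak_at_boundary=boundary, message=sol.message)
    return BoltzmannParams(Qmax=Qmax, Vpk=float(Vpk), alpha=alpha), \
        float(Clin), diags


def fit_charge_boltzmann(V, Q):
    """Least-squares fit of Q(V) = Q_offset + Qmax/(1+exp(-alpha(V-Vpk))).

    Returns (BoltzmannParams, Q_offset, FitDiagnostics).  Fitting the
    analytic derivative of a fitted charge curve with
    :func:`fit_capacitance_boltzmann` recovers the same parameters.
    """
    V = np.asarray(V, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if V.size < 8:
        raise ValueError("need at least 8 points")
    span = float(np.max(Q) - np.min(Q))
    if span <= 0 or span < 1e-9 * max(float(np.max(np.abs(Q))), 1e-300):
        raise FitError("flat charge curve: nothing to fit", residual=0.0)
    Qmax0 = span
    # half-rise potential as Vpk guess
    half = np.min(Q) + span / 2.0
    Vpk0 = float(V[int(np.argmin(np.abs(Q - half)))])
    # 10-90 rise width ~ 4.39/alpha
    v10 = float(V[int(np.argmin(np.abs(Q - (np.min(Q) + 0.1 * span))))])
    v90 = float(V[int(np.argmin(np.abs(Q - (np.min(Q) + 0.9 * span))))])
    width = max(abs(v90 - v10), float(V[-1] - V[0]) / 20.0)
    alpha0 = 4.39 / width
    off0 = float(np.min(Q))

    yscale = max(span, 1e-300)

    def resid(theta):
        Qmax, Vpk, alpha, off = theta
        p = BoltzmannParams(Qmax=abs(Qmax) + 1e-300, Vpk=Vpk,
                            alpha=abs(alpha) + 1e-300)
        return (off + boltzmann_charge(V, p) - Q) / yscale

    theta0 = np.array([Qmax0, Vpk0, alpha0, off0])
    scale = np.array([Qmax0, max(abs(Vpk0), 0.01), alpha0,
                      max(abs(off0), Qmax0)])
    sol = least_squares(resid, theta0, x_scale=scale, xtol=1e-12,
                        ftol=1e-12, gtol=1e-12, max_nfev=5000)
    Qmax, Vpk, alpha, off = sol.x
    Qmax, alpha = abs(Qmax), abs(alpha)
    resnorm = float(np.linalg.norm(sol.fun))
    if not sol.success or Qmax <= 0 or alpha <= 0:
        raise FitError(f"charge fit failed: {sol.message}",
                       residual=resnorm, last_iterate=sol.x)
    diags = FitDiagnostics(converged=bool(sol.success),
                           residual_norm=resnorm, n_points=int(V.size),
                           peak_at_boundary=not (V[0] < Vpk < V[-1]),
                           message=sol.message)
    return BoltzmannParams(Qmax=Qmax, Vpk=float(Vpk), alpha=alpha), \
        float(off), diags


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def cell_surface_area(length, diameter, include_caps: bool = False):
    """Cylinder surface area of an outer hair cell (micrometer inputs ->
    micrometer^2; any consistent length unit works).

    The default is the lateral wall only, pi*d*L — the lateral membrane
    dominates the electromotile surface; ``include_caps`` adds the two
    end caps (pi*d^2/4 each).
    """
    if length <= 0 or diameter <= 0:
        raise ValueError("length and diameter must be positive")
    area = math.pi * diameter * length
    if include_caps:
        area += math.pi * diameter ** 2 / 2.0
    return area
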