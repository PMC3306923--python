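"""One-compartment oral pharmacokinetics and the reverse-dosimetry inversion.

The forward model is first-order absorption into, and first-order elimination
from, a single body compartment after an oral bolus at time ``t0``:

    dG/dt = -k_a G        (gut amount, G(0) = dose)
    dB/dt =  k_a G - k_e B (body amount)
    dU/dt =  f_u k_e B     (urinary metabolite, molar 1:1 with parent)

which integrates to the closed-form cumulative urinary excretion per unit
parent dose

    M(tau) = f_u * [1 - (k_a e^{-k_e tau} - k_e e^{-k_a tau}) / (k_a - k_e)]

with ``tau`` hours since the bolus.  ``M`` rises monotonically from 0 to
``f_u``, the fraction of the absorbed parent dose ultimately excreted in
urine as the measured metabolite.

Reverse dosimetry inverts this: the average urinary excretion rate observed
between two voids is linear in the absorbed dose, so the dose is the observed
rate divided by the unit-dose rate over the same window.

Canonical units throughout: µmol, L, hours, kg.  All times are on a
continuous study clock (hours since midnight of day 1, so day-2 07:00 = 31).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, IntervalError, NonIdentifiableError

__all__ = [
    "PKParameters",
    "DoseEstimate",
    "body_burden",
    "cumulative_excreted",
    "unit_uer_avg",
    "invert_dose",
    "simulate_uer_profile",
    "peak_time",
    "MW_CHLORPYRIFOS",
    "MW_TCPY",
]

MW_CHLORPYRIFOS = 350.59  # g/mol, parent insecticide
MW_TCPY = 198.42  # g/mol, urinary metabolite 3,5,6-trichloro-2-pyridinol

# Relative perturbation used to lift the removable k_a == k_e singularity.
_KA_KE_EPS = 1e-9


@dataclass(frozen=True)
class PKParameters:
    """Kinetic constants that fully determine the unit-dose excretion curve.

    Parameters
    ----------
    t_half_elim : float
        Elimination half-life of the body compartment, hours.  Default 16 h,
        the conventional biological half-life of orally ingested chlorpyrifos.
    k_a : float
        First-order absorption rate constant, 1/h.  Default 1.386/h, i.e. a
        30-minute absorption half-time typical of a dietary bolus.
    f_u : float
        Fraction of the absorbed parent dose excreted in urine as the
        metabolite, in (0, 1].  Default 0.7, the conventional value for
        chlorpyrifos -> TCPy; it cancels out of ratio-based checks.
    mw_parent, mw_metabolite : float
        Molar masses (g/mol) of parent and metabolite.  Reported doses are
        parent-equivalents, so only ``mw_parent`` enters the mass conversion.
    """

    t_half_elim: float = 16.0
    k_a: float = 1.386
    f_u: float = 0.7
    mw_parent: float = MW_CHLORPYRIFOS
    mw_metabolite: float = MW_TCPY

    def __post_init__(self):
        if not (self.t_half_elim > 0 and math.isfinite(self.t_half_elim)):
            raise DomainError("t_half_elim must be positive and finite")
        if not (self.k_a > 0 and math.isfinite(self.k_a)):
            raise DomainError("k_a must be positive and finite")
        if not (0 < self.f_u <= 1):
            raise DomainError("f_u must lie in (0, 1]")
        if self.mw_parent <= 0 or self.mw_metabolite <= 0:
            raise DomainError("molar masses must be positive")

    @property
    def k_e(self) -> float:
        """Elimination rate constant ln2 / t_half, 1/h."""
        return math.log(2.0) / self.t_half_elim

    @property
    def k_a_eff(self) -> float:
        """Absorption constant, epsilon-perturbed away from k_e when equal."""
        ke = self.k_e
        if abs(self.k_a - ke) <= _KA_KE_EPS * max(self.k_a, ke):
            return ke * (1.0 + _KA_KE_EPS)
        return self.k_a


@dataclass(frozen=True)
class DoseEstimate:
    """One reconstructed absorbed dose for one void of one subject-period.

    ``dose`` is µg of parent compound per kg body weight, attributed to the
    single bolus at ``exposure_time`` and reported per day.
    """

    dose: float  # µg/kg/day
    slot: int | None = None
    exposure_time: float | None = None  # study-clock hours
    subject_period: object | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (math.isfinite(self.dose) and self.dose >= 0):
            raise DomainError("dose must be finite and non-negative")


def body_burden(params: PKParameters, tau):
    """Body-compartment amount per unit absorbed dose, tau hours post bolus.

    B(tau) = k_a/(k_a-k_e) * (e^{-k_e tau} - e^{-k_a tau});  B < 0 never.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise DomainError("tau must be non-negative")
    ka, ke = params.k_a_eff, params.k_e
    b = ka / (ka - ke) * (np.exp(-ke * tau_arr) - np.exp(-ka * tau_arr))
    return float(b) if tau_arr.ndim == 0 else b


def cumulative_excreted(params: PKParameters, tau):
    """Cumulative urinary metabolite excreted per unit parent dose by tau.

    Monotone non-decreasing, M(0) = 0, M(inf) = f_u.  Accepts scalars or
    arrays of hours since the bolus.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise DomainError("tau must be non-negative")
    ka, ke, fu = params.k_a_eff, params.k_e, params.f_u
    m = fu * (1.0 - (ka * np.exp(-ke * tau_arr) - ke * np.exp(-ka * tau_arr)) / (ka - ke))
    # clip stray negative rounding at tau ~ 0
    m = np.clip(m, 0.0, fu)
    return float(m) if tau_arr.ndim == 0 else m


def unit_uer_avg(params: PKParameters, t0: float, t_p: float, t_c: float) -> float:
    """Window-averaged urinary excretion rate per unit absorbed dose.

    Averages the unit-dose excretion curve over the void window
    ``(t_p, t_c)`` on the study clock, with the bolus at ``t0``.  The window
    may start before the exposure; contributions before ``t0`` are zero.
    Units: metabolite moles per parent mole per hour.
    """
    if not t_c > t_p:
        raise IntervalError(f"void window must have t_c > t_p (got {t_p} .. {t_c})")
    hi = cumulative_excreted(params, max(t_c - t0, 0.0))
    lo = cumulative_excreted(params, max(t_p - t0, 0.0))
    return (hi - lo) / (t_c - t_p)


def invert_dose(
    observed,
    params: PKParameters,
    t0: float,
    body_weight: float,
    *,
    slot: int | None = None,
    subject_period=None,
) -> DoseEstimate:
    """Reconstruct the absorbed dose from an observed average excretion rate.

    Parameters
    ----------
    observed
        A :class:`~spkdose.study_io.UERRecord` (preferred) or a bare
        ``(uer_avg, t_p, t_c)`` tuple; ``uer_avg`` in µmol/h on the study
        clock window ``(t_p, t_c)``.
    t0 : float
        Study-clock time of the oral bolus the window is attributed to.
    body_weight : float
        kg, used to normalise the reported dose.

    Returns
    -------
    DoseEstimate
        µg of parent per kg per day.  The inversion is linear in the
        observed rate, so an observed rate of zero maps to dose zero.

    Raises
    ------
    NonIdentifiableError
        If the window lies entirely before the exposure, where the unit-dose
        rate is zero and no dose is identifiable.
    """
    if hasattr(observed, "uer_avg"):
        uer, t_p, t_c = observed.uer_avg, observed.t_p, observed.t_c
    else:
        uer, t_p, t_c = observed
    if uer < 0:
        raise DomainError("observed uer_avg must be non-negative")
    if body_weight <= 0:
        raise DomainError("body_weight must be positive")
    denom = unit_uer_avg(params, t0, t_p, t_c)
    if denom <= 0.0:
        raise NonIdentifiableError(
            f"window ({t_p}, {t_c}) precedes the exposure at t0={t0}; dose not identifiable"
        )
    dose_umol = uer / denom  # metabolite µmol map 1:1 to parent µmol; f_u is inside M
    dose_ug_per_kg = dose_umol * params.mw_parent / body_weight  # µmol * g/mol = µg
    return DoseEstimate(
        dose=dose_ug_per_kg, slot=slot, exposure_time=t0, subject_period=subject_period
    )


def simulate_uer_profile(params: PKParameters, dose_ug: float, t0: float, times) -> np.ndarray:
    """Instantaneous urinary excretion rate (µmol/h) on a time grid.

    rate(t) = dose_µmol * f_u * k_e * B(t - t0), zero before the bolus.
    The trapezoid integral of the returned curve converges to
    ``f_u * dose_µmol * M(T)`` as the grid refines.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise DomainError("time grid must be 1-D with at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise DomainError("time grid must be strictly increasing")
    if dose_ug < 0:
        raise DomainError("dose must be non-negative")
    dose_umol = dose_ug / params.mw_parent
    tau = np.maximum(t - t0, 0.0)
    rate = dose_umol * params.f_u * params.k_e * body_burden(params, tau)
    rate[t < t0] = 0.0
    return rate


def peak_time(params: PKParameters) -> float:
    """Hours after the bolus at which the excretion rate peaks:
    ln(k_a/k_e) / (k_a - k_e)."""
    ka, ke = params.k_a_eff, params.k_e
    return math.log(ka / ke) / (ka - ke)
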