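"""Population-pharmacokinetic models for pyrazinamide and rifampicin.

Both drugs are described by one-compartment disposition models with
transit-compartment absorption.  Disposition parameters (clearance-type
and volume-type) are allometrically scaled to fat-free mass.  Pyrazinamide
is eliminated by a first-order process; rifampicin by a saturable
(Michaelis-Menten) process whose maximal capacity doubles once
autoinduction is complete (after roughly two weeks of daily dosing).

Between-subject variability (BSV) enters as log-normal random effects on
clearance (or ``vmax``), bioavailability, the absorption rate constant
``ka`` and the absorption mean transit time ``mtt``.

The linear model has a closed-form single-dose solution in terms of the
regularised lower incomplete gamma function; steady state is obtained by
superposition of single-dose profiles.  The saturable model is integrated
numerically, repeating dosing intervals until the trough has converged.
All prediction routines are vectorised over individuals, which is what
makes Monte-Carlo threshold simulation cheap.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import gammainc, gammaln

__all__ = [
    "PatientCovariates",
    "DrugModelSpec",
    "IndividualParameters",
    "DosingRegimen",
    "fat_free_mass",
    "scale_parameters",
    "sample_individual",
    "transit_input_rate",
    "concentration_linear",
    "concentration_saturable",
    "concentration_history_linear",
    "concentration_history_saturable",
    "elimination_capacity",
]

SEX_LEVELS = ("male", "female")

# Sex-specific constants of the BMI-parameterised fat-free-mass formula:
# FFM = c1 * weight / (c2 + c3 * BMI)
_FFM_CONSTANTS = {
    "male": (9270.0, 6680.0, 216.0),
    "female": (9270.0, 8780.0, 244.0),
}

_BSV_KEYS_LINEAR = frozenset({"clearance", "bioavailability", "ka", "mtt"})
_BSV_KEYS_SATURABLE = frozenset({"vmax", "bioavailability", "ka", "mtt"})


@dataclass(frozen=True)
class PatientCovariates:
    """Covariates needed for allometric scaling: weight (kg), height (m), sex."""

    weight: float
    height: float
    sex: str

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise ValueError(f"weight must be positive, got {self.weight}")
        if not (self.height > 0):
            raise ValueError(f"height must be positive, got {self.height}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")


def fat_free_mass(cov: PatientCovariates) -> float:
    """Fat-free mass (kg) from weight, height and sex.

    Uses the BMI-parameterised form ``FFM = c1*W / (c2 + c3*BMI)`` with
    sex-specific constants (male: 9270, 6680, 216; female: 9270, 8780, 244),
    where ``BMI = weight / height**2``.  The result is strictly below body
    weight for physiological inputs.
    """
    c1, c2, c3 = _FFM_CONSTANTS[cov.sex]
    bmi = cov.weight / cov.height**2
    return c1 * cov.weight / (c2 + c3 * bmi)


@dataclass(frozen=True)
class DrugModelSpec:
    """Structural and stochastic parameters of one drug's PK model.

    Parameters
    ----------
    drug
        Drug name, e.g. ``"pyrazinamide"`` or ``"rifampicin"``.
    elimination
        ``"first-order"`` (parameterised by ``clearance`` L/h) or
        ``"michaelis-menten"`` (parameterised by ``vmax`` mg/h pre-induction
        and ``km`` mg/L).
    volume
        Central volume of distribution (L) at the reference fat-free mass.
    mtt, n_transit, ka
        Absorption mean transit time (h), number of transit compartments
        (gamma-function form, so non-integer values are accepted) and
        first-order absorption rate constant (1/h) from the last transit
        (depot) compartment into the central compartment.
    bioavailability
        Typical oral bioavailable fraction.
    induction_fold
        Ratio of fully induced to pre-induction elimination capacity
        (1 for non-inducing drugs; 2 for rifampicin).
    bsv
        Log-normal variances (omega^2) keyed exactly by
        {``clearance``|``vmax``, ``bioavailability``, ``ka``, ``mtt``}.
    reference_ffm
        Fat-free mass (kg) at which the typical values apply.
    clearance_exponent, volume_exponent
        Allometric exponents (0.75 and 1.0).
    """

    drug: str
    elimination: str
    volume: float
    mtt: float
    n_transit: float
    ka: float
    bsv: dict[str, float]
    reference_ffm: float
    clearance: float | None = None
    vmax: float | None = None
    km: float | None = None
    bioavailability: float = 1.0
    induction_fold: float = 1.0
    clearance_exponent: float = 0.75
    volume_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.elimination not in ("first-order", "michaelis-menten"):
            raise ValueError(f"unknown elimination kind {self.elimination!r}")
        if self.elimination == "first-order":
            if self.clearance is None or self.clearance < 0:
                raise ValueError("first-order elimination needs clearance >= 0")
            expected = _BSV_KEYS_LINEAR
        else:
            if self.vmax is None or self.km is None or self.vmax < 0 or self.km <= 0:
                raise ValueError("michaelis-menten elimination needs vmax >= 0 and km > 0")
            expected = _BSV_KEYS_SATURABLE
        if set(self.bsv) != expected:
            raise ValueError(
                f"bsv keys must be exactly {sorted(expected)}, got {sorted(self.bsv)}"
            )
        for key, omega2 in self.bsv.items():
            if omega2 < 0:
                raise ValueError(f"bsv variance for {key} must be >= 0, got {omega2}")
        for name in ("volume", "mtt", "ka", "bioavailability", "reference_ffm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_transit < 0:
            raise ValueError("n_transit must be >= 0")
        if self.induction_fold < 1:
            raise ValueError("induction_fold must be >= 1")


@dataclass
class IndividualParameters:
    """Realised PK parameters for one or more (virtual) individuals.

    Fields are scalars or equally shaped arrays; prediction functions
    broadcast over them.  ``clearance`` holds CL (L/h) for first-order
    drugs and pre-induction ``vmax`` (mg/h) for Michaelis-Menten drugs.
    """

    elimination: str
    clearance: np.ndarray
    volume: np.ndarray
    ka: np.ndarray
    mtt: np.ndarray
    bioavailability: np.ndarray
    n_transit: float
    km: float | None = None
    induction_fold: float = 1.0

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("clearance", "volume", "ka", "mtt", "bioavailability"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            arrays[name] = arr
        shapes = {a.shape for a in arrays.values()}
        if len(shapes) != 1:
            raise ValueError(f"parameter arrays must share one shape, got {shapes}")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)

    @property
    def n(self) -> int:
        return self.clearance.size


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: amount (mg) per administration every ``interval`` h."""

    dose_amount: float | np.ndarray
    interval: float = 24.0
    n_doses_to_steady_state: int | str = "auto"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.dose_amount) < 0):
            raise ValueError("dose_amount must be >= 0")
        if self.interval <= 0:
            raise ValueError("interval must be positive")


def scale_parameters(spec: DrugModelSpec, ffm: float | np.ndarray) -> dict[str, np.ndarray]:
    """Typical parameter values scaled allometrically to a fat-free mass.

    Clearance-type parameters (CL or vmax) scale with
    ``(ffm / reference_ffm) ** 0.75``; volume scales linearly.  Absorption
    parameters and bioavailability are size-independent.
    """
    ffm = np.asarray(ffm, dtype=float)
    if np.any(ffm <= 0):
        raise ValueError("ffm must be positive")
    size_cl = (ffm / spec.reference_ffm) ** spec.clearance_exponent
    size_v = (ffm / spec.reference_ffm) ** spec.volume_exponent
    capacity = spec.clearance if spec.elimination == "first-order" else spec.vmax
    return {
        "clearance": capacity * size_cl,
        "volume": spec.volume * size_v,
        "ka": np.broadcast_to(np.asarray(spec.ka, float), ffm.shape).copy()
        if ffm.shape
        else np.asarray(spec.ka, float),
        "mtt": np.broadcast_to(np.asarray(spec.mtt, float), ffm.shape).copy()
        if ffm.shape
        else np.asarray(spec.mtt, float),
        "bioavailability": np.broadcast_to(
            np.asarray(spec.bioavailability, float), ffm.shape
        ).copy()
        if ffm.shape
        else np.asarray(spec.bioavailability, float),
    }


def sample_individual(
    spec: DrugModelSpec,
    ffm: float | np.ndarray,
    rng: np.random.Generator,
    n: int | None = None,
) -> IndividualParameters:
    """Draw individual parameters: scaled typical value times ``exp(eta)``.

    ``eta ~ Normal(0, omega^2)`` independently for clearance (or vmax),
    bioavailability, ka and mtt.  ``ffm`` may be a scalar (with ``n`` draws
    sharing it) or an array of per-individual fat-free masses.
    """
    ffm = np.asarray(ffm, dtype=float)
    if n is None:
        n = ffm.size if ffm.ndim else 1
    if ffm.ndim and ffm.size != n:
        raise ValueError("ffm array length must equal n")
    typ = scale_parameters(spec, np.broadcast_to(ffm, (n,)))
    cap_key = "clearance" if spec.elimination == "first-order" else "vmax"
    etas = {
        key: rng.normal(0.0, np.sqrt(spec.bsv[key]), size=n)
        for key in (cap_key, "bioavailability", "ka", "mtt")
    }
    return IndividualParameters(
        elimination=spec.elimination,
        clearance=typ["clearance"] * np.exp(etas[cap_key]),
        volume=typ["volume"],
        ka=typ["ka"] * np.exp(etas["ka"]),
        mtt=typ["mtt"] * np.exp(etas["mtt"]),
        bioavailability=typ["bioavailability"] * np.exp(etas["bioavailability"]),
        n_transit=spec.n_transit,
        km=spec.km,
        induction_fold=spec.induction_fold,
    )


def elimination_capacity(ind: IndividualParameters, induced: bool) -> np.ndarray:
    """Maximal elimination capacity: CL (L/h) or vmax (mg/h), with induction."""
    fold = ind.induction_fold if induced else 1.0
    return ind.clearance * fold


def transit_input_rate(
    t: float | np.ndarray,
    dose: float | np.ndarray,
    ind: IndividualParameters,
    n_transit: float | None = None,
) -> np.ndarray:
    """Drug input rate (mg/h) of the transit-compartment absorption chain.

    ``rate = F * dose * ktr * (ktr*t)**n * exp(-ktr*t) / n!`` with
    ``ktr = (n+1)/mtt``; ``n!`` is ``gamma(n+1)`` so non-integer ``n`` is
    allowed.  Evaluated in log-space for numerical stability.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    n = float(ind.n_transit if n_transit is None else n_transit)
    ktr = (n + 1.0) / ind.mtt
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rate = (
            np.log(ind.bioavailability * np.asarray(dose, float) * ktr)
            + n * np.log(ktr * t)
            - ktr * t
            - gammaln(n + 1.0)
        )
    rate = np.exp(log_rate)
    # t == 0 with n > 0 gives 0 * log(0); with n == 0 the rate is F*dose*ktr.
    rate = np.where(np.isnan(rate), 0.0, rate)
    return np.where(np.asarray(dose, float) == 0.0, 0.0, rate)


def _single_dose_amount_linear(
    ind: IndividualParameters, dose: float | np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Central amount (mg) at times ``t`` after one oral dose, first-order drug.

    Closed form: the transit chain delivers a gamma-shaped input into a
    depot that empties into the central compartment at rate ``ka``.
    With ``k = CL/V`` and ``ktr = (n+1)/mtt``,

        A(t) = F*D*ka/(ka-k) * [g(k, t) - g(ka, t)],
        g(lam, t) = (ktr/(ktr-lam))**(n+1) * exp(-lam*t) * P(n+1, (ktr-lam)*t),

    where P is the regularised lower incomplete gamma function.  Requires
    ``ktr > max(k, ka)``, i.e. transit through absorption is faster than
    both downstream rate constants (true for these drugs by a wide margin).
    Broadcasts individual-parameter arrays against ``t``.
    """
    k = (ind.clearance / ind.volume)[..., None]
    ka = ind.ka[..., None]
    ktr = ((ind.n_transit + 1.0) / ind.mtt)[..., None]
    n1 = ind.n_transit + 1.0
    t = np.asarray(t, dtype=float)[None, :]
    if np.any(ktr <= 1.0000001 * k):
        raise FloatingPointError(
            "transit rate constant must exceed CL/V for the closed-form "
            "solution; check mtt/n_transit configuration"
        )
    # Guard the removable singularity at ka == k.
    ka = np.where(np.abs(ka - k) < 1e-10 * k, ka * (1.0 + 1e-8), ka)

    def g(lam: np.ndarray, valid: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            log_pref = np.where(
                valid, n1 * (np.log(ktr) - np.log(np.abs(ktr - lam))) - lam * t, -np.inf
            )
            inc = gammainc(n1, np.where(valid, (ktr - lam) * t, 0.0))
        return np.exp(log_pref) * inc

    # The ka-term of the convolution needs ktr > ka for the incomplete-gamma
    # representation.  Where a BSV draw violates that, the term itself is
    # below machine precision whenever exp(-ka*t) is (ka > ktr implies a
    # fast-absorbing individual), so it is dropped there; other cases are a
    # genuine configuration error.
    ka_valid = ktr > 1.0000001 * ka
    negligible = (ka * t > 45.0) | (np.broadcast_to(t, np.broadcast_shapes(ka.shape, t.shape)) == 0.0)
    if np.any(~ka_valid & ~negligible):
        raise FloatingPointError(
            "closed-form linear solution invalid: ka exceeds the transit "
            "rate constant at a time where its term is not negligible"
        )
    fd = (ind.bioavailability * np.asarray(dose, float))[..., None] * np.ones_like(t)
    return fd * ka / (ka - k) * (g(k, np.ones_like(ka_valid)) - g(ka, ka_valid))


def concentration_linear(
    ind: IndividualParameters,
    regimen: DosingRegimen,
    times_after_last_dose: np.ndarray | list[float],
    ss_tol: float = 1e-6,
    max_doses: int = 1000,
) -> np.ndarray:
    """Steady-state concentrations (mg/L) for a first-order drug.

    Superposes single-dose profiles over preceding doses until the added
    term is below ``ss_tol`` of the running sum (or ``max_doses`` reached).
    Returns an array of shape ``(n_individuals, n_times)``.
    """
    if ind.elimination != "first-order":
        raise ValueError("concentration_linear requires a first-order drug model")
    times = np.atleast_1d(np.asarray(times_after_last_dose, dtype=float))
    if np.any(times < 0):
        raise ValueError("times after last dose must be >= 0")
    tau = regimen.interval
    dose = np.broadcast_to(np.asarray(regimen.dose_amount, float), (ind.n,))
    total = np.zeros((ind.n, times.size))
    for j in range(max_doses):
        term = _single_dose_amount_linear(ind, dose, times + j * tau)
        total += term
        if j >= 1 and np.all(term <= ss_tol * np.maximum(total, 1e-300)):
            break
    else:
        raise FloatingPointError(
            f"steady-state superposition did not converge in {max_doses} doses"
        )
    return total / ind.volume[..., None]


def concentration_history_linear(
    ind: IndividualParameters,
    dose_amount: float,
    dose_times_h: np.ndarray,
    sample_times_h: np.ndarray | list[float],
) -> np.ndarray:
    """Concentrations (mg/L) for one individual given explicit dose times.

    Superposes single-dose profiles of the doses actually taken; doses at
    or after a sample time contribute nothing to it.
    """
    if ind.n != 1:
        raise ValueError("history simulation expects a single individual")
    sample = np.atleast_1d(np.asarray(sample_times_h, dtype=float))
    dose_times = np.asarray(dose_times_h, dtype=float)
    conc = np.zeros(sample.size)
    for i, ts in enumerate(sample):
        dt = ts - dose_times[dose_times < ts]
        if dt.size:
            conc[i] = _single_dose_amount_linear(ind, dose_amount, dt).sum() / ind.volume[0]
    return conc


def _saturable_rhs_factory(
    ind: IndividualParameters, dose: np.ndarray, vmax: np.ndarray
):
    """Right-hand side of the depot+central system for a batch of individuals."""
    ka = ind.ka
    volume = ind.volume
    km = ind.km
    n_ind = ind.n

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        depot = y[:n_ind]
        central = y[n_ind:]
        rate_in = transit_input_rate(t, dose, ind)
        conc = np.maximum(central, 0.0) / volume
        elim = vmax * conc / (km + conc)
        return np.concatenate([rate_in - ka * depot, ka * depot - elim])

    return rhs


def _integrate_interval(
    rhs,
    y0: np.ndarray,
    t_end: float,
    rtol: float,
    dense: bool = False,
    t_eval: np.ndarray | None = None,
):
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="DOP853",
        rtol=rtol,
        atol=1e-10,
        dense_output=dense,
        t_eval=t_eval,
    )
    if not sol.success:
        raise FloatingPointError(f"ODE integration failed: {sol.message}")
    return sol


def _slice_individuals(ind: IndividualParameters, idx: np.ndarray) -> IndividualParameters:
    return IndividualParameters(
        elimination=ind.elimination,
        clearance=ind.clearance[idx],
        volume=ind.volume[idx],
        ka=ind.ka[idx],
        mtt=ind.mtt[idx],
        bioavailability=ind.bioavailability[idx],
        n_transit=ind.n_transit,
        km=ind.km,
        induction_fold=ind.induction_fold,
    )


def concentration_saturable(
    ind: IndividualParameters,
    regimen: DosingRegimen,
    times_after_last_dose: np.ndarray | list[float],
    induced: bool = True,
    trough_tol: float = 1e-3,
    rtol: float = 1e-8,
    max_intervals: int = 400,
) -> np.ndarray:
    """Steady-state concentrations (mg/L) for a Michaelis-Menten drug.

    Integrates repeated dosing intervals until the trough changes by less
    than ``trough_tol`` (relative) between successive intervals for every
    individual, then integrates one final post-dose stretch out to
    ``max(times)`` (no further doses) and evaluates the requested times.
    ``induced=True`` multiplies ``vmax`` by the induction fold (the default:
    the study simulates at full autoinduction / steady state).
    """
    if ind.elimination != "michaelis-menten":
        raise ValueError("concentration_saturable requires a michaelis-menten model")
    times = np.atleast_1d(np.asarray(times_after_last_dose, dtype=float))
    if np.any(times < 0):
        raise ValueError("times after last dose must be >= 0")
    tau = regimen.interval
    dose = np.broadcast_to(np.asarray(regimen.dose_amount, float), (ind.n,)).astype(float)
    vmax = elimination_capacity(ind, induced)
    intake = ind.bioavailability * dose / tau
    if np.any(intake >= 0.95 * vmax):
        worst = int(np.argmax(intake / vmax))
        raise FloatingPointError(
            "no steady state: average intake rate "
            f"({intake[worst]:.3g} mg/h) reaches the maximal elimination "
            f"capacity ({vmax[worst]:.3g} mg/h) for at least one individual; "
            "drug accumulates without bound under these parameters"
        )

    # Dose-to-steady-state, freezing individuals once their own trough has
    # converged so a few slowly accumulating draws (intake close to the
    # elimination capacity) do not keep the whole batch integrating.
    depot = np.zeros(ind.n)
    central = np.zeros(ind.n)
    prev_trough = np.full(ind.n, np.inf)
    active = np.arange(ind.n)
    for _ in range(max_intervals):
        sub = _slice_individuals(ind, active)
        rhs = _saturable_rhs_factory(sub, dose[active], vmax[active])
        y0 = np.concatenate([depot[active], central[active]])
        sol = _integrate_interval(rhs, y0, tau, rtol, t_eval=np.array([tau]))
        depot[active] = sol.y[: len(active), -1]
        central[active] = sol.y[len(active):, -1]
        trough = central[active] / ind.volume[active]
        denom = np.maximum(np.abs(trough), 1e-12)
        still = np.abs(trough - prev_trough[active]) > trough_tol * denom
        prev_trough[active] = trough
        active = active[still]
        if active.size == 0:
            break
    else:
        raise FloatingPointError(
            f"trough did not reach steady state in {max_intervals} intervals"
        )
    rhs = _saturable_rhs_factory(ind, dose, vmax)
    order = np.argsort(times)
    sol = _integrate_interval(
        rhs,
        np.concatenate([depot, central]),
        float(times.max()) + 1e-9,
        rtol,
        t_eval=times[order],
    )
    amounts = np.empty((ind.n, times.size))
    amounts[:, order] = sol.y[ind.n:, :]
    return np.maximum(amounts, 0.0) / ind.volume[..., None]


def concentration_history_saturable(
    ind: IndividualParameters,
    dose_amounts: np.ndarray,
    taken: np.ndarray,
    sample_times_h: list[tuple[int, float]],
    sample_days: list[int] | None = None,
    induction_day: float = 14.0,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Concentrations for a batch of individuals under explicit dosing histories.

    Parameters
    ----------
    dose_amounts
        Daily dose (mg) per individual, shape ``(n,)``.
    taken
        Boolean dose-taken matrix, shape ``(n, n_days)``; day ``d`` doses are
        administered at ``24*d`` hours.
    sample_times_h
        List of ``(individual_index, absolute_time_h)`` requests.
    sample_days
        Visit day of each request.  A request landing inside its own visit
        day is evaluated from a trajectory *without* that day's dose (the
        sample is drawn before the participant takes it); a request landing
        in the previous day (negative sampling jitter) sees that day's dose
        normally.  ``None`` means no same-day exclusion.
    induction_day
        Elimination capacity is pre-induction before this day and fully
        induced (``vmax * induction_fold``) from it onward, as a step; the
        study's thresholds assume full induction throughout, but histories
        start at treatment initiation.

    Returns one concentration (mg/L) per request, in order.
    """
    if ind.elimination != "michaelis-menten":
        raise ValueError("history simulation requires a michaelis-menten model")
    taken = np.asarray(taken, dtype=bool)
    n_ind, n_days = taken.shape
    if n_ind != ind.n:
        raise ValueError("taken matrix rows must match number of individuals")
    dose_amounts = np.asarray(dose_amounts, dtype=float)
    if sample_days is None:
        sample_days = [-1] * len(sample_times_h)
    by_day: dict[int, list[int]] = {}
    for idx, (_, t_abs) in enumerate(sample_times_h):
        by_day.setdefault(int(np.floor(t_abs / 24.0)), []).append(idx)
    out = np.zeros(len(sample_times_h))
    last_needed = max((t for _, t in sample_times_h), default=0.0)
    n_days_needed = min(n_days, int(np.floor(last_needed / 24.0)) + 1)
    if by_day and max(by_day) >= n_days:
        raise ValueError("sample time beyond the simulated dosing history")

    y = np.zeros(2 * n_ind)
    for day in range(n_days_needed):
        dose_today = dose_amounts * taken[:, day]
        vmax = ind.clearance * (ind.induction_fold if day >= induction_day else 1.0)
        rhs = _saturable_rhs_factory(ind, dose_today, vmax)
        todays = by_day.get(day, [])
        pre_dose = [i for i in todays if sample_days[i] == day]
        post_dose = [i for i in todays if sample_days[i] != day]
        t0 = 24.0 * day
        if pre_dose:
            rhs_nodose = _saturable_rhs_factory(ind, np.zeros(n_ind), vmax)
            sol_pre = _integrate_interval(rhs_nodose, y, 24.0, rtol, dense=True)
            for idx in pre_dose:
                who, t_abs = sample_times_h[idx]
                out[idx] = max(sol_pre.sol(t_abs - t0)[n_ind + who], 0.0) / ind.volume[who]
        sol = _integrate_interval(rhs, y, 24.0, rtol, dense=bool(post_dose))
        for idx in post_dose:
            who, t_abs = sample_times_h[idx]
            out[idx] = max(sol.sol(t_abs - t0)[n_ind + who], 0.0) / ind.volume[who]
        y = sol.y[:, -1]
    return out
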