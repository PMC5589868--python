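"""Bulk-optode ion-exchange equilibrium model.

An ion-selective optode contains three lipophilic components in a hydrophobic
matrix: a chromoionophore ``C`` (a fluorescent pH indicator), an ionophore
``I`` that selectively binds the analyte ion ``M^{z+}``, and a cation
exchanger ``R^-`` that fixes the total extractable positive charge. Extraction
of the analyte into the sensor phase displaces protons from the
chromoionophore, so the protonated fraction

    alpha = [CH+] / C_T

is the optical observable. At equilibrium, electroneutrality and mass balance
give the analyte activity as a closed-form function of alpha:

    a_M(alpha) = (z K_exch)^-1 * ((1 - alpha)/alpha * a_H)^z
                 * (R_T - alpha C_T) / (I_T - (R_T - alpha C_T) n/z)^n

with ``C_T``, ``R_T``, ``I_T`` the total component concentrations in the
sensor phase, ``z`` the ion charge, ``n`` the ionophores per complexed ion,
``K_exch`` the lumped ion/proton exchange constant and ``a_H`` the aqueous
proton activity (``10^-pH``).

Throughout this package **alpha is the protonated fraction**: ``alpha = 1``
at zero analyte (fully protonated chromoionophore) and alpha falls as the
analyte is extracted. a_M(alpha) is strictly decreasing on its feasibility
domain, which makes the numerical inversion (concentration -> alpha) a
bracketed bisection on a monotone function.

Aqueous activity is equated to molar concentration by default (dilute
solution); an ``activity_coefficient`` hook on the grid-level helpers allows
scaling when that assumption is inadequate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OptodeDomainError",
    "OptodeInputError",
    "OptodeComposition",
    "EquilibriumParams",
    "ResponseCurve",
    "ion_activity_from_alpha",
    "alpha_from_ion_activity",
    "model_midpoint_concentration",
    "response_curve",
    "ph_shift_curve",
    "exchange_constant_for_midpoint",
]


class OptodeDomainError(ValueError):
    """Protonation degree outside the feasible equilibrium domain."""


class OptodeInputError(ValueError):
    """Invalid input (non-finite, negative activity, bad grid, ...)."""


@dataclass(frozen=True)
class OptodeComposition:
    """Total sensor-phase component concentrations and ion stoichiometry.

    Parameters
    ----------
    chromoionophore_total : float
        C_T, total chromoionophore (mol per unit optode volume). Any common
        unit works as long as all three totals share it; only ratios enter
        the feasibility domain, and K_exch absorbs the absolute scale.
    exchanger_total : float
        R_T, total cation exchanger (same units).
    ionophore_total : float
        I_T, total ionophore (same units).
    ion_charge : int
        z >= 1, charge of the analyte cation (2 for Ca2+).
    stoichiometry : int
        n >= 1, ionophores per complexed ion.
    """

    chromoionophore_total: float
    exchanger_total: float
    ionophore_total: float
    ion_charge: int = 2
    stoichiometry: int = 2

    def __post_init__(self) -> None:
        for name in ("chromoionophore_total", "exchanger_total", "ionophore_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise OptodeInputError(f"{name} must be strictly positive, got {v!r}")
        for name in ("ion_charge", "stoichiometry"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise OptodeInputError(f"{name} must be a positive integer, got {v!r}")
        lb, ub = self.alpha_bounds
        if not lb < ub:
            raise OptodeInputError(
                "empty protonation-degree domain: "
                f"max(0, (R_T - I_T*z/n)/C_T) = {lb:.6g} must be < "
                f"min(1, R_T/C_T) = {ub:.6g}; increase ionophore or "
                "chromoionophore relative to the exchanger"
            )

    @property
    def alpha_bounds(self) -> tuple[float, float]:
        """Open feasibility interval (lb, ub) of the protonated fraction.

        Above ``ub = min(1, R_T/C_T)`` the exchanger could not balance the
        protonated chromoionophore; below
        ``lb = max(0, (R_T - I_T z/n)/C_T)`` the free ionophore would be
        exhausted.
        """
        c, r, i = self.chromoionophore_total, self.exchanger_total, self.ionophore_total
        lb = max(0.0, (r - i * self.ion_charge / self.stoichiometry) / c)
        ub = min(1.0, r / c)
        return lb, ub

    @property
    def alpha_midpoint(self) -> float:
        lb, ub = self.alpha_bounds
        return 0.5 * (lb + ub)


@dataclass(frozen=True)
class EquilibriumParams:
    """Lumped exchange constant and aqueous proton activity.

    ``exchange_constant`` (K_exch) is treated as a single dimensionless
    input; it has no default and must be supplied or calibrated (see
    :func:`exchange_constant_for_midpoint`). ``proton_activity`` is
    ``10^-pH``.
    """

    exchange_constant: float
    proton_activity: float

    def __post_init__(self) -> None:
        for name in ("exchange_constant", "proton_activity"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise OptodeInputError(f"{name} must be strictly positive, got {v!r}")

    @classmethod
    def from_ph(cls, exchange_constant: float, ph: float) -> "EquilibriumParams":
        return cls(exchange_constant=exchange_constant, proton_activity=10.0 ** (-ph))

    @property
    def ph(self) -> float:
        return -np.log10(self.proton_activity)

    def with_ph(self, ph: float) -> "EquilibriumParams":
        return dataclasses.replace(self, proton_activity=10.0 ** (-ph))


@dataclass(frozen=True)
class ResponseCurve:
    """Protonation degree along a concentration grid, plus the model midpoint.

    ``model_ec50`` is the concentration at which alpha sits midway between
    its two endpoint (plateau) values — the model-side analogue of the
    empirical EC50 obtained later from a Hill fit.
    """

    concentrations: np.ndarray
    alpha: np.ndarray
    model_ec50: float
    ph: float | None = None


def _check_alpha_domain(alpha: np.ndarray, comp: OptodeComposition) -> None:
    lb, ub = comp.alpha_bounds
    if np.any(alpha < lb) or np.any(alpha > ub):
        bad = float(np.asarray(alpha).ravel()[np.argmax((alpha < lb) | (alpha > ub))])
        if bad < lb:
            raise OptodeDomainError(
                f"alpha={bad:.6g} below lower bound {lb:.6g}: the free ionophore "
                "I_T - (R_T - alpha*C_T)*n/z would be exhausted (ionophore constraint)"
            )
        raise OptodeDomainError(
            f"alpha={bad:.6g} above upper bound {ub:.6g}: R_T - alpha*C_T would be "
            "negative / alpha would exceed 1 (electroneutrality constraint)"
        )


def ion_activity_from_alpha(
    alpha: float | np.ndarray,
    comp: OptodeComposition,
    eq: EquilibriumParams,
) -> float | np.ndarray:
    """Analyte activity a_M in equilibrium with protonated fraction ``alpha``.

    Closed-form forward model (see module docstring). Strictly decreasing in
    alpha. The closed endpoints are exact: ``alpha == ub`` returns 0 (zero-ion
    endpoint) and ``alpha == lb`` (when lb > 0) returns ``inf`` (ionophore
    saturation).

    Raises
    ------
    OptodeDomainError
        If alpha lies outside [lb, ub]; the message names the violated
        constraint.
    """
    a = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(a)):
        raise OptodeInputError("alpha must be finite")
    _check_alpha_domain(a, comp)

    z = comp.ion_charge
    n = comp.stoichiometry
    excess = comp.exchanger_total - a * comp.chromoionophore_total  # R_T - alpha C_T
    free_ionophore = comp.ionophore_total - excess * (n / z)
    with np.errstate(divide="ignore", invalid="ignore"):
        proton_term = ((1.0 - a) / a) * eq.proton_activity
        act = (
            (1.0 / (z * eq.exchange_constant))
            * proton_term**z
            * excess
            / free_ionophore**n
        )
    # alpha == ub: either (1-a)/a == 0 (ub == 1) or excess == 0 (ub == R/C);
    # both give an exact 0 except for the 0*inf corner when both hold.
    act = np.where(excess == 0.0, 0.0, act)
    act = np.where((a == 1.0) & (excess >= 0.0), 0.0, act)
    if a.ndim == 0:
        return float(act)
    return act


def alpha_from_ion_activity(
    activity: float | np.ndarray,
    comp: OptodeComposition,
    eq: EquilibriumParams,
    *,
    rtol: float = 1e-12,
    max_iter: int = 200,
) -> float | np.ndarray:
    """Invert the forward model: protonated fraction at a given ion activity.

    Bracketed bisection on the strictly monotone a_M(alpha) over (lb, ub);
    guaranteed to converge, robust arbitrarily close to the domain endpoints.
    ``activity == 0`` returns the zero-ion endpoint ``ub`` exactly.
    """
    act = np.asarray(activity, dtype=float)
    if np.any(~np.isfinite(act)) or np.any(act < 0):
        raise OptodeInputError("activity must be finite and non-negative")

    lb, ub = comp.alpha_bounds
    lo = np.full(act.shape, lb + 1e-15)
    hi = np.full(act.shape, ub)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = np.asarray(ion_activity_from_alpha(mid, comp, eq))
        above = f > act  # activity too high => alpha too low => move up
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
        if np.all(hi - lo <= rtol * np.maximum(np.abs(hi), 1e-30)):
            break
    out = 0.5 * (lo + hi)
    out = np.where(act == 0.0, ub, out)
    if act.ndim == 0:
        return float(out)
    return out


def model_midpoint_concentration(
    comp: OptodeComposition,
    eq: EquilibriumParams,
    *,
    activity_coefficient: float = 1.0,
) -> float:
    """Concentration at which alpha is midway between its plateau values.

    The midpoint alpha is ``(lb + ub)/2`` of the feasibility domain; the
    corresponding concentration follows in closed form from the forward
    model (the exact root of ``alpha(C) - alpha_mid``), divided by the
    activity coefficient to convert activity to concentration.
    """
    a_mid = comp.alpha_midpoint
    return float(ion_activity_from_alpha(a_mid, comp, eq)) / activity_coefficient


def response_curve(
    comp: OptodeComposition,
    eq: EquilibriumParams,
    conc_grid: np.ndarray,
    *,
    activity_coefficient: float = 1.0,
) -> ResponseCurve:
    """Protonation degree over a strictly increasing concentration grid."""
    grid = np.asarray(conc_grid, dtype=float)
    if grid.size == 0:
        raise OptodeInputError("concentration grid is empty")
    if np.any(grid < 0) or np.any(~np.isfinite(grid)):
        raise OptodeInputError("concentrations must be finite and non-negative")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise OptodeInputError("concentration grid must be strictly increasing")
    alpha = alpha_from_ion_activity(activity_coefficient * grid, comp, eq)
    ec50 = model_midpoint_concentration(
        comp, eq, activity_coefficient=activity_coefficient
    )
    return ResponseCurve(
        concentrations=grid, alpha=np.asarray(alpha), model_ec50=ec50, ph=eq.ph
    )


def ph_shift_curve(
    comp: OptodeComposition,
    eq: EquilibriumParams,
    ph_values,
    conc_grid: np.ndarray,
    *,
    activity_coefficient: float = 1.0,
) -> list[ResponseCurve]:
    """Family of response curves, one per pH.

    Because the proton activity enters the forward model only through the
    factor ``a_H^z``, the midpoint concentration scales as
    ``model_ec50(pH1)/model_ec50(pH2) = 10^(z (pH2 - pH1))``.
    """
    curves = []
    for ph in ph_values:
        if not (0.0 < ph < 14.0):
            raise OptodeInputError(f"pH must be in (0, 14), got {ph!r}")
        curves.append(
            response_curve(
                comp,
                eq.with_ph(ph),
                conc_grid,
                activity_coefficient=activity_coefficient,
            )
        )
    return curves


def exchange_constant_for_midpoint(
    comp: OptodeComposition,
    ph: float,
    midpoint_concentration: float,
    *,
    activity_coefficient: float = 1.0,
) -> float:
    """Solve for K_exch that places the model midpoint at a target concentration.

    The forward model is proportional to 1/K_exch at fixed alpha, so the
    solve is a single evaluation at K_exch = 1.
    """
    if midpoint_concentration <= 0:
        raise OptodeInputError("midpoint concentration must be positive")
    ref = EquilibriumParams.from_ph(1.0, ph)
    act_at_unit_k = float(ion_activity_from_alpha(comp.alpha_midpoint, comp, ref))
    return act_at_unit_k / (activity_coefficient * midpoint_concentration)
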