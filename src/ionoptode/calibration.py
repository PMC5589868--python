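"""Dose-response calibration of ratiometric optode nanosensors.

The sensor readout is the emission intensity ratio of the chromoionophore
channel (~670 nm) to the reference-dye channel (~575 nm),

    R = I_sense / I_ref.

Against acid/base endpoint standards (fully protonated / fully deprotonated
chromoionophore, ratios R_P and R_D) the ratio normalizes to the protonated
fraction

    alpha = (R - R_D) / (R_P - R_D).

Calibration series (ratio vs free-ion concentration) are fitted with the
four-parameter dose-response (Hill) model in log10 concentration,

    R(C) = R_min + (R_max - R_min) / (1 + 10^((log10 EC50 - log10 C) * p)),

whose half-maximal concentration EC50 is reported as the empirical
sensitivity index (it is NOT a binding Kd and is never labelled as one).
The slope p is signed: for these sensors the ratio falls as the ion rises,
so p < 0 and R_max is the zero-ion plateau.

Selectivity against an interfering ion is the fixed-interferent
(Nicolskii-Eisenman-style) optical selectivity coefficient

    log K = log10 EC50(interferent) - log10 EC50(primary).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationError",
    "RatioError",
    "HillFitError",
    "CalibrationSeries",
    "HillFit",
    "compute_ratio",
    "normalize_alpha",
    "hill_ratio",
    "fit_hill",
    "fit_hill_ratios",
    "selectivity_coefficient",
]


class CalibrationError(ValueError):
    """Invalid calibration input."""


class RatioError(CalibrationError):
    """Non-positive reference intensity in a ratio computation."""


class HillFitError(RuntimeError):
    """Dose-response fit failed to converge after multi-start."""


def compute_ratio(intensity_sense, intensity_ref, *, label: str = "sample"):
    """Emission intensity ratio R = I_sense / I_ref (chromoionophore : reference).

    Raises :class:`RatioError` naming the offending frame/well when the
    reference intensity is not strictly positive.
    """
    sense = np.asarray(intensity_sense, dtype=float)
    ref = np.asarray(intensity_ref, dtype=float)
    if np.any(~np.isfinite(sense)) or np.any(~np.isfinite(ref)):
        raise RatioError(f"non-finite intensity in {label}")
    bad = ref <= 0
    if np.any(bad):
        idx = int(np.argmax(np.asarray(bad).ravel()))
        raise RatioError(
            f"reference intensity <= 0 in {label} at index {idx}: "
            "cannot form the emission ratio"
        )
    out = sense / ref
    return float(out) if out.ndim == 0 else out


def normalize_alpha(ratio, ratio_protonated: float, ratio_deprotonated: float):
    """Protonated fraction from a ratio and the acid/base endpoint ratios.

    alpha = (R - R_D)/(R_P - R_D): 1 at the fully protonated (acid, zero-ion)
    endpoint, 0 at the fully deprotonated (base) endpoint. Noisy values
    slightly outside [0, 1] are returned as-is with a warning.
    """
    if ratio_protonated == ratio_deprotonated:
        raise CalibrationError(
            "degenerate endpoints: acid and base standards have the same ratio"
        )
    r = np.asarray(ratio, dtype=float)
    alpha = (r - ratio_deprotonated) / (ratio_protonated - ratio_deprotonated)
    if np.any(alpha < 0) or np.any(alpha > 1):
        warnings.warn(
            "normalized alpha outside [0, 1] (noise beyond an endpoint); "
            "values returned unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(alpha) if alpha.ndim == 0 else alpha


@dataclass
class CalibrationSeries:
    """A two-channel calibration table with acid/base endpoint standards.

    ``concentrations`` may contain repeated values (replicate wells) and may
    include 0 (ion-free chelator buffer). ``acid_endpoint``/``base_endpoint``
    are (I_sense, I_ref) pairs for the fully protonated / deprotonated
    standards.
    """

    concentrations: np.ndarray
    intensity_sense: np.ndarray
    intensity_ref: np.ndarray
    acid_endpoint: tuple[float, float]
    base_endpoint: tuple[float, float]
    replicate: np.ndarray | None = None
    label: str = "calibration"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensity_sense = np.asarray(self.intensity_sense, dtype=float)
        self.intensity_ref = np.asarray(self.intensity_ref, dtype=float)
        n = self.concentrations.size
        if self.intensity_sense.size != n or self.intensity_ref.size != n:
            raise CalibrationError("concentration and intensity columns differ in length")
        if np.any(self.concentrations < 0):
            raise CalibrationError("concentrations must be non-negative")
        for name, arr in (
            ("intensity_sense", self.intensity_sense),
            ("intensity_ref", self.intensity_ref),
        ):
            if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
                raise CalibrationError(f"{name} must be strictly positive and finite")
        for name, pair in (("acid_endpoint", self.acid_endpoint), ("base_endpoint", self.base_endpoint)):
            if len(pair) != 2 or any(v <= 0 or not np.isfinite(v) for v in pair):
                raise CalibrationError(f"{name} must be a positive (I_sense, I_ref) pair")
        if self.replicate is None:
            self.replicate = np.array(["r1"] * n)
        else:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.size != n:
                raise CalibrationError("replicate column length mismatch")

    @property
    def ratios(self) -> np.ndarray:
        return compute_ratio(self.intensity_sense, self.intensity_ref, label=self.label)

    @property
    def endpoint_ratios(self) -> tuple[float, float]:
        """(R_P, R_D): ratios of the acid and base endpoint standards."""
        r_p = compute_ratio(*self.acid_endpoint, label=f"{self.label} acid endpoint")
        r_d = compute_ratio(*self.base_endpoint, label=f"{self.label} base endpoint")
        return r_p, r_d

    @property
    def alpha(self) -> np.ndarray:
        r_p, r_d = self.endpoint_ratios
        return normalize_alpha(self.ratios, r_p, r_d)

    # --- delimited-text round trip -------------------------------------
    def to_csv(self, path, endpoints_path=None) -> None:
        """Write the series (and a companion two-row endpoints CSV)."""
        path = Path(path)
        pd.DataFrame(
            {
                "concentration_molar": self.concentrations,
                "I_sense": self.intensity_sense,
                "I_ref": self.intensity_ref,
                "replicate": self.replicate,
            }
        ).to_csv(path, index=False)
        if endpoints_path is None:
            endpoints_path = path.with_name(path.stem + "_endpoints.csv")
        pd.DataFrame(
            {
                "standard": ["acid", "base"],
                "I_sense": [self.acid_endpoint[0], self.base_endpoint[0]],
                "I_ref": [self.acid_endpoint[1], self.base_endpoint[1]],
            }
        ).to_csv(endpoints_path, index=False)

    @classmethod
    def from_csv(cls, path, endpoints_path=None, *, label=None) -> "CalibrationSeries":
        path = Path(path)
        df = pd.read_csv(path)
        required = {"concentration_molar", "I_sense", "I_ref"}
        missing = required - set(df.columns)
        if missing:
            raise CalibrationError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        if endpoints_path is None:
            endpoints_path = path.with_name(path.stem + "_endpoints.csv")
        edf = pd.read_csv(endpoints_path).set_index("standard")
        try:
            acid = (float(edf.loc["acid", "I_sense"]), float(edf.loc["acid", "I_ref"]))
            base = (float(edf.loc["base", "I_sense"]), float(edf.loc["base", "I_ref"]))
        except KeyError as exc:
            raise CalibrationError(
                f"{endpoints_path}: needs rows 'acid' and 'base' with I_sense/I_ref"
            ) from exc
        return cls(
            concentrations=df["concentration_molar"].to_numpy(),
            intensity_sense=df["I_sense"].to_numpy(),
            intensity_ref=df["I_ref"].to_numpy(),
            acid_endpoint=acid,
            base_endpoint=base,
            replicate=df["replicate"].to_numpy() if "replicate" in df else None,
            label=label or path.stem,
        )


_HILL_PARAM_NAMES = ("r_min", "r_max", "log10_ec50", "slope")


@dataclass
class HillFit:
    """Fitted four-parameter dose-response model.

    ``covariance`` (4x4, order r_min, r_max, log10_ec50, slope) comes from
    the nonlinear least squares in log10-concentration space. ``tag``
    records provenance ("in_solution" or "in_situ"); when both calibrations
    exist the in-situ one is preferred for intracellular quantification.
    """

    r_min: float
    r_max: float
    ec50: float
    slope: float
    residual_sse: float = float("nan")
    covariance: np.ndarray | None = None
    tag: str = "in_solution"
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ec50) and self.ec50 > 0):
            raise CalibrationError(f"ec50 must be positive, got {self.ec50!r}")
        if self.r_min == self.r_max:
            raise CalibrationError("r_min and r_max must differ")
        if self.slope == 0 or not np.isfinite(self.slope):
            raise CalibrationError("slope must be nonzero and finite")

    def ratio_at(self, concentration):
        """Forward dose-response model R(C) (defined for C > 0)."""
        return hill_ratio(concentration, self)

    @property
    def plateau_interval(self) -> tuple[float, float]:
        return (min(self.r_min, self.r_max), max(self.r_min, self.r_max))

    def to_json(self, path=None) -> str:
        payload = {
            "r_min": self.r_min,
            "r_max": self.r_max,
            "ec50_molar": self.ec50,
            "slope": self.slope,
            "residual_sse": self.residual_sse,
            "covariance": None
            if self.covariance is None
            else np.asarray(self.covariance).tolist(),
            "covariance_params": list(_HILL_PARAM_NAMES),
            "tag": self.tag,
            "n_points": self.n_points,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "HillFit":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        cov = payload.get("covariance")
        return cls(
            r_min=payload["r_min"],
            r_max=payload["r_max"],
            ec50=payload["ec50_molar"],
            slope=payload["slope"],
            residual_sse=payload.get("residual_sse", float("nan")),
            covariance=None if cov is None else np.asarray(cov),
            tag=payload.get("tag", "in_solution"),
            n_points=payload.get("n_points", 0),
        )


def hill_ratio(concentration, fit: HillFit):
    """Dose-response model R(C) = R_min + (R_max - R_min)/(1 + 10^((logEC50-logC) p))."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c <= 0):
        raise CalibrationError("hill_ratio requires strictly positive concentrations")
    logc = np.log10(c)
    out = fit.r_min + (fit.r_max - fit.r_min) / (
        1.0 + 10.0 ** ((np.log10(fit.ec50) - logc) * fit.slope)
    )
    return float(out) if out.ndim == 0 else out


def _hill_model(logc, r_min, r_max, logec50, p):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** ((logec50 - logc) * p))


def fit_hill_ratios(
    concentrations,
    ratios,
    *,
    zero_ion_ratio: float | None = None,
    plateau_bounds: tuple[float, float] | None = None,
    fixed_plateaus: tuple[float, float] | None = None,
    weights=None,
    tag: str = "in_solution",
) -> HillFit:
    """Nonlinear least squares of the dose-response model in log10(C).

    ``concentrations`` must be strictly positive here; the C = 0 chelator
    point has no logarithm and is passed separately as ``zero_ion_ratio`` to
    initialize the zero-ion plateau. Initialization follows standard
    dose-response practice (plateaus from observed extremes, EC50 from the
    concentration nearest the ratio midpoint) with a multi-start over both
    slope signs; the lowest-SSE converged start wins.

    ``plateau_bounds = (lo, hi)`` constrains both plateau parameters, the
    standard stabilization when the series does not reach its plateaus: the
    emission ratio is physically confined between the base and acid endpoint
    ratios, so r_min/r_max cannot wander far outside them. Without bounds a
    plateau-free series makes the four-parameter fit ill-posed.

    ``fixed_plateaus = (lo, hi)`` goes further and pins the plateaus at the
    given ratios (typically the measured endpoint-standard ratios), fitting
    only EC50 and slope — the right trade for short, noisy series such as
    stepped in-cell calibrations.
    """
    conc = np.asarray(concentrations, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if conc.size != r.size:
        raise CalibrationError("concentration/ratio length mismatch")
    if np.any(conc <= 0):
        raise CalibrationError("fit_hill_ratios requires strictly positive concentrations")
    if np.unique(conc).size < 5:
        raise CalibrationError(
            f"need >= 5 distinct nonzero concentrations, got {np.unique(conc).size}"
        )
    logc = np.log10(conc)

    r_lo, r_hi = float(np.min(r)), float(np.max(r))
    if r_hi - r_lo <= 0:
        raise CalibrationError("ratios show no response across the series")
    mid = 0.5 * (r_lo + r_hi)
    ec50_init = float(conc[np.argmin(np.abs(r - mid))])
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(w)

    starts = []
    for sign in (-1.0, +1.0):
        # zero-ion plateau: C -> 0 makes the logistic term vanish for p > 0
        # (R -> r_min) and saturate for p < 0 (R -> r_max).
        r_min0, r_max0 = r_lo, r_hi
        if zero_ion_ratio is not None:
            if sign < 0:
                r_max0 = float(zero_ion_ratio)
            else:
                r_min0 = float(zero_ion_ratio)
        starts.append((r_min0, r_max0, np.log10(ec50_init), sign))

    if fixed_plateaus is not None:
        p_lo, p_hi = sorted(fixed_plateaus)

        def model2(logc_, logec50, p):
            return _hill_model(logc_, p_lo, p_hi, logec50, p)

        best = None
        diagnostics = []
        for sign in (-1.0, +1.0):
            try:
                popt2, pcov2 = curve_fit(
                    model2,
                    logc,
                    r,
                    p0=(np.log10(ec50_init), sign),
                    sigma=sigma,
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as exc:
                diagnostics.append(f"slope sign {sign}: {exc}")
                continue
            sse = float(np.sum((r - model2(logc, *popt2)) ** 2))
            if best is None or sse < best[2]:
                best = (popt2, pcov2, sse)
        if best is None:
            raise HillFitError(
                "dose-response fit failed for all starts: " + "; ".join(diagnostics)
            )
        popt2, pcov2, sse = best
        popt = np.array([p_lo, p_hi, popt2[0], popt2[1]])
        pcov = np.zeros((4, 4))
        pcov[2:, 2:] = pcov2
    else:
        if plateau_bounds is not None:
            b_lo, b_hi = plateau_bounds
            bounds = (
                [b_lo, b_lo, np.log10(np.min(conc)) - 3.0, -6.0],
                [b_hi, b_hi, np.log10(np.max(conc)) + 3.0, 6.0],
            )
            starts = [tuple(np.clip(p0, bounds[0], bounds[1])) for p0 in starts]
        else:
            bounds = (-np.inf, np.inf)

        best = None
        diagnostics = []
        for p0 in starts:
            try:
                popt, pcov = curve_fit(
                    _hill_model, logc, r, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
                )
            except (RuntimeError, ValueError) as exc:  # non-convergence
                diagnostics.append(f"start {p0}: {exc}")
                continue
            sse = float(np.sum((r - _hill_model(logc, *popt)) ** 2))
            if best is None or sse < best[2]:
                best = (popt, pcov, sse)
        if best is None:
            raise HillFitError(
                "dose-response fit failed for all starts: " + "; ".join(diagnostics)
            )
        popt, pcov, sse = best
    # The model is invariant under (r_min <-> r_max, p -> -p); canonicalize
    # to r_max > r_min so a ratio that falls with concentration has p < 0.
    if popt[0] > popt[1]:
        popt = np.array([popt[1], popt[0], popt[2], -popt[3]])
        perm = np.array(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, -1.0]]
        )
        pcov = perm @ pcov @ perm.T
    ec50 = 10.0 ** popt[2]
    span = (float(np.min(conc)), float(np.max(conc)))
    if not (span[0] <= ec50 <= span[1]):
        warnings.warn(
            f"fitted EC50 {ec50:.3g} M lies outside the calibrated span "
            f"[{span[0]:.3g}, {span[1]:.3g}] M; treat with caution",
            RuntimeWarning,
            stacklevel=2,
        )
    return HillFit(
        r_min=float(popt[0]),
        r_max=float(popt[1]),
        ec50=float(ec50),
        slope=float(popt[3]),
        residual_sse=sse,
        covariance=pcov,
        tag=tag,
        n_points=int(conc.size),
    )


def fit_hill(
    series: CalibrationSeries,
    *,
    pooled: bool = False,
    weighted: bool = False,
    tag: str = "in_solution",
) -> HillFit:
    """Fit the dose-response model to a calibration series.

    Replicate wells at the same concentration are averaged before fitting
    (``pooled=True`` fits every well instead); ``weighted=True`` applies
    inverse-variance weights from the replicate spread. A C = 0 point, if
    present, is excluded from the regression and used only to initialize the
    zero-ion plateau. The acid/base endpoint standards bound the plateau
    parameters (with a 25%-of-span margin for noise), since the ratio of any
    intermediate protonation state lies between the endpoint ratios.
    """
    conc = series.concentrations
    ratios = np.asarray(series.ratios)
    zero_mask = conc == 0
    zero_ion_ratio = float(np.mean(ratios[zero_mask])) if np.any(zero_mask) else None
    conc_nz, ratios_nz = conc[~zero_mask], ratios[~zero_mask]
    r_p, r_d = series.endpoint_ratios
    span = abs(r_p - r_d)
    plateau_bounds = (min(r_p, r_d) - 0.25 * span, max(r_p, r_d) + 0.25 * span)

    if pooled:
        return fit_hill_ratios(
            conc_nz,
            ratios_nz,
            zero_ion_ratio=zero_ion_ratio,
            plateau_bounds=plateau_bounds,
            tag=tag,
        )
    df = pd.DataFrame({"c": conc_nz, "r": ratios_nz})
    g = df.groupby("c")["r"]
    means = g.mean()
    weights = None
    if weighted:
        var = g.var(ddof=1).fillna(0.0)
        var = var.replace(0.0, var[var > 0].min() if (var > 0).any() else 1.0)
        weights = (1.0 / var).to_numpy()
    return fit_hill_ratios(
        means.index.to_numpy(),
        means.to_numpy(),
        zero_ion_ratio=zero_ion_ratio,
        plateau_bounds=plateau_bounds,
        weights=weights,
        tag=tag,
    )


def selectivity_coefficient(ec50_interferent: float, ec50_primary: float) -> float:
    """Fixed-interferent optical selectivity coefficient, in log10 units.

    log K = log10(EC50_interferent) - log10(EC50_primary); unit-free as long
    as both EC50s share a unit. For a Ca2+ sensor with EC50 105 nM and a
    Mg2+ EC50 of 1 mM this gives 3.98, i.e. ~4 orders of magnitude of
    selectivity for calcium over magnesium.
    """
    for name, v in (("ec50_interferent", ec50_interferent), ("ec50_primary", ec50_primary)):
        if not np.isfinite(v) or v <= 0:
            raise CalibrationError(f"{name} must be strictly positive, got {v!r}")
    return float(np.log10(ec50_interferent) - np.log10(ec50_primary))
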