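"""Synthetic data with known ground truth for the full quantification chain.

Everything downstream of the equilibrium model — calibration fitting, ROI
extraction, bleach correction, ratio-to-concentration conversion — is
exercised on data generated *from* that model, so recovered quantities can
be compared against exact truth. The generator emulates:

* plate-reader calibration series over Ca2+/EGTA buffers with acid/base
  endpoint standards;
* stepped in-cell (ionomycin-equilibrated) calibration series;
* an agonist-evoked cytosolic Ca2+ transient (baseline ~100 nM rising to
  ~400 nM, then decaying back — the physiological regime these sensors are
  tuned for);
* a 100/1350 nM reversibility square wave;
* two-channel confocal-like image stacks: elliptical cells containing
  punctate nanosensor foci, per-channel exponential photobleaching,
  additive background, Poisson shot noise and Gaussian read noise.

Channel brightness is linear in the protonated/deprotonated chromoionophore
fractions with strictly positive offsets:

    I_sense = g_s (a_s * alpha + b_s)        (brighter when protonated)
    I_ref   = g_r (a_r * (1 - alpha) + b_r)  (moves oppositely)

so the emission ratio is finite and strictly increasing in alpha. Real
dye responses are not exactly linear in alpha; this map is the minimal
assumption consistent with two indicators moving in opposite directions,
and it makes the ratio -> alpha chain exactly invertible for testing.

Every stochastic operation is a pure function of its parameters and the
mandatory seed; ground truth is always returned alongside the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationSeries
from .optode import (
    EquilibriumParams,
    OptodeComposition,
    OptodeInputError,
    alpha_from_ion_activity,
    exchange_constant_for_midpoint,
    model_midpoint_concentration,
)
from .quantify import RoiSet, TwoChannelStack

__all__ = [
    "TransientSpec",
    "NoiseSpec",
    "ChannelGains",
    "SyntheticTruth",
    "DEFAULT_COMPOSITION",
    "default_equilibrium",
    "default_concentration_grid",
    "channel_intensities_from_alpha",
    "make_calibration_series",
    "make_transient_trace",
    "make_square_wave_trace",
    "render_stack",
    "make_in_situ_series",
]

# Component molar ratios of a Ca2+ optode tuned to the physiological range:
# ionophore : chromoionophore : exchanger = 2.278 : 1 : 1.276 (from 2 umol
# Ca ionophore II, 878 nmol chromoionophore III, 1.12 umol NaTFPB), z = 2
# with a 2:1 ionophore:ion complex.
DEFAULT_COMPOSITION = OptodeComposition(
    chromoionophore_total=1.0,
    exchanger_total=1.276,
    ionophore_total=2.278,
    ion_charge=2,
    stoichiometry=2,
)


def default_equilibrium(
    comp: OptodeComposition = DEFAULT_COMPOSITION,
    ph: float = 7.2,
    midpoint: float = 1.05e-7,
) -> EquilibriumParams:
    """Equilibrium parameters placing the model midpoint at ``midpoint``.

    Defaults to 105 nM at pH 7.2 — an in-solution sensitivity close to the
    ~100 nM resting cytosolic Ca2+ level.
    """
    k = exchange_constant_for_midpoint(comp, ph, midpoint)
    return EquilibriumParams.from_ph(k, ph)


def default_concentration_grid() -> np.ndarray:
    """11 log-spaced points, 10 nM - 10 uM, plus the C = 0 chelator buffer."""
    return np.concatenate([[0.0], np.logspace(-8, -5, 11)])


@dataclass(frozen=True)
class TransientSpec:
    """Agonist-evoked cytosolic Ca2+ transient.

    Defaults: 100 nM baseline rising to a 400 nM peak shortly after onset,
    then exponential decay back to baseline; 1 s frames for 10 min cover it.
    """

    baseline: float = 1.0e-7
    peak: float = 4.0e-7
    onset: float = 60.0
    rise_tau: float = 5.0
    decay_tau: float = 120.0
    duration: float = 600.0

    def __post_init__(self) -> None:
        if not (self.peak >= self.baseline >= 0):
            raise OptodeInputError("need peak >= baseline >= 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise OptodeInputError("time constants must be > 0")
        if self.duration < self.onset + 3 * self.decay_tau:
            raise OptodeInputError(
                "duration must cover onset plus several decay time constants"
            )


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition noise, bleaching and background for rendered data.

    ``photon_scale`` is the expected photon count per intensity unit (shot
    noise: counts ~ Poisson(I * photon_scale), rescaled back to a.u.);
    0 disables shot noise. Defaults give a single-frame whole-cell ROI
    ratio CV of roughly 3% under the default cell geometry ("paper-like"
    imaging quality). The seed is mandatory: every stochastic call is a
    pure function of (parameters, seed).
    """

    seed: int
    photon_scale: float = 0.008
    read_noise_sd: float = 3.0
    bleach_rate_sense: float = 2.0e-4
    bleach_rate_ref: float = 1.0e-4
    background_level: float = 40.0

    def __post_init__(self) -> None:
        if int(self.seed) != self.seed:
            raise OptodeInputError("seed must be an integer")
        for name in (
            "photon_scale",
            "read_noise_sd",
            "bleach_rate_sense",
            "bleach_rate_ref",
            "background_level",
        ):
            if getattr(self, name) < 0:
                raise OptodeInputError(f"{name} must be non-negative")

    @classmethod
    def noiseless(cls, seed: int) -> "NoiseSpec":
        return cls(
            seed=seed,
            photon_scale=0.0,
            read_noise_sd=0.0,
            bleach_rate_sense=0.0,
            bleach_rate_ref=0.0,
            background_level=0.0,
        )

    @classmethod
    def paper_like(cls, seed: int) -> "NoiseSpec":
        return cls(seed=seed)

    @classmethod
    def flowchamber(cls, seed: int) -> "NoiseSpec":
        """Surface-bound sensor film imaged at 10 s intervals: the sparse
        illumination duty cycle (vs 1 Hz live-cell imaging) scales the
        bleaching rates down tenfold; detection noise is unchanged."""
        return cls(seed=seed, bleach_rate_sense=2.0e-5, bleach_rate_ref=1.0e-5)

    @classmethod
    def plate_reader(cls, seed: int) -> "NoiseSpec":
        """Well-level measurement: a well integrates far more light than a
        pixel, so shot noise is ~1% of the signal and there is no bleaching
        or cellular background."""
        return cls(
            seed=seed,
            photon_scale=16.0,
            read_noise_sd=0.5,
            bleach_rate_sense=0.0,
            bleach_rate_ref=0.0,
            background_level=0.0,
        )

    @classmethod
    def high_snr(cls, seed: int) -> "NoiseSpec":
        return cls(seed=seed, photon_scale=2.0, read_noise_sd=0.5)

    @classmethod
    def low_snr(cls, seed: int) -> "NoiseSpec":
        return cls(seed=seed, photon_scale=0.005, read_noise_sd=6.0)


@dataclass(frozen=True)
class ChannelGains:
    """Linear intensity map per channel: I = gain * (span * fraction + offset).

    Defaults model a strongly pH-modulated chromoionophore channel against a
    reference dye with a weak (5% span) opposite-moving residual pH
    response: a nearly constant reference keeps the emission ratio close to
    affine in alpha, which is what makes the empirical dose-response EC50
    track the model midpoint.
    """

    gain_sense: float = 640.0
    gain_ref: float = 800.0
    span_sense: float = 1.0
    offset_sense: float = 0.3
    span_ref: float = 0.05
    offset_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gain_sense", "gain_ref", "span_sense", "span_ref"):
            if getattr(self, name) <= 0:
                raise OptodeInputError(f"{name} must be strictly positive")
        for name in ("offset_sense", "offset_ref"):
            if getattr(self, name) <= 0:
                raise OptodeInputError(f"{name} must be strictly positive (finite ratios)")


def channel_intensities_from_alpha(
    alpha, gains: ChannelGains = ChannelGains()
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-channel intensity at protonated fraction ``alpha``.

    The sense (chromoionophore) channel brightens with protonation; the
    reference channel moves oppositely, so the ratio is strictly increasing
    in alpha.
    """
    a = np.asarray(alpha, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise OptodeInputError("alpha must lie in [0, 1]")
    i_sense = gains.gain_sense * (gains.span_sense * a + gains.offset_sense)
    i_ref = gains.gain_ref * (gains.span_ref * (1.0 - a) + gains.offset_ref)
    if i_sense.ndim == 0:
        return float(i_sense), float(i_ref)
    return i_sense, i_ref


def _apply_noise(ideal: np.ndarray, rng: np.random.Generator, noise: NoiseSpec) -> np.ndarray:
    out = np.asarray(ideal, dtype=float)
    if noise.photon_scale > 0:
        out = rng.poisson(out * noise.photon_scale) / noise.photon_scale
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=np.shape(out))
    return out


def make_calibration_series(
    comp: OptodeComposition,
    eq: EquilibriumParams,
    conc_grid: np.ndarray | None = None,
    gains: ChannelGains = ChannelGains(),
    noise: NoiseSpec | None = None,
    *,
    n_replicates: int = 3,
    label: str = "synthetic_calibration",
) -> tuple[CalibrationSeries, dict]:
    """Plate-reader-style calibration series from the equilibrium model.

    Per concentration: alpha from the model, well intensities from the
    channel map, shot/read noise applied per replicate well. Acid/base
    endpoint standards are emitted at alpha = 1 and alpha = 0. Returns the
    series and a ground-truth dict (alphas, model midpoint, parameters).
    """
    if noise is None:
        raise OptodeInputError("a NoiseSpec with an explicit seed is required")
    grid = default_concentration_grid() if conc_grid is None else np.asarray(conc_grid, float)
    rng = np.random.default_rng(noise.seed)
    nonzero = grid[grid > 0]
    if np.any(np.diff(nonzero) <= 0):
        raise OptodeInputError("nonzero concentrations must be strictly increasing")
    alpha = np.asarray(alpha_from_ion_activity(grid, comp, eq))
    i_sense, i_ref = channel_intensities_from_alpha(alpha, gains)
    conc_rows, sense_rows, ref_rows, rep_rows = [], [], [], []
    for rep in range(n_replicates):
        conc_rows.append(grid)
        sense_rows.append(_apply_noise(i_sense, rng, noise))
        ref_rows.append(_apply_noise(i_ref, rng, noise))
        rep_rows.append(np.array([f"r{rep + 1}"] * grid.size))
    acid_s, acid_r = channel_intensities_from_alpha(1.0, gains)
    base_s, base_r = channel_intensities_from_alpha(0.0, gains)
    acid = (
        float(np.mean(_apply_noise(np.full(n_replicates, acid_s), rng, noise))),
        float(np.mean(_apply_noise(np.full(n_replicates, acid_r), rng, noise))),
    )
    base = (
        float(np.mean(_apply_noise(np.full(n_replicates, base_s), rng, noise))),
        float(np.mean(_apply_noise(np.full(n_replicates, base_r), rng, noise))),
    )
    series = CalibrationSeries(
        concentrations=np.concatenate(conc_rows),
        intensity_sense=np.maximum(np.concatenate(sense_rows), 1e-6),
        intensity_ref=np.maximum(np.concatenate(ref_rows), 1e-6),
        acid_endpoint=acid,
        base_endpoint=base,
        replicate=np.concatenate(rep_rows),
        label=label,
    )
    truth = {
        "concentrations_molar": grid.tolist(),
        "alpha": alpha.tolist(),
        "model_ec50_molar": model_midpoint_concentration(comp, eq),
        "composition": dataclasses.asdict(comp),
        "equilibrium": dataclasses.asdict(eq),
        "gains": dataclasses.asdict(gains),
        "noise": dataclasses.asdict(noise),
    }
    return series, truth


def make_transient_trace(
    spec: TransientSpec, frame_interval: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth Ca(t): baseline, rise to peak, exponential decay back.

    The waveform is a normalized double exponential
    ``(1 - exp(-dt/rise_tau)) * exp(-dt/decay_tau)`` scaled so its maximum
    equals ``peak`` exactly (up to frame discretization). Continuous at
    onset; returns (time_s, ca_molar).
    """
    if frame_interval <= 0:
        raise OptodeInputError("frame_interval must be > 0")
    t = np.arange(0.0, spec.duration, frame_interval)
    ca = np.full(t.shape, spec.baseline)
    dt = t - spec.onset
    after = dt >= 0
    shape = (1.0 - np.exp(-dt[after] / spec.rise_tau)) * np.exp(-dt[after] / spec.decay_tau)
    # analytic max of the double exponential, at dt* = rise_tau ln(1 + decay/rise)
    dt_star = spec.rise_tau * np.log1p(spec.decay_tau / spec.rise_tau)
    peak_shape = (1.0 - np.exp(-dt_star / spec.rise_tau)) * np.exp(-dt_star / spec.decay_tau)
    ca[after] = spec.baseline + (spec.peak - spec.baseline) * shape / peak_shape
    return t, ca


def make_square_wave_trace(
    low: float = 1.0e-7,
    high: float = 1.35e-6,
    dwell: float = 120.0,
    n_cycles: int = 5,
    frame_interval: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, float]]]:
    """Reversibility protocol: alternating low/high baths, exchanged every dwell.

    Starts at the low level (one dwell of baseline), then ``n_cycles`` of
    (high, low). Returns (time_s, ca_molar, plateaus) where plateaus is a
    list of (start_frame, stop_frame, level_molar) for each constant
    segment.
    """
    if low <= 0 or high <= low:
        raise OptodeInputError("need 0 < low < high")
    frames_per_dwell = int(round(dwell / frame_interval))
    if frames_per_dwell < 2:
        raise OptodeInputError("dwell must span at least 2 frames")
    levels = [low] + [high, low] * n_cycles
    ca = np.concatenate([np.full(frames_per_dwell, lvl) for lvl in levels])
    t = np.arange(ca.size) * frame_interval
    plateaus = [
        (i * frames_per_dwell, (i + 1) * frames_per_dwell, lvl)
        for i, lvl in enumerate(levels)
    ]
    return t, ca, plateaus


@dataclass
class SyntheticTruth:
    """Ground truth shipped with every rendered stack."""

    time: np.ndarray
    ca: np.ndarray
    alpha: np.ndarray
    density: np.ndarray
    cell_masks: dict[str, np.ndarray]
    background_mask: np.ndarray
    gains: ChannelGains
    noise: NoiseSpec
    frame_interval: float

    def roi_set(self) -> RoiSet:
        return RoiSet(rois=dict(self.cell_masks), background=self.background_mask)


def _place_cells(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_cells: int,
    foci_per_cell: tuple[int, int],
    cytosol_density: float,
    focus_density: tuple[float, float],
    focus_sigma: tuple[float, float],
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    density = np.zeros(shape)
    cell_masks: dict[str, np.ndarray] = {}
    for i in range(n_cells):
        for _ in range(50):  # rejection sampling: keep cells inside and apart
            cy = rng.uniform(0.2 * h, 0.8 * h)
            cx = rng.uniform(0.2 * w, 0.8 * w)
            ay = rng.uniform(0.08, 0.14) * h
            ax = rng.uniform(0.10, 0.18) * w
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            mask = (u / ax) ** 2 + (v / ay) ** 2 <= 1.0
            if not any((mask & m).any() for m in cell_masks.values()):
                break
        cell_masks[f"cell_{i + 1}"] = mask
        density[mask] += cytosol_density
        n_foci = rng.integers(foci_per_cell[0], foci_per_cell[1] + 1)
        inside = np.argwhere(mask)
        for _ in range(n_foci):
            fy, fx = inside[rng.integers(len(inside))]
            amp = rng.uniform(*focus_density)
            sig = rng.uniform(*focus_sigma)
            r = int(np.ceil(4 * sig))
            y0, y1 = max(0, fy - r), min(h, fy + r + 1)
            x0, x1 = max(0, fx - r), min(w, fx + r + 1)
            gy, gx = np.mgrid[y0:y1, x0:x1]
            blob = amp * np.exp(-((gy - fy) ** 2 + (gx - fx) ** 2) / (2 * sig**2))
            density[y0:y1, x0:x1] += blob * mask[y0:y1, x0:x1]
    # cell-free background ROI: a block well clear of every cell
    any_cell = np.zeros(shape, dtype=bool)
    for m in cell_masks.values():
        any_cell |= m
    block = max(8, min(h, w) // 10)
    background = None
    for by in range(0, h - block, block // 2):
        for bx in range(0, w - block, block // 2):
            if not any_cell[by : by + block, bx : bx + block].any():
                background = np.zeros(shape, dtype=bool)
                background[by : by + block, bx : bx + block] = True
                break
        if background is not None:
            break
    if background is None:  # pathological packing; fall back to a corner pixel block
        background = np.zeros(shape, dtype=bool)
        background[:4, :4] = True
    return density, cell_masks, background


def render_stack(
    ca_trace: tuple[np.ndarray, np.ndarray],
    comp: OptodeComposition,
    eq: EquilibriumParams,
    *,
    noise: NoiseSpec,
    gains: ChannelGains = ChannelGains(),
    shape: tuple[int, int] = (256, 256),
    n_cells: int = 3,
    foci_per_cell: tuple[int, int] = (5, 20),
    cytosol_density: float = 0.15,
    focus_density: tuple[float, float] = (0.8, 2.0),
    focus_sigma: tuple[float, float] = (1.5, 3.0),
) -> tuple[TwoChannelStack, SyntheticTruth]:
    """Render a two-channel stack from a ground-truth Ca(t).

    Per frame: alpha from the equilibrium model; per-pixel intensity is the
    nanosensor density field (elliptical cells with punctate foci) times the
    channel brightness at that alpha, attenuated by per-channel exponential
    bleaching, plus additive background; then shot and read noise. The
    density field multiplies both channels identically, so sensor amount
    cancels in the ratio — the core premise of ratiometric imaging.
    """
    t, ca = np.asarray(ca_trace[0], float), np.asarray(ca_trace[1], float)
    if t.size != ca.size or t.size == 0:
        raise OptodeInputError("ca_trace must be a nonempty (time, ca) pair")
    if t.size > 1:
        frame_interval = float(t[1] - t[0])
    else:
        frame_interval = 1.0
    rng = np.random.default_rng(noise.seed)
    density, cell_masks, background_mask = _place_cells(
        rng, shape, n_cells, foci_per_cell, cytosol_density, focus_density, focus_sigma
    )
    alpha = np.asarray(alpha_from_ion_activity(ca, comp, eq))
    f_sense, f_ref = channel_intensities_from_alpha(alpha, gains)
    sense = np.empty((t.size,) + shape, dtype=np.float32)
    ref = np.empty_like(sense)
    for i in range(t.size):
        bl_s = np.exp(-noise.bleach_rate_sense * t[i])
        bl_r = np.exp(-noise.bleach_rate_ref * t[i])
        ideal_s = density * (f_sense[i] * bl_s) + noise.background_level
        ideal_r = density * (f_ref[i] * bl_r) + noise.background_level
        sense[i] = _apply_noise(ideal_s, rng, noise)
        ref[i] = _apply_noise(ideal_r, rng, noise)
    stack = TwoChannelStack(sense=sense, ref=ref, frame_interval=frame_interval)
    truth = SyntheticTruth(
        time=t,
        ca=ca,
        alpha=alpha,
        density=density,
        cell_masks=cell_masks,
        background_mask=background_mask,
        gains=gains,
        noise=noise,
        frame_interval=frame_interval,
    )
    return stack, truth


def make_in_situ_series(
    comp: OptodeComposition,
    eq: EquilibriumParams,
    concentrations,
    *,
    noise: NoiseSpec,
    gains: ChannelGains = ChannelGains(),
    frames_per_step: int = 5,
    frame_interval: float = 10.0,
    shape: tuple[int, int] = (64, 64),
    n_cells: int = 1,
) -> tuple[list[tuple[float, TwoChannelStack]], SyntheticTruth]:
    """Stepped in-cell calibration: one short stack per bath concentration.

    The cell layout is fixed across steps (same field of view); each step is
    rendered at its equilibrated alpha with fresh noise. ``eq`` may differ
    from the in-solution equilibrium to emulate a cytosol-shifted
    sensitivity. Returns the steps and the shared truth (the truth's ``ca``
    holds the step concentrations).
    """
    concs = np.asarray(list(concentrations), dtype=float)
    if concs.size < 5 or np.any(np.diff(concs) <= 0):
        raise OptodeInputError("need >= 5 strictly increasing concentrations")
    layout_rng = np.random.default_rng(noise.seed)
    density, cell_masks, background_mask = _place_cells(
        layout_rng, shape, n_cells, (3, 8), 0.15, (0.8, 2.0), (1.5, 3.0)
    )
    alpha = np.asarray(alpha_from_ion_activity(concs, comp, eq))
    f_sense, f_ref = channel_intensities_from_alpha(alpha, gains)
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(noise.seed), 1]))
    steps = []
    for j, conc in enumerate(concs):
        ideal_s = density * f_sense[j] + noise.background_level
        ideal_r = density * f_ref[j] + noise.background_level
        sense = np.stack(
            [_apply_noise(ideal_s, noise_rng, noise) for _ in range(frames_per_step)]
        ).astype(np.float32)
        ref = np.stack(
            [_apply_noise(ideal_r, noise_rng, noise) for _ in range(frames_per_step)]
        ).astype(np.float32)
        steps.append(
            (float(conc), TwoChannelStack(sense=sense, ref=ref, frame_interval=frame_interval))
        )
    truth = SyntheticTruth(
        time=np.arange(concs.size, dtype=float) * frames_per_step * frame_interval,
        ca=concs,
        alpha=alpha,
        density=density,
        cell_masks=cell_masks,
        background_mask=background_mask,
        gains=gains,
        noise=noise,
        frame_interval=frame_interval,
    )
    return steps, truth
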