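"""ROI quantification of two-channel ratiometric time-lapse data.

Processing chain for a nanosensor-loaded time-lapse:

1. mean ROI intensity per frame, per channel;
2. background subtraction using a cell-free background ROI;
3. per-channel photobleaching correction (monoexponential fit on the
   pre-stimulus baseline, normalized to t = 0);
4. emission ratio R = I_sense / I_ref;
5. inversion of the fitted dose-response model,

       C = EC50 * ((R - R_min) / (R_max - R))^(1/p),

   the exact algebraic inverse of the calibration model. Ratios at or
   beyond the plateaus are flagged and left undefined — the inverse
   diverges there and extrapolating would fabricate concentrations.

Quality flags are carried per frame as a bitmask and flagged frames are
excluded from trace summaries.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationError, HillFit, fit_hill_ratios

__all__ = [
    "QuantifyError",
    "RoiError",
    "FLAG_NEGATIVE_INTENSITY",
    "FLAG_OUT_OF_RANGE",
    "FLAG_BLEACH_FIT_FAILED",
    "FLAG_ZERO_REFERENCE",
    "TwoChannelStack",
    "RoiSet",
    "RatioTrace",
    "extract_roi_traces",
    "background_subtract",
    "photobleach_correct",
    "compute_trace_ratio",
    "ratio_to_concentration",
    "quantify_timelapse",
    "in_situ_calibrate",
]


class QuantifyError(ValueError):
    """Invalid quantification input."""


class RoiError(QuantifyError):
    """Empty, out-of-bounds, or overlapping ROI definition."""


# per-frame quality flag bits
FLAG_NEGATIVE_INTENSITY = 1  # background subtraction went negative (floored at 0)
FLAG_OUT_OF_RANGE = 2  # ratio at/outside the calibration plateaus
FLAG_BLEACH_FIT_FAILED = 4  # photobleach fit did not converge; no correction applied
FLAG_ZERO_REFERENCE = 8  # corrected reference intensity <= 0; ratio undefined


@dataclass
class TwoChannelStack:
    """Time-ordered pair of single-channel image stacks.

    ``sense`` is the chromoionophore emission channel (~670 nm), ``ref`` the
    reference-dye channel (~575 nm); both are (T, H, W) arrays in arbitrary
    intensity units. On disk the stack is a multi-page TIFF with channels as
    alternating pages, page 0 = reference channel.
    """

    sense: np.ndarray
    ref: np.ndarray
    frame_interval: float
    channel_labels: tuple[str, str] = ("670nm", "575nm")

    def __post_init__(self) -> None:
        self.sense = np.asarray(self.sense)
        self.ref = np.asarray(self.ref)
        if self.sense.shape != self.ref.shape or self.sense.ndim != 3:
            raise QuantifyError(
                f"channels must share a (T, H, W) shape, got {self.sense.shape} "
                f"vs {self.ref.shape}"
            )
        if not self.frame_interval > 0:
            raise QuantifyError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.sense.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.sense.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def to_tiff(self, path, dtype=np.uint16) -> None:
        """Interleaved multi-page TIFF (ref0, sense0, ref1, sense1, ...)."""
        pages = np.empty((2 * self.n_frames,) + self.frame_shape, dtype=dtype)
        info = np.iinfo(dtype) if np.issubdtype(dtype, np.integer) else None
        ref, sense = self.ref, self.sense
        if info is not None:
            ref = np.clip(np.rint(ref), info.min, info.max)
            sense = np.clip(np.rint(sense), info.min, info.max)
        pages[0::2] = ref
        pages[1::2] = sense
        tifffile.imwrite(path, pages)

    @classmethod
    def from_tiff(cls, path, frame_interval: float) -> "TwoChannelStack":
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] % 2 != 0:
            raise QuantifyError(
                f"{path}: expected an even number of single-channel pages"
            )
        return cls(
            sense=pages[1::2].astype(float),
            ref=pages[0::2].astype(float),
            frame_interval=frame_interval,
        )

    @classmethod
    def from_channel_tiffs(cls, sense_path, ref_path, frame_interval: float) -> "TwoChannelStack":
        return cls(
            sense=tifffile.imread(sense_path).astype(float),
            ref=tifffile.imread(ref_path).astype(float),
            frame_interval=frame_interval,
        )


@dataclass
class RoiSet:
    """Named analysis ROIs plus one cell-free background ROI (boolean masks)."""

    rois: dict[str, np.ndarray]
    background: np.ndarray

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=bool)
        if not self.background.any():
            raise RoiError("background ROI is empty")
        clean = {}
        for name, mask in self.rois.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.background.shape:
                raise RoiError(f"ROI {name!r} shape differs from background mask")
            if not mask.any():
                raise RoiError(f"ROI {name!r} is empty")
            if (mask & self.background).any():
                raise RoiError(f"ROI {name!r} overlaps the background ROI")
            clean[name] = mask
        if not clean:
            raise RoiError("no analysis ROIs defined")
        self.rois = clean

    @property
    def shape(self) -> tuple[int, int]:
        return self.background.shape

    def to_label_tiff(self, path) -> list[str]:
        """Single-page label TIFF: 0 outside, 1 background, 2.. analysis ROIs.

        Returns the ROI names in label order (label = index + 2).
        """
        label = np.zeros(self.shape, dtype=np.uint16)
        label[self.background] = 1
        names = list(self.rois)
        for i, name in enumerate(names):
            label[self.rois[name]] = i + 2
        tifffile.imwrite(path, label)
        return names

    @classmethod
    def from_label_tiff(cls, path, names: list[str] | None = None) -> "RoiSet":
        label = tifffile.imread(path)
        labels = sorted(int(v) for v in np.unique(label) if v >= 2)
        if not labels:
            raise RoiError(f"{path}: no analysis ROI labels (>= 2) found")
        rois = {}
        for i, v in enumerate(labels):
            name = names[i] if names and i < len(names) else f"roi_{v}"
            rois[name] = label == v
        return cls(rois=rois, background=label == 1)

    def to_csv(self, path) -> None:
        """Run-length encoding: roi, row, col_start, col_stop (stop exclusive)."""
        rows = []
        for name, mask in [("background", self.background)] + list(self.rois.items()):
            for r in range(mask.shape[0]):
                cols = np.flatnonzero(mask[r])
                if cols.size == 0:
                    continue
                breaks = np.flatnonzero(np.diff(cols) > 1)
                starts = np.concatenate([[0], breaks + 1])
                stops = np.concatenate([breaks, [cols.size - 1]])
                for s, e in zip(starts, stops):
                    rows.append((name, r, int(cols[s]), int(cols[e]) + 1))
        pd.DataFrame(rows, columns=["roi", "row", "col_start", "col_stop"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, shape: tuple[int, int]) -> "RoiSet":
        df = pd.read_csv(path)
        masks: dict[str, np.ndarray] = {}
        for name, g in df.groupby("roi"):
            mask = np.zeros(shape, dtype=bool)
            for _, row in g.iterrows():
                mask[int(row["row"]), int(row["col_start"]) : int(row["col_stop"])] = True
            masks[str(name)] = mask
        if "background" not in masks:
            raise RoiError(f"{path}: no 'background' ROI present")
        background = masks.pop("background")
        return cls(rois=masks, background=background)


@dataclass
class RatioTrace:
    """Per-ROI, per-frame two-channel record through the quantification chain.

    Raw and corrected channel means, the emission ratio, the derived molar
    concentration (``None`` until conversion), and a per-frame flag bitmask.
    """

    name: str
    time: np.ndarray
    sense_raw: np.ndarray
    ref_raw: np.ndarray
    sense_corr: np.ndarray | None = None
    ref_corr: np.ndarray | None = None
    ratio: np.ndarray | None = None
    concentration: np.ndarray | None = None
    flags: np.ndarray | None = None
    bleach_rate_sense: float | None = None
    bleach_rate_ref: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for fname in ("sense_raw", "ref_raw", "sense_corr", "ref_corr", "ratio", "concentration"):
            arr = getattr(self, fname)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise QuantifyError(f"{fname} length {arr.size} != time length {n}")
                setattr(self, fname, arr)
        if self.flags is None:
            self.flags = np.zeros(n, dtype=int)
        else:
            self.flags = np.asarray(self.flags, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        def col(a, fill=np.nan):
            return a if a is not None else np.full(self.n_frames, fill)

        return pd.DataFrame(
            {
                "time_s": self.time,
                "I_sense_raw": self.sense_raw,
                "I_ref_raw": self.ref_raw,
                "I_sense_corr": col(self.sense_corr),
                "I_ref_corr": col(self.ref_corr),
                "ratio": col(self.ratio),
                "concentration_molar": col(self.concentration),
                "flags": self.flags,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_roi_traces(
    stack: TwoChannelStack, rois: RoiSet
) -> tuple[dict[str, RatioTrace], RatioTrace]:
    """Per-frame mean ROI intensities for each analysis ROI and the background.

    Returns ``(traces, background_trace)``.
    """
    if rois.shape != stack.frame_shape:
        raise RoiError(
            f"ROI shape {rois.shape} does not match frame shape {stack.frame_shape}"
        )
    t = stack.times

    def roi_mean(mask):
        flat = np.flatnonzero(mask.ravel())
        sense = stack.sense.reshape(stack.n_frames, -1)[:, flat].mean(axis=1)
        ref = stack.ref.reshape(stack.n_frames, -1)[:, flat].mean(axis=1)
        return sense, ref

    traces = {}
    for name, mask in rois.rois.items():
        s, r = roi_mean(mask)
        traces[name] = RatioTrace(name=name, time=t, sense_raw=s, ref_raw=r)
    bs, br = roi_mean(rois.background)
    background = RatioTrace(name="background", time=t, sense_raw=bs, ref_raw=br)
    return traces, background


def background_subtract(trace: RatioTrace, background: RatioTrace) -> RatioTrace:
    """Subtract the cell-free background trace per frame and channel.

    Negative results are floored at 0 and flagged (noise near background is
    expected, not an error).
    """
    if background.n_frames != trace.n_frames:
        raise QuantifyError(
            f"background has {background.n_frames} frames, trace has {trace.n_frames}"
        )
    sense = trace.sense_raw - background.sense_raw
    ref = trace.ref_raw - background.ref_raw
    flags = trace.flags.copy()
    negative = (sense < 0) | (ref < 0)
    flags[negative] |= FLAG_NEGATIVE_INTENSITY
    return dataclasses.replace(
        trace,
        sense_corr=np.maximum(sense, 0.0),
        ref_corr=np.maximum(ref, 0.0),
        flags=flags,
    )


def _fit_decay(t: np.ndarray, intensity: np.ndarray, model: str) -> tuple[float, float]:
    """Decay rate k (1/s) and its standard error from a baseline window.

    "exponential": least squares of ln I = ln I0 - k t (requires I > 0);
    "linear": least squares of I = I0 (1 - k t), i.e. a drift slope
    normalized by the t = 0 intercept.
    """
    if model == "exponential":
        if np.any(intensity <= 0):
            raise FloatingPointError("non-positive intensity in baseline window")
        y = np.log(intensity)
    elif model == "linear":
        y = intensity
    else:
        raise QuantifyError(f"unknown photobleach model {model!r}")
    (slope, intercept), cov = np.polyfit(t, y, 1, cov=True)
    slope_se = float(np.sqrt(cov[0, 0]))
    if model == "exponential":
        return -float(slope), slope_se
    if intercept <= 0:
        raise FloatingPointError("non-positive intercept in baseline window")
    return -float(slope / intercept), slope_se / float(intercept)


def photobleach_correct(
    trace: RatioTrace,
    baseline_window: tuple[int, int],
    *,
    model: str = "exponential",
    significance: float | None = 2.0,
    ref_window: tuple[int, int] | None = None,
    quiescent_windows: list[tuple[int, int]] | None = None,
) -> RatioTrace:
    """Per-channel photobleaching correction from the pre-stimulus baseline.

    A monoexponential ``I0 exp(-k t)`` (or, with ``model="linear"``, a linear
    drift) is fitted to each channel over ``baseline_window = (start, stop)``
    frames and divided out over the whole trace, normalizing to the t = 0
    value. When a channel's fit fails the trace passes through uncorrected
    with a prominent warning and a per-frame flag.

    ``significance`` guards against extrapolating pure noise: a channel is
    only corrected when its fitted rate exceeds ``significance`` standard
    errors (a decay that cannot be distinguished from zero in the baseline
    would, once extrapolated far beyond the fit window, inject more ratio
    error than it removes). Set ``significance=None`` to always correct.
    The fitted rate is reported either way.

    ``ref_window`` optionally fits the reference channel's decay over a
    different (typically much longer) frame range: when the reference dye's
    ion response is weak, its intensity is almost a pure bleaching reporter
    over the whole recording, which estimates its rate far more precisely
    than a short pre-stimulus baseline can.

    ``quiescent_windows`` adds further frame ranges known to sit at the
    pre-stimulus ion level (e.g. the tail of a transient that has fully
    recovered) to both channels' decay fits. Extending the fit's time span
    this way is the standard remedy for the otherwise ill-conditioned
    extrapolation of a rate estimated on a short early baseline.
    """
    start, stop = baseline_window
    if stop - start < 10:
        raise QuantifyError(
            f"baseline window [{start}, {stop}) must contain >= 10 frames"
        )
    if not (0 <= start < stop <= trace.n_frames):
        raise QuantifyError("baseline window outside the trace")
    sense = trace.sense_corr if trace.sense_corr is not None else trace.sense_raw
    ref = trace.ref_corr if trace.ref_corr is not None else trace.ref_raw

    base_idx = np.arange(start, stop)
    if quiescent_windows:
        extra = []
        for w0, w1 in quiescent_windows:
            if not (0 <= w0 < w1 <= trace.n_frames):
                raise QuantifyError("quiescent window outside the trace")
            extra.append(np.arange(w0, w1))
        base_idx = np.unique(np.concatenate([base_idx] + extra))
    windows = {"sense": base_idx, "ref": base_idx}
    if ref_window is not None:
        r0, r1 = ref_window
        if not (0 <= r0 < r1 <= trace.n_frames) or r1 - r0 < 10:
            raise QuantifyError("ref_window must span >= 10 frames inside the trace")
        windows["ref"] = np.arange(r0, r1)
    out = {}
    rates = {}
    flags = trace.flags.copy()
    for chan, arr in (("sense", sense), ("ref", ref)):
        idx = windows[chan]
        tw = trace.time[idx]
        try:
            k, k_se = _fit_decay(tw, arr[idx], model)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"photobleach fit failed on {chan} channel of ROI "
                f"{trace.name!r} ({exc}); no correction applied",
                RuntimeWarning,
                stacklevel=2,
            )
            flags |= FLAG_BLEACH_FIT_FAILED
            out[chan] = arr.copy()
            rates[chan] = None
            continue
        rates[chan] = k
        if significance is not None and abs(k) <= significance * k_se:
            out[chan] = arr.copy()  # rate indistinguishable from zero
            continue
        if model == "exponential":
            profile = np.exp(-k * trace.time)
        else:
            profile = np.maximum(1.0 - k * trace.time, 1e-12)
        out[chan] = arr / profile
    return dataclasses.replace(
        trace,
        sense_corr=out["sense"],
        ref_corr=out["ref"],
        flags=flags,
        bleach_rate_sense=rates["sense"],
        bleach_rate_ref=rates["ref"],
    )


def compute_trace_ratio(trace: RatioTrace) -> RatioTrace:
    """Emission ratio from the corrected channels; zero reference flagged."""
    sense = trace.sense_corr if trace.sense_corr is not None else trace.sense_raw
    ref = trace.ref_corr if trace.ref_corr is not None else trace.ref_raw
    flags = trace.flags.copy()
    bad = ref <= 0
    flags[bad] |= FLAG_ZERO_REFERENCE
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, sense / np.where(bad, 1.0, ref))
    return dataclasses.replace(trace, ratio=ratio, flags=flags)


def ratio_to_concentration(ratio, fit: HillFit):
    """Invert the dose-response model: C = EC50 ((R - R_min)/(R_max - R))^(1/p).

    Defined only for R strictly between the plateaus; outside, NaN is
    returned (callers flag the frame rather than extrapolate).
    """
    r = np.asarray(ratio, dtype=float)
    lo, hi = fit.plateau_interval
    in_range = (r > lo) & (r < hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (r - fit.r_min) / (fit.r_max - r)
        conc = fit.ec50 * arg ** (1.0 / fit.slope)
    conc = np.where(in_range, conc, np.nan)
    return float(conc) if conc.ndim == 0 else conc


def convert_trace(trace: RatioTrace, fit: HillFit) -> RatioTrace:
    """Attach a concentration trace; out-of-range ratios flagged, not clipped."""
    if trace.ratio is None:
        trace = compute_trace_ratio(trace)
    conc = ratio_to_concentration(trace.ratio, fit)
    flags = trace.flags.copy()
    out_of_range = np.isfinite(trace.ratio) & ~np.isfinite(conc)
    flags[out_of_range] |= FLAG_OUT_OF_RANGE
    return dataclasses.replace(trace, concentration=conc, flags=flags)


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    return pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()


def summarize_trace(
    trace: RatioTrace,
    stimulus_frame: int,
    *,
    peak_smooth_s: float = 20.0,
    peak_search_s: float | None = None,
) -> dict:
    """Baseline, peak, time-to-peak and recovery from a concentration trace.

    Baseline is the median over valid pre-stimulus frames. The peak is
    estimated on split frames: odd-indexed post-stimulus frames, smoothed
    with a moving median whose window matches the transient's rise time
    scale (``peak_smooth_s``), locate the peak frame, and the peak value is
    the median of the *even*-indexed concentrations near that frame; the
    complementary split (locate on evens, estimate on odds) is averaged in.
    Because the locating and estimating frames carry independent noise,
    this avoids the upward selection bias of taking a running maximum of a
    noisy trace — which matters here because the shallow sensor response
    amplifies ratio noise strongly in concentration. ``peak_search_s``
    limits how far past the stimulus the peak is sought (agonist-evoked
    store release peaks within the first minute or two; restricting the
    search keeps slow late-trace drift from masquerading as the response
    peak). ``recovery_level`` is
    the median over the final 10% of frames and ``recovery_fraction`` the
    fractional return from peak toward baseline. Flagged frames are
    excluded throughout.
    """
    if trace.concentration is None:
        raise QuantifyError("trace has no concentration; run convert_trace first")
    valid = (trace.flags == 0) & np.isfinite(trace.concentration)
    conc = np.where(valid, trace.concentration, np.nan)
    pre = conc[:stimulus_frame]
    dt = float(trace.time[1] - trace.time[0]) if trace.n_frames > 1 else 1.0
    stop = trace.n_frames
    if peak_search_s is not None:
        stop = min(stop, stimulus_frame + max(1, int(round(peak_search_s / dt))))
    post = conc[stimulus_frame:stop]
    baseline = float(np.nanmedian(pre)) if np.isfinite(pre).any() else float("nan")
    window = max(3, int(round(peak_smooth_s / dt)) | 1)  # odd, >= 3

    def _split_peak(locate_offset: int) -> tuple[float, int] | None:
        locate = post[locate_offset::2]
        if not np.isfinite(locate).any():
            return None
        smooth = _moving_median(locate, max(3, (window // 2) | 1))
        ipk = locate_offset + 2 * int(np.nanargmax(smooth))
        estimate_idx = np.arange(1 - locate_offset, post.size, 2)
        sel = estimate_idx[np.abs(estimate_idx - ipk) <= window // 2 + 1]
        if sel.size == 0 or not np.isfinite(post[sel]).any():
            return None
        return float(np.nanmedian(post[sel])), ipk

    halves = [h for h in (_split_peak(1), _split_peak(0)) if h is not None]
    if post.size >= 4 and len(halves) == 2:
        peak = 0.5 * (halves[0][0] + halves[1][0])
        ipk = halves[0][1]  # odd-frame location, reported for time-to-peak
        time_to_peak = float(trace.time[stimulus_frame + ipk] - trace.time[stimulus_frame])
    elif np.isfinite(post).any():
        ipk = int(np.nanargmax(post))
        peak = float(post[ipk])
        time_to_peak = float(trace.time[stimulus_frame + ipk] - trace.time[stimulus_frame])
    else:
        peak, time_to_peak = float("nan"), float("nan")
    tail = conc[-max(1, trace.n_frames // 10) :]
    recovery_level = float(np.nanmedian(tail)) if np.isfinite(tail).any() else float("nan")
    if np.isfinite(peak) and np.isfinite(baseline) and peak != baseline:
        recovery_fraction = float((peak - recovery_level) / (peak - baseline))
    else:
        recovery_fraction = float("nan")
    return {
        "baseline_molar": baseline,
        "peak_molar": peak,
        "time_to_peak_s": time_to_peak,
        "recovery_level_molar": recovery_level,
        "recovery_fraction": recovery_fraction,
        "n_flagged_frames": int(np.sum(trace.flags != 0)),
    }


def quantify_timelapse(
    stack: TwoChannelStack,
    rois: RoiSet,
    fit: HillFit,
    stimulus_frame: int,
    *,
    baseline_window: tuple[int, int] | None = None,
    bleach_model: str = "exponential",
    bleach_significance: float | None = 2.0,
    static_reference: bool = False,
    quiescent_windows: list[tuple[int, int]] | None = None,
    peak_smooth_s: float = 20.0,
    peak_search_s: float | None = None,
) -> tuple[dict[str, RatioTrace], dict[str, dict]]:
    """Full chain: extract -> background subtract -> bleach correct -> ratio -> C.

    ``baseline_window`` defaults to every frame before ``stimulus_frame``
    (minimum 10 frames). ``static_reference=True`` declares the reference
    channel's ion response negligible, letting its photobleaching rate be
    fitted over the whole recording instead of only the baseline. Returns
    per-ROI concentration traces and summary dictionaries (baseline, peak,
    time-to-peak, recovery).
    """
    if not (0 < stimulus_frame <= stack.n_frames):
        raise QuantifyError("stimulus_frame outside the stack")
    if baseline_window is None:
        baseline_window = (0, stimulus_frame)
    traces, background = extract_roi_traces(stack, rois)
    out_traces: dict[str, RatioTrace] = {}
    summaries: dict[str, dict] = {}
    for name, trace in traces.items():
        trace = background_subtract(trace, background)
        trace = photobleach_correct(
            trace,
            baseline_window,
            model=bleach_model,
            significance=bleach_significance,
            ref_window=(0, stack.n_frames) if static_reference else None,
            quiescent_windows=quiescent_windows,
        )
        trace = compute_trace_ratio(trace)
        trace = convert_trace(trace, fit)
        out_traces[name] = trace
        summaries[name] = summarize_trace(
            trace,
            stimulus_frame,
            peak_smooth_s=peak_smooth_s,
            peak_search_s=peak_search_s,
        )
    return out_traces, summaries


def plateau_concentrations(
    stack: TwoChannelStack,
    rois: RoiSet,
    fit: HillFit,
    plateaus,
    *,
    skip_frames: int = 1,
    bleach_model: str = "exponential",
    bleach_significance: float | None = 2.0,
    static_reference: bool = True,
    quiescent_windows: list[tuple[int, int]] | None = None,
) -> list[float]:
    """Equilibrium concentration per constant-bath segment of a recording.

    For protocols that hold the bath at known alternating levels (e.g. a
    reversibility test cycling two Ca2+ buffers), each plateau's ratio is
    the median over its frames (``skip_frames`` dropped after each solution
    exchange), pooled across ROIs, and converted *after* pooling — the
    dose-response inverse diverges near its plateaus, so converting a
    median ratio propagates far less noise than taking a median of
    per-frame concentrations. ``plateaus`` is a sequence of
    ``(start_frame, stop_frame, ...)``; extra tuple entries are ignored.
    ``quiescent_windows`` (typically the repeated low-level plateaus) and
    ``static_reference`` steer the photobleach fit as in
    :func:`photobleach_correct`. Returns one molar concentration per
    plateau.
    """
    first = plateaus[0]
    baseline_window = (int(first[0]), int(first[1]))
    traces, background = extract_roi_traces(stack, rois)
    per_roi_ratios = []
    for trace in traces.values():
        trace = background_subtract(trace, background)
        trace = photobleach_correct(
            trace,
            baseline_window,
            model=bleach_model,
            significance=bleach_significance,
            ref_window=(0, stack.n_frames) if static_reference else None,
            quiescent_windows=quiescent_windows,
        )
        trace = compute_trace_ratio(trace)
        per_roi_ratios.append(
            [
                float(np.nanmedian(trace.ratio[int(p[0]) + skip_frames : int(p[1])]))
                for p in plateaus
            ]
        )
    pooled = np.mean(np.asarray(per_roi_ratios), axis=0)
    return [float(ratio_to_concentration(r, fit)) for r in pooled]


def in_situ_calibrate(
    steps,
    rois: RoiSet,
    endpoints: tuple[float, float] | None = None,
    *,
    min_frames: int = 3,
    subtract_background: bool = True,
) -> HillFit:
    """Dose-response fit from an in-cell calibration (stepped superfusion).

    ``steps`` is a sequence of ``(free_ion_molar, TwoChannelStack)`` pairs,
    one short stack per equilibrated bath concentration (an ion carrier such
    as ionomycin equilibrates intra- and extracellular levels). Each step's
    equilibrium ratio is the median over its frames; every analysis ROI
    contributes a replicate and the fit averages replicates per
    concentration. ``endpoints``, if given, are the acid/base standard
    ratios (R_P, R_D); they pin the plateau parameters, leaving only EC50
    and slope to be fitted — a short stepped series cannot constrain all
    four dose-response parameters. The returned fit is tagged "in_situ"
    and should be preferred over an in-solution fit for intracellular work.
    """
    steps = list(steps)
    if len(steps) < 5:
        raise QuantifyError(f"need >= 5 concentration steps, got {len(steps)}")
    concs = np.array([c for c, _ in steps], dtype=float)
    if np.unique(concs).size != concs.size or np.any(np.diff(concs) <= 0):
        raise QuantifyError("concentration steps must be strictly increasing and unique")
    conc_rows, ratio_rows = [], []
    for conc, stack in steps:
        if stack.n_frames < min_frames:
            raise QuantifyError(
                f"step at {conc:.3g} M has {stack.n_frames} frames; need >= {min_frames}"
            )
        traces, background = extract_roi_traces(stack, rois)
        for trace in traces.values():
            if subtract_background:
                trace = background_subtract(trace, background)
            trace = compute_trace_ratio(trace)
            conc_rows.append(conc)
            ratio_rows.append(float(np.nanmedian(trace.ratio)))
    df = pd.DataFrame({"c": conc_rows, "r": ratio_rows})
    means = df[df["c"] > 0].groupby("c")["r"].mean()
    zero = df[df["c"] == 0]["r"]
    zero_ion_ratio = float(zero.mean()) if len(zero) else (
        endpoints[0] if endpoints is not None else None
    )
    if endpoints is not None:
        # endpoint standards pin the plateaus outright: a short stepped
        # series cannot constrain four parameters, and the acid/base ratios
        # ARE the physical plateaus of the normalized response
        return fit_hill_ratios(
            means.index.to_numpy(),
            means.to_numpy(),
            zero_ion_ratio=zero_ion_ratio,
            fixed_plateaus=endpoints,
            tag="in_situ",
        )
    # no endpoint standards: keep the plateaus within shouting distance of
    # the observed ratio span so a plateau-free series cannot send the
    # four-parameter fit off to infinity
    r_all = np.asarray(ratio_rows, dtype=float)
    span = float(np.nanmax(r_all) - np.nanmin(r_all))
    plateau_bounds = (
        float(np.nanmin(r_all)) - 0.75 * span,
        float(np.nanmax(r_all)) + 0.75 * span,
    )
    return fit_hill_ratios(
        means.index.to_numpy(),
        means.to_numpy(),
        zero_ion_ratio=zero_ion_ratio,
        plateau_bounds=plateau_bounds,
        tag="in_situ",
    )
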