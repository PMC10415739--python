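"""Per-droplet kinetics analysis: QC, slopes, variability, stoichiometry maps.

Mirrors the droplet data treatment end to end:

1. **QC filtering** — drop traces with negative initial slopes, significant
   intensity jumps, or too little reference signal (out-of-focus proxy).
2. **Reference normalization** — divide the reporter (red) channel by the
   reference (green) channel per frame to cancel common-mode illumination
   changes; used for fixed-stoichiometry runs where every droplet carries
   reference dye.
3. **Initial slopes** — two-point slope s = (f2-f1)/(t2-t1) over a window
   (10-50 s by default, 10-90 s for mixing sweeps), then mean-normalized;
   s is proportional to the initial velocity v0 = k [A]0 [B]0.
4. **Variability statistics** — CV, IQR and MAD of the slope distribution,
   plus a Gaussian fit to the central peak (robust to the s > 1.5 outliers).
5. **Stoichiometry mapping** — per-droplet invader concentration from the
   reference intensity (10-lowest / 10-highest anchors, linear in between)
   and the finite-window slope parabola v = k xi (1-xi) [A]s [B]s overlaid
   with a single fitted scale factor.
6. **Rate-constant fits** — least squares of the closed-form second-order
   solution to a mean fluorescence trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import EmptyResultError, FitError, InputError
from .kinetics import (
    MAX_NU,
    RateParameters,
    SlopeWindow,
    closed_form_conversion,
    finite_window_slope,
    window_slope,
)
from .synthetic_traces import DropletTrace

__all__ = [
    "QCThresholds",
    "QCReport",
    "SlopeSet",
    "VariabilityStats",
    "GaussianPeak",
    "ConcentrationMap",
    "RateFit",
    "OverlayResult",
    "qc_filter",
    "reference_normalize",
    "estimate_slopes",
    "variability_stats",
    "central_peak_fit",
    "estimate_invader_concentrations",
    "fit_rate_constant",
    "cv_decomposition",
    "parabola_overlay",
    "mean_trace",
]


# ---------------------------------------------------------------------------
# QC filtering


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for trace quality control.

    ``jump_threshold``: max frame-to-frame change in the red channel,
    relative to max(local intensity, jump_floor_frac * trace max) — the
    floor keeps additive noise at the dim start of a trace from registering
    as a jump.  ``low_signal``: minimum mean green intensity; ``None`` uses
    half the population median.
    """

    window: SlopeWindow = field(default_factory=SlopeWindow)
    jump_threshold: float = 0.25
    jump_floor_frac: float = 0.25
    low_signal: float | None = None


@dataclass(frozen=True)
class QCReport:
    """Partition of droplet ids into kept and discarded (with reasons)."""

    kept: tuple[str, ...]
    discarded: dict[str, str]  # id -> reason

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)


def _window_indices(times: np.ndarray, window: SlopeWindow) -> tuple[int, int]:
    if window.t1 < times[0] or window.t2 > times[-1]:
        raise InputError(
            f"slope window ({window.t1}, {window.t2}) s outside the "
            f"acquisition span ({times[0]}, {times[-1]}) s"
        )
    return int(np.argmin(np.abs(times - window.t1))), int(
        np.argmin(np.abs(times - window.t2))
    )


def _regression_slope(times: np.ndarray, values: np.ndarray,
                      window: SlopeWindow) -> float:
    mask = (times >= window.t1) & (times <= window.t2)
    if mask.sum() < 2:
        raise InputError("fewer than two frames inside the slope window")
    return float(np.polyfit(times[mask], values[mask], 1)[0])


def qc_filter(
    traces: Sequence[DropletTrace], thresholds: QCThresholds | None = None
) -> QCReport:
    """Deterministically partition traces into analysable and discarded.

    Checks, in order of precedence: fitted red-channel slope over the
    analysis window negative -> ``negative_slope``; mean reference intensity
    below the low-signal threshold -> ``out_of_focus_or_low_signal``;
    relative frame-to-frame intensity change above the jump threshold ->
    ``intensity_jump``.
    """
    if not traces:
        raise InputError("need at least one trace")
    thr = thresholds or QCThresholds()

    mean_greens = np.array([float(np.mean(tr.green)) for tr in traces])
    low_signal = (
        thr.low_signal
        if thr.low_signal is not None
        else 0.5 * float(np.median(mean_greens))
    )

    kept: list[str] = []
    discarded: dict[str, str] = {}
    for tr, g in zip(traces, mean_greens):
        slope = _regression_slope(tr.times, tr.red, thr.window)
        if slope < 0:
            discarded[tr.droplet_id] = "negative_slope"
            continue
        if g < low_signal:
            discarded[tr.droplet_id] = "out_of_focus_or_low_signal"
            continue
        steps = np.abs(np.diff(tr.red))
        floor = thr.jump_floor_frac * float(np.max(np.abs(tr.red)))
        local = np.maximum(np.abs(tr.red[:-1]), floor)
        if local.size and float(np.max(steps / np.maximum(local, 1e-12))) > thr.jump_threshold:
            discarded[tr.droplet_id] = "intensity_jump"
            continue
        kept.append(tr.droplet_id)
    if not kept:
        raise EmptyResultError("QC discarded every trace")
    return QCReport(kept=tuple(kept), discarded=discarded)


# ---------------------------------------------------------------------------
# Normalization and slopes


def reference_normalize(trace: DropletTrace) -> np.ndarray:
    """Red channel divided by green per frame, rescaled to stay in n.u.

    Cancels multiplicative fluctuations shared by both channels (uneven
    illumination, focus drift).  Requires strictly positive green at every
    frame; traces without usable reference signal must take the raw-red
    path instead (mixing sweeps, where green is proportional to xi and may
    legitimately be ~0).
    """
    if np.any(trace.green <= 0):
        raise InputError(
            f"trace {trace.droplet_id}: non-positive reference intensity; "
            "route to QC discard or use the raw-red path"
        )
    return trace.red / trace.green * float(np.mean(trace.green))


@dataclass(frozen=True)
class SlopeSet:
    """Per-droplet initial slopes, raw and mean-normalized."""

    droplet_ids: tuple[str, ...]
    raw: np.ndarray  # n.u. / s
    normalized: np.ndarray  # raw / mean(raw)
    window: SlopeWindow
    mode: str = "two_point"

    @property
    def mean(self) -> float:
        return float(np.mean(self.raw))

    @classmethod
    def from_raw(
        cls,
        raw: Sequence[float] | np.ndarray,
        window: SlopeWindow | None = None,
        droplet_ids: Sequence[str] | None = None,
        mode: str = "two_point",
    ) -> "SlopeSet":
        raw = np.asarray(raw, dtype=float)
        if raw.size == 0:
            raise InputError("slope set must be non-empty")
        ids = tuple(droplet_ids) if droplet_ids is not None else tuple(
            f"d{i}" for i in range(raw.size)
        )
        mean = raw.mean()
        if mean == 0:
            raise InputError("mean slope is zero; cannot mean-normalize")
        return cls(ids, raw, raw / mean, window or SlopeWindow(), mode)


def estimate_slopes(
    traces: Sequence[DropletTrace],
    window: SlopeWindow | None = None,
    mode: str = "two_point",
    normalize: str = "none",
) -> SlopeSet:
    """Initial slope per droplet over the window, then mean-normalized.

    ``two_point`` reads the frames nearest t1 and t2 (the droplet-assay
    estimator); ``regression`` least-squares fits all frames inside the
    window (robustness option).  ``normalize="ref"`` applies reference
    normalization to the red channel first.
    """
    if not traces:
        raise InputError("need at least one trace")
    if mode not in ("two_point", "regression"):
        raise InputError(f"unknown slope mode {mode!r}")
    if normalize not in ("none", "ref"):
        raise InputError(f"unknown normalization {normalize!r}")
    window = window or SlopeWindow()

    raw = np.empty(len(traces))
    for j, tr in enumerate(traces):
        values = reference_normalize(tr) if normalize == "ref" else tr.red
        if mode == "two_point":
            i1, i2 = _window_indices(tr.times, window)
            raw[j] = window_slope(float(values[i1]), float(values[i2]), window)
        else:
            _window_indices(tr.times, window)  # validates span
            raw[j] = _regression_slope(tr.times, values, window)
    return SlopeSet.from_raw(
        raw, window, [tr.droplet_id for tr in traces], mode
    )


# ---------------------------------------------------------------------------
# Variability statistics


@dataclass(frozen=True)
class VariabilityStats:
    """Dispersion summaries of a slope distribution.

    CV and IQR are computed on mean-normalized slopes (dimensionless); MAD
    (mean absolute deviation) on raw slopes, so its magnitude carries the
    raw slope scale.
    """

    cv: float
    iqr: float
    mad: float
    n: int


def variability_stats(slopes: SlopeSet) -> VariabilityStats:
    """CV (sample SD / mean), IQR (type-7 percentiles) and MAD of slopes."""
    if slopes.raw.size < 4:
        raise InputError("need at least 4 slopes for dispersion statistics")
    norm = slopes.normalized
    cv = float(np.std(norm, ddof=1) / np.mean(norm))
    q25, q75 = np.percentile(norm, [25.0, 75.0])  # linear interpolation
    mad = float(np.mean(np.abs(slopes.raw - slopes.raw.mean())))
    return VariabilityStats(cv=cv, iqr=float(q75 - q25), mad=mad, n=norm.size)


@dataclass(frozen=True)
class GaussianPeak:
    """Gaussian fit to the central peak of the normalized-slope histogram."""

    mu: float
    sigma: float
    cv: float  # sigma / mu
    n_used: int


def central_peak_fit(
    slopes: SlopeSet, cut: float = 1.5, bins: int = 30
) -> GaussianPeak:
    """Fit a Gaussian to the histogram of normalized slopes below ``cut``.

    Large-slope outliers (s > ~1.5) inflate the plain CV; restricting to the
    central peak recovers the dispersion of the bulk of the population.
    """
    if slopes.raw.size < 20:
        raise InputError("need at least 20 slopes for a central-peak fit")
    sample = slopes.normalized[slopes.normalized < cut]
    if sample.size < 20 or np.ptp(sample) == 0:
        raise FitError("degenerate histogram: too few slopes below the cut")
    counts, edges = np.histogram(sample, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    p0 = (float(counts.max()), float(np.median(sample)), float(np.std(sample)))
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian central-peak fit failed: {exc}") from exc
    _, mu, sigma = popt
    sigma = abs(float(sigma))
    if mu <= 0:
        raise FitError("Gaussian central-peak fit produced non-positive mean")
    return GaussianPeak(mu=float(mu), sigma=sigma, cv=sigma / float(mu),
                        n_used=int(sample.size))


# ---------------------------------------------------------------------------
# Stoichiometry mapping


@dataclass(frozen=True)
class ConcentrationMap:
    """Per-droplet invader concentration estimated from reference intensity."""

    droplet_ids: tuple[str, ...]
    conc: np.ndarray  # M, clipped to [0, stock]
    i_min: float  # mean of the n_anchor lowest intensities -> 0
    i_max: float  # mean of the n_anchor highest intensities -> stock
    stock: float  # M


def estimate_invader_concentrations(
    traces_or_intensities: Sequence[DropletTrace] | Sequence[float] | np.ndarray,
    stock: float,
    n_anchor: int = 10,
    droplet_ids: Sequence[str] | None = None,
) -> ConcentrationMap:
    """Map reference intensities to invader concentrations.

    The mean of the ``n_anchor`` lowest per-droplet reference intensities
    anchors zero concentration, the mean of the ``n_anchor`` highest anchors
    the stock concentration; intermediate droplets interpolate linearly and
    are clipped to [0, stock].
    """
    if stock <= 0:
        raise InputError("stock must be positive")
    items = list(traces_or_intensities)
    if items and isinstance(items[0], DropletTrace):
        intensities = np.array([float(np.mean(tr.green)) for tr in items])
        ids = tuple(tr.droplet_id for tr in items)
    else:
        intensities = np.asarray(items, dtype=float)
        ids = tuple(droplet_ids) if droplet_ids is not None else tuple(
            f"d{i}" for i in range(intensities.size)
        )
    if intensities.size < n_anchor:
        raise InputError(f"need at least n_anchor={n_anchor} droplets")
    srt = np.sort(intensities)
    i_min = float(srt[:n_anchor].mean())
    i_max = float(srt[-n_anchor:].mean())
    if i_max <= i_min:
        raise InputError("degenerate anchors: highest and lowest intensities equal")
    conc = np.clip(stock * (intensities - i_min) / (i_max - i_min), 0.0, stock)
    return ConcentrationMap(ids, conc, i_min, i_max, stock)


# ---------------------------------------------------------------------------
# Rate-constant fitting


@dataclass(frozen=True)
class RateFit:
    """Second-order rate constant fitted to a mean fluorescence trace."""

    k_hat: float  # M^-1 s^-1
    residual_norm: float  # n.u., RMS residual
    I0: float
    R0: float
    background: float


def mean_trace(traces: Sequence[DropletTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise mean red trace over a set of droplets (times, values)."""
    if not traces:
        raise InputError("need at least one trace")
    times = traces[0].times
    reds = np.stack([tr.red for tr in traces])
    return times, reds.mean(axis=0)


def fit_rate_constant(
    times: np.ndarray,
    values: np.ndarray,
    I0: float,
    R0: float,
    full_scale_conc: float,
    max_nu: float = MAX_NU,
    background: float | None = None,
) -> RateFit:
    """Least-squares fit of the closed-form second-order solution to a trace.

    The model is f(t) = bg + max_nu * [F](t; k, I0, R0) / full_scale_conc;
    k is fitted on a log scale, and the background is fitted too unless
    given.  The trace must span enough curvature (>= 25% conversion of the
    limiting reagent) for the fit to be identifiable.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size != values.size or times.size < 3:
        raise InputError("times and values must have equal length >= 3")
    if I0 <= 0 or R0 <= 0 or full_scale_conc <= 0:
        raise InputError("concentrations must be positive")

    span_nu = float(values.max() - values.min())
    limiting_nu = max_nu * min(I0, R0) / full_scale_conc
    if span_nu < 0.25 * limiting_nu:
        raise FitError(
            f"trace spans {span_nu:.3g} n.u. but >= {0.25 * limiting_nu:.3g} "
            "n.u. (25% conversion) is required for a k fit"
        )

    # initial guess from the earliest finite-difference slope
    s0 = max((values[1] - values[0]) / (times[1] - times[0]), 1e-12)
    k_guess = s0 * full_scale_conc / (max_nu * I0 * R0)

    fit_bg = background is None

    def model(t: np.ndarray, log10_k: float, bg: float) -> np.ndarray:
        f = closed_form_conversion(10.0**log10_k, I0, R0, t)
        return bg + max_nu * np.asarray(f) / full_scale_conc

    try:
        if fit_bg:
            popt, _ = curve_fit(
                model, times, values,
                p0=(np.log10(k_guess), float(values[0])),
                xtol=1e-14, ftol=1e-14, maxfev=20_000,
            )
            log10_k, bg = popt
        else:
            popt, _ = curve_fit(
                lambda t, lk: model(t, lk, background), times, values,
                p0=(np.log10(k_guess),), xtol=1e-14, ftol=1e-14, maxfev=20_000,
            )
            log10_k, bg = popt[0], background
    except RuntimeError as exc:
        raise FitError(f"rate-constant fit did not converge: {exc}") from exc

    resid = values - model(times, log10_k, bg)
    return RateFit(
        k_hat=float(10.0**log10_k),
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        I0=I0,
        R0=R0,
        background=float(bg),
    )


# ---------------------------------------------------------------------------
# Error budget and parabola overlay


def cv_decomposition(rel_dk: float, rel_dA: float, rel_dB: float) -> float:
    """First-order error budget for the initial velocity v0 = k [A]0 [B]0.

    dv0/v0 ~ dk/k + d[A]0/[A]0 + d[B]0/[B]0: exact for common-mode relative
    errors, an upper bound when the components vary independently.
    """
    if rel_dk < 0 or rel_dA < 0 or rel_dB < 0:
        raise InputError("relative errors must be >= 0")
    return rel_dk + rel_dA + rel_dB


@dataclass(frozen=True)
class OverlayResult:
    """Model parabola scaled onto measured slopes (no shape fitting)."""

    scale: float  # n.u. per M: fitted conversion factor
    grid_xi: np.ndarray
    model_slopes: np.ndarray  # M/s on the grid
    residuals: np.ndarray  # data - scale * model at the data points
    argmax_xi: float  # grid argmax of the model curve
    droplet_ids: tuple[str, ...]


def parabola_overlay(
    conc_estimates: ConcentrationMap,
    slopes: SlopeSet,
    params: RateParameters,
    stock_A: float,
    stock_B: float,
    window: SlopeWindow | None = None,
    grid_step: float = 0.01,
) -> OverlayResult:
    """Overlay the model slope-vs-stoichiometry curve on measured slopes.

    Model finite-window slopes are computed by ODE integration on a xi grid;
    the only fitted quantity is a single multiplicative scale (fluorescence
    n.u. per molar), found in closed form by least squares.  The grid argmax
    locates the expected optimum at xi = 1/2 (balanced stoichiometry).
    """
    window = window or SlopeWindow(10.0, 90.0)
    conc_by_id = dict(zip(conc_estimates.droplet_ids, conc_estimates.conc))
    common = [i for i in slopes.droplet_ids if i in conc_by_id]
    if not common:
        raise InputError("no droplet ids shared between slopes and concentrations")
    slope_by_id = dict(zip(slopes.droplet_ids, slopes.raw))
    s_data = np.array([slope_by_id[i] for i in common])
    xi_data = np.array([conc_by_id[i] / conc_estimates.stock for i in common])

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    model = np.array(
        [
            finite_window_slope(
                params, xi * stock_A, (1.0 - xi) * stock_B, window
            )
            for xi in grid
        ]
    )
    m_data = np.interp(xi_data, grid, model)
    denom = float(np.dot(m_data, m_data))
    scale = float(np.dot(s_data, m_data) / denom) if denom > 0 else 0.0
    return OverlayResult(
        scale=scale,
        grid_xi=grid,
        model_slopes=model,
        residuals=s_data - scale * m_data,
        argmax_xi=float(grid[int(np.argmax(model))]),
        droplet_ids=tuple(common),
    )
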