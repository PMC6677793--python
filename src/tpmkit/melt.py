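"""CD thermal-melt analysis: normalization, smoothed derivative, Gaussian
peak decomposition (Tm), and Tm shifts between conditions.

The processing order is fixed: normalize -> Savitzky-Golay smooth ->
differentiate with respect to temperature -> fit a sum of Gaussians (plus a
constant baseline) to df/dT.  Component centers are the melting temperatures
Tm; a transition's shift between two conditions is the difference of the
matching centers with fit uncertainties propagated in quadrature.

``ThermalMeltModel`` wraps the pipeline in a statsmodels-style model/results
pair; the module-level functions expose each step individually.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit.models import ConstantModel, GaussianModel
from scipy.signal import find_peaks, savgol_filter

from .errors import FitError, NormalizationError, ParameterError

MIN_POINTS = 10


@dataclass
class MeltCurve:
    """Temperature-indexed signal (ellipticity in mdeg, or fraction unfolded)."""

    temperature: np.ndarray
    signal: np.ndarray
    label: str | None = None
    replicate: int | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.signal = np.asarray(self.signal, float)
        if self.temperature.shape != self.signal.shape or self.temperature.ndim != 1:
            raise ParameterError("temperature and signal must be equal-length 1-D arrays")
        if len(self.temperature) < MIN_POINTS:
            raise ParameterError(f"melt curve needs >={MIN_POINTS} points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ParameterError("temperature grid must be strictly increasing")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label: str | None = None, replicate: int | None = None
    ) -> "MeltCurve":
        return cls(
            temperature=df["temperature_C"].to_numpy(float),
            signal=df["signal"].to_numpy(float),
            label=label,
            replicate=replicate,
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "MeltCurve":
        return cls.from_dataframe(pd.read_csv(path), **kw)


def average_replicates(curves: Sequence[MeltCurve], grid: np.ndarray | None = None) -> MeltCurve:
    """Average replicate curves on a common grid by linear interpolation."""
    if not curves:
        raise ParameterError("no curves to average")
    if grid is None:
        grid = curves[0].temperature
    sig = np.mean([np.interp(grid, c.temperature, c.signal) for c in curves], axis=0)
    return MeltCurve(temperature=np.asarray(grid, float), signal=sig, label=curves[0].label)


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return slope, intercept


def normalize_melt(
    curve: MeltCurve,
    method: str = "baseline",
    end_fraction: float = 0.10,
    clip: tuple[float, float] = (-0.05, 1.05),
) -> MeltCurve:
    """Fraction unfolded f(T) from a raw melt curve.

    ``baseline`` (default): fit linear pre- and post-transition baselines
    over the first/last ``end_fraction`` of points and compute
    f = (signal - folded) / (unfolded - folded), clipped to ``clip``.
    ``minmax``: simple (s - min) / (max - min) scaling.
    Already-normalized curves pass through unchanged.
    """
    if curve.normalized:
        return curve
    t, s = curve.temperature, curve.signal
    if method == "minmax":
        lo, hi = float(np.min(s)), float(np.max(s))
        if hi - lo < 1e-12:
            raise NormalizationError("flat signal: min and max coincide")
        f = (s - lo) / (hi - lo)
    elif method == "baseline":
        n_end = max(3, int(round(end_fraction * len(t))))
        if 2 * n_end >= len(t):
            raise NormalizationError("baseline windows overlap: curve too short for end_fraction")
        sl_f, ic_f = _linear_fit(t[:n_end], s[:n_end])
        sl_u, ic_u = _linear_fit(t[-n_end:], s[-n_end:])
        folded = sl_f * t + ic_f
        unfolded = sl_u * t + ic_u
        denom = unfolded - folded
        if np.min(np.abs(denom[len(t) // 2 :])) < 1e-9 * max(1.0, np.ptp(s)):
            raise NormalizationError("baselines indistinguishable over the transition")
        f = (s - folded) / denom
    else:
        raise ParameterError(f"unknown normalization method {method!r}")
    f = np.clip(f, *clip)
    return MeltCurve(
        temperature=t, signal=f, label=curve.label, replicate=curve.replicate, normalized=True
    )


def smooth_derivative(curve: MeltCurve, window: int = 5, polyorder: int = 2) -> MeltCurve:
    """Savitzky-Golay smoothing followed by numerical differentiation.

    The smoothed signal is differentiated with central differences at
    interior points and one-sided differences at the ends (per degC).
    Exactly reproduces the derivative of any quadratic at interior points.
    """
    t, s = curve.temperature, curve.signal
    if window % 2 == 0 or window > len(t) or window < polyorder + 2:
        raise ParameterError(
            f"window must be odd, >= polyorder+2 and <= n points (window={window}, "
            f"polyorder={polyorder}, n={len(t)})"
        )
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("Savitzky-Golay smoothing needs a uniform temperature grid")
    smoothed = savgol_filter(s, window_length=window, polyorder=polyorder, mode="interp")
    deriv = np.gradient(smoothed, t)
    return MeltCurve(
        temperature=t, signal=deriv, label=curve.label, replicate=curve.replicate, normalized=False
    )


# ---------------------------------------------------------------------------
# Gaussian peak fit
# ---------------------------------------------------------------------------


@dataclass
class PeakComponent:
    amplitude: float  # peak height of the Gaussian component
    center: float     # Tm, degC
    sigma: float      # Gaussian sigma, degC
    center_stderr: float | None = None


@dataclass
class PeakFit:
    """Sum-of-Gaussians decomposition of a melt-curve derivative."""

    components: list[PeakComponent]
    baseline: float
    rss: float
    n_points: int
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def tm(self) -> list[float]:
        """Melting temperatures: component centers, ascending."""
        return [c.center for c in self.components]

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "rss": self.rss,
            "n_points": self.n_points,
            "components": [
                {
                    "amplitude": c.amplitude,
                    "tm_C": c.center,
                    "sigma_C": c.sigma,
                    "tm_stderr_C": c.center_stderr,
                }
                for c in self.components
            ],
        }


def _initial_centers(t: np.ndarray, d: np.ndarray, n: int) -> list[float]:
    span = np.ptp(d)
    # 1e-12 per degC is far below any physical unfolding signal but above
    # the float noise a smoothed constant curve leaves behind
    if span <= 1e-12:
        raise FitError("flat derivative: no peak to fit")
    idx, props = find_peaks(d, prominence=0.05 * span)
    if len(idx) == 0:
        raise FitError("no peak found in the derivative")
    order = np.argsort(props["prominences"])[::-1]
    centers = [float(t[idx[k]]) for k in order[:n]]
    while len(centers) < n:  # fewer maxima than requested components
        centers.append(float(np.quantile(t, 0.25 + 0.5 * len(centers) / n)))
    return centers


def fit_peaks(
    derivative: MeltCurve,
    n_components: int = 1,
    init_centers: Sequence[float] | None = None,
    fit_baseline: bool = True,
) -> PeakFit:
    """Nonlinear least-squares fit of Gaussian peaks (+ constant) to df/dT.

    Initialization uses the ``n_components`` most prominent local maxima
    unless ``init_centers`` is given.  Components are returned sorted by
    center.  Two centers closer than 0.5 degC raise a degeneracy warning
    (flagged on the result, not fatal).
    """
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    t, d = derivative.temperature, derivative.signal
    if len(t) < 5 * n_components:
        raise ParameterError(f"need >={5 * n_components} points for {n_components} components")
    centers = (
        list(map(float, init_centers)) if init_centers is not None else _initial_centers(t, d, n_components)
    )
    if len(centers) != n_components:
        raise ParameterError("init_centers length must equal n_components")

    model = ConstantModel(prefix="bl_") if fit_baseline else None
    span = float(np.ptp(t))
    for k in range(n_components):
        g = GaussianModel(prefix=f"g{k}_")
        model = g if model is None else model + g
    params = model.make_params()
    if fit_baseline:
        params["bl_c"].set(value=float(np.min(d)))
    height0 = max(float(np.max(d) - np.min(d)), 1e-12)
    for k, c0 in enumerate(centers):
        sigma0 = 2.0
        params[f"g{k}_center"].set(value=c0, min=float(t[0]), max=float(t[-1]))
        params[f"g{k}_sigma"].set(value=sigma0, min=0.05, max=span)
        # lmfit Gaussian amplitude is the area: height * sigma * sqrt(2*pi)
        params[f"g{k}_amplitude"].set(
            value=height0 * sigma0 * np.sqrt(2 * np.pi) / n_components, min=1e-12
        )
    try:
        out = model.fit(d, params, x=t)
    except Exception as exc:  # lmfit raises various numerical errors
        raise FitError(f"Gaussian peak fit failed: {exc}") from exc
    if not out.success:
        raise FitError(f"Gaussian peak fit did not converge: {out.message} (rss={np.sum(out.residual**2):.3g})")

    comps = []
    for k in range(n_components):
        sigma = float(out.params[f"g{k}_sigma"].value)
        area = float(out.params[f"g{k}_amplitude"].value)
        se = out.params[f"g{k}_center"].stderr
        comps.append(
            PeakComponent(
                amplitude=area / (sigma * np.sqrt(2 * np.pi)),
                center=float(out.params[f"g{k}_center"].value),
                sigma=sigma,
                center_stderr=float(se) if se is not None else None,
            )
        )
    comps.sort(key=lambda c: c.center)
    if max(c.amplitude for c in comps) < 1e-9:
        raise FitError("no peak: fitted component heights are all ~0")
    degenerate = any(
        b.center - a.center < 0.5 for a, b in zip(comps, comps[1:])
    )
    if degenerate:
        warnings.warn("two fitted peak centers within 0.5 degC: components degenerate", stacklevel=2)
    return PeakFit(
        components=comps,
        baseline=float(out.params["bl_c"].value) if fit_baseline else 0.0,
        rss=float(np.sum(out.residual**2)),
        n_points=len(t),
        degenerate=degenerate,
    )


def delta_tm(
    control: PeakFit, treated: PeakFit, component: int = 0
) -> tuple[float, float | None]:
    """Tm shift (treated - control) for one matched component.

    Returns (delta, stderr); the uncertainty is the quadrature sum of the
    two center standard errors when both are available.
    """
    try:
        c = control.components[component]
        tr = treated.components[component]
    except IndexError as exc:
        raise IndexError(
            f"component {component} out of range "
            f"(control has {control.n_components}, treated has {treated.n_components})"
        ) from exc
    delta = tr.center - c.center
    if c.center_stderr is None or tr.center_stderr is None:
        return delta, None
    return delta, float(np.hypot(c.center_stderr, tr.center_stderr))


# ---------------------------------------------------------------------------
# model / results wrapper
# ---------------------------------------------------------------------------


class ThermalMeltModel:
    """Full melt pipeline as a model object.

    Build from raw replicate curves (averaged on a common grid), then
    ``fit(n_components)`` runs normalize -> smooth -> differentiate ->
    Gaussian decomposition and returns :class:`ThermalMeltResults`.
    """

    def __init__(
        self,
        curves: Sequence[MeltCurve] | MeltCurve,
        normalize: str | None = "baseline",
        window: int = 5,
        polyorder: int = 2,
    ) -> None:
        if isinstance(curves, MeltCurve):
            curves = [curves]
        self.curve = average_replicates(list(curves))
        self.n_replicates = len(curves)
        self.normalize = normalize
        self.window = window
        self.polyorder = polyorder

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "ThermalMeltModel":
        if "replicate" in df.columns:
            curves = [
                MeltCurve.from_dataframe(g, replicate=int(r))
                for r, g in df.groupby("replicate")
            ]
        else:
            curves = [MeltCurve.from_dataframe(df)]
        return cls(curves, **kw)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "ThermalMeltModel":
        return cls.from_dataframe(pd.read_csv(path), **kw)

    def fit(
        self, n_components: int = 1, init_centers: Sequence[float] | None = None
    ) -> "ThermalMeltResults":
        normalized = (
            normalize_melt(self.curve, method=self.normalize)
            if self.normalize
            else self.curve
        )
        derivative = smooth_derivative(normalized, self.window, self.polyorder)
        peaks = fit_peaks(derivative, n_components=n_components, init_centers=init_centers)
        return ThermalMeltResults(
            model=self, normalized=normalized, derivative=derivative, peaks=peaks
        )


@dataclass
class ThermalMeltResults:
    model: ThermalMeltModel
    normalized: MeltCurve
    derivative: MeltCurve
    peaks: PeakFit

    @property
    def tm(self) -> list[float]:
        return self.peaks.tm

    def summary(self) -> str:
        lines = [
            "Thermal melt: Gaussian decomposition of d(fraction unfolded)/dT",
            f"  points: {self.peaks.n_points}, replicates averaged: {self.model.n_replicates}",
            f"  smoothing: Savitzky-Golay window {self.model.window}, order {self.model.polyorder}",
            f"  components: {self.peaks.n_components}  (rss = {self.peaks.rss:.3g})",
        ]
        for k, c in enumerate(self.peaks.components):
            se = f" +/- {c.center_stderr:.2f}" if c.center_stderr is not None else ""
            lines.append(
                f"    Tm[{k}] = {c.center:6.2f}{se} degC   "
                f"(height {c.amplitude:.4f}, sigma {c.sigma:.2f} degC)"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_C": self.derivative.temperature,
                "dfdT": self.derivative.signal,
            }
        )
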