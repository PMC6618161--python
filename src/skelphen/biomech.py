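"""Extraction of biomechanical parameters from load-displacement curves.

A destructive three-point-bend or compression test yields a sampled
load-displacement trace.  Four parameters summarise it: stiffness (slope of
the linear elastic phase, N/mm), yield load (departure from elasticity, N),
maximum load (N) and fracture load (load at terminal failure, N).

The elastic window is found by exhaustive search over contiguous windows
between the contact point and the load maximum, preferring the longest
window whose linear fit reaches a configurable R² threshold.  Yield is
detected with an offset-from-elastic-line rule and fracture as the largest
single-step post-peak load drop; both rules scale with the maximum load, so
every reported quantity is exactly equivariant under rescaling of the load
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LoadDisplacementCurve",
    "BiomechConfig",
    "ElasticFit",
    "BiomechanicalParameters",
    "CurveAnalysisError",
    "detect_contact_and_elastic",
    "extract_biomech_params",
    "trim_contact",
]


class CurveAnalysisError(ValueError):
    """Raised when a curve cannot be analysed (no elastic region, bad data)."""


@dataclass(frozen=True)
class LoadDisplacementCurve:
    """Sampled displacement (mm) / load (N) trace of one destructive test.

    Parameters
    ----------
    displacement, load:
        Equal-length 1-D arrays.  Displacement must be non-decreasing
        (the actuator is displacement-controlled).
    sample_rate:
        Acquisition rate in Hz; metadata only.
    test_type:
        ``"three_point_bend"`` or ``"compression"``; metadata only, the
        analysis is identical.
    """

    displacement: np.ndarray
    load: np.ndarray
    sample_rate: float = 20.0
    test_type: str = "three_point_bend"
    specimen_id: str = ""

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=float)
        load = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "displacement", disp)
        object.__setattr__(self, "load", load)
        if disp.ndim != 1 or load.ndim != 1 or disp.shape != load.shape:
            raise CurveAnalysisError("displacement and load must be equal-length 1-D arrays")
        if disp.size < 20:
            raise CurveAnalysisError(f"curve too short: {disp.size} samples (need >= 20)")
        if not (np.isfinite(disp).all() and np.isfinite(load).all()):
            raise CurveAnalysisError("curve contains non-finite values")
        if np.any(np.diff(disp) < 0):
            raise CurveAnalysisError("displacement is not non-decreasing")
        if self.test_type not in ("three_point_bend", "compression"):
            raise CurveAnalysisError(f"unknown test_type {self.test_type!r}")

    def __len__(self) -> int:
        return int(self.displacement.size)


@dataclass(frozen=True)
class BiomechConfig:
    """Tunable thresholds of the extraction algorithm (defaults documented)."""

    contact_fraction: float = 0.01
    min_window_fraction: float = 0.10
    r2_min: float = 0.995
    yield_offset_fraction: float = 0.02
    fracture_drop_fraction: float = 0.30
    smooth_window: Optional[int] = None  # centred moving average, detection only
    contact_run: int = 3  # consecutive above-threshold samples defining contact

    def __post_init__(self) -> None:
        if not 0 < self.contact_fraction < 1:
            raise ValueError("contact_fraction must be in (0,1)")
        if not 0 < self.min_window_fraction <= 1:
            raise ValueError("min_window_fraction must be in (0,1]")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must be in (0,1]")
        if self.smooth_window is not None and (
            self.smooth_window < 3 or self.smooth_window % 2 == 0
        ):
            raise ValueError("smooth_window must be odd and >= 3")
        if self.contact_run < 1:
            raise ValueError("contact_run must be >= 1")


@dataclass(frozen=True)
class ElasticFit:
    """Result of elastic-phase detection."""

    contact_index: int
    window: tuple[int, int]  # half-open [start, stop) sample indices
    stiffness: float  # N/mm
    r_squared: float
    intercept: float  # of the load-on-displacement fit, N


@dataclass(frozen=True)
class BiomechanicalParameters:
    yield_load: float
    max_load: float
    fracture_load: float
    stiffness: float
    elastic_window: tuple[int, int]
    r_squared: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.yield_load > self.max_load * (1 + 1e-12):
            raise CurveAnalysisError("yield_load exceeds max_load")
        if self.fracture_load > self.max_load * (1 + 1e-12):
            raise CurveAnalysisError("fracture_load exceeds max_load")
        if self.stiffness <= 0:
            raise CurveAnalysisError("stiffness must be positive")


def _smooth(y: np.ndarray, window: Optional[int]) -> np.ndarray:
    if window is None:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _window_fits(x: np.ndarray, y: np.ndarray):
    """Prefix-sum machinery for O(1) least-squares stats on any window."""
    sx = np.concatenate([[0.0], np.cumsum(x)])
    sy = np.concatenate([[0.0], np.cumsum(y)])
    sxx = np.concatenate([[0.0], np.cumsum(x * x)])
    sxy = np.concatenate([[0.0], np.cumsum(x * y)])
    syy = np.concatenate([[0.0], np.cumsum(y * y)])

    def fit(i: int, j: int) -> tuple[float, float, float]:
        """Slope, intercept, R² of y~x over samples [i, j)."""
        n = j - i
        dx = sxx[j] - sxx[i] - (sx[j] - sx[i]) ** 2 / n
        dy = syy[j] - syy[i] - (sy[j] - sy[i]) ** 2 / n
        dxy = sxy[j] - sxy[i] - (sx[j] - sx[i]) * (sy[j] - sy[i]) / n
        if dx <= 0:
            return np.nan, np.nan, -np.inf
        slope = dxy / dx
        intercept = (sy[j] - sy[i]) / n - slope * (sx[j] - sx[i]) / n
        if dy <= 0:
            # zero load variance: horizontal line, not an elastic segment
            return slope, intercept, -np.inf
        r2 = (dxy * dxy) / (dx * dy)
        return slope, intercept, r2

    return fit


def _find_contact(load_det: np.ndarray, threshold: float, run: int) -> int:
    """First index from which ``run`` consecutive samples meet the threshold.

    Equivalent to "first sample with load >= threshold" on monotone
    noiseless curves; the run requirement keeps isolated noise spikes in
    the pre-contact toe from triggering early.
    """
    above = load_det >= threshold
    if run > 1:
        ok = above.copy()
        for k in range(1, run):
            ok[:-k] &= above[k:]
        ok[-(run - 1):] = above[-(run - 1):]  # allow contact near the end
        above = ok
    if not above.any():
        raise CurveAnalysisError("no elastic region: load never reaches contact threshold")
    return int(np.argmax(above))


def _centered_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Well-conditioned least-squares line fit: slope, intercept, R²."""
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    syy = float(ym @ ym)
    sxy = float(xm @ ym)
    if sxx <= 0 or syy <= 0:
        return np.nan, np.nan, -np.inf
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = sxy * sxy / (sxx * syy)
    return slope, intercept, r2


def detect_contact_and_elastic(
    curve: LoadDisplacementCurve, config: BiomechConfig = BiomechConfig()
) -> ElasticFit:
    """Locate the contact point and the linear elastic window.

    Contact is the first sample whose load reaches
    ``contact_fraction x max(load)``.  The elastic window is anchored at
    the contact sample (the elastic phase begins at contact): among
    windows ``[contact, contact + L)`` with ``L`` at least
    ``min_window_fraction`` of the contact-to-peak span, the longest whose
    linear fit reaches ``r2_min`` is selected.  Trailing samples are then
    trimmed greedily while that strictly improves the fit R², so an
    exactly linear elastic segment is recovered to machine precision even
    when the passing window initially overhangs the yield point.

    Raises
    ------
    CurveAnalysisError
        If no window reaches the R² threshold (the message reports the
        best R² achieved) or the curve is degenerate.
    """
    load_det = _smooth(curve.load, config.smooth_window)
    max_load = float(np.max(load_det))
    if max_load <= 0:
        raise CurveAnalysisError("no elastic region: curve never exceeds zero load")

    contact = _find_contact(load_det, config.contact_fraction * max_load, config.contact_run)
    peak = int(np.argmax(load_det))
    span = peak - contact + 1
    min_len = max(int(np.ceil(config.min_window_fraction * span)), 3)
    if span < min_len:
        raise CurveAnalysisError(
            f"no elastic region: only {span} samples between contact and peak"
        )

    x = curve.displacement[contact : peak + 1]
    y = load_det[contact : peak + 1]
    fit = _window_fits(x, y)

    stop = None
    best_r2 = -np.inf
    for length in range(span, min_len - 1, -1):
        _, _, r2 = fit(0, length)
        best_r2 = max(best_r2, r2)
        if r2 >= config.r2_min:
            stop = length
            break
    if stop is None:
        raise CurveAnalysisError(
            f"no elastic region: best window R²={best_r2:.4f} < {config.r2_min}"
        )

    # Greedy trailing trim: drop post-yield overhang while R² strictly rises.
    _, _, r2 = fit(0, stop)
    while stop > min_len:
        _, _, r2_next = fit(0, stop - 1)
        if r2_next > r2:
            stop -= 1
            r2 = r2_next
        else:
            break

    # Reported slope from the raw (unsmoothed) loads, well-conditioned fit.
    slope, intercept, r2 = _centered_fit(
        curve.displacement[contact : contact + stop],
        curve.load[contact : contact + stop],
    )
    if not np.isfinite(slope) or slope <= 0:
        raise CurveAnalysisError("no elastic region: non-positive elastic slope")
    return ElasticFit(
        contact_index=contact,
        window=(contact, contact + stop),
        stiffness=float(slope),
        r_squared=float(r2),
        intercept=float(intercept),
    )


def extract_biomech_params(
    curve: LoadDisplacementCurve, config: BiomechConfig = BiomechConfig()
) -> BiomechanicalParameters:
    """Extract yield, maximum and fracture loads plus stiffness.

    Yield is the load at the first post-elastic-window sample where the
    elastic-line prediction exceeds the observed load by at least
    ``yield_offset_fraction x max_load``; absent such a sample the curve is
    flagged ``no_distinct_yield`` and yield equals the maximum load.
    Fracture is the load immediately preceding the largest single-step
    post-peak drop, provided that drop is at least
    ``fracture_drop_fraction x max_load``; otherwise the final load is
    reported with a ``no_clean_fracture`` flag.
    """
    elastic = detect_contact_and_elastic(curve, config)
    load_det = _smooth(curve.load, config.smooth_window)
    contact = elastic.contact_index

    peak = contact + int(np.argmax(load_det[contact:]))
    max_load = float(curve.load[contact + int(np.argmax(curve.load[contact:]))])
    flags: list[str] = []

    # --- yield: offset from the elastic line ------------------------------
    predicted = elastic.intercept + elastic.stiffness * curve.displacement
    offset = config.yield_offset_fraction * max_load
    win_stop = elastic.window[1]
    yield_load = max_load
    yield_found = False
    for i in range(win_stop, peak + 1):
        if predicted[i] - load_det[i] >= offset:
            yield_load = float(curve.load[i])
            yield_found = True
            break
    if not yield_found:
        flags.append("no_distinct_yield")
    yield_load = min(yield_load, max_load)

    # --- fracture: largest post-peak single-step drop ---------------------
    # Detected on the raw loads: smoothing would smear the terminal step
    # below threshold, and a step of this size is robust to noise anyway.
    if peak < len(curve) - 1:
        drops = curve.load[peak:-1] - curve.load[peak + 1 :]
        k = int(np.argmax(drops))
        if drops[k] >= config.fracture_drop_fraction * max_load:
            fracture_load = float(curve.load[peak + k])
        else:
            fracture_load = float(curve.load[-1])
            flags.append("no_clean_fracture")
    else:
        fracture_load = float(curve.load[-1])
        flags.append("no_clean_fracture")
    fracture_load = min(fracture_load, max_load)

    return BiomechanicalParameters(
        yield_load=yield_load,
        max_load=max_load,
        fracture_load=fracture_load,
        stiffness=elastic.stiffness,
        elastic_window=elastic.window,
        r_squared=elastic.r_squared,
        flags=tuple(flags),
    )


def trim_contact(
    curve: LoadDisplacementCurve, config: BiomechConfig = BiomechConfig()
) -> LoadDisplacementCurve:
    """Return the curve with the pre-contact toe removed.

    The displacement origin is shifted to the contact sample.  Running the
    extraction on the trimmed curve yields identical parameters
    (idempotence of the analysis).
    """
    load_det = _smooth(curve.load, config.smooth_window)
    max_load = float(np.max(load_det))
    if max_load <= 0:
        raise CurveAnalysisError("cannot trim: curve never exceeds zero load")
    contact = _find_contact(load_det, config.contact_fraction * max_load, config.contact_run)
    return LoadDisplacementCurve(
        displacement=curve.displacement[contact:] - curve.displacement[contact],
        load=curve.load[contact:],
        sample_rate=curve.sample_rate,
        test_type=curve.test_type,
        specimen_id=curve.specimen_id,
    )
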