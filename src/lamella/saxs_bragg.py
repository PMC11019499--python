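"""Bragg-peak analysis of 1-D lamellar SAXS profiles.

A multilamellar stack scatters at harmonically related positions
q_n = 2*pi*n/d.  This module detects those orders on top of a decaying
background, assigns integer orders, fits the repeat distance d by least
squares through the origin (slope of q_n vs n), classifies a profile as
uni- vs multilamellar, converts d and a bilayer thickness into a hydration
layer, and tracks d across a contact-time series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core_io import PeakSettings, SAXSProfile, ValidationError

__all__ = [
    "BraggPeak",
    "BraggPeakSet",
    "LamellarityCall",
    "HydrationLayer",
    "DSpacingSeries",
    "detect_bragg_peaks",
    "assign_orders_and_fit_d",
    "classify_lamellarity",
    "hydration_layer",
    "dspacing_vs_time",
    "analyze_profile",
]


@dataclass
class BraggPeak:
    q: float                 # nm^-1, Gaussian-refined center
    amplitude: float
    width: float             # nm^-1, Gaussian sigma
    prominence: float
    order: int | None = None


@dataclass
class BraggPeakSet:
    """Detected Bragg orders and, once orders are assigned, the fitted
    lamellar repeat d = 2*pi / slope(q_n vs n)."""

    peaks: list[BraggPeak]
    background: tuple[float, float, float] | None = None  # a, b, c of a*q^-b + c
    d: float | None = None
    d_sd: float | None = None
    unassigned: list[BraggPeak] | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def q_values(self) -> np.ndarray:
        return np.array([p.q for p in self.peaks])


def _power_law(q, a, b, c):
    return a * np.power(q, -b) + c


def _robust_sd(x: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _fit_background(
    q: np.ndarray, intensity: np.ndarray, n_iter: int = 6
) -> tuple[tuple[float, float, float], np.ndarray]:
    """Power-law-plus-constant background by iterative peak masking: fit,
    drop points > 2 robust sd above the fit, refit."""
    c0 = float(np.percentile(intensity, 5))
    a0 = max((intensity[0] - c0), 1e-9) * q[0] ** 2
    params = np.array([a0, 2.0, max(c0, 1e-12)])
    mask = np.ones(len(q), dtype=bool)
    for _ in range(n_iter):
        try:
            params, _ = curve_fit(
                _power_law,
                q[mask],
                intensity[mask],
                p0=params,
                bounds=([0.0, 0.0, 0.0], [np.inf, 8.0, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:  # pragma: no cover - fit failed to converge
            break
        bg = np.maximum(_power_law(q, *params), 1e-12)
        z = (intensity - bg) / np.sqrt(bg)  # variance-stabilised for counting noise
        sd = _robust_sd(z[mask])
        new_mask = z < 2.0 * max(sd, 1e-12)
        if new_mask.sum() < max(10, len(q) // 10):
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return (float(params[0]), float(params[1]), float(params[2])), mask


def _gaussian(q, amp, mu, sigma):
    return amp * np.exp(-((q - mu) ** 2) / (2 * sigma**2))


def _refine_peak(
    q: np.ndarray, resid: np.ndarray, i: int, halfwidth: float
) -> tuple[float, float, float]:
    """Local Gaussian fit of a candidate peak; falls back to the raw sample."""
    dq = q[1] - q[0]
    hw = max(4, int(round(halfwidth / dq)))
    sl = slice(max(0, i - hw), min(len(q), i + hw + 1))
    try:
        popt, _ = curve_fit(
            _gaussian,
            q[sl],
            resid[sl],
            p0=[max(resid[i], 1e-9), q[i], 2 * dq],
            bounds=([0.0, q[sl][0], dq / 4], [np.inf, q[sl][-1], halfwidth]),
            maxfev=10000,
        )
        return float(popt[1]), float(popt[0]), float(popt[2])
    except (RuntimeError, ValueError):
        return float(q[i]), float(resid[i]), float(2 * dq)


def detect_bragg_peaks(
    profile: SAXSProfile, settings: PeakSettings | None = None
) -> BraggPeakSet:
    """Find Bragg orders: fit a power-law background by iterative peak
    masking, smooth the residual, and variance-stabilise it by sqrt of the
    local background (counting noise grows with intensity).  Local maxima
    are kept when their prominence reaches both the noise criterion
    (prominence_factor x residual noise sd) and the relative floor
    (min_rel_prominence x sqrt local background); the boundary case
    (exactly at threshold) counts as a peak.  Each survivor is refined by a
    local Gaussian fit on the unscaled residual."""
    s = settings or PeakSettings()
    s.validate()
    q, intensity = profile.q, profile.intensity
    if len(q) < max(50, s.smoothing_window):
        raise ValidationError(
            f"profile too short: {len(q)} points < {max(50, s.smoothing_window)}"
        )
    bg_params, bg_mask = _fit_background(q, intensity)
    bg = np.maximum(_power_law(q, *bg_params), 1e-12)
    resid = uniform_filter1d(intensity - bg, size=s.smoothing_window, mode="nearest")
    # variance-stabilised residual: counting noise scales like sqrt(background)
    z = resid / np.sqrt(bg)
    noise_sd = _robust_sd(z[bg_mask]) if bg_mask.any() else _robust_sd(z)
    prom_floor = max(s.prominence_factor * noise_sd, 1e-12)
    dq = q[1] - q[0]
    # prominence evaluated in a local window so slow baseline drift cannot
    # accumulate into a fake peak; height must clear the threshold too
    wlen = max(15, int(round(2 * s.refine_halfwidth / dq)))
    idx, props = find_peaks(z, prominence=prom_floor, height=prom_floor, wlen=wlen)
    peaks: list[BraggPeak] = []
    for i, prom, height in zip(idx, props["prominences"], props["peak_heights"]):
        threshold = max(prom_floor, s.min_rel_prominence * np.sqrt(bg[i]))
        if prom >= threshold and height >= threshold:  # tie-break: at threshold => peak
            mu, amp, width = _refine_peak(q, resid, int(i), s.refine_halfwidth)
            peaks.append(BraggPeak(q=mu, amplitude=amp, width=width, prominence=float(prom)))
    peaks.sort(key=lambda p: p.q)
    return BraggPeakSet(peaks=peaks, background=bg_params)


def assign_orders_and_fit_d(
    peakset: BraggPeakSet, tolerance: float = 0.15
) -> BraggPeakSet:
    """Assign integer orders by the nearest-integer ratio to the lowest peak
    (relative tolerance) and fit d through the origin:

        slope = sum(n * q_n) / sum(n^2),   d = 2*pi / slope.

    A single peak gives d = 2*pi/q_1 exactly.  Peaks that do not land on an
    integer ratio are reported unassigned and excluded from the fit.
    """
    if peakset.n_peaks == 0:
        raise ValidationError("no peaks to assign orders to")
    q1 = peakset.peaks[0].q
    assigned: dict[int, BraggPeak] = {}
    unassigned: list[BraggPeak] = []
    for peak in peakset.peaks:
        ratio = peak.q / q1
        n = max(1, int(round(ratio)))
        if abs(ratio / n - 1.0) > tolerance:
            unassigned.append(peak)
            continue
        if n in assigned:
            # keep the candidate closer to the harmonic position
            if abs(peak.q / (n * q1) - 1) < abs(assigned[n].q / (n * q1) - 1):
                unassigned.append(assigned[n])
                assigned[n] = replace(peak, order=n)
            else:
                unassigned.append(peak)
            continue
        assigned[n] = replace(peak, order=n)
    if not assigned:
        raise ValidationError("no assignable Bragg orders")
    orders = np.array(sorted(assigned))
    q_n = np.array([assigned[n].q for n in orders])
    slope = float(np.sum(orders * q_n) / np.sum(orders**2))
    d = 2 * np.pi / slope
    d_per_peak = 2 * np.pi * orders / q_n
    d_sd = float(d_per_peak.std(ddof=0)) if len(orders) > 1 else 0.0
    return BraggPeakSet(
        peaks=[assigned[n] for n in orders],
        background=peakset.background,
        d=float(d),
        d_sd=d_sd,
        unassigned=unassigned,
    )


@dataclass
class LamellarityCall:
    label: str                 # 'multilamellar' | 'unilamellar'
    evidence: BraggPeakSet

    @property
    def multilamellar(self) -> bool:
        return self.label == "multilamellar"


def classify_lamellarity(
    profile: SAXSProfile, settings: PeakSettings | None = None
) -> LamellarityCall:
    """Multilamellar iff at least one Bragg order is detected; the peak list
    and background fit travel along as evidence."""
    peaks = detect_bragg_peaks(profile, settings)
    label = "multilamellar" if peaks.n_peaks >= 1 else "unilamellar"
    return LamellarityCall(label=label, evidence=peaks)


@dataclass
class HydrationLayer:
    thickness: float
    flag: str | None  # None | 'thin' | 'negative'


def hydration_layer(
    d: float, bilayer_thickness: float, thin_threshold: float = 0.5
) -> HydrationLayer:
    """Water layer between stacked membranes: d minus the bilayer thickness.
    Negative values are allowed but flagged; small positive ones are flagged
    thin."""
    if d <= 0 or bilayer_thickness <= 0:
        raise ValidationError("d and bilayer thickness must be positive")
    value = d - bilayer_thickness
    flag = None
    if value < 0:
        flag = "negative"
    elif value < thin_threshold:
        flag = "thin"
    return HydrationLayer(thickness=float(value), flag=flag)


def analyze_profile(
    profile: SAXSProfile, settings: PeakSettings | None = None
) -> tuple[LamellarityCall, BraggPeakSet | None]:
    """Peak detection -> order assignment -> d fit; fitted set is None for a
    peak-free (unilamellar) profile."""
    s = settings or PeakSettings()
    call = classify_lamellarity(profile, s)
    if not call.multilamellar:
        return call, None
    return call, assign_orders_and_fit_d(call.evidence, tolerance=s.order_tolerance)


@dataclass
class DSpacingSeries:
    """d-spacing vs contact time; ``table`` has one row per profile
    (time, q1, n_orders, d, lamellarity), NaN where no peak exists."""

    table: pd.DataFrame

    @property
    def delta_d(self) -> float:
        """Reduction of d between the first and last time points where d is
        defined (positive when d shrinks); NaN with < 2 defined entries."""
        defined = self.table["d"].dropna()
        if len(defined) < 2:
            return float("nan")
        return float(defined.iloc[0] - defined.iloc[-1])


def dspacing_vs_time(
    profiles: Sequence[SAXSProfile], settings: PeakSettings | None = None
) -> DSpacingSeries:
    """Run the peak -> order -> d pipeline on every profile of a
    contact-time series."""
    if any(p.contact_time is None for p in profiles):
        raise ValidationError("every profile needs a contact time")
    times = [p.contact_time for p in profiles]
    if len(set(times)) != len(times):
        raise ValidationError("duplicate contact times")
    rows = []
    for p in sorted(profiles, key=lambda p: p.contact_time):
        call, fitted = analyze_profile(p, settings)
        rows.append(
            {
                "time_s": p.contact_time,
                "q1_nm^-1": fitted.peaks[0].q if fitted else float("nan"),
                "n_orders": fitted.n_peaks if fitted else 0,
                "d_nm": fitted.d if fitted else float("nan"),
                "lamellarity": call.label,
            }
        )
    table = pd.DataFrame(rows).rename(columns={"d_nm": "d", "q1_nm^-1": "q1"})
    return DSpacingSeries(table=table)
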