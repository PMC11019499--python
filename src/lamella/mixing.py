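"""Microfluidic flow-focusing dilution bookkeeping.

A center stream (liposome suspension) is sheathed by ethanol side streams
in a rectangular channel.  The quantities that matter downstream of the
scattering analysis are simple: the fully-mixed ethanol fraction set by the
flow-rate ratio, the position <-> residence-time map set by the mean axial
velocity, and the gradual cross-channel homogenisation of ethanol, which is
modelled here as steady plug-flow advection with transverse diffusion

    dc/dx = (D / u) d^2c/dy^2,   no-flux walls,

marched explicitly in x.  Plug flow (uniform u) is deliberate: the mixed
fraction and residence times are velocity-profile independent, and the
cross-channel maps are only compared qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_io import ValidationError

__all__ = [
    "ChannelSpec",
    "ConcentrationField",
    "mean_velocity",
    "mixed_fraction",
    "residence_time",
    "reynolds_number",
    "solve_advection_diffusion",
    "concentration_at_time",
]


@dataclass
class ChannelSpec:
    """Channel geometry and flow settings.

    Defaults are the measurement conditions: 1 mm x 0.7 mm channel, total
    flow 50 uL/min, flow-rate ratio 5 (side:center), pure-ethanol side
    streams, ethanol-water diffusivity 1.2e-9 m^2/s.
    """

    width_mm: float = 1.0
    depth_mm: float = 0.7
    flow_ul_min: float = 50.0
    frr: float = 5.0
    c_stock: float = 100.0        # vol% ethanol in the side streams
    diffusivity_m2_s: float = 1.2e-9

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "flow_ul_min", "c_stock"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.frr < 0:
            raise ValidationError("frr must be >= 0")
        if self.diffusivity_m2_s < 0:
            raise ValidationError("diffusivity must be >= 0")

    @property
    def diffusivity_mm2_s(self) -> float:
        return self.diffusivity_m2_s * 1e6


def mean_velocity(spec: ChannelSpec) -> float:
    """Mean axial velocity u = Q / (width * depth), in mm/s
    (1 uL = 1 mm^3)."""
    area = spec.width_mm * spec.depth_mm
    if area <= 0:
        raise ValidationError("zero channel cross-section")
    return (spec.flow_ul_min / 60.0) / area


def mixed_fraction(spec: ChannelSpec) -> float:
    """Ethanol vol% once side and center streams are completely mixed:
    c_stock * FRR / (FRR + 1)."""
    return spec.c_stock * spec.frr / (spec.frr + 1.0)


def residence_time(spec: ChannelSpec, x_mm) -> np.ndarray | float:
    """Contact time t = x / u at downstream position(s) x (mm)."""
    x = np.asarray(x_mm, dtype=float)
    if np.any(x < 0):
        raise ValidationError("x must be >= 0")
    t = x / mean_velocity(spec)
    return float(t) if t.ndim == 0 else t


def reynolds_number(
    spec: ChannelSpec, density_kg_m3: float = 997.0, viscosity_pa_s: float = 0.89e-3
) -> float:
    """Re = rho * u * D_h / mu with the hydraulic diameter
    D_h = 2 w d / (w + d).  Exposed for orientation only: the result depends
    on the assumed fluid properties and characteristic length."""
    u = mean_velocity(spec) * 1e-3  # m/s
    d_h = 2 * spec.width_mm * spec.depth_mm / (spec.width_mm + spec.depth_mm) * 1e-3
    return density_kg_m3 * u * d_h / viscosity_pa_s


@dataclass
class ConcentrationField:
    """c(x, y) in vol% on a marching grid; x downstream (mm), y across the
    channel (mm)."""

    x: np.ndarray
    y: np.ndarray
    c: np.ndarray          # shape (n_x, n_y)
    u: float               # mm/s
    spec: ChannelSpec

    @property
    def residence_times(self) -> np.ndarray:
        return self.x / self.u

    def mean_concentration(self) -> np.ndarray:
        """Flow-weighted (here: uniform) cross-channel mean at each x."""
        return self.c.mean(axis=1)

    def centerline(self) -> np.ndarray:
        mid = len(self.y) // 2
        if len(self.y) % 2 == 0:
            return self.c[:, mid - 1 : mid + 1].mean(axis=1)
        return self.c[:, mid]

    def center_stream_mask(self) -> np.ndarray:
        half_band = self.spec.width_mm / (2 * (self.spec.frr + 1.0))
        center = self.spec.width_mm / 2
        return np.abs(self.y - center) < half_band

    def stream_average(self) -> np.ndarray:
        mask = self.center_stream_mask()
        return self.c[:, mask].mean(axis=1)


def solve_advection_diffusion(
    spec: ChannelSpec,
    n_y: int = 120,
    x_max_mm: float = 100.0,
    dx_mm: float | None = None,
) -> ConcentrationField:
    """March the plug-flow advection-diffusion equation down the channel.

    Inlet: a step profile with the center stream occupying 1/(FRR+1) of the
    width at c = 0 and the side streams at c_stock.  Walls are no-flux, so
    the cross-channel mean is conserved exactly and c approaches the fully
    mixed fraction at large x.  The explicit step obeys the diffusive
    stability bound dx <= dy^2 u / (2 D); an oversized ``dx_mm`` is
    rejected, naming the bound.
    """
    if n_y < 50:
        raise ValidationError("need at least 50 cross-channel cells")
    u = mean_velocity(spec)
    dy = spec.width_mm / n_y
    y = (np.arange(n_y) + 0.5) * dy
    d_mm = spec.diffusivity_mm2_s
    if d_mm > 0:
        dx_stable = dy**2 * u / (2 * d_mm)
        if dx_mm is None:
            dx = 0.5 * dx_stable
        elif dx_mm > dx_stable:
            raise ValidationError(
                f"dx = {dx_mm} mm is unstable; the bound is "
                f"dx <= dy^2 u / (2 D) = {dx_stable:.6f} mm"
            )
        else:
            dx = dx_mm
    else:
        dx = dx_mm if dx_mm is not None else x_max_mm / 1000.0
    n_x = int(np.ceil(x_max_mm / dx)) + 1
    lam = d_mm * dx / (u * dy**2)

    c = np.full(n_y, spec.c_stock)
    c[np.abs(y - spec.width_mm / 2) < spec.width_mm / (2 * (spec.frr + 1.0))] = 0.0
    field = np.empty((n_x, n_y))
    field[0] = c
    for i in range(1, n_x):
        lap = np.empty_like(c)
        lap[1:-1] = c[2:] - 2 * c[1:-1] + c[:-2]
        lap[0] = c[1] - c[0]        # mirrored ghost cell: no-flux wall
        lap[-1] = c[-2] - c[-1]
        c = c + lam * lap
        field[i] = c
    x = np.arange(n_x) * dx
    return ConcentrationField(x=x, y=y, c=field, u=u, spec=spec)


def concentration_at_time(
    field: ConcentrationField,
    t_s: float,
    summary: Literal["centerline", "stream_average"] = "centerline",
) -> float:
    """Ethanol vol% seen by the center stream after contact time t, by
    inverting t(x) = x/u and sampling the field at that x."""
    if t_s < 0:
        raise ValidationError("t must be >= 0")
    x = t_s * field.u
    if x > field.x[-1]:
        raise ValidationError(
            f"t = {t_s} s maps to x = {x:.2f} mm beyond the simulated "
            f"{field.x[-1]:.2f} mm"
        )
    if summary == "centerline":
        series = field.centerline()
    elif summary == "stream_average":
        series = field.stream_average()
    else:
        raise ValidationError(f"unknown summary {summary!r}")
    return float(np.interp(x, field.x, series))
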