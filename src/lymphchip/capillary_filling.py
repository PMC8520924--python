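"""Capillary pinning vs. viscous filling of the COL1 precursor.

During gel loading the liquid COL1 precursor is injected into the ECM
channel.  A step edge between the ECM channel and the neighbouring
medium channels pins the advancing meniscus: the liquid stays confined
as long as the viscous pressure required to drive the filling flow
(Poiseuille drop along the filled length) stays below the burst pressure
the pinned meniscus can withstand (Young-Laplace with Gibbs edge-angle
augmentation).  This module evaluates both pressures and maps the stable
filling window over a range of fill rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .device_model import DeviceGeometry, Fluid, ValidationError

__all__ = [
    "FillingAssessment",
    "PinningParameters",
    "meniscus_pressure",
    "filling_pressure",
    "filling_stability_map",
]

#: Default COL1 precursor viscosity (Pa s); configurable.
DEFAULT_PRECURSOR_VISCOSITY = 0.01


@dataclass(frozen=True)
class PinningParameters:
    """Wetting parameters at the pinning step edge.

    Contact angles are in degrees.  On a hydrophobic (polydopamine-coated,
    heat-dried) PDMS surface the equilibrium angle is ~100-120 deg; the
    Gibbs criterion lets the apparent angle at a step edge grow by the
    edge expansion angle before the meniscus depins, saturating at 180 deg.
    """

    surface_tension: float = 0.072       # N/m
    contact_angle_top_bottom: float = 110.0
    contact_angle_side: float = 110.0
    edge_expansion_angle: float = 90.0   # step-edge opening angle


@dataclass(frozen=True)
class FillingAssessment:
    """Outcome of the pinning-vs-filling comparison at one fill rate."""

    fill_rate: float       # m^3/s
    p_filling: float       # Pa
    p_meniscus: float      # Pa
    margin: float          # Pa, p_meniscus - p_filling
    stable: bool
    metadata: dict = field(default_factory=dict, compare=False)


def _pinned_angle(contact_angle: float, edge_expansion_angle: float) -> float:
    """Gibbs criterion: apparent angle at the edge, saturated at 180 deg."""
    return min(contact_angle + edge_expansion_angle, 180.0)


def meniscus_pressure(
    sigma: float,
    contact_angle_top_bottom: float,
    contact_angle_side: float,
    edge_expansion_angle: float,
    channel_height: float,
    channel_width: float,
) -> float:
    """Maximum pressure (Pa, >= 0) a meniscus pinned at the step edge holds.

    Young-Laplace burst pressure for a rectangular cross-section,

        P = -2 sigma (cos(theta*_h)/h + cos(theta*_w)/w),

    where theta* = min(theta + edge_expansion_angle, 180 deg) is the
    Gibbs-augmented apparent contact angle at the pinning edge (applied
    to both wall pairs).  Negative values (wicking regime, theta* < 90
    deg) are clamped to zero: such a meniscus withstands no overpressure.
    """
    if not sigma > 0:
        raise ValidationError(f"surface tension must be > 0, got {sigma!r}")
    if not (channel_height > 0 and channel_width > 0):
        raise ValidationError("channel dimensions must be > 0")
    for ang in (contact_angle_top_bottom, contact_angle_side):
        if not 0 < ang <= 180:
            raise ValidationError(f"contact angles must be in (0, 180] deg, got {ang!r}")
    if not 0 <= edge_expansion_angle <= 180:
        raise ValidationError("edge expansion angle must be in [0, 180] deg")

    th_h = math.radians(_pinned_angle(contact_angle_top_bottom, edge_expansion_angle))
    th_w = math.radians(_pinned_angle(contact_angle_side, edge_expansion_angle))
    p = -2.0 * sigma * (math.cos(th_h) / channel_height + math.cos(th_w) / channel_width)
    return max(p, 0.0)


def filling_pressure(
    flow_rate: float,
    viscosity: float,
    channel_width: float,
    channel_height: float,
    filled_length: float,
) -> float:
    """Poiseuille pressure drop (Pa) driving filling of a rectangular duct.

    First-order aspect-ratio-corrected laminar resistance:

        dP = 12 mu L Q / (w h^3 (1 - 0.63 h/w)),   w >= h.
    """
    if channel_height > channel_width:
        raise ValidationError(
            "channel_height exceeds channel_width; the aspect-ratio correction "
            "requires w >= h — swap the axes"
        )
    if not (flow_rate > 0 and viscosity > 0 and filled_length > 0 and channel_height > 0):
        raise ValidationError("flow_rate, viscosity, filled_length and dimensions must be > 0")
    w, h = channel_width, channel_height
    return 12.0 * viscosity * filled_length * flow_rate / (w * h**3 * (1.0 - 0.63 * h / w))


def filling_stability_map(
    fill_rates,
    geometry: DeviceGeometry | None = None,
    fluid: Fluid | None = None,
    pinning: PinningParameters | None = None,
    precursor_viscosity: float = DEFAULT_PRECURSOR_VISCOSITY,
    rtol: float = 1e-6,
) -> tuple[list[FillingAssessment], float | None]:
    """Assess pinning stability for each fill rate.

    The worst case is evaluated: the Poiseuille drop over the fully
    filled channel length.  Returns one :class:`FillingAssessment` per
    rate plus the critical rate (margin = 0, located by bisection to
    relative tolerance ``rtol``) when the scanned range brackets a
    stable-to-burst transition, else ``None``.
    """
    fill_rates = list(fill_rates)
    if not fill_rates:
        raise ValidationError("fill_rates must be non-empty")
    geometry = geometry or DeviceGeometry()
    pinning = pinning or PinningParameters()

    w = geometry.ecm_channel_width
    h = geometry.ecm_channel_height
    length = geometry.channel_length
    p_men = meniscus_pressure(
        pinning.surface_tension,
        pinning.contact_angle_top_bottom,
        pinning.contact_angle_side,
        pinning.edge_expansion_angle,
        h,
        w,
    )

    def margin(q: float) -> float:
        return p_men - filling_pressure(q, precursor_viscosity, w, h, length)

    meta = {"channel_length": length, "precursor_viscosity": precursor_viscosity}
    out = []
    for q in fill_rates:
        p_fill = filling_pressure(q, precursor_viscosity, w, h, length)
        m = p_men - p_fill
        out.append(FillingAssessment(q, p_fill, p_men, m, stable=m > 0, metadata=dict(meta)))

    critical = None
    lo, hi = min(fill_rates), max(fill_rates)
    if margin(lo) * margin(hi) < 0:
        critical = brentq(margin, lo, hi, rtol=rtol)
    return out, critical
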