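"""Fraser-Lee back-calculation of body length at an interior vertebral radius.

The Fraser-Lee model assumes body length is proportional to vertebral centrum
radius once corrected for a biological intercept ``a`` (the length at zero
radius implied by the juvenile length-radius regression):

    L_t = (R_t / R_V) * (L_C - a) + a

where ``R_t`` is the transect distance from the focus to the feature of
interest (here the detected in utero habitat shift), ``R_V`` the full centrum
radius, and ``L_C`` the total length at capture. Defaults come from the
juvenile scalloped hammerhead relation L_C = 17.349 R_V + 14.516 (cm, R_V in
mm); both coefficients are configurable and never re-fit here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BackCalcParams", "fraser_lee", "radius_from_length"]

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class BackCalcParams:
    """Length-radius relation L_C = slope * R_V + intercept."""

    slope: float = 17.349      # cm per mm of centrum radius
    intercept: float = 14.516  # cm; the Fraser-Lee correcting factor a
    radius_unit: str = "mm"    # unit of R_V in the relation ("mm" or "um")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if self.intercept < 0:
            raise ValueError("intercept must be >= 0")
        if self.radius_unit not in ("mm", "um"):
            raise ValueError("radius_unit must be 'mm' or 'um'")


def fraser_lee(
    r_t: float,
    r_v: float,
    l_capture: float,
    params: BackCalcParams = BackCalcParams(),
) -> float:
    """Back-calculated total length (cm) at interior radius ``r_t``.

    ``r_t`` and ``r_v`` must be in the same unit. Guarantees
    a <= L_t <= L_C for 0 <= r_t <= r_v.
    """
    if r_v <= 0:
        raise ValueError("R_V must be > 0")
    if not 0 <= r_t <= r_v:
        raise ValueError(f"R_t must be in [0, R_V]; got R_t={r_t}, R_V={r_v}")
    a = params.intercept
    if l_capture <= a:
        raise ValueError(f"length at capture ({l_capture}) must exceed intercept ({a})")
    return (r_t / r_v) * (l_capture - a) + a


def radius_from_length(l_capture: float, params: BackCalcParams = BackCalcParams()) -> float:
    """Invert the length-radius relation: R_V = (L_C - a) / slope.

    Used by the synthetic generator to assign centrum radii consistent with
    drawn body lengths. Returns the radius in ``params.radius_unit``.
    """
    if l_capture <= params.intercept:
        raise ValueError(
            f"length at capture ({l_capture}) must exceed intercept ({params.intercept})"
        )
    return (l_capture - params.intercept) / params.slope
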