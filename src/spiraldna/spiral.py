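"""Fermat-spiral embedding of sequence positions.

Each 1-based position ``i`` of a sequence maps to the polar angle
``theta = 2*pi*(i-1)/(L-1)`` and radius ``rho = sqrt(theta)`` — the Fermat
spiral. L is a reference length shared across a comparison set (conventionally
the shortest sequence in the set), so position L completes exactly one turn;
later positions keep spiralling outward, which is what lets length differences
be down-weighted by the mass restraint instead of wrapped away. Both theta and
rho are strictly increasing in position, so the embedding is injective and
preserves the global ordering of the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

TWO_PI = 2.0 * math.pi

RESTRAINT_VARIANTS = ("exp-decay", "linear-floor", "none")
COM_VARIANTS = ("as-printed", "true-com")


@dataclass(frozen=True)
class RepresentationParams:
    """Parameters of the massive-point spiral representation.

    Parameters
    ----------
    L : int
        Reference length (>= 2); one full spiral turn spans positions 1..L.
        For multi-sequence sets use the shortest sequence length so all
        descriptors share a geometry.
    epsilon : float
        Scale of the mass restraint applied to positions beyond L
        (default 0.0375). Zero disables the restraint.
    restraint_variant : {"exp-decay", "linear-floor", "none"}
        Functional form of the post-L mass decay (see `mass.restrain_mass`).
    com_variant : {"as-printed", "true-com"}
        Centroid convention for the moment computation (see
        `descriptor.center_of_mass`).
    """

    L: int
    epsilon: float = 0.0375
    restraint_variant: str = "exp-decay"
    com_variant: str = "as-printed"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.restraint_variant not in RESTRAINT_VARIANTS:
            raise ValueError(f"unknown restraint_variant {self.restraint_variant!r}")
        if self.com_variant not in COM_VARIANTS:
            raise ValueError(f"unknown com_variant {self.com_variant!r}")

    def fingerprint(self) -> dict:
        """Parameter record stamped into descriptor outputs so results from
        different runs are only compared when computed alike."""
        return {
            "L": self.L,
            "epsilon": self.epsilon,
            "restraint_variant": self.restraint_variant,
            "com_variant": self.com_variant,
        }


@dataclass(frozen=True)
class SpiralPoint:
    """One nucleotide's embedding on the spiral.

    ``mass`` is None until the mass model has run; afterwards it lies in (0, 1].
    """

    base: str
    position: int
    theta: float
    rho: float
    x: float
    y: float
    mass: float | None = None

    def with_mass(self, mass: float) -> "SpiralPoint":
        return replace(self, mass=mass)


def polar_angle(position: int, L: int) -> float:
    """Polar angle 2*pi*(position-1)/(L-1) of a 1-based sequence position.

    Strictly increasing in position; exceeds 2*pi for positions beyond L
    (the spiral is unbounded — no wrapping).
    """
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return TWO_PI * (position - 1) / (L - 1)


def fermat_radius(theta: float) -> float:
    """Spiral radius rho = sqrt(theta)."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return math.sqrt(theta)


def to_cartesian(theta: float, rho: float) -> tuple[float, float]:
    """Polar (theta, rho) -> Cartesian (rho*cos(theta), rho*sin(theta))."""
    if rho < 0:
        raise ValueError(f"rho must be >= 0, got {rho}")
    return rho * math.cos(theta), rho * math.sin(theta)


def embed_positions(
    positions: Sequence[int], base: str, params: RepresentationParams
) -> list[SpiralPoint]:
    """Embed one base's position list onto the spiral (masses left unset)."""
    points = []
    for p in positions:
        theta = polar_angle(p, params.L)
        rho = fermat_radius(theta)
        x, y = to_cartesian(theta, rho)
        points.append(SpiralPoint(base=base, position=p, theta=theta, rho=rho, x=x, y=y))
    return points
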