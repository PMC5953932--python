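"""The six-level context-mass model and the post-L mass restraint.

Local sequence information enters through a mass attached to each spiral
point. The context of a nucleotide is the 4-window covering its immediate 5'
neighbor, itself, and its two immediate 3' neighbors; each window slot is
scored 1 if it carries the same base as the focal (second) slot, else 0. The
focal slot always scores 1, leaving eight possible match patterns. Grading
first by the repeat count and then by how compactly the repeats are arranged
gives six situations, massed 1/6 .. 6/6:

    0100 -> 1/6        singleton
    0101 -> 2/6        two copies, separated
    1100, 0110 -> 3/6  two copies, adjacent
    1101 -> 4/6        three copies, one gap
    1110, 0111 -> 5/6  three copies, compact
    1111 -> 1          homogeneous window

Window slots that fall outside the sequence (position 1 lacks a 5' neighbor,
the last two positions lack 3' slots) score 0, i.e. mismatch — every position
gets a mass without inventing wrap-around context.

Positions beyond the reference length L are additionally down-weighted
("restrained") so that a long tail contributes large radii but small masses:
gross length differences between distant species are suppressed while small
length differences between close species still register.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from .sequence_io import NucleotideSequence
from .spiral import RepresentationParams, SpiralPoint

#: Mass per context pattern; six distinct levels shared by eight patterns.
MASS_TABLE: Mapping[str, float] = {
    "0100": 1 / 6,
    "0101": 2 / 6,
    "1100": 3 / 6,
    "0110": 3 / 6,
    "1101": 4 / 6,
    "1110": 5 / 6,
    "0111": 5 / 6,
    "1111": 1.0,
}

#: Floor for the linear restraint variant — masses must stay positive because
#: the normalized moment divides by the total mass.
LINEAR_FLOOR = 1e-6


def context_pattern(seq: NucleotideSequence, i: int) -> str:
    """4-bit match pattern of position ``i`` (1-based) against its context.

    The window covers original positions (i-1, i, i+1, i+2); out-of-range
    slots compare as mismatch. The focal bit (slot 2) is always 1.
    """
    n = len(seq)
    if not 1 <= i <= n:
        raise IndexError(f"position {i} out of range 1..{n}")
    focal = seq.residues[i - 1]
    bits = []
    for offset in (-1, 0, 1, 2):
        j = i + offset
        bits.append("1" if 1 <= j <= n and seq.residues[j - 1] == focal else "0")
    return "".join(bits)


def pattern_mass(pattern: str) -> float:
    """Mass of a context pattern (see module docstring for the six levels)."""
    try:
        return MASS_TABLE[pattern]
    except KeyError:
        raise ValueError(
            f"invalid context pattern {pattern!r}: focal bit must be 1"
        ) from None


def restrain_mass(mass: float, position: int, params: RepresentationParams) -> float:
    """Down-weight the mass of a position beyond the reference length L.

    Positions <= L pass through unchanged. Beyond L:

    - ``exp-decay`` (default): ``mass * exp(-epsilon * (position - L))`` —
      smooth, strictly positive, strictly decreasing in position for
      epsilon > 0.
    - ``linear-floor``: ``max(mass * (1 - epsilon*(position - L)), 1e-6)``.
    - ``none``: identity (restraint disabled).
    """
    if params.restraint_variant not in ("exp-decay", "linear-floor", "none"):
        raise ValueError(f"unknown restraint variant {params.restraint_variant!r}")
    if position <= params.L or params.epsilon == 0:
        return mass
    overshoot = position - params.L
    if params.restraint_variant == "exp-decay":
        return mass * math.exp(-params.epsilon * overshoot)
    if params.restraint_variant == "linear-floor":
        return max(mass * (1 - params.epsilon * overshoot), LINEAR_FLOOR)
    if params.restraint_variant == "none":
        return mass
    raise ValueError(f"unknown restraint variant {params.restraint_variant!r}")


def assign_masses(
    seq: NucleotideSequence,
    points_by_base: Mapping[str, Sequence[SpiralPoint]],
    params: RepresentationParams,
) -> dict[str, list[SpiralPoint]]:
    """Attach the restrained context mass to every embedded point.

    ``points_by_base`` must come from embedding the partition of ``seq`` —
    each point's position indexes the original sequence for its context
    window.
    """
    out: dict[str, list[SpiralPoint]] = {}
    n = len(seq)
    for base, points in points_by_base.items():
        massed = []
        for pt in points:
            if not 1 <= pt.position <= n or seq.residues[pt.position - 1] != pt.base:
                raise ValueError(
                    f"point ({pt.base}, {pt.position}) does not match sequence {seq.id!r}"
                )
            m = pattern_mass(context_pattern(seq, pt.position))
            massed.append(pt.with_mass(restrain_mass(m, pt.position, params)))
        out[base] = massed
    return out
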