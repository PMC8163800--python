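"""Combinatorics of mutant-subunit arrangements on a hexameric ring.

NSF is a homohexamer.  When wild-type (WT) and mutant protomers are mixed
and re-hexamerized, each hexamer carries a random arrangement of mutants.
Because the ring is rotationally symmetric, arrangements that differ only
by rotation are experimentally indistinguishable; this module enumerates
placements, groups them into rotational classes, and evaluates geometric
binding rules (e.g. "an alpha-SNAP-binding site needs three consecutive WT
N-domains") to predict which composition classes remain binding-competent.

Rotational symmetry only is used (no reflection): a ring viewed from the
fixed face of the complex distinguishes mirror-image arrangements, and the
class inventory for three mutants (ABC/ABD/ACD/ACE) relies on ABD and ACD
being distinct classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd

N_SUBUNITS = 6
_POSITION_LETTERS = "ABCDEF"


@dataclass(frozen=True)
class RingArrangement:
    """An occupancy pattern on the 6-ring; ``True`` marks a mutant subunit."""

    mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.mask) != N_SUBUNITS:
            raise ValueError(f"ring must have {N_SUBUNITS} positions, got {len(self.mask)}")
        object.__setattr__(self, "mask", tuple(bool(b) for b in self.mask))

    @property
    def n_mutant(self) -> int:
        return sum(self.mask)

    def rotate(self, shift: int) -> "RingArrangement":
        s = shift % N_SUBUNITS
        return RingArrangement(self.mask[s:] + self.mask[:s])

    def rotations(self) -> list["RingArrangement"]:
        return [self.rotate(s) for s in range(N_SUBUNITS)]

    def canonical(self) -> "RingArrangement":
        """Canonical rotation: colexicographically smallest mutant positions.

        Among all rotations, pick the one whose sorted mutant-position
        tuple is smallest when compared from the largest element down.
        This anchors a mutant at position A and reproduces the standard
        class names (ABC, ABD, ACD, ACE for three mutants; AB, AC, AD for
        two).
        """
        def colex_key(arr: "RingArrangement"):
            pos = tuple(i for i, m in enumerate(arr.mask) if m)
            return tuple(reversed(pos))

        return min(self.rotations(), key=colex_key)

    @property
    def label(self) -> str:
        """Positional label of the mutants in canonical form (A = position 0)."""
        can = self.canonical()
        if can.n_mutant == 0:
            return "WT"
        return "".join(_POSITION_LETTERS[i] for i, m in enumerate(can.mask) if m)


@dataclass(frozen=True)
class ArrangementClass:
    """A rotational equivalence class of arrangements with fixed mutant count."""

    representative: RingArrangement
    orbit_size: int
    fraction: float
    label: str


@dataclass(frozen=True)
class MixtureSpec:
    """Random mixing of mutant and WT protomers at mutant fraction ``x``."""

    mutant_fraction: float
    n_subunits: int = N_SUBUNITS

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeometricRule:
    """A rotation-invariant predicate deciding binding competence.

    The predicate must be deterministic and invariant under rotation of its
    argument; :func:`is_rotation_invariant` checks the latter exhaustively.
    """

    name: str
    predicate: Callable[[RingArrangement], bool] = field(compare=False)

    def __call__(self, arrangement: RingArrangement) -> bool:
        return bool(self.predicate(arrangement))


def _three_consecutive_wt(arr: RingArrangement) -> bool:
    m = arr.mask
    return any(not m[i] and not m[(i + 1) % 6] and not m[(i + 2) % 6] for i in range(6))


def _no_diagonal_pair(arr: RingArrangement) -> bool:
    m = arr.mask
    return not any(m[i] and m[(i + 3) % 6] for i in range(3))


#: Requires an intact triple of consecutive WT N-domains — the footprint of
#: one alpha-SNAP dimer spanning three neighboring subunits.  Rejects the
#: alternating (ACE) class, i.e. treats binding through only two N-domains
#: as impossible.
THREE_CONSECUTIVE_WT = GeometricRule("three_consecutive_wt_n_domains", _three_consecutive_wt)

#: Forbids simultaneous loss of two diametrically opposed N-domains, but
#: permits the alternating (ACE) class — the permissive variant in which
#: two non-adjacent N-domains may still suffice.
NO_DIAGONAL_PAIR_MISSING = GeometricRule("no_diagonal_pair_missing", _no_diagonal_pair)

RULES: dict[str, GeometricRule] = {
    THREE_CONSECUTIVE_WT.name: THREE_CONSECUTIVE_WT,
    NO_DIAGONAL_PAIR_MISSING.name: NO_DIAGONAL_PAIR_MISSING,
}


def enumerate_placements(k: int) -> list[RingArrangement]:
    """All C(6, k) distinct placements of ``k`` mutant subunits on the ring."""
    if not 0 <= k <= N_SUBUNITS:
        raise ValueError(f"mutant count must be 0..{N_SUBUNITS}, got {k}")
    out = []
    for pos in itertools.combinations(range(N_SUBUNITS), k):
        mask = tuple(i in pos for i in range(N_SUBUNITS))
        out.append(RingArrangement(mask))
    return out


def rotation_classes(placements: Sequence[RingArrangement]) -> list[ArrangementClass]:
    """Group placements into rotational equivalence classes.

    All placements must share the same mutant count; class fractions are
    orbit_size / C(6, k) and sum to one.
    """
    ks = {p.n_mutant for p in placements}
    if len(ks) != 1:
        raise ValueError(f"placements must share one mutant count, got {sorted(ks)}")
    k = ks.pop()
    total = comb(N_SUBUNITS, k)
    orbits: dict[tuple[bool, ...], int] = {}
    for p in placements:
        orbits[p.canonical().mask] = orbits.get(p.canonical().mask, 0) + 1
    if sum(orbits.values()) != total:
        raise ValueError(f"expected all {total} placements of k={k}, got {sum(orbits.values())}")
    classes = []
    for mask, orbit in sorted(orbits.items(), key=lambda kv: RingArrangement(kv[0]).label):
        rep = RingArrangement(mask)
        classes.append(
            ArrangementClass(
                representative=rep,
                orbit_size=orbit,
                fraction=orbit / total,
                label=rep.label,
            )
        )
    return classes


def classes_for_k(k: int) -> list[ArrangementClass]:
    """Convenience: rotational classes of all placements with ``k`` mutants."""
    return rotation_classes(enumerate_placements(k))


def mixing_distribution(spec: MixtureSpec) -> np.ndarray:
    """Binomial distribution of mutant counts per hexamer under random mixing.

    P(k) = C(6, k) x^k (1-x)^(6-k) for independent protomer draws at mutant
    fraction x.
    """
    x = spec.mutant_fraction
    k = np.arange(spec.n_subunits + 1)
    return np.array([comb(spec.n_subunits, int(i)) for i in k]) * x**k * (1 - x) ** (spec.n_subunits - k)


def functional_fraction(rule: GeometricRule, k: int) -> float:
    """Fraction of k-mutant placements that satisfy ``rule``.

    Weighting by orbit size is automatic because every placement (not every
    class) counts once; rotation invariance of the rule makes the two views
    agree.
    """
    placements = enumerate_placements(k)
    return sum(rule(p) for p in placements) / len(placements)


def predicted_avidity_profile(rule: GeometricRule, spec: MixtureSpec | None = None) -> pd.DataFrame:
    """Predicted relative avidity by mutant count, normalized to k = 1.

    The measurable quantity is the enrichment of each composition class in
    the bound population relative to the unselected pool; under a hard
    geometric rule that enrichment is the binding-competent fraction, so
    the profile is functional_fraction(k) / functional_fraction(1).
    """
    f1 = functional_fraction(rule, 1)
    if f1 == 0:
        raise ZeroDivisionError("cannot normalize: no single-mutant placement satisfies the rule")
    rows = []
    for k in range(N_SUBUNITS + 1):
        fk = functional_fraction(rule, k)
        rows.append({"k": k, "functional_fraction": fk, "relative_avidity": fk / f1})
    return pd.DataFrame(rows)


def is_rotation_invariant(rule: GeometricRule) -> bool:
    """Exhaustively verify rule(arr) == rule(rotate(arr)) for all arrangements."""
    for k in range(N_SUBUNITS + 1):
        for p in enumerate_placements(k):
            vals = {rule(r) for r in p.rotations()}
            if len(vals) != 1:
                return False
    return True
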