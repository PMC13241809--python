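"""Fractional-polynomial (FP) age smooths.

An FP specification is a non-decreasing multiset of powers drawn from the
Royston–Altman set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}.  For a positive shifted
age ``a``, power ``p`` contributes the column ``a**p`` (``ln a`` for p = 0);
a power repeated k >= 2 times contributes the base column multiplied by
``ln(a)**(j-1)`` for its j-th occurrence.  Ages are shifted by a positive
``age_offset`` before transformation so that age 0 is admissible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ALLOWED_POWERS", "FPSpec", "fp_basis", "enumerate_fp_specs"]

#: Canonical Royston–Altman power set.
ALLOWED_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True, order=True)
class FPSpec:
    """A fractional-polynomial specification: a sorted tuple of powers.

    Lengths 1–3 arise from model enumeration; the empty tuple denotes an
    intercept-only (constant) predictor and is accepted by the fitter but
    never produced by :func:`enumerate_fp_specs`.
    """

    powers: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        powers = tuple(float(p) for p in self.powers)
        if len(powers) > 3:
            raise ValueError(f"FP order is at most 3, got {len(powers)} powers")
        if any(not np.isfinite(p) for p in powers):
            raise ValueError("FP powers must be finite")
        if list(powers) != sorted(powers):
            raise ValueError(f"FP powers must be non-decreasing, got {powers}")
        object.__setattr__(self, "powers", powers)

    @property
    def order(self) -> int:
        return len(self.powers)

    def __str__(self) -> str:  # compact, e.g. "(0, 1)" or "()"
        return "(" + ", ".join(f"{p:g}" for p in self.powers) + ")"


def fp_basis(ages: np.ndarray, spec: FPSpec, age_offset: float = 1.0) -> np.ndarray:
    """Evaluate the FP basis columns for ``spec`` at ``ages``.

    Returns an ``(n, order)`` array; the empty spec yields ``(n, 0)``.
    Raises ``ValueError`` if any shifted age is non-positive.
    """
    ages = np.asarray(ages, dtype=float)
    a = ages + float(age_offset)
    if a.size and np.nanmin(a) <= 0:
        raise ValueError(
            f"shifted ages must be positive; min(age + {age_offset}) = {np.nanmin(a)}"
        )
    if not np.all(np.isfinite(a)):
        raise ValueError("ages must be finite")
    n = a.shape[0] if a.ndim else 1
    a = np.atleast_1d(a)
    if spec.order == 0:
        return np.empty((n, 0))
    loga = np.log(a)
    cols = []
    seen: dict[float, int] = {}
    for p in spec.powers:
        rep = seen.get(p, 0)
        base = loga if p == 0.0 else a**p
        cols.append(base * loga**rep if rep else base)
        seen[p] = rep + 1
    return np.column_stack(cols)


def enumerate_fp_specs(
    power_set: tuple[float, ...] = ALLOWED_POWERS, max_order: int = 3
) -> list[FPSpec]:
    """All FP specs (power multisets) of order 1..``max_order``.

    Deterministic order: ascending order (length), then lexicographic in the
    sorted powers.  With the canonical 8-power set this yields 8, 44 and 164
    specs for max_order 1, 2 and 3.
    """
    if max_order not in (1, 2, 3):
        raise ValueError(f"max_order must be 1, 2 or 3, got {max_order}")
    powers = tuple(sorted(float(p) for p in power_set))
    if len(set(powers)) != len(powers):
        raise ValueError("power_set contains duplicates")
    specs: list[FPSpec] = []
    for order in range(1, max_order + 1):
        for combo in itertools.combinations_with_replacement(powers, order):
            specs.append(FPSpec(combo))
    return specs
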