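"""Integer lipid allocation under area-per-lipid and ratio constraints.

Given the free leaflet area A_free and the requested area per lipid
(APL), the total lipid count is the nearest integer to A_free/APL,

    N_max = [A_free / APL]

which bounds the count error by 0.5 lipids regardless of patch size.
The total is then allocated across lipid types: each type first receives
the floor of its ideal share,

    N_min = sum_i floor(w_i / sum_j w_j * N_max)

and the remaining N_max - N_min lipids are assigned one at a time to the
type that is currently most underrepresented *relative to its requested
ratio*, i.e. with the largest relative deficit

    d_i = (ideal_i - count_i) / ideal_i,   ideal_i = w_i / sum w * N_max.

This greedy fill minimises the worst relative deficit over all integer
compositions that respect the floors (verified exhaustively in the test
suite for small instances).

For comparison, :func:`insane_count` reproduces the counting formula of
the widely used *insane* bilayer tool exactly as published,

    N_insane = [x / APL] * [y / APL]

note that this expression divides a length by an area; it is kept
verbatim as the reference formula for the accuracy study rather than
"repaired", and its large deviation from the ideal count is precisely
what the accuracy sweep quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "ideal_count",
    "max_count",
    "floor_allocation",
    "fill_to_max",
    "allocate",
    "insane_count",
    "DeviationRecord",
    "accuracy_sweep",
    "sweep_to_csv",
]


def round_half_away(x: float) -> int:
    """Nearest integer with halves rounded away from zero.

    The "[.]" bracket of the counting formulas; chosen over banker's
    rounding for platform-independent reproducibility.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def ideal_count(a_free: float, apl: float) -> float:
    """Ideal (real-valued) lipid count A_free/APL, no rounding."""
    if not (apl > 0):
        raise ValueError(f"apl must be > 0, got {apl}")
    if a_free < 0:
        raise ValueError(f"a_free must be >= 0, got {a_free}")
    return a_free / apl


def max_count(a_free: float, apl: float) -> int:
    """Highest allowed lipid count: A_free/APL rounded to nearest integer."""
    return round_half_away(ideal_count(a_free, apl))


def floor_allocation(weights: dict[str, float], n_max: int) -> tuple[dict[str, int], int]:
    """Per-type floors of the ideal shares.

    Returns ``(counts, n_min)`` with ``counts[i] = floor(w_i/sum_w * n_max)``
    and ``n_min = sum(counts)``.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    if not weights:
        if n_max > 0:
            raise ValueError("cannot allocate lipids with an empty composition")
        return {}, 0
    total_w = 0.0
    for name, w in weights.items():
        if not (w > 0):
            raise ValueError(f"ratio weight for {name!r} must be positive, got {w}")
        total_w += w
    counts = {name: int(math.floor(w / total_w * n_max)) for name, w in weights.items()}
    return counts, sum(counts.values())


def fill_to_max(counts: dict[str, int], weights: dict[str, float], n_max: int) -> dict[str, int]:
    """Top the floor allocation up to ``n_max``.

    Each of the remaining lipids goes to the type with the largest
    relative deficit ``(ideal_i - count_i)/ideal_i``; ties are broken by
    the declaration order of the composition (dict insertion order).
    """
    counts = dict(counts)
    total_w = sum(weights.values())
    names = list(weights)
    ideal = {n: weights[n] / total_w * n_max for n in names}
    remaining = n_max - sum(counts.values())
    if remaining < 0:
        raise ValueError("counts already exceed n_max")
    for _ in range(remaining):
        best: Optional[str] = None
        best_d = -math.inf
        for n in names:
            d = (ideal[n] - counts[n]) / ideal[n]
            if d > best_d + 1e-12:  # strict improvement; first wins ties
                best, best_d = n, d
        counts[best] += 1
    return counts


def allocate(weights: dict[str, float], a_free: float, apl: float):
    """Full allocation pipeline: floors, then greedy fill.

    Returns a :class:`~cgbuild.core.LeafletPlan`.
    """
    from .core import LeafletPlan

    n_max = max_count(a_free, apl)
    floors, n_min = floor_allocation(weights, n_max)
    counts = fill_to_max(floors, weights, n_max)
    return LeafletPlan(counts=counts, n_min=n_min, n_max=n_max, a_free=a_free)


def fill_to_max_absolute(counts: dict[str, int], weights: dict[str, float],
                         n_max: int) -> dict[str, int]:
    """Alternative prioritisation: fill by largest *absolute* deficit.

    Exposed behind the ``priority='absolute'`` flag of the build spec;
    the default relative-deficit rule is usually preferable because it
    protects rare lipid types.
    """
    counts = dict(counts)
    total_w = sum(weights.values())
    names = list(weights)
    ideal = {n: weights[n] / total_w * n_max for n in names}
    for _ in range(n_max - sum(counts.values())):
        best, best_d = None, -math.inf
        for n in names:
            d = ideal[n] - counts[n]
            if d > best_d + 1e-12:
                best, best_d = n, d
        counts[best] += 1
    return counts


def insane_count(x: float, y: float, apl: float) -> int:
    """Reference leaflet count of the *insane* tool, [x/APL]*[y/APL].

    Implemented literally as published (length divided by area in each
    bracket); serves only as the comparison baseline of the accuracy
    study, never for building.
    """
    if not (x > 0 and y > 0):
        raise ValueError("box sides must be > 0")
    if not (apl > 0):
        raise ValueError(f"apl must be > 0, got {apl}")
    return round_half_away(x / apl) * round_half_away(y / apl)


@dataclass
class DeviationRecord:
    """Accuracy of one square-patch build at one size.

    ``dev_*`` are N_built/N_ideal ratios (1.0 is perfect);
    ``ratio_dev`` is the interleaflet ratio deviation
    (N_up,built : N_low,built) / (N_up,ideal : N_low,ideal), present only
    for asymmetric sweeps.
    """

    side: float
    n_ideal_upper: float
    n_ideal_lower: float
    n_built_upper: int
    n_built_lower: int
    n_insane_upper: int
    n_insane_lower: int
    dev_built: float
    dev_insane: float
    ratio_dev: Optional[float] = None
    ratio_dev_insane: Optional[float] = None


def accuracy_sweep(side_min: float = 4.0, side_max: float = 51.0, step: float = 0.05,
                   apl_upper: float = 0.6, apl_lower: Optional[float] = None
                   ) -> list[DeviationRecord]:
    """Count-accuracy sweep over square membrane patches.

    For each side length the upper-leaflet count is computed through the
    nearest-integer pathway and through the *insane* reference formula,
    and both are compared against the ideal real-valued count.  With
    ``apl_lower`` set (asymmetric membrane) the interleaflet ratio
    deviation is recorded as well.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if side_max < side_min:
        raise ValueError("empty sweep range")
    symmetric = apl_lower is None
    apl_lo = apl_upper if symmetric else apl_lower
    records: list[DeviationRecord] = []
    n_steps = int(round((side_max - side_min) / step))
    for i in range(n_steps + 1):
        side = side_min + i * step
        area = side * side
        n_id_up = ideal_count(area, apl_upper)
        n_id_lo = ideal_count(area, apl_lo)
        n_up = max_count(area, apl_upper)
        n_lo = max_count(area, apl_lo)
        n_ins_up = insane_count(side, side, apl_upper)
        n_ins_lo = insane_count(side, side, apl_lo)
        rec = DeviationRecord(
            side=side,
            n_ideal_upper=n_id_up, n_ideal_lower=n_id_lo,
            n_built_upper=n_up, n_built_lower=n_lo,
            n_insane_upper=n_ins_up, n_insane_lower=n_ins_lo,
            dev_built=n_up / n_id_up,
            dev_insane=n_ins_up / n_id_up,
        )
        if not symmetric:
            rec.ratio_dev = (n_up / n_lo) / (n_id_up / n_id_lo)
            rec.ratio_dev_insane = (n_ins_up / n_ins_lo) / (n_id_up / n_id_lo)
        records.append(rec)
    return records


def sweep_to_csv(records: Iterable[DeviationRecord], path: str) -> None:
    """Export sweep records as CSV."""
    import pandas as pd

    rows = [{
        "side": r.side,
        "n_ideal": r.n_ideal_upper,
        "n_built": r.n_built_upper,
        "n_insane": r.n_insane_upper,
        "dev_built": r.dev_built,
        "dev_insane": r.dev_insane,
        "ratio_dev": r.ratio_dev,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
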