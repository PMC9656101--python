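"""Molecular-formula decomposition of accurate masses under element bounds.

Given an observed m/z, enumerate every CHNO composition whose exact ion mass
falls inside a ppm window (with an absolute floor for low masses), under
per-element maximum counts.  The default bounds are the formula-predictor
settings used for the alkaloid screen: C<=30, H<=60, O<=20, N<=10, with
MS1/MS2 tolerances of 5 and 10 ppm.

Two routes are provided: :func:`decompose` (depth-first search with residual
mass pruning) and :func:`brute_force_decompose` (vectorised full enumeration),
which serves as the correctness oracle in the test suite.  No valence/RDBE
filter is applied by default; an even-electron plausibility filter can be
enabled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formula import ATOMIC_MASSES, ELECTRON_MASS, Formula, monoisotopic_mz, ppm_error

__all__ = ["ElementBounds", "ToleranceSpec", "decompose", "brute_force_decompose"]

DEFAULT_BOUNDS = {"C": 30, "H": 60, "N": 10, "O": 20}


@dataclass(frozen=True)
class ElementBounds:
    """Per-element maximum counts for the decomposition search."""

    maxima: tuple[tuple[str, int], ...] = tuple(sorted(DEFAULT_BOUNDS.items()))

    @classmethod
    def from_dict(cls, maxima: dict[str, int]) -> "ElementBounds":
        for sym, n in maxima.items():
            if sym not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol {sym!r}")
            if n < 0:
                raise ValueError(f"negative maximum for {sym!r}")
        return cls(tuple(sorted(maxima.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.maxima)


@dataclass(frozen=True)
class ToleranceSpec:
    """A ppm tolerance with an absolute floor in u.

    The effective window at mass m is ``max(ppm * m / 1e6, absolute_floor)``.
    The 1.5-mDa default floor keeps low-mass diagnostic ions (the m/z 58
    iminium family ion is routinely measured 12-15 ppm high) inside the
    window without loosening high-mass matching.
    """

    ppm: float = 5.0
    absolute_floor: float = 0.0015

    def __post_init__(self) -> None:
        if self.ppm < 0 or self.absolute_floor < 0:
            raise ValueError("tolerance components must be non-negative")

    def window(self, mz: float) -> float:
        return max(self.ppm * mz * 1e-6, self.absolute_floor)


def _even_electron_plausible(counts: dict[str, int]) -> bool:
    # Ring-plus-double-bond equivalents of the cation composition must land on
    # a half-integer >= -0.5 for an even-electron CHNO cation.
    rdbe = counts.get("C", 0) - counts.get("H", 0) / 2 + counts.get("N", 0) / 2 + 1
    return rdbe >= 0 and (rdbe * 2) % 2 == 1


def _sort_results(results: list[tuple[Formula, float]], mz: float) -> list[Formula]:
    results.sort(key=lambda fm: (abs(ppm_error(mz, fm[1])), fm[0].hill()))
    return [f for f, _ in results]


def _validate(mz: float, bounds: ElementBounds) -> None:
    if mz <= 0:
        raise ValueError("observed m/z must be positive")
    if not bounds.maxima:
        raise ValueError("element bounds must not be empty")


def decompose(
    mz: float,
    charge: int = 1,
    tol: ToleranceSpec = ToleranceSpec(),
    bounds: ElementBounds = ElementBounds(),
    even_electron_filter: bool = False,
) -> list[Formula]:
    """Enumerate formulas within tolerance of ``mz``, sorted by |ppm error|.

    The search runs over elements in decreasing atomic mass; each branch is
    pruned when the residual mass cannot be completed by the remaining
    (lighter) elements even at their count bounds, which keeps the default
    bound space (~440k compositions) to a few thousand visited nodes.
    """
    _validate(mz, bounds)
    if charge not in (0, 1):
        raise ValueError(f"unsupported charge {charge}")
    window = tol.window(mz)
    # Work on the summed-atom target: ion mass + charge * electron mass.
    target = mz + charge * ELECTRON_MASS
    elements = sorted(
        bounds.maxima, key=lambda item: ATOMIC_MASSES[item[0]], reverse=True
    )
    masses = [ATOMIC_MASSES[s] for s, _ in elements]
    # max attainable mass from element i onward, at full bounds
    suffix_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * elements[i][1]

    results: list[tuple[Formula, float]] = []
    counts: dict[str, int] = {}

    def search(i: int, acc: float) -> None:
        if acc > target + window:
            return
        if acc + suffix_max[i] < target - window:
            return
        if i == len(elements):
            if abs(acc - target) <= window and any(counts.values()):
                f = Formula.from_counts(counts, charge)
                if not even_electron_filter or _even_electron_plausible(
                    f.as_dict()
                ):
                    results.append((f, acc - charge * ELECTRON_MASS))
            return
        sym, cap = elements[i]
        m = masses[i]
        # tightest admissible count range for this element
        lo = max(0, int(np.ceil((target - window - acc - suffix_max[i + 1]) / m)))
        hi = min(cap, int(np.floor((target + window - acc) / m)))
        for n in range(lo, hi + 1):
            counts[sym] = n
            search(i + 1, acc + n * m)
        counts.pop(sym, None)

    search(0, 0.0)
    return _sort_results(results, mz)


def brute_force_decompose(
    mz: float,
    charge: int = 1,
    tol: ToleranceSpec = ToleranceSpec(),
    bounds: ElementBounds = ElementBounds(),
    even_electron_filter: bool = False,
) -> list[Formula]:
    """Reference oracle: full enumeration of the bound grid (vectorised).

    Identical contract to :func:`decompose`; intended for tests with small
    bounds where the grid stays affordable.
    """
    _validate(mz, bounds)
    if charge not in (0, 1):
        raise ValueError(f"unsupported charge {charge}")
    window = tol.window(mz)
    target = mz + charge * ELECTRON_MASS
    syms = [s for s, _ in bounds.maxima]
    axes = [np.arange(cap + 1) for _, cap in bounds.maxima]
    grids = np.meshgrid(*axes, indexing="ij")
    total = sum(
        g * ATOMIC_MASSES[s] for s, g in zip(syms, grids)
    )
    hit = np.abs(total - target) <= window
    results: list[tuple[Formula, float]] = []
    for idx in np.argwhere(hit):
        counts = {s: int(g[tuple(idx)]) for s, g in zip(syms, grids)}
        if not any(counts.values()):
            continue
        if even_electron_filter and not _even_electron_plausible(counts):
            continue
        f = Formula.from_counts(counts, charge)
        results.append((f, monoisotopic_mz(f)))
    return _sort_results(results, mz)
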