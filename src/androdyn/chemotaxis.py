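"""Chemotaxis-index statistic and group comparisons.

In the plate assay, ~10+ males are placed at an origin spot equidistant from
two sodium-azide destination spots (test supernatant vs buffer control) and
scored by final location after an hour. The chemotaxis index of a plate is

    CI = (n_super - n_ctrl) / (n_total - n_origin),

ranging from -1 (all scored worms at the control spot) to +1 (all at the
supernatant). Worms elsewhere on the plate count in the denominator's
n_total only. Indices are aggregated as mean ± SEM over plates and compared
between groups by unpaired t test or by label permutation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from androdyn.errors import DataError, ParameterError
from androdyn.survival import unpaired_t_test

__all__ = ["ChemotaxisPlate", "CIResult", "chemotaxis_index", "aggregate_ci",
           "compare_ci"]


@dataclass(frozen=True)
class ChemotaxisPlate:
    """Worm counts by final location on one assay plate."""

    n_super: int
    n_ctrl: int
    n_origin: int
    n_total: int

    def __post_init__(self) -> None:
        counts = (self.n_super, self.n_ctrl, self.n_origin, self.n_total)
        if any(c < 0 for c in counts):
            raise ParameterError("plate counts must be >= 0")
        if self.n_super + self.n_ctrl + self.n_origin > self.n_total:
            raise ParameterError("located worms exceed the total placed")


@dataclass(frozen=True)
class CIResult:
    mean_ci: float
    sem: float
    n_plates: int


def chemotaxis_index(plate: ChemotaxisPlate) -> float:
    """CI = (n_super - n_ctrl) / (n_total - n_origin) for one plate."""
    denom = plate.n_total - plate.n_origin
    if denom <= 0:
        raise DataError("all worms at origin; chemotaxis index undefined")
    return (plate.n_super - plate.n_ctrl) / denom


def aggregate_ci(plates: Sequence[ChemotaxisPlate]) -> CIResult:
    """Mean chemotaxis index ± SEM (sd/sqrt(n)) over plates.

    A single plate has no between-plate spread; its SEM is reported as 0
    with a warning so pipelines stay total.
    """
    if len(plates) == 0:
        raise DataError("no plates supplied")
    indices = np.array([chemotaxis_index(p) for p in plates])
    if indices.size == 1:
        warnings.warn("single plate: SEM reported as 0", stacklevel=2)
        return CIResult(mean_ci=float(indices[0]), sem=0.0, n_plates=1)
    sem = float(np.std(indices, ddof=1) / math.sqrt(indices.size))
    return CIResult(mean_ci=float(np.mean(indices)), sem=sem,
                    n_plates=int(indices.size))


def compare_ci(plates_a: Sequence[ChemotaxisPlate],
               plates_b: Sequence[ChemotaxisPlate],
               method: str = "t", n_resamples: int = 10_000,
               seed: int | None = None) -> float:
    """Two-sided p-value comparing per-plate chemotaxis indices of two groups.

    ``method="t"`` runs the unpaired Student t test on the plate indices.
    ``method="permutation"`` permutes group labels and compares absolute mean
    differences; with 12 or fewer plates in total every relabelling is
    enumerated exactly, otherwise ``n_resamples`` random relabellings are
    drawn (add-one Monte-Carlo estimate), deterministic given ``seed``.
    """
    if len(plates_a) < 2 or len(plates_b) < 2:
        raise DataError("need at least two plates per group")
    a = np.array([chemotaxis_index(p) for p in plates_a])
    b = np.array([chemotaxis_index(p) for p in plates_b])
    if method == "t":
        return unpaired_t_test(a, b)[2]
    if method != "permutation":
        raise ParameterError(f"unknown method {method!r}")

    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, pooled.size
    observed = abs(a.mean() - b.mean())
    tol = 1e-12  # relabellings tied with the observed statistic count
    if n_tot <= 12:
        hits = total = 0
        for idx in combinations(range(n_tot), n_a):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(idx)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            hits += stat >= observed - tol
            total += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(n_tot)
        stat = abs(pooled[perm[:n_a]].mean() - pooled[perm[n_a:]].mean())
        hits += stat >= observed - tol
    return (hits + 1) / (n_resamples + 1)
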