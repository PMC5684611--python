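"""Quasi-Monte-Carlo orientation designs and basis-size heuristics.

The B-field orientation is parametrized by the spherical angles
theta in [0, 180] deg and phi in [-180, 180] deg, both uniform: with only
range information available, the maximum-entropy distribution is uniform.
Designs are drawn from the unscrambled 2-D Sobol sequence mapped affinely
onto the angle rectangle; the sequence's all-zeros first point is retained
(it maps to theta = 0, phi = -180, a valid orientation) and designs are
nested — the first n points of a 2n-point design equal the n-point design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "THETA_RANGE",
    "PHI_RANGE",
    "ExperimentalDesign",
    "basis_size",
    "thumb_rule_size",
    "sobol_design",
]

THETA_RANGE = (0.0, 180.0)
PHI_RANGE = (-180.0, 180.0)


@dataclass(frozen=True)
class ExperimentalDesign:
    """N orientations (theta_deg, phi_deg) with their distribution fixed.

    ``sequence_index_offset`` records how many Sobol points were skipped
    before the first row, so continuations of a design are reproducible.
    """

    points: np.ndarray
    sequence_index_offset: int = 0
    theta_range: tuple[float, float] = THETA_RANGE
    phi_range: tuple[float, float] = PHI_RANGE

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("design points must be an (n, 2) array")
        if pts.shape[0] < 1:
            raise ValueError("design needs at least one point")
        if np.any(pts[:, 0] < self.theta_range[0]) or np.any(pts[:, 0] > self.theta_range[1]):
            raise ValueError("theta out of range")
        if np.any(pts[:, 1] < self.phi_range[0]) or np.any(pts[:, 1] > self.phi_range[1]):
            raise ValueError("phi out of range")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("design contains duplicate orientations")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["theta_deg", "phi_deg"])

    def head(self, n: int) -> "ExperimentalDesign":
        if n > self.n:
            raise ValueError(f"cannot take {n} rows from a design of {self.n}")
        return ExperimentalDesign(self.points[:n], self.sequence_index_offset)


def basis_size(M: int, p: int) -> int:
    """Number of multivariate polynomials of total degree <= p in M variables.

    P = (M + p)! / (M! p!) = C(M + p, p).
    """
    if M < 1 or p < 0:
        raise ValueError(f"need M >= 1 and p >= 0, got M={M}, p={p}")
    return math.comb(M + p, p)


def thumb_rule_size(M: int, p: int) -> int:
    """Empirical starting design size N = (M - 1) * P for the LOO loop."""
    if M < 2:
        raise ValueError("thumb rule needs at least two input variables")
    return (M - 1) * basis_size(M, p)


def sobol_design(n: int, offset: int = 0) -> ExperimentalDesign:
    """First ``n`` orientations of the 2-D Sobol sequence after ``offset``.

    Unscrambled standard direction numbers, so the design is identical
    across runs and nested across sizes.
    """
    if n < 1:
        raise ValueError("design size must be >= 1")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    eng = qmc.Sobol(d=2, scramble=False)
    if offset:
        eng.fast_forward(offset)
    with warnings.catch_warnings():
        # drawing a non-power-of-two count is intentional here
        warnings.simplefilter("ignore", UserWarning)
        u = eng.random(n)
    theta = THETA_RANGE[0] + u[:, 0] * (THETA_RANGE[1] - THETA_RANGE[0])
    phi = PHI_RANGE[0] + u[:, 1] * (PHI_RANGE[1] - PHI_RANGE[0])
    return ExperimentalDesign(np.column_stack([theta, phi]), sequence_index_offset=offset)
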