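"""Sparse Legendre polynomial-chaos surrogate fitted by Least Angle Regression.

The surrogate expands a scalar response Y (here: a tissue's E^99th) on the
orthonormal Legendre tensor basis of the two uniform inputs theta and phi,

    Y = sum_j alpha_j * psi_j(theta, phi) + eps,   psi_(j1,j2) = L~_j1(u1) L~_j2(u2),

where u_i is the affine map of each input onto [-1, 1] and L~_j is the
Legendre polynomial normalized to unit variance under Uniform(-1, 1)
(L~_j = sqrt(2j+1) L_j).  The index set is the full total-degree simplex
j1 + j2 <= p; sparsity comes from the estimator, not the index set: LAR
ranks candidate terms, each LAR prefix is refit by ordinary least squares
(hybrid LAR), and the prefix with the smallest leave-one-out error is kept.
Unselected coefficients are exactly zero.

Orthonormality makes the output variance of the surrogate equal to the sum
of squared non-constant coefficients, which is what lets Sobol sensitivity
indices be read directly off the coefficient vector (see
:mod:`elfdosim.analysis`).

Usage follows the model/results convention::

    model = PolynomialChaos(y, design, degree=5)
    res = model.fit()
    res.predict(points); res.sobol_indices(); print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from numpy.polynomial import legendre as npleg
from sklearn.linear_model import lars_path

from .design import PHI_RANGE, THETA_RANGE, ExperimentalDesign, basis_size

__all__ = [
    "PolynomialChaos",
    "PolynomialChaosResults",
    "legendre_1d",
    "multi_index_set",
    "basis_matrix",
    "fit_lar",
    "evaluate",
]

_RANGE_TOL = 1e-12
DEFAULT_RANGES = (THETA_RANGE, PHI_RANGE)


def legendre_1d(j: int, x):
    """Orthonormal Legendre polynomial of degree ``j`` on [-1, 1].

    Normalized so that E[L~_j(U)^2] = 1 for U ~ Uniform(-1, 1):
    L~_j = sqrt(2j + 1) * L_j.
    """
    if j < 0:
        raise ValueError("degree must be non-negative")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("argument outside [-1, 1]")
    c = np.zeros(j + 1)
    c[j] = 1.0
    out = np.sqrt(2 * j + 1) * npleg.legval(x, c)
    return out if out.ndim else float(out)


def multi_index_set(M: int, p: int) -> list[tuple[int, ...]]:
    """Total-degree multi-index simplex in graded lexicographic order."""
    if M != 2:
        raise NotImplementedError("only the two-input (theta, phi) case is supported")
    idx = [(d - j2, j2) for d in range(p + 1) for j2 in range(d + 1)]
    assert len(idx) == basis_size(M, p)
    return idx


def _to_unit(points: np.ndarray, ranges) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = np.empty_like(pts)
    for i, (lo, hi) in enumerate(ranges):
        if np.any(pts[:, i] < lo - _RANGE_TOL) or np.any(pts[:, i] > hi + _RANGE_TOL):
            raise ValueError(
                f"input {i} outside its distribution range [{lo}, {hi}]; "
                "the surrogate is only defined there"
            )
        u[:, i] = np.clip(2.0 * (pts[:, i] - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    return u


def basis_matrix(points: np.ndarray, index_set, ranges=DEFAULT_RANGES) -> np.ndarray:
    """Evaluate every basis polynomial at every point: Psi[i, j] = psi_j(x_i)."""
    u = _to_unit(points, ranges)
    max_deg = max(max(ix) for ix in index_set)
    # 1-D orthonormal Legendre values up to max_deg, per input
    L = [
        np.stack([legendre_1d(d, u[:, i]) for d in range(max_deg + 1)]) for i in range(2)
    ]
    cols = [L[0][j1] * L[1][j2] for j1, j2 in index_set]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------


class PolynomialChaos:
    """Truncated Legendre chaos model of a scalar response on (theta, phi).

    Parameters
    ----------
    endog : array of N observations Y0 (the forward-solver outputs).
    design : the orientations at which Y0 was observed.
    degree : maximum total polynomial degree p.
    input_ranges : the fixed distribution ranges defining orthogonality
        (the distribution, not the sample, defines the inner product).
    """

    def __init__(
        self,
        endog,
        design: ExperimentalDesign,
        degree: int = 5,
        input_ranges=DEFAULT_RANGES,
    ):
        self.endog = np.asarray(endog, dtype=float).ravel()
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("observations must be finite")
        if self.endog.size != design.n:
            raise ValueError(
                f"{self.endog.size} observations for a design of {design.n} points"
            )
        if self.endog.size < 2:
            raise ValueError("need at least two observations")
        if degree < 0:
            raise ValueError("degree must be non-negative")
        self.design = design
        self.degree = int(degree)
        self.input_ranges = tuple(tuple(map(float, r)) for r in input_ranges)
        self.index_set = multi_index_set(2, self.degree)
        self.exog = basis_matrix(design.points, self.index_set, self.input_ranges)

    @property
    def nobs(self) -> int:
        return self.endog.size

    def fit(self) -> "PolynomialChaosResults":
        """Hybrid LAR: rank terms by LAR, OLS-refit each prefix, keep the
        prefix with the smallest (exact, hat-matrix) leave-one-out error."""
        y = self.endog
        N, P = self.exog.shape
        coef = np.zeros(P)

        if np.ptp(y) <= 1e-14 * max(1.0, np.abs(y).mean()) or self.degree == 0:
            coef[0] = y.mean()
            return PolynomialChaosResults(self, coef, selection_loo=0.0)

        order = self._lar_order()
        var_y = y.var()
        best = None  # (score, n_terms, coef)
        for k in range(len(order) + 1):
            active = [0] + order[:k]
            if len(active) >= N:  # saturated: no residual freedom for LOO
                break
            X = self.exog[:, active]
            if np.linalg.matrix_rank(X) < len(active):
                warnings.warn(
                    f"rank-deficient active set at LAR step {k}; step skipped",
                    stacklevel=2,
                )
                continue
            beta, h = _ols_with_leverage(X, y)
            if np.any(h > 1 - 1e-10):  # saturated fold: LOO undefined
                continue
            loo = (y - X @ beta) / (1.0 - h)
            score = float(np.mean(loo**2) / var_y)
            if best is None or score < best[0]:
                c = np.zeros(P)
                c[active] = beta
                best = (score, len(active), c)
        if best is None:
            coef[0] = y.mean()
            return PolynomialChaosResults(self, coef, selection_loo=float(np.mean((y - y.mean()) ** 2) / var_y))
        return PolynomialChaosResults(self, best[2], selection_loo=best[0])

    def _lar_order(self) -> list[int]:
        """Order in which non-constant basis terms enter the LAR path."""
        X = self.exog[:, 1:]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = np.nonzero(sd > 1e-14)[0]
        Xs = (X[:, keep] - mu[keep]) / sd[keep]
        yc = self.endog - self.endog.mean()
        with warnings.catch_warnings():
            # near N == P the tail of the path is degenerate by construction;
            # those steps are discarded by the LOO selection anyway
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            _, active, _ = lars_path(Xs, yc, method="lar", verbose=False)
        return [int(keep[a]) + 1 for a in active]


def _ols_with_leverage(X: np.ndarray, y: np.ndarray):
    """Least squares via QR, plus hat-matrix diagonal (leverages)."""
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    h = np.sum(Q**2, axis=1)
    return beta, h


# ---------------------------------------------------------------------------


@dataclass
class PolynomialChaosResults:
    """Fitted sparse PCE: coefficients aligned with the total-degree index set.

    ``selection_loo`` is the (absolute, variance-normalized) leave-one-out
    error used to pick the LAR prefix; ``pmse_percent`` is the relative-error
    relative leave-one-out error, filled in by
    :func:`elfdosim.validation.loo_pmse`.
    """

    model: PolynomialChaos
    params: np.ndarray
    selection_loo: float | None = None
    pmse_percent: float | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (len(self.model.index_set),):
            raise ValueError("coefficient vector does not match the index set")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("coefficients must be finite")

    # -- core surface ------------------------------------------------------

    @property
    def index_set(self):
        return self.model.index_set

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.params))

    def predict(self, points) -> np.ndarray:
        """Evaluate the expansion at (theta_deg, phi_deg) points (vectorized)."""
        Psi = basis_matrix(points, self.model.index_set, self.model.input_ranges)
        return Psi @ self.params

    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.params

    # -- variance decomposition -------------------------------------------

    def variance(self) -> float:
        """Surrogate output variance: sum of squared non-constant coefficients."""
        return float(np.sum(self.params[1:] ** 2))

    def sobol_indices(self, normalized: bool = True):
        from .analysis import sobol_indices

        return sobol_indices(self, normalized=normalized)

    def sample_exposure(self, n: int = 10000, offset: int = 4096) -> np.ndarray:
        from .analysis import sample_exposure

        return sample_exposure(self, n=n, offset=offset)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Polynomial chaos expansion (orthonormal Legendre, hybrid LAR)",
            "=" * 62,
            f"observations: {self.model.nobs:>6d}    max total degree p: {self.model.degree}",
            f"basis size P: {len(self.index_set):>6d}    active terms: {self.n_active}",
            f"theta range: {self.model.input_ranges[0]}  phi range: {self.model.input_ranges[1]}",
        ]
        if self.selection_loo is not None:
            lines.append(f"selection LOO error (rel. variance): {self.selection_loo:.3e}")
        if self.pmse_percent is not None:
            lines.append(f"leave-one-out pMSE: {self.pmse_percent:.4f} %")
        try:
            s = self.sobol_indices(normalized=True)
            lines.append(f"normalized Sobol indices: S_theta={s.s_theta:.3f}  S_phi={s.s_phi:.3f}")
        except ValueError:
            pass
        lines.append("-" * 62)
        lines.append(f"{'j_theta':>8s} {'j_phi':>6s} {'coefficient':>16s}")
        for (j1, j2), a in zip(self.index_set, self.params):
            if a != 0.0:
                lines.append(f"{j1:>8d} {j2:>6d} {a:>16.8e}")
        lines.append("=" * 62)
        return "\n".join(lines)

    # -- serialization: structured text ------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "model": "legendre-pce",
            "M": 2,
            "p": self.model.degree,
            "input_ranges": [list(r) for r in self.model.input_ranges],
            "pmse_percent": self.pmse_percent,
            "terms": [
                {"j_theta": int(j1), "j_phi": int(j2), "alpha": float(a)}
                for (j1, j2), a in zip(self.index_set, self.params)
                if a != 0.0
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path, design: ExperimentalDesign | None = None):
        doc = yaml.safe_load(Path(path).read_text())
        if doc.get("model") != "legendre-pce":
            raise ValueError("not a serialized polynomial-chaos model")
        ranges = tuple(tuple(r) for r in doc["input_ranges"])
        p = int(doc["p"])
        if design is None:
            # a two-point placeholder design; only the basis metadata matters
            from .design import sobol_design

            design = sobol_design(2)
        model = PolynomialChaos(np.zeros(design.n), design, degree=p, input_ranges=ranges)
        params = np.zeros(len(model.index_set))
        lut = {ix: i for i, ix in enumerate(model.index_set)}
        for t in doc["terms"]:
            params[lut[(int(t["j_theta"]), int(t["j_phi"]))]] = float(t["alpha"])
        return cls(model, params, pmse_percent=doc.get("pmse_percent"))


# ---------------------------------------------------------------------------
# functional aliases
# ---------------------------------------------------------------------------


def fit_lar(design: ExperimentalDesign, y, p: int) -> PolynomialChaosResults:
    """Fit a degree-``p`` sparse Legendre PCE to observations ``y``."""
    return PolynomialChaos(y, design, degree=p).fit()


def evaluate(results: PolynomialChaosResults, points) -> np.ndarray:
    """Evaluate a fitted expansion at orientation points."""
    return results.predict(points)
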