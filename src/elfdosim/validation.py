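"""Leave-one-out validation and the adaptive design-size / degree loop.

The surrogate is accepted when its percentage mean-square leave-one-out
error is below a threshold (default 5 %).  For each observation i the model
is refit on the other N-1 points and its prediction at the held-out point
gives the squared relative error

    E_i = ((y_i - yhat_i) / y_i)^2,      pMSE = 100 * (1/N) * sum_i E_i.

The relative form is kept exactly as defined, so any y_i == 0 is refused.

If the initial design (sized by the thumb rule N = (M-1) P) does not reach
the threshold, the loop alternately grows the design by continuing the
Sobol sequence (in steps of 3, re-using every previous forward evaluation)
and re-tries the maximum degree p in {p0, p0-1, p0+1}, stopping at the
first accepted configuration or at hard caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chaos import PolynomialChaos, PolynomialChaosResults, fit_lar
from .design import ExperimentalDesign, sobol_design, thumb_rule_size

__all__ = ["ValidationReport", "loo_pmse", "adaptive_fit", "ForwardEvaluationError"]

DEFAULT_THRESHOLD = 5.0
N_CAP = 200
P_CAP = 8
N_STEP = 3


class ForwardEvaluationError(RuntimeError):
    """A forward solve failed; carries the orientation that triggered it."""

    def __init__(self, orientation, cause: Exception):
        theta, phi = orientation
        super().__init__(
            f"forward evaluation failed at theta={theta:.3f}, phi={phi:.3f}: {cause}"
        )
        self.orientation = tuple(orientation)
        self.__cause__ = cause


@dataclass(frozen=True)
class ValidationReport:
    n: int
    p: int
    pmse_percent: float
    per_point_errors: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    @property
    def accepted(self) -> bool:
        return self.pmse_percent < self.threshold


def loo_pmse(
    design: ExperimentalDesign, y, p: int, threshold: float = DEFAULT_THRESHOLD
) -> ValidationReport:
    """Explicit leave-one-out cross-validation of the degree-``p`` PCE."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != design.n:
        raise ValueError("observation count does not match the design")
    if n < 3:
        raise ValueError("leave-one-out needs at least three observations")
    if np.any(y == 0):
        raise ValueError("relative leave-one-out error undefined: some y_i are zero")
    errors = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        sub = ExperimentalDesign(design.points[keep], design.sequence_index_offset)
        try:
            res = PolynomialChaos(y[keep], sub, degree=p).fit()
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"leave-one-out fit failed on fold {i}") from exc
        keep[i] = True
        yhat = float(res.predict(design.points[i : i + 1])[0])
        errors[i] = ((y[i] - yhat) / y[i]) ** 2
    pmse = 100.0 * float(errors.mean())
    return ValidationReport(n, p, pmse, errors, threshold)


@dataclass
class AdaptiveFitTrace:
    """One row per tried (N, p) configuration."""

    steps: list[dict] = field(default_factory=list)

    def append(self, n: int, p: int, pmse: float, accepted: bool) -> None:
        self.steps.append({"n": n, "p": p, "pmse_percent": pmse, "accepted": accepted})


def adaptive_fit(
    forward,
    threshold: float = DEFAULT_THRESHOLD,
    p0: int = 5,
    n_cap: int = N_CAP,
    p_cap: int = P_CAP,
    step: int = N_STEP,
    offset: int = 0,
    trace: AdaptiveFitTrace | None = None,
) -> tuple[PolynomialChaosResults, ValidationReport, ExperimentalDesign]:
    """Grow (N, p) until the leave-one-out pMSE drops below ``threshold``.

    ``forward`` maps an orientation (theta_deg, phi_deg) to the scalar
    response; it must be deterministic, and is called exactly once per
    distinct design point (results are cached as the design grows).  Degrees
    are tried in the order p0, p0-1, p0+1 at each N, preferring the nominal
    degree.  If the caps (N <= n_cap, p <= p_cap) are exhausted the best
    configuration seen is returned with ``accepted == False``.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    degrees = [p for p in (p0, p0 - 1, p0 + 1) if 0 <= p <= p_cap]
    n = thumb_rule_size(2, p0)
    cache: list[float] = []
    best: tuple[PolynomialChaosResults, ValidationReport, ExperimentalDesign] | None = None

    while True:
        design = sobol_design(n, offset)
        while len(cache) < n:
            pt = design.points[len(cache)]
            try:
                cache.append(float(forward(pt[0], pt[1])))
            except Exception as exc:
                raise ForwardEvaluationError(pt, exc) from exc
        y = np.asarray(cache)

        for p in degrees:
            report = loo_pmse(design, y, p, threshold)
            if trace is not None:
                trace.append(n, p, report.pmse_percent, report.accepted)
            if best is None or report.pmse_percent < best[1].pmse_percent:
                res = fit_lar(design, y, p)
                res.pmse_percent = report.pmse_percent
                best = (res, report, design)
            if report.accepted:
                res = fit_lar(design, y, p)
                res.pmse_percent = report.pmse_percent
                return res, report, design

        if n >= n_cap:
            return best
        n = min(n + step, n_cap)
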