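"""Magnetoquasistatic forward solver on a voxel phantom.

At power frequency the body is a tiny fraction of a wavelength, so the
magnetic vector potential A of the uniform source decouples from the induced
field and can be written down directly, A = (1/2) B x (r - r_c).  Neglecting
displacement currents (sigma >> omega * eps at 50 Hz), current conservation
div(sigma E) = 0 with E = -grad(Phi) - j*omega*A reduces to one scalar
Poisson-type equation for the electric scalar potential:

    -div(sigma grad Phi) = j*omega * div(sigma A).

Because the source term is j*omega times a real field, substituting
Phi = j*omega*psi leaves a single real symmetric system for psi, and
|E| = omega * |grad(psi) + A|.

Discretization: cell-centered 7-point finite-volume stencil on the voxel
grid with harmonic averaging of sigma on cell faces.  A face with air on
either side has zero conductivity, which enforces the zero-normal-current
boundary condition naturally; the flux form makes the discrete source
exactly compatible (it sums to zero), so the singular Neumann system is
consistent and is solved by preconditioned conjugate gradients with the
constant null-space projected out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .phantoms import VoxelPhantom

__all__ = [
    "UniformFieldSource",
    "FieldSolution",
    "SolverError",
    "vector_potential",
    "solve_scalar_potential",
    "analytic_sphere_field",
]


class SolverError(RuntimeError):
    """Linear solve failed; carries the final relative residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class UniformFieldSource:
    """Perfectly homogeneous sinusoidal B-field of given spherical orientation.

    ``B_rms_T`` is the RMS flux density; induced-field outputs are then RMS,
    matching the ICNIRP tissue metric.  The direction convention is the
    standard physics one, b = (sin(theta) cos(phi), sin(theta) sin(phi),
    cos(theta)) in the body frame (z vertical), so theta = 0 is the TOP
    orientation.
    """

    frequency_Hz: float = 50.0
    B_rms_T: float = 200e-6
    theta_deg: float = 0.0
    phi_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_Hz <= 0 or self.B_rms_T <= 0:
            raise ValueError("frequency and B amplitude must be positive")
        if not (0.0 <= self.theta_deg <= 180.0):
            raise ValueError(f"theta {self.theta_deg} outside [0, 180] degrees")
        if not (-180.0 <= self.phi_deg <= 180.0):
            raise ValueError(f"phi {self.phi_deg} outside [-180, 180] degrees")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency_Hz

    @property
    def direction(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        ph = np.deg2rad(self.phi_deg)
        return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])

    @property
    def B_vector(self) -> np.ndarray:
        return self.B_rms_T * self.direction


@dataclass
class FieldSolution:
    """Reduced scalar potential and induced-field magnitude on the grid.

    ``psi`` is the reduced potential (Phi = j*omega*psi, units V*s); the
    physical field is E = -j*omega*(grad psi + A), stored here through its
    real component grids ``E_field`` (the common phase factor is dropped)
    and its RMS magnitude ``E_mag_rms``.
    """

    psi: np.ndarray
    E_field: np.ndarray  # shape (3, nx, ny, nz), RMS per component, V/m
    E_mag_rms: np.ndarray
    residual: float
    iterations: int
    source: UniformFieldSource | None = None


def vector_potential(source: UniformFieldSource, points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Magnetic vector potential A(r) = (1/2) B x (r - center) of a uniform field.

    ``points`` has shape (..., 3); returns the same shape.  Satisfies
    curl A = B and div A = 0 identically.
    """
    r = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    B = source.B_vector
    return 0.5 * np.cross(np.broadcast_to(B, r.shape), r)


def analytic_sphere_field(f: float, B: float, rho: float):
    """Closed-form induced-field magnitude in a homogeneous sphere.

    For a uniform sinusoidal B along an axis, the eddy-current electric field
    is azimuthal with |E| = pi * f * B * rho at distance rho from the axis
    (RMS if B is RMS).  Independent of conductivity.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    return np.pi * f * B * rho


def _face_coordinates(phantom: VoxelPhantom, axis: int) -> list[np.ndarray]:
    """Center coordinates of the + faces along ``axis`` for every voxel pair."""
    h = phantom.voxel_size_m
    ax = phantom.voxel_centers_axes()
    coords = []
    for a in range(3):
        c = ax[a]
        if a == axis:
            c = c[:-1] + h / 2.0  # face midway between voxel i and i+1
        coords.append(c)
    return coords


def solve_scalar_potential(
    phantom: VoxelPhantom,
    source: UniformFieldSource,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> FieldSolution:
    """Solve the scalar-potential system and evaluate the induced E field.

    Returns RMS field values for an RMS ``B_rms_T``.  Raises
    :class:`SolverError` if conjugate gradients does not reach ``tol``
    relative residual within the iteration budget.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    sigma = phantom.sigma_grid()
    mask = sigma > 0
    m = int(mask.sum())
    if m == 0:
        raise ValueError("phantom has no conductive voxels")
    h = phantom.voxel_size_m
    omega = source.omega

    idx = -np.ones(phantom.shape, dtype=np.int64)
    idx[mask] = np.arange(m)

    # conductive-region centroid, the gauge point for A
    ax = phantom.voxel_centers_axes()
    ii, jj, kk = np.nonzero(mask)
    center = np.array([ax[0][ii].mean(), ax[1][jj].mean(), ax[2][kk].mean()])

    rows, cols, vals = [], [], []
    diag = np.zeros(m)
    b = np.zeros(m)
    B = source.B_vector

    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s_lo = sigma[tuple(sl_lo)]
        s_hi = sigma[tuple(sl_hi)]
        both = (s_lo > 0) & (s_hi > 0)
        if not both.any():
            continue
        # harmonic mean of sigma across the shared face
        sf = np.zeros_like(s_lo)
        sf[both] = 2.0 * s_lo[both] * s_hi[both] / (s_lo[both] + s_hi[both])

        i_lo = idx[tuple(sl_lo)][both]
        i_hi = idx[tuple(sl_hi)][both]
        w = sf[both]

        rows += [i_lo, i_hi]
        cols += [i_hi, i_lo]
        vals += [-w, -w]
        # i_lo / i_hi are duplicate-free within one axis pass
        diag[i_lo] += w
        diag[i_hi] += w

        # source flux sigma_f * (A . n) * h through each interior face;
        # A evaluated at the face center.
        fc = _face_coordinates(phantom, axis)
        pts = np.stack(np.meshgrid(*fc, indexing="ij"), axis=-1)[both]
        a_n = 0.5 * np.cross(B, pts - center)[:, axis]
        flux = w * a_n * h
        b[i_lo] += flux                # outward normal +axis for the low voxel
        b[i_hi] -= flux                # outward normal -axis for the high voxel

    rows.append(np.arange(m))
    cols.append(np.arange(m))
    vals.append(diag)
    L = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(m, m)
    ).tocsr()

    # Jacobi preconditioner; system is SPSD with a constant null space and a
    # compatible right-hand side (sum(b) == 0 by the telescoping flux form).
    d_inv = 1.0 / diag
    M = LinearOperator((m, m), matvec=lambda v: d_inv * v)

    if max_iter is None:
        max_iter = int(2000 * m ** (1.0 / 3.0))
    n_iter = 0

    def _count(_):
        nonlocal n_iter
        n_iter += 1

    x, info = cg(L, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M, callback=_count)
    b_norm = np.linalg.norm(b)
    residual = float(np.linalg.norm(L @ x - b) / b_norm) if b_norm > 0 else 0.0
    if info != 0:
        raise SolverError(
            f"conjugate gradients did not converge in {max_iter} iterations "
            f"(relative residual {residual:.3e}, tol {tol:.1e})",
            residual=residual,
        )
    x -= x.mean()  # zero-mean gauge over conductive voxels

    psi = np.zeros(phantom.shape)
    psi[mask] = x

    pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    A = vector_potential(source, pts, center)
    grad = _masked_gradient(psi, mask, h, A)
    E = np.zeros((3,) + phantom.shape)
    for c in range(3):
        E[c][mask] = omega * (grad[c][mask] + A[..., c][mask])
    # sign convention: E = -j*omega*(grad psi + A); magnitudes are unaffected,
    # and the stored components share one common phase.
    E_mag = np.sqrt((E**2).sum(axis=0))
    E_mag[~mask] = 0.0
    for c in range(3):
        E[c][~mask] = 0.0
    return FieldSolution(psi, E, E_mag, residual, n_iter, source)


def _masked_gradient(psi: np.ndarray, mask: np.ndarray, h: float, A: np.ndarray) -> list[np.ndarray]:
    """Gradient of psi on the conductive region, honouring the Neumann BC.

    The voxel-centre derivative along each axis is the mean of the two face
    derivatives.  An interior face (both voxels conductive) contributes the
    difference quotient; a conductor-air face contributes the boundary
    condition's exact value d(psi)/dn = -A.n, i.e. zero normal current.
    Using the BC rather than a one-sided difference suppresses the spurious
    field spikes a staircased surface otherwise produces.
    """
    out = []
    for axis in range(3):
        fwd = np.zeros_like(psi)  # face derivative on the + face of each voxel
        bwd = np.zeros_like(psi)  # face derivative on the - face

        sl_c = [slice(None)] * 3
        sl_p = [slice(None)] * 3
        sl_c[axis] = slice(None, -1)
        sl_p[axis] = slice(1, None)
        pair = mask[tuple(sl_c)] & mask[tuple(sl_p)]
        d = np.where(pair, (psi[tuple(sl_p)] - psi[tuple(sl_c)]) / h, 0.0)

        # boundary faces: d(psi)/d(axis) = -A_axis at the face; A varies
        # linearly, so the face value is the mean of the two voxel centres
        A_ax = A[..., axis]
        a_face = 0.5 * (A_ax[tuple(sl_c)] + A_ax[tuple(sl_p)])
        d_bc = np.where(pair, d, -a_face)

        fwd[tuple(sl_c)] = d_bc
        bwd[tuple(sl_p)] = d_bc
        # outermost grid faces are always air-air (air shell invariant), but
        # fill them with the BC value for completeness
        sl_last = [slice(None)] * 3
        sl_last[axis] = -1
        fwd[tuple(sl_last)] = -A_ax[tuple(sl_last)]
        sl_first = [slice(None)] * 3
        sl_first[axis] = 0
        bwd[tuple(sl_first)] = -A_ax[tuple(sl_first)]

        out.append(0.5 * (fwd + bwd))
    return out
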