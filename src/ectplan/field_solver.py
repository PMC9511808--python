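"""Electrostatic conduction solver for needle electrode arrays.

Solves the steady current-flow problem div(sigma grad phi) = 0 on a uniform
2-D grid representing the tissue cross-section at needle mid-depth, with
Dirichlet potentials on the needle conductors (+V/2 on anodes, -V/2 on
cathodes) and insulating (zero-flux) outer boundaries.

Discretization is a 5-point finite-volume scheme with harmonic averaging of
the conductivity on cell faces.  Faces that cross a needle surface use a
cut-cell (Shortley-Weller) conductance based on the true distance from the
circular conductor surface to the neighbouring cell centre, which removes
the first-order staircase bias of the rasterized disks while keeping the
M-matrix structure (so the discrete maximum principle holds exactly).

Per-needle currents come from the discrete flux integral over the faces
surrounding each needle's cells; the 2-D per-unit-length current is scaled
by the insertion depth to amperes.  Because the interior equations are exact
discrete conservation laws, the signed electrode currents sum to zero up to
the linear-solver residual.

Analytic fixtures used by the validation suite:

* parallel plates at distance d and voltage V -> uniform field V/d;
* coaxial conductors (radii a < b) -> |E|(r) = V / (r ln(b/a));
* two parallel cylinders (radius a, centre distance d) -> conductance per
  unit length G = pi sigma / arccosh(d / 2a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .electrode_geometry import ElectrodeArray, Polarity

__all__ = [
    "SimulationGrid",
    "ConductivityField",
    "FieldSolution",
    "solve_potential",
    "solve_dirichlet",
    "field_magnitude",
    "electrode_current",
    "total_anode_current",
    "calibrate_conductivity",
    "two_cylinder_conductance",
    "DEFAULT_SIGMA_S_PER_M",
]

#: Homogeneous soft-tissue conductivity used when no measurement is supplied.
DEFAULT_SIGMA_S_PER_M = 0.2

#: Relative residual the linear solve must reach.
RESIDUAL_TOL = 1e-8

#: Grid-cell count above which the sparse direct solve gives way to
#: preconditioned conjugate gradients.
DIRECT_CELL_LIMIT = 2_000_000


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform cell-centred grid.  Cell centres at origin + index * spacing (mm)."""

    nx: int
    ny: int
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 cells per axis")

    @classmethod
    def centered(cls, extent_mm: float, spacing_mm: float) -> "SimulationGrid":
        """Square grid of the given side length centred on the origin."""
        n = int(round(extent_mm / spacing_mm))
        x0 = -(n - 1) / 2.0 * spacing_mm
        return cls(nx=n, ny=n, spacing=spacing_mm, origin=(x0, x0))

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.nx) * self.spacing

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.ny) * self.spacing

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area_mm2(self) -> float:
        return self.spacing**2


def default_grid() -> SimulationGrid:
    """40 x 40 mm domain at 0.05 mm spacing, centred on the array."""
    return SimulationGrid.centered(40.0, 0.05)


@dataclass(frozen=True)
class ConductivityField:
    """Per-cell electrical conductivity (S/m) on a simulation grid."""

    grid: SimulationGrid
    sigma: np.ndarray

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != self.grid.shape:
            raise ValueError(f"sigma shape {sigma.shape} != grid shape {self.grid.shape}")
        if not np.all(sigma > 0):
            raise ValueError("conductivity must be positive everywhere")
        object.__setattr__(self, "sigma", sigma)

    @classmethod
    def homogeneous(cls, grid: SimulationGrid, sigma: float) -> "ConductivityField":
        if sigma <= 0:
            raise ValueError("conductivity must be positive")
        return cls(grid, np.full(grid.shape, float(sigma)))


@dataclass
class FieldSolution:
    """Potential, field magnitude and per-electrode currents of one solve."""

    grid: SimulationGrid
    potential: np.ndarray  # V, shape (ny, nx)
    field_magnitude: np.ndarray  # V/cm, NaN inside electrodes
    electrode_currents: np.ndarray  # A, signed, one per needle (+ = leaving)
    applied_voltage: float
    electrode_labels: np.ndarray  # int8, -1 = tissue, k = needle index
    sigma: np.ndarray  # S/m
    residual: float  # relative linear-solve residual

    @property
    def total_current(self) -> float:
        """Circuit current: total current leaving the anodes (A)."""
        return float(self.electrode_currents[self.electrode_currents > 0].sum())


def two_cylinder_conductance(d_mm: float, a_mm: float, sigma: float) -> float:
    """Closed-form conductance per unit length (S/m) between two parallel
    cylinders of radius ``a`` with centres ``d`` apart in an infinite medium."""
    if d_mm <= 2 * a_mm:
        raise ValueError("cylinders overlap")
    return math.pi * sigma / math.acosh(d_mm / (2.0 * a_mm))


# ---------------------------------------------------------------------------
# assembly helpers


def _face_conductances(
    sigma: np.ndarray,
    spacing_mm: float,
    labels: np.ndarray,
    disks: Optional[Sequence[tuple[float, float, float]]],
    X: np.ndarray,
    Y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-face conductance per unit depth (S/m), with cut-cell correction.

    Returns ``(gx, gy)``: gx[j, i] couples cells (j, i)-(j, i+1), gy[j, i]
    couples (j, i)-(j+1, i).  The bulk value is the harmonic mean of the two
    cell conductivities (face area h x depth over distance h cancels h).  A
    face with exactly one electrode cell is rescaled by h / delta, where
    delta is the distance from the circular conductor surface to the tissue
    cell centre, clipped to [0.1 h, 2 h].
    """
    h = spacing_mm
    gx = 2.0 * sigma[:, :-1] * sigma[:, 1:] / (sigma[:, :-1] + sigma[:, 1:])
    gy = 2.0 * sigma[:-1, :] * sigma[1:, :] / (sigma[:-1, :] + sigma[1:, :])
    if not disks:
        return gx, gy
    for g, la, lb, xa, ya in (
        (gx, labels[:, :-1], labels[:, 1:], X[:, 1:], Y[:, 1:]),
        (gx, labels[:, 1:], labels[:, :-1], X[:, :-1], Y[:, :-1]),
        (gy, labels[:-1, :], labels[1:, :], X[1:, :], Y[1:, :]),
        (gy, labels[1:, :], labels[:-1, :], X[:-1, :], Y[:-1, :]),
    ):
        m = (la >= 0) & (lb < 0)  # electrode cell facing a tissue cell
        if not m.any():
            continue
        k = la[m]
        has_disk = np.array([disks[i] is not None for i in k])
        if not has_disk.any():
            continue
        cx = np.array([disks[i][0] if disks[i] else 0.0 for i in k])
        cy = np.array([disks[i][1] if disks[i] else 0.0 for i in k])
        rad = np.array([disks[i][2] if disks[i] else 0.0 for i in k])
        # |.| handles both disks (tissue outside the surface) and circular
        # cavities such as an outer coaxial conductor (tissue inside)
        delta = np.abs(np.hypot(xa[m] - cx, ya[m] - cy) - rad)
        corr = h / np.clip(delta, 0.1 * h, 2.0 * h)
        g[m] = np.where(has_disk, g[m] * corr, g[m])
    return gx, gy


def _edges(gx, gy, nx, ny):
    idx = np.arange(nx * ny).reshape(ny, nx)
    p = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    q = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    g = np.concatenate([gx.ravel(), gy.ravel()])
    return p, q, g


def solve_dirichlet(
    conductivity: ConductivityField,
    labels: np.ndarray,
    values: Sequence[float],
    disks: Optional[Sequence[tuple[float, float, float]]] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the conduction problem for arbitrary Dirichlet regions.

    ``labels`` is an int array over the grid, -1 for tissue, k >= 0 for the
    k-th electrode region held at ``values[k]`` volts.  ``disks`` optionally
    gives (cx, cy, radius) in mm per label for the cut-cell face correction
    of circular conductors.  Returns ``(potential, currents_per_unit_length,
    residual)``; currents are in A per metre of depth, positive outward.
    """
    grid = conductivity.grid
    labels = np.asarray(labels)
    if labels.shape != grid.shape:
        raise ValueError("labels shape does not match grid")
    n_regions = len(values)
    if labels.max() >= n_regions:
        raise ValueError("label exceeds number of Dirichlet values")
    X, Y = grid.meshgrid()
    gx, gy = _face_conductances(conductivity.sigma, grid.spacing, labels, disks, X, Y)
    nx, ny = grid.nx, grid.ny
    N = nx * ny
    labf = labels.ravel()
    vals = np.zeros(N)
    for k, v in enumerate(values):
        vals[labf == k] = v
    free = labf < 0
    n_free = int(free.sum())
    if n_free == 0:
        raise ValueError("no free cells to solve for")
    uidx = -np.ones(N, dtype=np.int64)
    uidx[free] = np.arange(n_free)

    p, q, g = _edges(gx, gy, nx, ny)
    pu, qu = uidx[p], uidx[q]
    both = (pu >= 0) & (qu >= 0)
    diag = np.zeros(n_free)
    b = np.zeros(n_free)
    np.add.at(diag, pu[pu >= 0], g[pu >= 0])
    np.add.at(diag, qu[qu >= 0], g[qu >= 0])
    pb = (pu >= 0) & (qu < 0)
    np.add.at(b, pu[pb], g[pb] * vals[q[pb]])
    qb = (qu >= 0) & (pu < 0)
    np.add.at(b, qu[qb], g[qb] * vals[p[qb]])
    rows = np.concatenate([pu[both], qu[both], np.arange(n_free)])
    cols = np.concatenate([qu[both], pu[both], np.arange(n_free)])
    data = np.concatenate([-g[both], -g[both], diag])
    A = sp.csr_matrix((data, (rows, cols)), shape=(n_free, n_free))

    if N <= DIRECT_CELL_LIMIT:
        x = spla.spsolve(A, b, permc_spec="MMD_AT_PLUS_A")
    else:
        M = sp.diags(1.0 / A.diagonal())
        x, info = spla.cg(A, b, rtol=RESIDUAL_TOL / 10.0, maxiter=400_000, M=M)
        if info != 0:
            raise RuntimeError(f"iterative solve failed to converge (info={info})")
    bnorm = np.linalg.norm(b)
    residual = float(np.linalg.norm(A @ x - b) / bnorm) if bnorm > 0 else 0.0
    if residual > RESIDUAL_TOL:
        raise RuntimeError(f"linear solve residual {residual:.2e} exceeds {RESIDUAL_TOL}")

    phi = vals.copy()
    phi[free] = x

    # flux integral around each Dirichlet region: faces (electrode, tissue)
    currents = np.zeros(n_regions)
    el_p = labf[p] >= 0
    el_q = labf[q] >= 0
    m = el_p & ~el_q
    np.add.at(currents, labf[p][m], g[m] * (phi[p][m] - phi[q][m]))
    m = el_q & ~el_p
    np.add.at(currents, labf[q][m], g[m] * (phi[q][m] - phi[p][m]))
    return phi.reshape(grid.shape), currents, residual


# ---------------------------------------------------------------------------
# array-level interface


def _rasterize(array: ElectrodeArray, grid: SimulationGrid) -> np.ndarray:
    """Cell-center-in-disk rasterization: labels[j, i] = needle index or -1."""
    X, Y = grid.meshgrid()
    labels = np.full(grid.shape, -1, dtype=np.int16)
    for k, n in enumerate(array.needles):
        inside = np.hypot(X - n.center_x, Y - n.center_y) <= n.radius
        labels[inside] = k
    return labels


def _check_geometry(array: ElectrodeArray, grid: SimulationGrid, labels: np.ndarray) -> None:
    h = grid.spacing
    for k, n in enumerate(array.needles):
        count = int((labels == k).sum())
        if count < 4:
            raise ValueError(
                f"needle {k} covers only {count} grid cells; refine the grid "
                f"(spacing {h} mm) so every needle disk covers >= 4 cells"
            )
        if not (
            grid.x[0] + h < n.center_x - n.radius
            and n.center_x + n.radius < grid.x[-1] - h
            and grid.y[0] + h < n.center_y - n.radius
            and n.center_y + n.radius < grid.y[-1] - h
        ):
            raise ValueError(f"needle {k} not inside the simulation domain")
    extent = array.extent
    width = (grid.nx - 1) * h
    height = (grid.ny - 1) * h
    if min(width, height) < 5.0 * extent:
        raise ValueError(
            f"domain {width:.1f} x {height:.1f} mm too small for array extent "
            f"{extent:.1f} mm; need >= 5 x extent for a credible far-field"
        )
    # a needle's flux contour must not touch another needle's cells
    for la, lb in (
        (labels[:, :-1], labels[:, 1:]),
        (labels[:-1, :], labels[1:, :]),
    ):
        clash = (la >= 0) & (lb >= 0) & (la != lb)
        if clash.any():
            raise ValueError(
                "adjacent cells belong to different needles; enlarge the gaps "
                "or refine the grid so flux contours do not intersect"
            )


def solve_potential(
    array: ElectrodeArray,
    conductivity: ConductivityField | float = DEFAULT_SIGMA_S_PER_M,
    grid: Optional[SimulationGrid] = None,
    voltage: float = 400.0,
) -> FieldSolution:
    """Solve for the potential around an electrode array.

    Anode needles are held at +V/2 and cathodes at -V/2 (the symmetric split
    pins the mean of the solution; any other split is the same field up to a
    constant).  ``conductivity`` may be a ConductivityField or a scalar S/m
    value, in which case a homogeneous field on ``grid`` is built.
    """
    if grid is None:
        grid = conductivity.grid if isinstance(conductivity, ConductivityField) else default_grid()
    if not isinstance(conductivity, ConductivityField):
        conductivity = ConductivityField.homogeneous(grid, float(conductivity))
    elif conductivity.grid != grid:
        raise ValueError("conductivity grid does not match simulation grid")
    if voltage <= 0:
        raise ValueError("voltage must be positive")

    labels = _rasterize(array, grid)
    _check_geometry(array, grid, labels)
    values = [
        +voltage / 2.0 if n.polarity is Polarity.ANODE else -voltage / 2.0
        for n in array.needles
    ]
    disks = [(n.center_x, n.center_y, n.radius) for n in array.needles]
    phi, currents_per_len, residual = solve_dirichlet(conductivity, labels, values, disks)
    currents = currents_per_len * np.array(
        [n.insertion_depth * 1e-3 for n in array.needles]
    )
    sol = FieldSolution(
        grid=grid,
        potential=phi,
        field_magnitude=np.empty(0),
        electrode_currents=currents,
        applied_voltage=voltage,
        electrode_labels=labels,
        sigma=conductivity.sigma,
        residual=residual,
    )
    sol.field_magnitude = field_magnitude(sol)
    return sol


def field_magnitude(solution: FieldSolution) -> np.ndarray:
    """|E| in V/cm from central differences of the potential.

    Cells inside needles are masked with NaN: the conductor interior has no
    meaningful tissue field.
    """
    h_m = solution.grid.spacing * 1e-3
    gy, gx = np.gradient(solution.potential, h_m)
    mag = np.hypot(gx, gy) / 100.0  # V/m -> V/cm
    mag = mag.astype(float)
    mag[solution.electrode_labels >= 0] = np.nan
    return mag


def electrode_current(solution: FieldSolution, array: ElectrodeArray, needle_index: int) -> float:
    """Signed current (A) through one needle; positive when leaving an anode."""
    if not 0 <= needle_index < len(array.needles):
        raise IndexError("needle index out of range")
    return float(solution.electrode_currents[needle_index])


def total_anode_current(solution: FieldSolution) -> float:
    return solution.total_current


def calibrate_conductivity(
    array: ElectrodeArray,
    grid: Optional[SimulationGrid] = None,
    voltage: float = 400.0,
    measured_resistance: Optional[float] = None,
    measured_current: Optional[float] = None,
) -> float:
    """Homogeneous conductivity (S/m) reproducing a measured load.

    The problem is linear in sigma, so one unit-conductivity solve suffices:
    sigma* = I_measured / I_model(sigma=1), or equivalently
    sigma* = R_model(sigma=1) / R_measured.  Re-solving with sigma* returns
    the measured value exactly (up to the linear-solver residual).
    """
    if (measured_resistance is None) == (measured_current is None):
        raise ValueError("give exactly one of measured_resistance or measured_current")
    if grid is None:
        grid = default_grid()
    sol = solve_potential(array, 1.0, grid, voltage)
    i_model = sol.total_current
    if measured_current is not None:
        if measured_current <= 0:
            raise ValueError("measured current must be positive")
        return float(measured_current / i_model)
    if measured_resistance <= 0:
        raise ValueError("measured resistance must be positive")
    r_model = voltage / i_model
    return float(r_model / measured_resistance)
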