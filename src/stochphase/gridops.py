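"""Finite-difference discretization of the Kolmogorov operators on a rectangle.

The backward (generator) operator

    L+[u] = f . grad u + sum_ij G_ij d_i d_j u

is assembled with second-order centred stencils in the interior.  At the
border, rows either switch to inward one-sided stencils (``one_sided``,
for unbounded systems truncated to a large box) or are obtained by
transposing the conservative reflecting forward operator against the
trapezoidal quadrature inner product (``reflecting_adjoint``, for bounded
systems).  The forward (Fokker–Planck) operator

    L[P] = -div(f P) + sum_ij d_i d_j (G_ij P)

is always built in finite-volume flux form with zero-flux faces, so the
quadrature-weighted column sums vanish identically and total probability
is conserved.  Constants are an exact null vector of every assembled
backward operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "RectGrid",
    "DiscreteOperator",
    "make_grid",
    "default_grid",
    "assemble_backward",
    "assemble_forward",
    "gradient_matrices",
    "second_derivative_matrices",
]

MIN_POINTS = 9  # an 8-point axis cannot separate the low-lying modes


@dataclass(frozen=True)
class RectGrid:
    """N x M node grid over [x-, x+] x [y-, y+], both endpoints included.

    Nodes are ordered row-major over x: flat index k = i*M + j for
    x-index i and y-index j.  Quadrature weights are trapezoidal cell
    weights and sum to the domain area.
    """

    bounds: tuple
    N: int
    M: int

    def __post_init__(self):
        x_lo, x_hi, y_lo, y_hi = self.bounds
        if not (x_lo < x_hi and y_lo < y_hi):
            raise ValueError(f"degenerate bounds {self.bounds!r}")
        if self.N < MIN_POINTS or self.M < MIN_POINTS:
            raise ValueError(f"grid too coarse: need at least {MIN_POINTS} "
                             f"points per axis, got {self.N}x{self.M}")

    @property
    def x(self):
        return np.linspace(self.bounds[0], self.bounds[1], self.N)

    @property
    def y(self):
        return np.linspace(self.bounds[2], self.bounds[3], self.M)

    @property
    def dx(self):
        return (self.bounds[1] - self.bounds[0]) / (self.N - 1)

    @property
    def dy(self):
        return (self.bounds[3] - self.bounds[2]) / (self.M - 1)

    def meshes(self):
        return np.meshgrid(self.x, self.y, indexing="ij")

    def index(self, i, j):
        return i * self.M + j

    def node(self, k):
        return divmod(k, self.M)

    @property
    def weights_x(self):
        w = np.full(self.N, self.dx)
        w[0] = w[-1] = 0.5 * self.dx
        return w

    @property
    def weights_y(self):
        w = np.full(self.M, self.dy)
        w[0] = w[-1] = 0.5 * self.dy
        return w

    @property
    def weights(self):
        """Flattened trapezoidal quadrature weights (sum = domain area)."""
        return np.outer(self.weights_x, self.weights_y).ravel()

    def reshape(self, u):
        return np.asarray(u).reshape(self.N, self.M)

    def integrate(self, u):
        return float(np.real_if_close(np.sum(self.weights * np.ravel(u))))

    def to_json_dict(self):
        return {"bounds": list(map(float, self.bounds)), "N": self.N, "M": self.M,
                "dx": self.dx, "dy": self.dy, "ordering": "row-major over x"}


def make_grid(bounds, N=120, M=120) -> RectGrid:
    """Grid factory; ``bounds`` = (x-, x+, y-, y+)."""
    return RectGrid(tuple(float(b) for b in bounds), int(N), int(M))


def default_grid(model, N=None, M=None) -> RectGrid:
    """The per-model production grid: the model's domain at 120x120."""
    return make_grid(model.domain, N or 120, M or 120)


@dataclass
class DiscreteOperator:
    """A sparse linear map on flattened grid functions."""

    matrix: sp.spmatrix
    grid: RectGrid
    kind: str  # "backward" | "forward"
    boundary_flavor: str
    _cache: dict = field(default_factory=dict, repr=False)

    def apply(self, u):
        u = np.asarray(u)
        flat = u.ndim == 1
        out = self.matrix @ u.ravel()
        return out if flat else self.grid.reshape(out)

    def __matmul__(self, u):
        return self.matrix @ u

    def export_coo(self, path):
        """Write (row, col, value) triplets as delimited text for debugging."""
        coo = self.matrix.tocoo()
        np.savetxt(path, np.column_stack([coo.row, coo.col, coo.data]),
                   fmt=["%d", "%d", "%.17g"], header="row col value")


# ---------------------------------------------------------------------------
# one-dimensional building blocks
# ---------------------------------------------------------------------------

def _d1(n, h):
    """First derivative: centred interior, second-order one-sided ends."""
    D = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        D[i, i - 1] = -0.5 / h
        D[i, i + 1] = 0.5 / h
    D[0, 0], D[0, 1], D[0, 2] = -1.5 / h, 2.0 / h, -0.5 / h
    D[-1, -1], D[-1, -2], D[-1, -3] = 1.5 / h, -2.0 / h, 0.5 / h
    return D.tocsr()


def _d2(n, h):
    """Second derivative: centred interior, first-order one-sided ends."""
    D = sp.lil_matrix((n, n))
    h2 = h * h
    for i in range(1, n - 1):
        D[i, i - 1], D[i, i], D[i, i + 1] = 1 / h2, -2 / h2, 1 / h2
    D[0, 0], D[0, 1], D[0, 2] = 1 / h2, -2 / h2, 1 / h2
    D[-1, -1], D[-1, -2], D[-1, -3] = 1 / h2, -2 / h2, 1 / h2
    return D.tocsr()


def _avg_faces(n):
    """Node-to-face averaging, faces between consecutive nodes."""
    return sp.diags_array([0.5 * np.ones(n - 1), 0.5 * np.ones(n - 1)],
                          offsets=[0, 1], shape=(n - 1, n)).tocsr()


def _diff_faces(n, h):
    """Node-to-face first difference."""
    return sp.diags_array([-np.ones(n - 1) / h, np.ones(n - 1) / h],
                          offsets=[0, 1], shape=(n - 1, n)).tocsr()


def _div_faces(n, w):
    """Face-to-node divergence with zero-flux boundary faces; w = cell widths."""
    D = sp.lil_matrix((n, n - 1))
    for i in range(n):
        if i > 0:
            D[i, i - 1] = -1.0 / w[i]
        if i < n - 1:
            D[i, i] = 1.0 / w[i]
    return D.tocsr()


def gradient_matrices(grid: RectGrid):
    """(Dx, Dy) acting on flattened grid functions; one-sided at the border."""
    Ix = sp.identity(grid.N, format="csr")
    Iy = sp.identity(grid.M, format="csr")
    Dx = sp.kron(_d1(grid.N, grid.dx), Iy, format="csr")
    Dy = sp.kron(Ix, _d1(grid.M, grid.dy), format="csr")
    return Dx, Dy


def second_derivative_matrices(grid: RectGrid):
    """(Dxx, Dyy, Dxy) on flattened grid functions."""
    Ix = sp.identity(grid.N, format="csr")
    Iy = sp.identity(grid.M, format="csr")
    Dxx = sp.kron(_d2(grid.N, grid.dx), Iy, format="csr")
    Dyy = sp.kron(Ix, _d2(grid.M, grid.dy), format="csr")
    Dxy = sp.kron(_d1(grid.N, grid.dx), _d1(grid.M, grid.dy), format="csr")
    return Dxx, Dyy, Dxy


def _node_fields(model, grid):
    X, Y = grid.meshes()
    fx, fy = model.drift(X, Y)
    g11, g12, g22 = model.diffusion(X, Y)
    bcast = lambda a: np.broadcast_to(np.asarray(a, float), X.shape).ravel()
    return bcast(fx), bcast(fy), bcast(g11), bcast(g12), bcast(g22)


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

def assemble_backward(model, grid: RectGrid, boundary_flavor=None) -> DiscreteOperator:
    """Discretize the generator L+[u] = f.grad u + sum G_ij d_i d_j u."""
    flavor = boundary_flavor or model.boundary_flavor
    if flavor == "reflecting_adjoint":
        fwd = assemble_forward(model, grid)
        w = grid.weights
        mat = sp.diags_array(1.0 / w) @ fwd.matrix.T @ sp.diags_array(w)
        return DiscreteOperator(mat.tocsr(), grid, "backward", flavor)
    if flavor != "one_sided":
        raise ValueError(f"unknown boundary flavor {flavor!r}")

    fx, fy, g11, g12, g22 = _node_fields(model, grid)
    Dx, Dy = gradient_matrices(grid)
    Dxx, Dyy, Dxy = second_derivative_matrices(grid)
    dia = sp.diags_array
    mat = (dia(fx) @ Dx + dia(fy) @ Dy + dia(g11) @ Dxx
           + 2.0 * (dia(g12) @ Dxy) + dia(g22) @ Dyy)
    return DiscreteOperator(mat.tocsr(), grid, "backward", "one_sided")


def assemble_forward(model, grid: RectGrid) -> DiscreteOperator:
    """Discretize L[P] = -div(f P - div(G P)) in conservative flux form.

    Fluxes live on cell faces; boundary faces carry zero flux, so the
    scheme conserves probability exactly (quadrature-weighted column sums
    vanish to rounding).
    """
    N, M = grid.N, grid.M
    x, y = grid.x, grid.y
    X, Y = grid.meshes()
    g11, g12, g22 = (np.broadcast_to(np.asarray(v, float), X.shape).ravel()
                     for v in model.diffusion(X, Y))
    Ix = sp.identity(N, format="csr")
    Iy = sp.identity(M, format="csr")
    dia = sp.diags_array

    # node-wise tangential derivatives used inside the cross-flux terms
    Dy_node = sp.kron(Ix, _d1(M, grid.dy), format="csr")
    Dx_node = sp.kron(_d1(N, grid.dx), Iy, format="csr")

    # --- x-faces: shape (N-1)*M ---------------------------------------
    Ax = sp.kron(_avg_faces(N), Iy, format="csr")
    Gx = sp.kron(_diff_faces(N, grid.dx), Iy, format="csr")
    xf = 0.5 * (x[:-1] + x[1:])
    Xf, Yf = np.meshgrid(xf, y, indexing="ij")
    fxf, _ = model.drift(Xf, Yf)
    fxf = np.broadcast_to(np.asarray(fxf, float), Xf.shape).ravel()
    flux_x = (dia(fxf) @ Ax - Gx @ dia(g11) - Ax @ (Dy_node @ dia(g12)))
    div_x = sp.kron(_div_faces(N, grid.weights_x), Iy, format="csr")

    # --- y-faces: shape N*(M-1) ---------------------------------------
    Ay = sp.kron(Ix, _avg_faces(M), format="csr")
    Gy = sp.kron(Ix, _diff_faces(M, grid.dy), format="csr")
    yf = 0.5 * (y[:-1] + y[1:])
    Xf2, Yf2 = np.meshgrid(x, yf, indexing="ij")
    _, fyf = model.drift(Xf2, Yf2)
    fyf = np.broadcast_to(np.asarray(fyf, float), Xf2.shape).ravel()
    flux_y = (dia(fyf) @ Ay - Gy @ dia(g22) - Ay @ (Dx_node @ dia(g12)))
    div_y = sp.kron(Ix, _div_faces(M, grid.weights_y), format="csr")

    mat = -(div_x @ flux_x) - (div_y @ flux_y)
    return DiscreteOperator(mat.tocsr(), grid, "forward", "reflecting")
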