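"""Parameterized scaling-model components with analytic gradients.

Three families of components are provided:

* Gaussian-smoothed 1D components over an adjusted rotation angle — the scale
  ``C(r)`` and relative-B decay ``T(t) = exp(B(t)/(2 d^2))`` terms of the
  physical model.  The value at adjusted coordinate ``x`` is a
  Gaussian-weighted sum of the nearest three parameters,
  ``sum_i w_i p_i / sum_i w_i`` with ``w_i = exp(-(x - x_i)^2 / V)``.
* A spherical-harmonic absorption surface
  ``S = 1 + sum_lm P_lm * (Y_lm(-s0) + Y_lm(s1))/2`` over beam directions in
  the crystal frame, using real spherical harmonics for ``l = 1..l_max``.
* Gaussian-smoothed 2D/3D grid components (the array model's decay,
  absorption and modulation terms) using separable weights over the nearest
  three grid nodes per dimension, with coordinates clamped to the grid hull.

Every component exposes ``values_and_derivatives`` returning the per-row
component value and a sparse derivative matrix with respect to its own
parameters; models combine these by the product rule.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.sparse as sp
from scipy.special import sph_harm_y


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------

def n_sph_coeffs(lmax: int) -> int:
    """Number of (l, m) coefficients for l = 1..lmax: sum of (2l+1)."""
    return sum(2 * l + 1 for l in range(1, lmax + 1))


def real_sph_harm_basis(lmax: int, vecs: np.ndarray) -> np.ndarray:
    """Real spherical-harmonic basis Y_lm evaluated at unit vectors.

    Returns an (n, n_coeffs) matrix ordered (l=1,m=-1..1), (l=2,m=-2..2), ...
    Uses the orthonormal real basis without the Condon-Shortley phase.
    """
    vecs = np.asarray(vecs, dtype=float)
    theta = np.arccos(np.clip(vecs[:, 2], -1.0, 1.0))
    phi = np.arctan2(vecs[:, 1], vecs[:, 0])
    cols = []
    for l in range(1, lmax + 1):
        for m in range(-l, l + 1):
            Y = sph_harm_y(l, abs(m), theta, phi)
            sign = (-1.0) ** m  # cancels the Condon-Shortley phase
            if m < 0:
                cols.append(np.sqrt(2.0) * sign * Y.imag)
            elif m == 0:
                cols.append(Y.real)
            else:
                cols.append(np.sqrt(2.0) * sign * Y.real)
    return np.column_stack(cols) if cols else np.zeros((len(vecs), 0))


# ---------------------------------------------------------------------------
# 1D Gaussian smoother
# ---------------------------------------------------------------------------

def smooth_1d_layout(width: float, spacing: float) -> tuple[int, float]:
    """Node count and first-node position for a 1D smoothed component.

    The adjusted coordinate spans [0, X] with X = width/spacing; the number
    of parameters is ceil(X) + 2 (one padding node beyond each end) and nodes
    sit at ``x_i = c + i`` with ``c = (X - (n-1))/2`` so they are symmetric
    about the sweep centre.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    X = width / spacing
    n = int(np.ceil(X - 1e-9)) + 2
    c = (X - (n - 1)) / 2.0
    return n, c


def eval_smooth_1d(params: np.ndarray, first_position: float, x: np.ndarray,
                   V: float):
    """Gaussian-weighted sum over the nearest 3 of regularly spaced params.

    Returns ``(value, weights, cols)`` where ``weights`` (n, 3) are the
    normalized Gaussian weights (the sparse gradient of the value with
    respect to the parameters) and ``cols`` (n, 3) the parameter indices.
    """
    if V <= 0:
        raise ValueError("smoothing variance V must be positive")
    params = np.asarray(params, dtype=float)
    n = len(params)
    if n < 3:
        raise ValueError("smoothed component needs at least 3 parameters")
    x = np.asarray(x, dtype=float)
    idx = np.clip(np.round(x - first_position).astype(int), 1, n - 2)
    cols = idx[:, None] + np.array([-1, 0, 1])
    xi = first_position + cols
    w = np.exp(-((x[:, None] - xi) ** 2) / V)
    w /= w.sum(axis=1, keepdims=True)
    value = (w * params[cols]).sum(axis=1)
    return value, w, cols


def _sparse_from_triplets(weights, cols, n_params):
    n = weights.shape[0]
    rows = np.repeat(np.arange(n), weights.shape[1])
    return sp.csr_matrix((weights.ravel(), (rows, cols.ravel())),
                         shape=(n, n_params))


class Smooth1DComponent:
    """Multiplicative smoothly varying scale C(r) (identity: all params 1)."""

    kind = "scale"
    coordinate = "r"
    null_value = 1.0

    def __init__(self, n_params: int, first_position: float, spacing: float,
                 V: float = 0.5, restraint_weight: float = 0.0):
        self.params = np.full(n_params, self.null_value, dtype=float)
        self.first_position = first_position
        self.spacing = spacing
        self.V = V
        self.restraint_weight = restraint_weight

    @property
    def n_params(self) -> int:
        return len(self.params)

    def prepare(self, table):
        return table[self.coordinate].to_numpy(dtype=float)

    def values_and_derivatives(self, cache):
        x = cache
        value, w, cols = eval_smooth_1d(self.params, self.first_position, x,
                                        self.V)
        return value, _sparse_from_triplets(w, cols, self.n_params)


class SmoothBComponent(Smooth1DComponent):
    """Decay term T(t) = exp(B(t)/(2 d^2)) with smoothed relative B factor."""

    kind = "decay"
    coordinate = "t"
    null_value = 0.0

    def prepare(self, table):
        return (table["t"].to_numpy(dtype=float),
                table["d"].to_numpy(dtype=float))

    def values_and_derivatives(self, cache):
        t, d = cache
        B, w, cols = eval_smooth_1d(self.params, self.first_position, t,
                                    self.V)
        inv2d2 = 1.0 / (2.0 * d ** 2)
        value = np.exp(B * inv2d2)
        dv = w * (value * inv2d2)[:, None]
        return value, _sparse_from_triplets(dv, cols, self.n_params)


class SphericalHarmonicComponent:
    """Absorption surface S = 1 + sum_lm P_lm (Y_lm(-s0)+Y_lm(s1))/2."""

    kind = "absorption"
    null_value = 0.0

    def __init__(self, lmax: int = 4, V: float = 0.5,
                 restraint_weight: float = 1e6):
        self.lmax = int(lmax)
        self.params = np.zeros(n_sph_coeffs(self.lmax))
        self.restraint_weight = restraint_weight

    @property
    def n_params(self) -> int:
        return len(self.params)

    def prepare(self, table):
        if self.lmax < 1:
            return np.zeros((len(table), 0))
        s0c = table[["s0cx", "s0cy", "s0cz"]].to_numpy(dtype=float)
        s1c = table[["s1cx", "s1cy", "s1cz"]].to_numpy(dtype=float)
        # symmetrized basis: mean of the two direction evaluations, so the
        # surface is insensitive to swapping incoming/outgoing directions
        return 0.5 * (real_sph_harm_basis(self.lmax, s0c)
                      + real_sph_harm_basis(self.lmax, s1c))

    def values_and_derivatives(self, cache):
        basis = cache
        value = 1.0 + basis @ self.params
        return value, sp.csr_matrix(basis)


class ArrayComponent:
    """Gaussian-smoothed grid component of the array model (2D or 3D).

    ``kind`` is one of decay (r x d'), absorption (x' x y' x r) or modulation
    (x' x y').  Grid nodes sit at integer positions 0..n-1 per dimension;
    normalized [0, 1] coordinates map to ``u = norm * n - 0.5`` and are
    clamped to the hull.  Separable Gaussian weights over the nearest three
    in-range nodes per dimension, explicitly normalized.
    """

    COORDS = {"decay": ("phi_norm", "dprime"),
              "absorption": ("xp", "yp", "phi_norm"),
              "modulation": ("xp", "yp")}
    null_value = 1.0

    def __init__(self, kind: str, shape: tuple[int, ...], V: float = 0.5,
                 restraint_weight: float = 0.0):
        if kind not in self.COORDS:
            raise ValueError(f"unknown array component kind {kind!r}")
        if len(shape) != len(self.COORDS[kind]):
            raise ValueError("grid dimensionality does not match kind")
        self.kind = kind
        self.shape = tuple(int(s) for s in shape)
        self.params = np.ones(int(np.prod(self.shape)))
        self.V = V
        self.restraint_weight = restraint_weight

    @property
    def n_params(self) -> int:
        return len(self.params)

    def prepare(self, table):
        cols = self.COORDS[self.kind]
        u = np.column_stack([
            np.clip(table[c].to_numpy(dtype=float) * n - 0.5, 0.0, n - 1.0)
            for c, n in zip(cols, self.shape)])
        return u

    def values_and_derivatives(self, cache):
        u = cache
        ndim = len(self.shape)
        nrow = u.shape[0]
        offsets = np.array(list(itertools.product((-1, 0, 1), repeat=ndim)))
        centre = np.round(u).astype(int)  # (n, ndim), already in range
        nodes = centre[:, None, :] + offsets[None, :, :]  # (n, 27|9, ndim)
        valid = np.ones(nodes.shape[:2], dtype=bool)
        for dim, ndim_size in enumerate(self.shape):
            valid &= (nodes[:, :, dim] >= 0) & (nodes[:, :, dim] < ndim_size)
        dist2 = ((u[:, None, :] - nodes) ** 2).sum(axis=2)
        w = np.where(valid, np.exp(-dist2 / self.V), 0.0)
        w /= w.sum(axis=1, keepdims=True)
        flat = np.zeros(nodes.shape[:2], dtype=int)
        for dim in range(ndim):
            flat = flat * self.shape[dim] + np.clip(nodes[:, :, dim], 0,
                                                    self.shape[dim] - 1)
        value = (w * self.params[flat]).sum(axis=1)
        rows = np.repeat(np.arange(nrow), w.shape[1])
        deriv = sp.csr_matrix((w.ravel(), (rows, flat.ravel())),
                              shape=(nrow, self.n_params))
        return value, deriv


class KBComponent:
    """Single scale k and isotropic B factor: g = k * exp(B/(2 d^2))."""

    kind = "kb"
    null_value = None

    def __init__(self, k: float = 1.0, B: float = 0.0,
                 restraint_weight: float = 0.0):
        self.params = np.array([k, B], dtype=float)
        self.restraint_weight = restraint_weight

    @property
    def n_params(self) -> int:
        return 2

    def prepare(self, table):
        return table["d"].to_numpy(dtype=float)

    def values_and_derivatives(self, cache):
        d = cache
        k, B = self.params
        inv2d2 = 1.0 / (2.0 * d ** 2)
        value = k * np.exp(B * inv2d2)
        deriv = np.column_stack([value / k, value * inv2d2])
        return value, sp.csr_matrix(deriv)
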