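"""Orthogonal polynomial basis on the dimensionless expansion domain.

The domain is the region ``0 <= t <= T``, ``0 <= p <= exp(t)`` (tildes
dropped throughout this module), equipped with the weighted inner product

    <f, g> = int_0^T dt  int_0^{exp(t)} dp  e^{-t} f(t, p) g(t, p).

The exponential weight makes every fixed-t slice contribute equally: the
slice measure ``e^{-t} * exp(t) = 1`` is constant, so ``<1, 1> = T``.

Basis functions are built by Gram-Schmidt orthonormalization of the graded
monomial sequence ``1, t, p, t^2, t*p, p^2, ...`` under this inner product,
evaluated via tensorized Gauss-Legendre quadrature (exact in p, spectrally
convergent in t).  Coefficient fits are ordinary least squares on the basis
evaluated at sample coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss


def graded_monomials(count: int) -> list[tuple[int, int]]:
    """First ``count`` exponent pairs (i, j) for t^i p^j in graded order.

    Within each total degree d, t-powers come first: (d,0), (d-1,1), ...,
    (0,d), reproducing 1, t, p, t^2, t*p, p^2, ...
    """
    out: list[tuple[int, int]] = []
    d = 0
    while len(out) < count:
        for i in range(d, -1, -1):
            out.append((i, d - i))
            if len(out) == count:
                break
        d += 1
    return out


@dataclass(frozen=True)
class InnerProduct:
    """Quadrature rule for the weighted inner product on the domain.

    Attributes
    ----------
    T : float
        Domain extent in dimensionless time.
    nodes_t, nodes_p : arrays, shape (n_t * n_p,)
        Flattened quadrature node coordinates.
    weights : array, shape (n_t * n_p,)
        Quadrature weights with the e^{-t} factor folded in.
    """

    T: float
    nodes_t: np.ndarray
    nodes_p: np.ndarray
    weights: np.ndarray
    n_t: int
    n_p: int

    def dot(self, f: np.ndarray, g: np.ndarray) -> float:
        """<f, g> for functions tabulated at the quadrature nodes."""
        return float(np.sum(self.weights * f * g))

    def evaluate(self, func) -> np.ndarray:
        return func(self.nodes_t, self.nodes_p)


def build_inner_product(T: float, n_nodes: tuple[int, int] = (64, 64)) -> InnerProduct:
    """Tensor Gauss-Legendre rule for the weighted domain integral.

    For each t-node the p-integral runs over [0, exp(t)]; its Jacobian
    exp(t)/2 cancels the e^{-t} weight exactly, so the combined weight is
    simply (T/2) * w_t * w_p / 2.  The rule integrates polynomials exactly
    in p and spectrally in t (the reduced t-integrand contains e^{k t}).
    """
    if T <= 0:
        raise ValueError("domain extent T must be positive")
    n_t, n_p = n_nodes
    xt, wt = leggauss(n_t)
    xp, wp = leggauss(n_p)
    t = 0.5 * T * (xt + 1.0)                      # [0, T]
    tt = np.repeat(t, n_p)
    # p in [0, exp(t)] per t-node
    pp = (0.5 * np.exp(t)[:, None] * (xp + 1.0)[None, :]).ravel()
    ww = (0.5 * T * wt)[:, None] * (0.5 * wp)[None, :]  # e^{-t} * d p-interval cancels
    return InnerProduct(T=float(T), nodes_t=tt, nodes_p=pp,
                        weights=ww.ravel(), n_t=n_t, n_p=n_p)


@dataclass(frozen=True)
class BasisSet:
    """Orthonormal polynomial system on the expansion domain.

    ``coeffs[m, k]`` is the coefficient of monomial ``t^i p^j`` (exponents
    ``monomials[k]``) in basis function P_m.  P_0 is the constant
    ``1/sqrt(T)``.
    """

    T: float
    monomials: tuple[tuple[int, int], ...]
    coeffs: np.ndarray          # (M+1, M+1)
    n_nodes: tuple[int, int]

    @property
    def M(self) -> int:
        return self.coeffs.shape[0] - 1

    @property
    def size(self) -> int:
        return self.coeffs.shape[0]

    @property
    def p0(self) -> float:
        """Value of the constant basis function P_0."""
        return float(self.coeffs[0, 0])

    def evaluate(self, t: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions; returns shape (len(t), M+1)."""
        t = np.asarray(t, float).ravel()
        p = np.asarray(p, float).ravel()
        mono = np.stack([t**i * p**j for i, j in self.monomials], axis=1)
        return mono @ self.coeffs.T

    def to_json(self) -> str:
        return json.dumps({
            "T": self.T,
            "monomials": [list(m) for m in self.monomials],
            "coeffs": self.coeffs.tolist(),
            "n_nodes": list(self.n_nodes),
        })

    @classmethod
    def from_json(cls, text: str) -> "BasisSet":
        d = json.loads(text)
        return cls(T=d["T"],
                   monomials=tuple(tuple(m) for m in d["monomials"]),
                   coeffs=np.asarray(d["coeffs"], float),
                   n_nodes=tuple(d["n_nodes"]))


def gram_schmidt_basis(inner: InnerProduct, M: int = 5) -> BasisSet:
    """Orthonormalize the first M+1 graded monomials under ``inner``.

    Modified Gram-Schmidt with a second re-orthogonalization pass for
    numerical stability; deterministic given the quadrature rule.
    """
    monos = graded_monomials(M + 1)
    # monomial values at quadrature nodes
    vals = np.stack([inner.nodes_t**i * inner.nodes_p**j for i, j in monos], axis=0)
    coeffs = np.eye(M + 1)
    for m in range(M + 1):
        v = vals[m].copy()
        c = coeffs[m].copy()
        for _pass in range(2):
            for k in range(m):
                proj = inner.dot(vals[k], v)
                v -= proj * vals[k]
                c -= proj * coeffs[k]
        norm = np.sqrt(inner.dot(v, v))
        if norm < 1e-12:
            raise ValueError(
                f"rank deficiency at monomial t^{monos[m][0]} p^{monos[m][1]}")
        vals[m] = v / norm
        coeffs[m] = c / norm
    return BasisSet(T=inner.T, monomials=tuple(monos), coeffs=coeffs,
                    n_nodes=(inner.n_t, inner.n_p))


def evaluate_design(basis: BasisSet, coords) -> np.ndarray:
    """Design matrix with entry (l, m) = P_m(t_l, p_l).

    ``coords`` is a sequence of ScaledCoordinate; all must be in-domain.
    """
    for c in coords:
        if not c.in_domain:
            raise ValueError(
                f"coordinate (t~={c.t_tilde:.4g}, p~={c.p_tilde:.4g}) is outside the domain")
    t = np.array([c.t_tilde for c in coords])
    p = np.array([c.p_tilde for c in coords])
    return basis.evaluate(t, p)


def fit_single(g: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for one sample vector.

    Returns the OLS solution; for a rank-deficient design the minimum-norm
    solution is returned with a warning.
    """
    g = np.asarray(g, float)
    if g.shape[0] != design.shape[0]:
        raise ValueError("sample vector and design row counts differ")
    if g.shape[0] < design.shape[1]:
        raise ValueError("fewer samples than basis functions")
    sol, _res, rank, _sv = np.linalg.lstsq(design, g, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; returning minimum-norm solution",
                      RuntimeWarning, stacklevel=2)
    return sol


def fit_stacked(gs: list[np.ndarray], designs: list[np.ndarray]) -> np.ndarray:
    """Single coefficient vector from vertically stacked replicate fits."""
    if len(gs) != len(designs) or not gs:
        raise ValueError("need one design per replicate sample vector")
    g = np.concatenate([np.asarray(x, float) for x in gs])
    X = np.vstack(designs)
    return fit_single(g, X)


def reconstruct(c: np.ndarray, basis: BasisSet,
                t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Smooth field sum_m c_m P_m(t, p) on the given grid (shape of t)."""
    t = np.asarray(t, float)
    shape = t.shape
    vals = basis.evaluate(t.ravel(), np.asarray(p, float).ravel()) @ np.asarray(c, float)
    return vals.reshape(shape)


def domain_grid(T: float, n_t: int = 50, n_p: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Regular in-domain grid (t, p) with p scaled to the local boundary."""
    t = np.linspace(0.0, T, n_t)
    frac = np.linspace(0.0, 1.0, n_p)
    tt, ff = np.meshgrid(t, frac, indexing="ij")
    return tt, ff * np.exp(tt)
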