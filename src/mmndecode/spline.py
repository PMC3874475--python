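"""Spherical-spline scalp interpolation and the spline surface Laplacian.

Scalp potentials are modelled as a spherical spline: a constant plus a
weighted sum of kernels ``g(cos θ)`` built from a Legendre series,

    g(x) = 1/(4π) · Σ_{l=1..L} (2l+1) / (l(l+1))^m · P_l(x)

with stiffness order ``m`` (default 4) and ``L`` series terms.  Fitting
the spline to the good electrodes gives an estimate of the potential
anywhere on the sphere — used to repair bad channels — and applying the
surface-Laplacian kernel to the same fitted weights yields the current
source density used for Laplacian re-referencing.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

__all__ = ["spline_g", "spline_h", "interpolation_matrix", "surface_laplacian"]

DEFAULT_ORDER = 4
DEFAULT_TERMS = 50
DEFAULT_RIDGE = 1e-5


def _legendre_series(x: np.ndarray, order: int, n_terms: int,
                     laplacian: bool) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), -1.0, 1.0)
    out = np.zeros_like(x)
    for l in range(1, n_terms + 1):
        denom = (l * (l + 1.0)) ** order
        factor = (2 * l + 1.0) / denom
        if laplacian:
            factor *= l * (l + 1.0)
        out += factor * eval_legendre(l, x)
    return out / (4.0 * np.pi)


def spline_g(cosang: np.ndarray, order: int = DEFAULT_ORDER,
             n_terms: int = DEFAULT_TERMS) -> np.ndarray:
    """Potential kernel g(cos θ)."""
    return _legendre_series(cosang, order, n_terms, laplacian=False)


def spline_h(cosang: np.ndarray, order: int = DEFAULT_ORDER,
             n_terms: int = DEFAULT_TERMS) -> np.ndarray:
    """Surface-Laplacian kernel h(cos θ) (CSD, up to a head-radius scale)."""
    return _legendre_series(cosang, order, n_terms, laplacian=True)


def _solve_weights(pos_from: np.ndarray, ridge: float, order: int,
                   n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """LU-style solve operator for the constrained spline system.

    Returns ``(G, S_inv)`` where ``S_inv`` inverts the bordered system
    ``[[G + ridge·I, 1], [1ᵀ, 0]]`` so that ``[c; c0] = S_inv @ [v; 0]``.
    """
    nf = len(pos_from)
    G = spline_g(pos_from @ pos_from.T, order, n_terms)
    S = np.zeros((nf + 1, nf + 1))
    S[:nf, :nf] = G + ridge * np.eye(nf)
    S[:nf, nf] = 1.0
    S[nf, :nf] = 1.0
    return G, np.linalg.inv(S)


def interpolation_matrix(pos_from: np.ndarray, pos_to: np.ndarray,
                         order: int = DEFAULT_ORDER,
                         n_terms: int = DEFAULT_TERMS,
                         ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Linear operator mapping potentials at ``pos_from`` to ``pos_to``.

    ``v_to ≈ M @ v_from`` with ``M`` of shape (n_to, n_from).
    """
    pos_from = np.asarray(pos_from, dtype=float)
    pos_to = np.asarray(pos_to, dtype=float)
    nf = len(pos_from)
    _, S_inv = _solve_weights(pos_from, ridge, order, n_terms)
    G_to = spline_g(pos_to @ pos_from.T, order, n_terms)
    # v_to = G_to @ c + c0 ; [c; c0] = S_inv @ [v; 0]
    A = np.hstack([G_to, np.ones((len(pos_to), 1))])  # (n_to, nf+1)
    return A @ S_inv[:, :nf]


def surface_laplacian(pos: np.ndarray, order: int = DEFAULT_ORDER,
                      n_terms: int = DEFAULT_TERMS,
                      ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Operator mapping scalp potentials to their surface Laplacian (CSD)."""
    pos = np.asarray(pos, dtype=float)
    nf = len(pos)
    _, S_inv = _solve_weights(pos, ridge, order, n_terms)
    H = spline_h(pos @ pos.T, order, n_terms)
    A = np.hstack([H, np.zeros((nf, 1))])  # the constant has zero Laplacian
    return A @ S_inv[:, :nf]
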