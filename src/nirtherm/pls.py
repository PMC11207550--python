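"""NIPALS partial least squares regression for a single response (PLS1).

For centred spectra X (n x p) and centred response y (n,), each component
extracts

    w = X^T y / ||X^T y||      (weight)
    t = X w                    (score)
    p = X^T t / (t^T t)        (loading)
    q = y^T t / (t^T t)        (response loading)

and deflates X <- X - t p^T, y <- y - t q.  The regression vector for h
components is b = W (P^T W)^{-1} q, so that yhat = X b.  For a single response
the NIPALS inner loop converges in one pass (no iteration is required); a
zero-norm weight vector means the residual response is orthogonal to the
residual spectra and raises :class:`RankError` at that component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, RankError

__all__ = ["PLSCore", "nipals_pls1"]

#: below this relative norm the residual response is treated as orthogonal to X
_WEIGHT_TOL = 1e-10


@dataclass(frozen=True)
class PLSCore:
    """Fitted NIPALS decomposition on centred data.

    ``b`` maps a centred spectrum to a centred response prediction.  ``W``,
    ``P`` are (p, h); ``q`` is (h,).
    """

    b: np.ndarray
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    n_latent: int

    def regression_vector(self, h: int | None = None) -> np.ndarray:
        """b for the leading ``h`` components (defaults to all fitted)."""
        if h is None:
            h = self.n_latent
        if not (1 <= h <= self.n_latent):
            raise ConfigError(f"h={h} outside 1..{self.n_latent}")
        W, P, q = self.W[:, :h], self.P[:, :h], self.q[:h]
        return W @ np.linalg.solve(P.T @ W, q)


def nipals_pls1(X: np.ndarray, y: np.ndarray, h: int) -> PLSCore:
    """Fit ``h`` PLS1 components to centred X (n x p) and centred y (n,)."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ConfigError("X must be (n, p) and y (n,) with matching n")
    n, p = X.shape
    if not (1 <= h <= min(n - 1, p)):
        raise ConfigError(f"h={h} outside 1..min(n-1, p)={min(n - 1, p)}")

    y_scale = float(np.linalg.norm(y))
    W = np.empty((p, h))
    P = np.empty((p, h))
    q = np.empty(h)
    for a in range(h):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm <= _WEIGHT_TOL * max(y_scale, 1.0):
            raise RankError(
                f"response orthogonal to spectra at component {a + 1}; "
                f"reduce h below {a + 1}"
            )
        w /= norm
        t = X @ w
        tt = float(t @ t)
        pa = X.T @ t / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pa)
        y = y - t * qa
        W[:, a], P[:, a], q[a] = w, pa, qa

    core = PLSCore(b=np.empty(0), W=W, P=P, q=q, n_latent=h)
    object.__setattr__(core, "b", core.regression_vector(h))
    return core
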