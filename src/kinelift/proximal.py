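"""Proximal operators shared by the alternating-solver subproblems.

Both operators are the exact minimizers of their prox problems:

* ``svt(M, tau)`` solves ``argmin_Y tau*||Y||_* + 1/2*||Y - M||_F^2``
  (singular-value soft-thresholding, the proximal operator of the
  nuclear norm).
* ``shrink(M, tau)`` solves ``argmin_Y tau*||Y||_1 + 1/2*||Y - M||_F^2``
  (element-wise soft-thresholding, the proximal operator of the L1 norm).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

#: singular values below this are treated as exactly zero when reporting rank
SINGULAR_VALUE_FLOOR = 1e-12


def _check_matrix(M: np.ndarray, tau: float) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 1 or M.shape[1] < 1:
        raise InvalidInputError(f"expected a 2-D matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise InvalidInputError("matrix contains non-finite entries")
    if not np.isfinite(tau) or tau < 0:
        raise InvalidInputError(f"threshold must be a nonnegative real, got {tau!r}")
    return M


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding.

    Parameters
    ----------
    M : (m, n) array
        Matrix to threshold. Must be finite.
    tau : float
        Nonnegative threshold applied to every singular value.

    Returns
    -------
    (m, n) array
        ``U @ diag(max(s - tau, 0)) @ Vt`` for an economy SVD ``U s Vt`` of M.
    """
    M = _check_matrix(M, tau)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = s - tau
    np.maximum(s, 0.0, out=s)
    s[s < SINGULAR_VALUE_FLOOR] = 0.0
    return (U * s) @ Vt


def shrink(M: np.ndarray, tau: float) -> np.ndarray:
    """Element-wise soft-thresholding: ``sign(m) * max(|m| - tau, 0)``."""
    M = _check_matrix(M, tau)
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)
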