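"""Batched small-matrix exponentials.

The panel likelihood and the life-table occupancy chain both need the
exponential of thousands of tiny (4x4) generator matrices per evaluation.
``scipy.linalg.expm`` handles one matrix at a time with substantial Python
overhead, so this module implements the standard scaling-and-squaring
Pade-13 algorithm over a stacked ``(B, n, n)`` array using batched
``matmul`` / ``solve``.  Accuracy is the same order as scipy's
implementation (it is the same rational approximant); tests cross-check
against ``scipy.linalg.expm`` directly.
"""

from __future__ import annotations

import numpy as np

# Pade-13 numerator/denominator coefficients (b_0 .. b_13), as used by the
# Higham 2005 scaling-and-squaring algorithm.
_B = (
    64764752532480000.0,
    32382376266240000.0,
    7771770303897600.0,
    1187353796428800.0,
    129060195264000.0,
    10559470521600.0,
    670442572800.0,
    33522128640.0,
    1323241920.0,
    40840800.0,
    960960.0,
    16380.0,
    182.0,
    1.0,
)

# theta_13: the largest 1-norm for which the unscaled Pade-13 approximant
# attains full double precision.
_THETA13 = 5.371920351148152


def expm_batch(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of square matrices.

    Parameters
    ----------
    a : ndarray, shape (..., n, n)
        Stack of real square matrices.

    Returns
    -------
    ndarray of the same shape, ``expm`` applied to each matrix.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim < 2 or a.shape[-1] != a.shape[-2]:
        raise ValueError(f"expected a stack of square matrices, got shape {a.shape}")
    if a.size == 0:
        return a.copy()
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite entries in matrix stack")

    # Shared number of squarings for the whole batch, from the largest
    # 1-norm; extra squarings of already-small matrices are harmless.
    norms = np.abs(a).sum(axis=-2).max(axis=-1)
    max_norm = float(norms.max())
    s = 0
    if max_norm > _THETA13:
        s = int(np.ceil(np.log2(max_norm / _THETA13)))
    a_s = a / (2.0**s)

    n = a.shape[-1]
    ident = np.broadcast_to(np.eye(n), a_s.shape)
    a2 = a_s @ a_s
    a4 = a2 @ a2
    a6 = a2 @ a4
    b = _B
    u = a_s @ (
        a6 @ (b[13] * a6 + b[11] * a4 + b[9] * a2)
        + b[7] * a6
        + b[5] * a4
        + b[3] * a2
        + b[1] * ident
    )
    v = (
        a6 @ (b[12] * a6 + b[10] * a4 + b[8] * a2)
        + b[6] * a6
        + b[4] * a4
        + b[2] * a2
        + b[0] * ident
    )
    p = np.linalg.solve(v - u, v + u)
    for _ in range(s):
        p = p @ p
    return p
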