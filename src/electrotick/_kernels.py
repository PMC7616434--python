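"""Jitted 7-point stencil kernels for the 3-D Laplace solver.

The discrete operator is the standard second-order 7-point Laplacian on a
uniform isotropic grid, written without the 1/h^2 factor (it cancels from
A x = b when the right-hand side is built with the same convention).
Zero-normal-flux exterior faces are realised by mirror reflection, and every
node is weighted by (1/2)^(number of domain faces it lies on) — the
finite-volume half-cell weighting that makes the operator symmetric, so
conjugate gradients applies.  Dirichlet nodes (conductors, grounded bottom)
are handled in correction form: their values are moved to the right-hand
side and the corresponding entries of all work vectors are pinned to zero.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _weight(i, n):
    return 0.5 if (i == 0 or i == n - 1) else 1.0


@njit(cache=True)
def apply_raw(v, out):
    """out <- A v with mirror boundaries and half-cell weights (no masking)."""
    n0, n1, n2 = v.shape
    for i in range(n0):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < n0 - 1 else n0 - 2
        wi = _weight(i, n0)
        for j in range(n1):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < n1 - 1 else n1 - 2
            wij = wi * _weight(j, n1)
            for k in range(n2):
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < n2 - 1 else n2 - 2
                s = (
                    v[im, j, k]
                    + v[ip, j, k]
                    + v[i, jm, k]
                    + v[i, jp, k]
                    + v[i, j, km]
                    + v[i, j, kp]
                )
                out[i, j, k] = wij * _weight(k, n2) * (6.0 * v[i, j, k] - s)


@njit(cache=True)
def residual(v, b, mask, out):
    """out <- b - A v at free nodes, 0 at Dirichlet nodes."""
    n0, n1, n2 = v.shape
    for i in range(n0):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < n0 - 1 else n0 - 2
        wi = _weight(i, n0)
        for j in range(n1):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < n1 - 1 else n1 - 2
            wij = wi * _weight(j, n1)
            for k in range(n2):
                if mask[i, j, k]:
                    out[i, j, k] = 0.0
                    continue
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < n2 - 1 else n2 - 2
                s = (
                    v[im, j, k]
                    + v[ip, j, k]
                    + v[i, jm, k]
                    + v[i, jp, k]
                    + v[i, j, km]
                    + v[i, j, kp]
                )
                out[i, j, k] = b[i, j, k] - wij * _weight(k, n2) * (
                    6.0 * v[i, j, k] - s
                )


@njit(cache=True)
def rb_gauss_seidel(v, b, mask, parity):
    """One red-black half-sweep (nodes with (i+j+k) % 2 == parity), in place."""
    n0, n1, n2 = v.shape
    for i in range(n0):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < n0 - 1 else n0 - 2
        wi = _weight(i, n0)
        for j in range(n1):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < n1 - 1 else n1 - 2
            wij = wi * _weight(j, n1)
            kstart = (parity - (i + j)) % 2
            for k in range(kstart, n2, 2):
                if mask[i, j, k]:
                    continue
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < n2 - 1 else n2 - 2
                s = (
                    v[im, j, k]
                    + v[ip, j, k]
                    + v[i, jm, k]
                    + v[i, jp, k]
                    + v[i, j, km]
                    + v[i, j, kp]
                )
                v[i, j, k] = (b[i, j, k] / (wij * _weight(k, n2)) + s) / 6.0
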