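"""Independent scalar 1D MUSCL reference implementation.

A deliberately plain, loop-based Kurganov-Tadmor / superbee advection
right-hand side used as the oracle for the packaged 3D operator.  It shares
no code with the package.
"""

import numpy as np


def superbee_1d(r):
    return max(0.0, min(2.0 * r, 1.0), min(r, 2.0))


def muscl_rhs_1d(f, u_faces, dx):
    """d fbar / dt for 1D advection; zero ghost cells on both sides.

    ``u_faces`` has length n + 1, face i between cells i-1 and i.
    """
    f = np.asarray(f, dtype=float)
    n = f.size
    fp = np.zeros(n + 4)
    fp[2:-2] = f

    # limited increment sigma_i = phi(r_i)/2 * (f_{i+1} - f_i), cells -1..n
    sigma = np.zeros(n + 2)
    for i in range(n + 2):
        fm, f0, f1 = fp[i], fp[i + 1], fp[i + 2]
        d = f1 - f0
        if d == 0.0:
            sigma[i] = 0.0      # phi = 2 branch; increment vanishes
        else:
            r = (f0 - fm) / d
            sigma[i] = 0.5 * superbee_1d(r) * d

    F = np.zeros(n + 1)
    for i in range(n + 1):
        fL = fp[i + 1] + sigma[i]
        fR = fp[i + 2] - sigma[i + 1]
        u = u_faces[i]
        F[i] = 0.5 * u * (fR + fL) - 0.5 * abs(u) * (fR - fL)

    rhs = np.empty(n)
    for i in range(n):
        rhs[i] = -(F[i + 1] - F[i]) / dx
    return rhs


def ssprk3_1d(f, u_faces, dx, dt):
    k1 = muscl_rhs_1d(f, u_faces, dx)
    k2 = muscl_rhs_1d(f + dt * k1, u_faces, dx)
    k3 = muscl_rhs_1d(f + dt * (k1 + k2) / 4.0, u_faces, dx)
    return f + dt / 6.0 * (k1 + k2 + 4.0 * k3)
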