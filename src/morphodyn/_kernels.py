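"""Compiled inner loop of the explicit two-state integrator.

The forward-Euler update is trivially vectorisable, but at the reference
resolution (10 001 nodes, 10^6 steps for a 100 s run at dt = 1e-4) the
per-step numpy overhead dominates; a numba kernel keeps a full run in the
tens of seconds.  fastmath is deliberately off so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def advance_two_state(u, v, a, g, D, b, c, dx, dt, n_steps):
    """Advance (u, v) in place by ``n_steps`` explicit-Euler steps.

    du/dt = D lap(u) - a u + b v + g    (Neumann ends via mirrored ghosts)
    dv/dt = a u - (b + c) v             (no diffusion of the bound field)
    """
    n = u.shape[0]
    r = D * dt / (dx * dx)
    bc = b + c
    u_new = np.empty(n)
    for _ in range(n_steps):
        u_new[0] = u[0] + 2.0 * r * (u[1] - u[0]) + dt * (-a[0] * u[0] + b * v[0] + g[0])
        for i in range(1, n - 1):
            u_new[i] = (u[i] + r * (u[i + 1] - 2.0 * u[i] + u[i - 1])
                        + dt * (-a[i] * u[i] + b * v[i] + g[i]))
        u_new[n - 1] = (u[n - 1] + 2.0 * r * (u[n - 2] - u[n - 1])
                        + dt * (-a[n - 1] * u[n - 1] + b * v[n - 1] + g[n - 1]))
        for i in range(n):
            v[i] = v[i] + dt * (a[i] * u[i] - bc * v[i])
            u[i] = u_new[i]
    return u, v
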