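"""Shared test utilities: small CPG simulations and period extraction."""

import numpy as np

from cpgwalk.body import integrate_step
from cpgwalk.controller import CPGNetwork, cpg_derivatives


def two_unit_network(tau=0.1, taup=0.2, beta=2.5, a=-2.5, u0=1.0,
                     u_init=(0.1, 0.0)):
    """12-unit network with only the first two units mutually coupled."""
    W = np.zeros((12, 12))
    W[0, 1] = W[1, 0] = a
    net = CPGNetwork(tau=np.full(12, tau), taup=np.full(12, taup),
                     beta=beta, W=W, u0=u0)
    net.u[:2] = u_init
    return net


def simulate_cpg(net, T, dt=1e-3):
    """Integrate the CPG alone (no feedback); returns y0(t)."""
    s = np.concatenate([net.u, net.v])

    def deriv(sv):
        n = CPGNetwork(u=sv[:12], v=sv[12:], tau=net.tau, taup=net.taup,
                       beta=net.beta, W=net.W, u0=net.u0)
        du, dv = cpg_derivatives(n, np.zeros(12))
        return np.concatenate([du, dv])

    n_steps = int(round(T / dt))
    y0 = np.empty(n_steps)
    for i in range(n_steps):
        s = integrate_step(s, deriv, dt)
        y0[i] = max(0.0, s[0])
    return y0


def dominant_period(y, dt):
    """Oscillation period from mean-crossing intervals (second half)."""
    h = y[len(y) // 2:]
    m = h.mean()
    up = np.flatnonzero((h[1:] >= m) & (h[:-1] < m))
    assert len(up) >= 3, "no sustained oscillation"
    return float(np.diff(up).mean() * dt)
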