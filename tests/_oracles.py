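"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles (dense linear
algebra over explicitly enumerated networks, published empirical formulas,
finite-difference solutions) and shares no code with the implementation
under test.
"""

import math

import numpy as np

MMHG_PA = 133.322


def pries_secomb_invitro(d_um: float, hct: float) -> float:
    """Published in-vitro relative apparent viscosity of blood in tube flow.

    mu_rel = 1 + (mu45 - 1) * ((1 - H)^C - 1) / ((1 - 0.45)^C - 1), with
    mu45(d) = 6 e^(-0.085 d) + 3.2 - 2.44 e^(-0.06 d^0.645) and the standard
    diameter-dependent exponent C(d).
    """
    d = float(d_um)
    mu45 = 6.0 * math.exp(-0.085 * d) + 3.2 - 2.44 * math.exp(-0.06 * d ** 0.645)
    sig = 1.0 / (1.0 + 1e-11 * d ** 12)
    c = (0.8 + math.exp(-0.075 * d)) * (sig - 1.0) + sig
    if hct == 0.0:
        return 1.0
    return 1.0 + (mu45 - 1.0) * (((1.0 - hct) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0))


def brute_force_tree_resistance(radii, lams, mus, p_terminal_pa, q_root):
    """Equivalent root resistance of a full symmetric binary tree, by dense solve.

    ``radii``/``lams``/``mus`` give per-generation segment properties
    (generation 0 = the single root segment, generation n = the 2^n terminal
    segments).  Every terminal segment ends in a load resistance
    p_terminal / q_terminal to the zero-pressure ground.  Returns
    P_root_inlet / q_root from a dense nodal solve of the explicit network,
    and the terminal node pressures.
    """
    n = len(radii) - 1
    # node numbering: 0 = root inlet; then heap-style numbering of segment
    # outlet nodes: segment (g, k) for k in 0..2^g-1 has outlet node
    # offset[g] + k + 1.
    offset = [0]
    for g in range(n + 1):
        offset.append(offset[-1] + 2 ** g)
    n_nodes = 1 + offset[n + 1]
    a = np.zeros((n_nodes, n_nodes))
    b = np.zeros(n_nodes)

    def seg_resistance(g):
        r, lam, mu = radii[g], lams[g], mus[g]
        return 8.0 * mu * (lam * r) / (math.pi * r ** 4)

    def outlet_node(g, k):
        return 1 + offset[g] + k

    def inlet_node(g, k):
        return 0 if g == 0 else outlet_node(g - 1, k // 2)

    for g in range(n + 1):
        rg = seg_resistance(g)
        for k in range(2 ** g):
            i, j = inlet_node(g, k), outlet_node(g, k)
            gcond = 1.0 / rg
            a[i, i] += gcond
            a[j, j] += gcond
            a[i, j] -= gcond
            a[j, i] -= gcond
    q_terminal = q_root / 2 ** n
    r_term = p_terminal_pa / q_terminal
    for k in range(2 ** n):
        j = outlet_node(n, k)
        a[j, j] += 1.0 / r_term
    b[0] = q_root
    p = np.linalg.solve(a, b)
    terminals = np.array([p[outlet_node(n, k)] for k in range(2 ** n)])
    return p[0] / q_root, terminals


def dense_graph_solve(edges, mu_by_edge, inflows, outlet_ground):
    """Independent nodal solve of an arbitrary conductor graph.

    ``edges``: iterable of objects with .id/.u/.v/.kind/.radius/
    .inner_radius/.length.  ``inflows``: node -> injected m3/s.
    ``outlet_ground``: node -> ground resistance (Pa s/m3), or 0 for a
    zero-pressure outlet.  Returns (pressure dict, edge flow dict).
    """
    nodes = []
    for e in edges:
        for nd in (e.u, e.v):
            if nd not in nodes:
                nodes.append(nd)
    idx = {nd: i for i, nd in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    b = np.zeros(n)
    cond = {}
    for e in edges:
        mu = mu_by_edge[e.id]
        r, l = e.radius, e.length
        if e.kind == "annulus" and e.inner_radius > 0:
            ri = e.inner_radius
            k = r ** 4 - ri ** 4 - (r ** 2 - ri ** 2) ** 2 / math.log(r / ri)
            g = math.pi * k / (8.0 * mu * l)
        else:
            g = math.pi * r ** 4 / (8.0 * mu * l)
        cond[e.id] = g
        i, j = idx[e.u], idx[e.v]
        a[i, i] += g
        a[j, j] += g
        a[i, j] -= g
        a[j, i] -= g
    for nd, q in inflows.items():
        b[idx[nd]] += q
    dirichlet = []
    for nd, rg in outlet_ground.items():
        if rg > 0:
            a[idx[nd], idx[nd]] += 1.0 / rg
        else:
            dirichlet.append(idx[nd])
    for i in dirichlet:
        a[i, :] = 0.0
        a[i, i] = 1.0
        b[i] = 0.0
    p = np.linalg.solve(a, b)
    pressure = {nd: p[idx[nd]] for nd in nodes}
    flow = {e.id: cond[e.id] * (pressure[e.u] - pressure[e.v]) for e in edges}
    return pressure, flow


def annulus_profile_fd(q, r_outer, r_inner, mu, n_points=40001):
    """Finite-difference annular Poiseuille solution.

    Integrates the radial momentum equation for the axial velocity with
    no-slip at both walls, scales the pressure gradient to carry flow ``q``,
    and returns (tau_vessel, tau_catheter) from one-sided second-order
    differences at the walls.
    """
    r = np.linspace(r_inner, r_outer, n_points)
    # u(r) for unit pressure gradient G=1: u = (1/4mu)(A + B ln r - r^2)
    # with u(a)=u(R)=0
    a2, r2 = r_inner ** 2, r_outer ** 2
    bcoef = (r2 - a2) / math.log(r_outer / r_inner)
    acoef = r2 - bcoef * math.log(r_outer)
    u = (acoef + bcoef * np.log(r) - r ** 2) / (4.0 * mu)
    q_unit = np.trapezoid(2.0 * math.pi * r * u, r)
    scale = q / q_unit
    u *= scale
    h = r[1] - r[0]
    dudr_inner = (-3 * u[0] + 4 * u[1] - u[2]) / (2 * h)
    dudr_outer = (3 * u[-1] - 4 * u[-2] + u[-3]) / (2 * h)
    return mu * abs(dudr_outer), mu * abs(dudr_inner)
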