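"""Independent oracles used to cross-check the production code paths.

These are deliberately naive implementations — per-branch fixed-grid RK4
integration for the two-region likelihood, closed-form pure-birth likelihood,
brute-force edge enumeration for Faith PD, and textbook normal equations for
least squares. They share no code with the production solvers beyond the tree
container.
"""

from __future__ import annotations

import numpy as np

from biomediv.phylo import Phylogeny


def geosse_loglik_rk4(tree: Phylogeny, states: dict[str, int], rates,
                      sampling=(1.0, 1.0, 1.0), step: float = 1e-3,
                      slopes=None, root_mode: str = "obs") -> float:
    """Fine-step fixed-grid RK4 evaluation of the two-region likelihood.

    ``rates`` is (sA, sB, sAB, xA, xB, dA, dB); optional ``slopes`` of the
    same length give linear time dependence r(t) = max(0, r0 + m t).
    State indices: 0 = A, 1 = B, 2 = AB; paper tip coding 1/2/0.
    """
    r0 = np.asarray(rates, dtype=float)
    mm = np.zeros(7) if slopes is None else np.asarray(slopes, dtype=float)
    rho0, rho1, rho2 = sampling
    e0 = np.array([1 - rho1, 1 - rho2, 1 - rho0])
    ages = tree.ages()
    tip_of = tree.tip_index()

    def rate(t):
        return np.maximum(0.0, r0 + mm * t)

    def ode(t, y):
        sA, sB, sAB, xA, xB, dA, dB = rate(t)
        EA, EB, EAB, DA, DB, DAB = y
        return np.array([
            xA - (sA + dA + xA) * EA + dA * EAB + sA * EA ** 2,
            xB - (sB + dB + xB) * EB + dB * EAB + sB * EB ** 2,
            -(sA + sB + sAB + xA + xB) * EAB + xA * EB + xB * EA
            + sA * EA * EAB + sB * EB * EAB + sAB * EA * EB,
            -(sA + dA + xA) * DA + dA * DAB + 2 * sA * EA * DA,
            -(sB + dB + xB) * DB + dB * DAB + 2 * sB * EB * DB,
            -(sA + sB + sAB + xA + xB) * DAB + xA * DB + xB * DA
            + sA * (EAB * DA + EA * DAB) + sB * (EAB * DB + EB * DAB)
            + sAB * (EA * DB + EB * DA),
        ])

    def up_branch(t0, t1, y):
        n = max(int(np.ceil((t1 - t0) / step)), 1)
        h = (t1 - t0) / n
        t = t0
        for _ in range(n):
            k1 = ode(t, y)
            k2 = ode(t + h / 2, y + h / 2 * k1)
            k3 = ode(t + h / 2, y + h / 2 * k2)
            k4 = ode(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        return y

    logcomp = [0.0]

    def solve(node):
        if tree.is_tip[node]:
            d = np.zeros(3)
            st = states[tree.labels[node]]
            d[{1: 0, 2: 1, 0: 2}[st]] = {1: rho1, 2: rho2, 0: rho0}[st]
            return np.concatenate([e0, d])
        ys = []
        for c in tree.children[node]:
            ys.append(up_branch(ages[c] if tree.is_tip[c] else ages[c],
                                ages[node], solve(c)))
        yl, yr = ys
        sA, sB, sAB, *_ = rate(ages[node])
        d = np.array([
            sA * yl[3] * yr[3],
            sB * yl[4] * yr[4],
            0.5 * (sA * (yl[3] * yr[5] + yl[5] * yr[3])
                   + sB * (yl[4] * yr[5] + yl[5] * yr[4])
                   + sAB * (yl[3] * yr[4] + yl[4] * yr[3])),
        ])
        s = d.sum()
        logcomp[0] += np.log(s)
        return np.concatenate([(yl[:3] + yr[:3]) / 2, d / s])

    y_root = solve(tree.postorder()[-1])
    d_root = y_root[3:]
    e_root = y_root[:3]
    if root_mode == "equal":
        lik = d_root.mean()
    else:
        w = d_root / d_root.sum()
        lik = float((w * d_root).sum())
        if root_mode == "survival":
            sA, sB, sAB, *_ = rate(tree.ages()[tree.postorder()[-1]])
            lam = np.array([sA, sB, sA + sB + sAB])
            lik /= float((w * lam * (1 - e_root) ** 2).sum())
    return float(np.log(lik) + logcomp[0])


def yule_loglik(branching_times: np.ndarray, lam: float) -> float:
    """Closed-form pure-birth likelihood, conditioned on crown survival.

    With mu = 0 and complete sampling: q(t) = exp(-lam t), F = 1, so
    lnL = -2 lam x1 + sum_{i>=2} (ln lam - lam x_i).
    """
    x = np.sort(np.asarray(branching_times, dtype=float))[::-1]
    return float(-2 * lam * x[0] + np.sum(np.log(lam) - lam * x[1:]))


def faith_pd_bruteforce(tree: Phylogeny, species: set[str]) -> float:
    """Root-inclusive Faith PD by enumerating root-path edges per tip."""
    tip_of = tree.tip_index()
    edges: set[int] = set()
    for sp in species:
        node = tip_of[sp]
        while node != tree.root:
            edges.add(node)
            node = int(tree.parent[node])
    return float(sum(tree.length[e] for e in edges))


def ols_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares residuals via the raw normal equations."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta
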