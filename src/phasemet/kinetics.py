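"""First-order kinetic networks: closed-form chains and RK4 for DAGs.

The synthetic ground-truth dynamics are linear mass-action systems
``dx/dt = A x``.  Pure chains are solved with the classical cascade
(Bateman) expression, general DAGs with fixed-step 4th-order
Runge-Kutta; the two agree on chains to ~1e-9 and the closed form
doubles as the test oracle for the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "KineticNetworkSpec",
    "KineticsError",
    "bateman_chain",
    "simulate_kinetics",
]


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class KineticNetworkSpec:
    """A DAG of first-order conversions rooted at the parent species."""

    species: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]  # (from, to, k per hour)
    parent: str = ""
    initial: dict = field(default_factory=dict)  # defaults: parent=1, rest 0
    elimination: dict = field(default_factory=dict)  # species -> k out of system

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise KineticsError("duplicate species ids")
        parent = self.parent or (self.species[0] if self.species else "")
        object.__setattr__(self, "parent", parent)
        for src, dst, k in self.edges:
            if src not in self.species or dst not in self.species:
                raise KineticsError(f"edge {src}->{dst} references unknown species")
            if k < 0:
                raise KineticsError(f"negative rate on edge {src}->{dst}")
        for s, k in self.elimination.items():
            if s not in self.species or k < 0:
                raise KineticsError(f"bad elimination entry {s}: {k}")
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        g.add_edges_from((s, d) for s, d, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise KineticsError("kinetic network contains a cycle")

    def initial_vector(self) -> np.ndarray:
        x0 = np.zeros(len(self.species))
        if self.initial:
            for s, v in self.initial.items():
                x0[self.species.index(s)] = v
        else:
            x0[self.species.index(self.parent)] = 1.0
        return x0

    def rate_matrix(self) -> np.ndarray:
        n = len(self.species)
        idx = {s: i for i, s in enumerate(self.species)}
        a = np.zeros((n, n))
        for src, dst, k in self.edges:
            a[idx[dst], idx[src]] += k
            a[idx[src], idx[src]] -= k
        for s, k in self.elimination.items():
            a[idx[s], idx[s]] -= k
        return a

    def is_chain(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        g.add_edges_from((s, d) for s, d, _ in self.edges)
        degs_ok = all(g.out_degree(s) <= 1 and g.in_degree(s) <= 1 for s in self.species)
        return degs_ok and nx.is_weakly_connected(g) and not self.elimination


def bateman_chain(rates: list[float], times: np.ndarray, x0: float = 1.0) -> np.ndarray:
    """Closed-form cascade solution for A1 -> A2 -> ... -> An.

    ``rates`` holds the n-1 conversion rate constants; the terminal
    species does not decay.  Requires pairwise-distinct rates (the
    classical expression has removable singularities at equal rates).
    Returns an array of shape (n_species, n_times).
    """
    times = np.asarray(times, dtype=float)
    lam = list(rates) + [0.0]  # decay constant of each species
    n = len(lam)
    if len(set(lam)) != n:
        raise KineticsError("closed-form cascade requires pairwise-distinct rates")
    out = np.zeros((n, len(times)))
    for i in range(n):
        prod_k = np.prod(rates[:i]) if i > 0 else 1.0
        acc = np.zeros(len(times))
        for j in range(i + 1):
            denom = np.prod([lam[m] - lam[j] for m in range(i + 1) if m != j])
            acc += np.exp(-lam[j] * times) / denom
        out[i] = x0 * prod_k * acc
    return out


def _rk4(a: np.ndarray, x0: np.ndarray, times: np.ndarray, dt: float) -> np.ndarray:
    """Fixed-step RK4 for dx/dt = A x, sampled at ``times`` (sorted)."""
    out = np.zeros((len(x0), len(times)))
    x = x0.astype(float).copy()
    t = 0.0
    for j, target in enumerate(times):
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = a @ x
            k2 = a @ (x + 0.5 * h * k1)
            k3 = a @ (x + 0.5 * h * k2)
            k4 = a @ (x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[:, j] = x
    return out


def simulate_kinetics(
    spec: KineticNetworkSpec,
    times,
    method: str = "auto",
    dt: float = 0.01,
) -> np.ndarray:
    """Noiseless trajectories at the requested times (species x time).

    ``method``: "auto" uses the closed-form cascade for chains with
    distinct rates and RK4 otherwise; "bateman" and "rk4" force one path.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise KineticsError("times must be non-negative and strictly increasing")
    if method not in ("auto", "bateman", "rk4"):
        raise KineticsError(f"unknown method {method!r}")
    use_bateman = False
    if method == "bateman" or (method == "auto" and spec.is_chain()):
        try:
            ordered, rates = _chain_order(spec)
            x0 = spec.initial_vector()
            head_idx = spec.species.index(ordered[0])
            if any(v != 0 for i, v in enumerate(x0) if i != head_idx):
                raise KineticsError(
                    "closed-form cascade requires all initial mass in the head species"
                )
            use_bateman = True
        except KineticsError:
            if method == "bateman":
                raise
    if use_bateman:
        x0 = spec.initial_vector()
        parent_amount = x0[spec.species.index(ordered[0])]
        traj = bateman_chain(rates, times, x0=parent_amount)
        out = np.zeros((len(spec.species), len(times)))
        for row, s in zip(traj, ordered):
            out[spec.species.index(s)] = row
        return out
    return _rk4(spec.rate_matrix(), spec.initial_vector(), times, dt)


def _chain_order(spec: KineticNetworkSpec) -> tuple[list[str], list[float]]:
    if not spec.is_chain():
        raise KineticsError("network is not a chain")
    succ = {s: (d, k) for s, d, k in spec.edges}
    heads = [s for s in spec.species if s not in {d for _, d, _ in spec.edges}]
    if len(heads) != 1:
        raise KineticsError("chain must have a unique head")
    order, rates = [heads[0]], []
    while order[-1] in succ:
        dst, k = succ[order[-1]]
        order.append(dst)
        rates.append(k)
    if len(order) != len(spec.species):
        raise KineticsError("disconnected chain")
    lam = rates + [0.0]
    if len(set(lam)) != len(lam):
        raise KineticsError("chain rates not pairwise distinct")
    return order, rates
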