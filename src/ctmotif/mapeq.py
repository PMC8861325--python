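"""Module detection by two-level codelength minimisation on the C-T network.

A random walk with uniform teleportation induces a visit distribution over
nodes; a partition of the nodes is scored by the expected per-step
description length of the walk under a two-level (index + per-module)
codebook,

    L(M) = q * H(Q) + sum_i p_circ_i * H(P_i)      [bits/step]

where ``q_i`` is the per-step probability of exiting module ``i`` (including
teleportation flow when tau > 0), ``q = sum_i q_i``, ``H(Q)`` the entropy of
the normalised exit rates, ``p_circ_i = q_i + sum_{a in i} p_a`` and
``H(P_i)`` the entropy of the within-module codebook ``(q_i, p_a ...)``.

Logs are base 2 and ``0 log 0 = 0``.  The search is a seeded multi-restart
greedy over single-node moves plus module merges; the significance filter
compares each module's codelength saving against degree-preserving
rewirings of the bipartite edge set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import CTNetwork

logger = logging.getLogger(__name__)

_EPS = 1e-13


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0.0 else 0.0


def entropy(weights) -> float:
    """Shannon entropy (bits) of a non-negative weight vector after normalisation."""
    w = np.asarray(list(weights), dtype=float)
    s = w.sum()
    if s <= 0:
        return 0.0
    p = w[w > 0] / s
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VisitDistribution:
    """Stationary visit rates of the (teleporting) random walk."""

    p: dict  # node -> visit rate
    tau: float

    def __post_init__(self) -> None:
        total = sum(self.p.values())
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"visit rates sum to {total}, not 1")
        if any(v < 0 for v in self.p.values()):
            raise ValueError("negative visit rate")


@dataclass(frozen=True)
class Partition:
    """Node -> module assignment with contiguous module ids 1..m."""

    assignment: dict
    m: int

    def __post_init__(self) -> None:
        mids = set(self.assignment.values())
        if mids and mids != set(range(1, self.m + 1)):
            raise ValueError("module ids must be contiguous from 1")

    @classmethod
    def from_assignment(cls, assignment: dict) -> "Partition":
        """Renumber arbitrary module labels to 1..m (ordered by min node label)."""
        groups: dict = {}
        for node, mid in assignment.items():
            groups.setdefault(mid, []).append(node)
        order = sorted(groups, key=lambda mid: min(map(str, groups[mid])))
        relabel = {old: i + 1 for i, old in enumerate(order)}
        return cls({n: relabel[m] for n, m in assignment.items()}, len(order))

    def modules(self) -> dict:
        out: dict = {i: set() for i in range(1, self.m + 1)}
        for node, mid in self.assignment.items():
            out[mid].add(node)
        return out


@dataclass(frozen=True)
class CodelengthReport:
    """Every term of the two-level codelength, assembled exactly as

    ``L = q_total * HQ + sum_i p_circ[i] * HP[i]``.
    """

    L: float
    q_total: float
    HQ: float
    q_exit: dict  # module id -> exit rate
    p_circ: dict  # module id -> within-module codebook use rate
    HP: dict  # module id -> within-module entropy

    def __post_init__(self) -> None:
        assembled = self.q_total * self.HQ + sum(
            self.p_circ[i] * self.HP[i] for i in self.p_circ
        )
        if abs(assembled - self.L) > 1e-9:
            raise ValueError("codelength does not match its term decomposition")
        if self.HQ < 0 or any(h < -0.0 for h in self.HP.values()):
            raise ValueError("negative entropy term")


@dataclass(frozen=True)
class SDFM:
    """A module that passed (or is being tested for) the significance filter."""

    module_id: int
    members: frozenset  # prefixed node labels
    p_value: float
    saving: float  # bits saved vs the one-module partition

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("SDFM members must be non-empty")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def components(self) -> frozenset:
        return frozenset(n[2:] for n in self.members if n.startswith("C:"))

    @property
    def targets(self) -> frozenset:
        return frozenset(n[2:] for n in self.members if n.startswith("T:"))


# ---------------------------------------------------------------------------
# Graph plumbing
# ---------------------------------------------------------------------------


class _GraphData:
    """Index-based adjacency snapshot of an undirected weighted graph."""

    def __init__(self, graph: nx.Graph):
        self.nodes = sorted(graph.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.N = len(self.nodes)
        nbr: list = [[] for _ in range(self.N)]
        for u, v, data in graph.edges(data=True):
            w = float(data.get("weight", 1.0))
            iu, iv = self.index[u], self.index[v]
            nbr[iu].append((iv, w))
            nbr[iv].append((iu, w))
        self.neighbors = [np.array([i for i, _ in lst], dtype=np.int64) for lst in nbr]
        self.weights = [np.array([w for _, w in lst], dtype=float) for lst in nbr]
        self.strength = np.array([w.sum() for w in self.weights])
        self.graph = graph


def _as_graph(net) -> nx.Graph:
    if isinstance(net, CTNetwork):
        return net.to_graph()
    if isinstance(net, nx.Graph):
        return net
    raise TypeError(f"expected CTNetwork or networkx.Graph, got {type(net)!r}")


def _degree_rates(gd: _GraphData) -> np.ndarray:
    """Closed-form stationary rates of the undirected walk: strength / 2W."""
    total = gd.strength.sum()
    if total <= 0:
        raise ValueError("graph has no edges")
    return gd.strength / total


def _transition_matrix(gd: _GraphData):
    """Sparse row-stochastic transition matrix (dangling rows left empty)."""
    from scipy import sparse

    rows, cols, vals = [], [], []
    for i in range(gd.N):
        if gd.strength[i] > 0:
            rows.extend([i] * len(gd.neighbors[i]))
            cols.extend(gd.neighbors[i].tolist())
            vals.extend((gd.weights[i] / gd.strength[i]).tolist())
    return sparse.csr_matrix((vals, (rows, cols)), shape=(gd.N, gd.N))


# ---------------------------------------------------------------------------
# Visit rates
# ---------------------------------------------------------------------------


def visit_rates(net, tau: float = 0.15, tol: float = 1e-12, max_iter: int = 100_000):
    """Stationary distribution of the teleporting random walk.

    With ``tau = 0`` the graph must be connected (the closed form
    ``p_a = strength(a) / 2W`` is then the unique stationary distribution);
    a disconnected graph raises instructing ``tau > 0``.  Convergence is
    verified by the L1 residual of a full transition step.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"tau must be in [0, 1), got {tau}")
    graph = _as_graph(net)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    gd = _GraphData(graph)
    if tau == 0.0:
        if not nx.is_connected(graph):
            raise ValueError(
                "tau = 0 requires a connected network; use tau > 0 for "
                "disconnected networks"
            )
        # start from the closed form; the residual check below certifies it
        p = _degree_rates(gd)
    else:
        # start from the tau=0 closed form when edges exist, else uniform
        p = _degree_rates(gd) if gd.strength.sum() > 0 else np.full(gd.N, 1.0 / gd.N)

    PT = _transition_matrix(gd).T.tocsr()  # column-stochastic after transpose
    dangling = gd.strength == 0
    any_dangling = bool(dangling.any())

    def step(vec: np.ndarray) -> np.ndarray:
        free = (1.0 - tau) * vec[dangling].sum() if any_dangling else 0.0
        return (1.0 - tau) * (PT @ vec) + (tau + free) / gd.N

    converged = False
    for _ in range(max_iter):
        nxt = step(p)
        if np.abs(nxt - p).sum() < tol:
            p = nxt
            converged = True
            break
        # damped update guards against the period-2 modes of bipartite graphs
        p = 0.5 * p + 0.5 * nxt
    if not converged:  # pragma: no cover - max_iter is generous
        raise RuntimeError("power iteration did not converge")
    p = p / p.sum()
    return VisitDistribution({n: float(p[gd.index[n]]) for n in gd.nodes}, tau)


# ---------------------------------------------------------------------------
# Codelength
# ---------------------------------------------------------------------------


def _module_flow_stats(gd: _GraphData, p: np.ndarray, assign: np.ndarray, tau: float):
    """Per-module (q_i, S_i, n_i) arrays for the given assignment."""
    mids = np.unique(assign)
    pos = {m: i for i, m in enumerate(mids)}
    k = len(mids)
    S = np.zeros(k)
    n = np.zeros(k)
    edge_exit = np.zeros(k)
    tele_S = np.zeros(k)
    N = gd.N
    for i in range(N):
        mi = pos[assign[i]]
        S[mi] += p[i]
        n[mi] += 1
        if gd.strength[i] > 0:
            out_w = gd.weights[i][assign[gd.neighbors[i]] != assign[i]].sum()
            edge_exit[mi] += p[i] * out_w / gd.strength[i]
            tele_S[mi] += tau * p[i]
        else:
            tele_S[mi] += p[i]  # dangling mass teleports entirely
    q = (1.0 - tau) * edge_exit + tele_S * (N - n) / N
    return mids, q, S, n


def codelength(net, partition: Partition, v: VisitDistribution) -> CodelengthReport:
    """Assemble the full codelength report for ``partition`` under flow ``v``."""
    graph = _as_graph(net)
    gd = _GraphData(graph)
    missing = [n for n in gd.nodes if n not in partition.assignment]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    p = np.array([v.p[n] for n in gd.nodes])
    assign = np.array([partition.assignment[n] for n in gd.nodes])
    mids, q, S, n = _module_flow_stats(gd, p, assign, v.tau)

    q_total = float(q.sum())
    HQ = entropy(q) if len(mids) > 1 else 0.0
    if q_total <= 0:
        HQ = 0.0
    q_exit, p_circ, HP = {}, {}, {}
    members = {m: [] for m in mids}
    for i, m in enumerate(assign):
        members[m].append(p[i])
    L = q_total * HQ
    for j, m in enumerate(mids):
        pc = float(q[j] + S[j])
        h = entropy([q[j], *members[m]])
        q_exit[int(m)] = float(q[j])
        p_circ[int(m)] = pc
        HP[int(m)] = h
        L += pc * h
    return CodelengthReport(L=float(L), q_total=q_total, HQ=HQ, q_exit=q_exit,
                            p_circ=p_circ, HP=HP)


def _L_from_stats(q: np.ndarray, S: np.ndarray, const: float) -> float:
    """Expanded codelength: plogp(q) - 2*sum plogp(q_i) + sum plogp(q_i+S_i) - const.

    ``const = sum_a plogp(p_a)`` is partition-independent.
    """
    q_total = q.sum()
    L = _plogp(q_total) - const
    for j in range(len(q)):
        L += -2.0 * _plogp(q[j]) + _plogp(q[j] + S[j])
    return L


# ---------------------------------------------------------------------------
# Partition search
# ---------------------------------------------------------------------------


class _SearchState:
    """Mutable module statistics supporting O(deg) move evaluation."""

    def __init__(self, gd: _GraphData, p: np.ndarray, tau: float):
        self.gd = gd
        self.p = p
        self.tau = tau
        self.N = gd.N
        self.tele = np.where(gd.strength > 0, tau * p, p)
        self.const = sum(_plogp(x) for x in p)
        # one module per node initially
        self.assign = np.arange(self.N, dtype=np.int64)
        self.S = p.copy()
        self.teleS = self.tele.copy()
        self.n = np.ones(self.N, dtype=np.int64)
        self.EE = np.zeros(self.N)  # edge-exit flow per module
        for i in range(self.N):
            if gd.strength[i] > 0:
                self.EE[i] = p[i]  # all edges external in singleton modules
        self.active = set(range(self.N))
        self.freed: list = []

    def q_of(self, m: int, EE=None, teleS=None, n=None) -> float:
        EE = self.EE[m] if EE is None else EE
        teleS = self.teleS[m] if teleS is None else teleS
        n = self.n[m] if n is None else n
        return (1.0 - self.tau) * EE + teleS * (self.N - n) / self.N

    def total_L(self) -> float:
        mids = sorted(self.active)
        q = np.array([self.q_of(m) for m in mids])
        S = np.array([self.S[m] for m in mids])
        return _L_from_stats(q, S, self.const)

    # -- move bookkeeping ---------------------------------------------------

    def _move_deltas(self, x: int, B: int):
        """Stat updates for moving node x from its module A to module B."""
        gd, p = self.gd, self.p
        A = int(self.assign[x])
        w_to_A = 0.0
        w_to_B = 0.0
        ee_shift_A = 0.0  # neighbours in A whose edge to x flips to external
        ee_shift_B = 0.0  # neighbours in B whose edge to x flips to internal
        nbrs, wts = gd.neighbors[x], gd.weights[x]
        for k in range(len(nbrs)):
            y = int(nbrs[k])
            w = wts[k]
            my = int(self.assign[y])
            sy = gd.strength[y]
            if my == A:
                w_to_A += w
                ee_shift_A += p[y] * w / sy
            elif my == B:
                w_to_B += w
                ee_shift_B += p[y] * w / sy
        sx = gd.strength[x]
        exit_x_in_A = p[x] * (sx - w_to_A) / sx if sx > 0 else 0.0
        exit_x_in_B = p[x] * (sx - w_to_B) / sx if sx > 0 else 0.0
        newA = (
            self.EE[A] - exit_x_in_A + ee_shift_A,
            self.teleS[A] - self.tele[x],
            self.S[A] - p[x],
            self.n[A] - 1,
        )
        newB = (
            self.EE[B] + exit_x_in_B - ee_shift_B,
            self.teleS[B] + self.tele[x],
            self.S[B] + p[x],
            self.n[B] + 1,
        )
        return A, newA, newB

    def eval_move(self, x: int, B: int) -> float:
        """Codelength change if node x moved to module B (no mutation)."""
        A = int(self.assign[x])
        if A == B:
            return 0.0
        A, (eeA, tsA, SA, nA), (eeB, tsB, SB, nB) = self._move_deltas(x, B)
        qA_old, qB_old = self.q_of(A), self.q_of(B)
        qA_new = self.q_of(A, eeA, tsA, nA) if nA > 0 else 0.0
        qB_new = self.q_of(B, eeB, tsB, nB)
        SA_new = SA if nA > 0 else 0.0
        q_old = self._q_cache
        q_new = q_old - qA_old - qB_old + qA_new + qB_new
        d = _plogp(q_new) - _plogp(q_old)
        d += -2.0 * (_plogp(qA_new) + _plogp(qB_new) - _plogp(qA_old) - _plogp(qB_old))
        d += (
            _plogp(qA_new + SA_new)
            + _plogp(qB_new + SB)
            - _plogp(qA_old + self.S[A])
            - _plogp(qB_old + self.S[B])
        )
        return d

    def apply_move(self, x: int, B: int) -> None:
        A, newA, newB = self._move_deltas(x, B)
        qA_old, qB_old = self.q_of(A), self.q_of(B)
        self.EE[A], self.teleS[A], self.S[A], self.n[A] = newA
        self.EE[B], self.teleS[B], self.S[B], self.n[B] = newB
        self.assign[x] = B
        if B not in self.active:
            self.active.add(B)
            if B in self.freed:
                self.freed.remove(B)
        if self.n[A] == 0:
            self.active.discard(A)
            self.freed.append(A)
            self.EE[A] = self.teleS[A] = self.S[A] = 0.0
        qA_new = self.q_of(A) if self.n[A] > 0 else 0.0
        self._q_cache += -qA_old - qB_old + qA_new + self.q_of(B)

    def refresh_q_cache(self) -> None:
        self._q_cache = float(sum(self.q_of(m) for m in self.active))

    # -- merges -------------------------------------------------------------

    def _cross_flow(self, A: int, B: int) -> float:
        """Exit flow carried by edges between modules A and B (both directions)."""
        gd, p = self.gd, self.p
        membersA = [i for i in range(self.N) if self.assign[i] == A]
        flow = 0.0
        for i in membersA:
            nbrs, wts = gd.neighbors[i], gd.weights[i]
            for k in range(len(nbrs)):
                y = int(nbrs[k])
                if self.assign[y] == B:
                    flow += p[i] * wts[k] / gd.strength[i]
                    flow += p[y] * wts[k] / gd.strength[y]
        return flow

    def eval_merge(self, A: int, B: int) -> float:
        qA, qB = self.q_of(A), self.q_of(B)
        ee = self.EE[A] + self.EE[B] - self._cross_flow(A, B)
        ts = self.teleS[A] + self.teleS[B]
        S = self.S[A] + self.S[B]
        n = self.n[A] + self.n[B]
        qM = self.q_of(A, ee, ts, n)
        q_old = self._q_cache
        q_new = q_old - qA - qB + qM
        d = _plogp(q_new) - _plogp(q_old)
        d += -2.0 * (_plogp(qM) - _plogp(qA) - _plogp(qB))
        d += _plogp(qM + S) - _plogp(qA + self.S[A]) - _plogp(qB + self.S[B])
        return d

    def apply_merge(self, A: int, B: int) -> None:
        """Merge module B into module A."""
        for i in range(self.N):
            if self.assign[i] == B:
                self.assign[i] = A
        ee = self.EE[A]  # recompute A's stats from scratch (B already folded in)
        self.S[A] += self.S[B]
        self.teleS[A] += self.teleS[B]
        self.n[A] += self.n[B]
        gd, p = self.gd, self.p
        new_ee = 0.0
        for i in range(self.N):
            if self.assign[i] == A and gd.strength[i] > 0:
                out_w = gd.weights[i][self.assign[gd.neighbors[i]] != A].sum()
                new_ee += p[i] * out_w / gd.strength[i]
        self.EE[A] = new_ee
        self.EE[B] = self.teleS[B] = self.S[B] = 0.0
        self.n[B] = 0
        self.active.discard(B)
        self.freed.append(B)
        self.refresh_q_cache()


def _greedy_once(gd: _GraphData, p: np.ndarray, tau: float, rng: np.random.Generator,
                 max_sweeps: int):
    state = _SearchState(gd, p, tau)
    state.refresh_q_cache()
    N = gd.N
    while True:
        moved_any = False
        for _ in range(max_sweeps):
            moved = False
            order = rng.permutation(N)
            for x in order:
                x = int(x)
                A = int(state.assign[x])
                cands = sorted({int(state.assign[int(y)]) for y in gd.neighbors[x]} - {A})
                if state.n[A] > 1 and state.freed:
                    cands.append(state.freed[-1])  # split into a fresh module
                best_d, best_B = -_EPS, None
                for B in cands:
                    d = state.eval_move(x, B)
                    if d < best_d:
                        best_d, best_B = d, B
                if best_B is not None:
                    state.apply_move(x, best_B)
                    moved = moved_any = True
            if not moved:
                break
        # merge pass over connected module pairs
        merged = False
        while True:
            pairs = set()
            for i in range(N):
                mi = int(state.assign[i])
                for y in gd.neighbors[i]:
                    mj = int(state.assign[int(y)])
                    if mi != mj:
                        pairs.add((min(mi, mj), max(mi, mj)))
            best_d, best_pair = -_EPS, None
            for A, B in sorted(pairs):
                d = state.eval_merge(A, B)
                if d < best_d:
                    best_d, best_pair = d, (A, B)
            if best_pair is None:
                break
            state.apply_merge(*best_pair)
            merged = moved_any = True
        if not (merged and N > 1):
            if not merged:
                break
    return state.assign.copy(), state.total_L()


def optimize_partition(net, v: VisitDistribution | None = None, seed: int = 0,
                       n_restarts: int = 10, max_sweeps: int = 100,
                       tau: float = 0.15):
    """Minimise the codelength over partitions; returns ``(Partition, CodelengthReport)``.

    Deterministic for a fixed ``seed``; best over ``n_restarts`` randomised
    greedy runs.  The returned codelength never exceeds the one-module
    codelength.
    """
    graph = _as_graph(net)
    if graph.number_of_nodes() < 2:
        raise ValueError("optimize_partition requires >= 2 nodes")
    if v is None:
        v = visit_rates(net, tau)
    gd = _GraphData(graph)
    p = np.array([v.p[n] for n in gd.nodes])
    rng = np.random.default_rng(seed)
    best_assign, best_L = None, math.inf
    for _ in range(max(1, n_restarts)):
        assign, L = _greedy_once(gd, p, v.tau, rng, max_sweeps)
        if L < best_L - _EPS:
            best_assign, best_L = assign, L
    # never worse than the trivial one-module partition
    one_L = _L_from_stats(np.array([0.0]), np.array([1.0]),
                          sum(_plogp(x) for x in p))
    if best_L > one_L + _EPS:
        best_assign = np.zeros(gd.N, dtype=np.int64)
    part = Partition.from_assignment(
        {gd.nodes[i]: int(best_assign[i]) for i in range(gd.N)}
    )
    return part, codelength(graph, part, v)


# ---------------------------------------------------------------------------
# Significance filter
# ---------------------------------------------------------------------------


def rewire_bipartite(net: CTNetwork, rng: np.random.Generator,
                     n_swaps: int | None = None) -> CTNetwork:
    """Degree-preserving null network via double edge swaps.

    Picks two edges (c1,t1), (c2,t2) and rewires to (c1,t2), (c2,t1) when
    that creates no duplicate; component and target degree sequences are
    preserved exactly.
    """
    edges = [list(e) for e in net.edges]
    m = len(edges)
    if m < 2:
        return net
    if n_swaps is None:
        n_swaps = 10 * m
    present = {(c, t) for c, t, _ in net.edges}
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        c1, t1, w1 = edges[i]
        c2, t2, w2 = edges[j]
        if c1 == c2 or t1 == t2:
            continue
        if (c1, t2) in present or (c2, t1) in present:
            continue
        present.discard((c1, t1))
        present.discard((c2, t2))
        present.add((c1, t2))
        present.add((c2, t1))
        edges[i][1], edges[j][1] = t2, t1
    return CTNetwork(net.components, net.targets,
                     tuple((c, t, w) for c, t, w in edges))


def _split_saving(gd: _GraphData, p: np.ndarray, tau: float, member_idx: set) -> float:
    """Bits saved by splitting ``member_idx`` out of the one-module partition."""
    if not member_idx or len(member_idx) == gd.N:
        return 0.0
    const = sum(_plogp(x) for x in p)
    one_L = _L_from_stats(np.array([0.0]), np.array([1.0]), const)
    assign = np.array([1 if i in member_idx else 2 for i in range(gd.N)])
    _, q, S, _ = _module_flow_stats(gd, p, assign, tau)
    return one_L - _L_from_stats(q, S, const)


def module_significance(net: CTNetwork, partition: Partition,
                        v: VisitDistribution | None = None, n_perm: int = 199,
                        seed: int = 0, tau: float = 0.15) -> list:
    """Permutation p-value per module of ``partition``.

    The statistic is the codelength saving of splitting the module out of the
    one-module partition; the null redistributes edges by degree-preserving
    bipartite rewiring.  ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    Modules of size 1 get ``p = 1`` by convention.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    if not isinstance(net, CTNetwork):
        raise TypeError("module_significance requires a CTNetwork")
    if v is None:
        v = visit_rates(net, tau)
    tau = v.tau
    gd = _GraphData(net.to_graph())
    p = np.array([v.p[n] for n in gd.nodes])
    modules = partition.modules()
    observed, testable = {}, {}
    for mid, members in modules.items():
        idx = {gd.index[n] for n in members}
        observed[mid] = _split_saving(gd, p, tau, idx)
        testable[mid] = len(members) > 1 and len(members) < gd.N
        if not testable[mid]:
            logger.info("module %d (size %d) assigned p = 1 by convention",
                        mid, len(members))
    counts = {mid: 0 for mid in modules}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        null_net = rewire_bipartite(net, rng)
        ngd = _GraphData(null_net.to_graph())
        if tau == 0.0:
            np_rates = _degree_rates(ngd)  # stationary even if rewiring disconnects
        else:
            vb = visit_rates(null_net, tau)
            np_rates = np.array([vb.p[n] for n in ngd.nodes])
        for mid, members in modules.items():
            if not testable[mid]:
                continue
            idx = {ngd.index[n] for n in members}
            if _split_saving(ngd, np_rates, tau, idx) >= observed[mid] - 1e-12:
                counts[mid] += 1
    out = []
    for mid, members in sorted(modules.items()):
        if testable[mid]:
            pval = (1 + counts[mid]) / (1 + n_perm)
        else:
            pval = 1.0
        out.append(SDFM(module_id=mid, members=frozenset(members),
                        p_value=pval, saving=observed[mid]))
    return out


def select_sdfms(modules, alpha: float = 0.05) -> list:
    """Keep modules with ``p < alpha``, ordered by codelength saving (descending)."""
    kept = [m for m in modules if m.p_value < alpha]
    return sorted(kept, key=lambda m: (-m.saving, m.module_id))
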