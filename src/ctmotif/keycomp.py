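"""Component ranking inside response motifs by information gain x target influence.

Components are sorted by descending target count (ties broken
lexicographically by id, because the gain depends on the order).  The
information gain of the n-th component is the fraction of the total motif
target set newly covered given all higher-ranked components:

    dZ_n = |(TC_n \\ union_{i<n} TC_i) ∩ T_all| / |T_all|

Target counts and gains are then min-max normalised and multiplied into the
Q score; components with Q strictly above the threshold form the key group.
A degenerate min-max (all values equal) normalises to 1.0 so a constant
dimension does not annihilate Q.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import CTNetwork, comp_node, target_node


@dataclass(frozen=True)
class ComponentScore:
    component_id: str
    T: int  # target count within motif scope
    dZ: float  # information gain
    T_nor: float
    dZ_nor: float
    Q: float

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not 0.0 <= self.dZ <= 1.0:
            raise ValueError(f"dZ {self.dZ} outside [0, 1]")
        for fname in ("T_nor", "dZ_nor", "Q"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname} {v} outside [0, 1]")


def rank_by_target_count(net: CTNetwork, frm_node_sets=None):
    """Ordered ``[(component_id, target_set), ...]`` restricted to motif scope.

    ``frm_node_sets`` is an iterable of prefixed-node-label sets (one per
    motif); ``None`` means the whole network.  Sort: target count descending,
    then id ascending.
    """
    if frm_node_sets is not None:
        scope: set = set()
        for members in frm_node_sets:
            scope |= set(members)
        net = net.restrict(scope)
    mapping = net.component_targets()
    if not mapping:
        raise ValueError("motif-restricted network has no components")
    return sorted(mapping.items(), key=lambda kv: (-len(kv[1]), kv[0]))


def information_gain(ordered_target_sets, t_all) -> list:
    """Per-component information gain for an ordered list of target sets."""
    t_all = set(t_all)
    ta = len(t_all)
    if ta == 0:
        raise ValueError("T_all must be non-empty")
    gains = []
    covered: set = set()
    for tc in ordered_target_sets:
        tc = set(tc)
        gains.append(len((tc - covered) & t_all) / ta)
        covered |= tc
    return gains


def _minmax(values) -> list:
    lo, hi = min(values), max(values)
    if hi == lo:
        # degenerate dimension: defined as 1.0 so it does not zero out Q
        return [1.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def q_scores(component_ids, T, dZ) -> list:
    """Min-max normalise target counts and gains, multiply into Q scores."""
    component_ids, T, dZ = list(component_ids), list(T), list(dZ)
    if not len(component_ids) == len(T) == len(dZ):
        raise ValueError("misaligned score vectors")
    if not component_ids:
        return []
    t_nor = _minmax(T)
    z_nor = _minmax(dZ)
    return [
        ComponentScore(component_id=str(cid), T=int(t), dZ=float(z),
                       T_nor=float(tn), dZ_nor=float(zn), Q=float(tn * zn))
        for cid, t, z, tn, zn in zip(component_ids, T, dZ, t_nor, z_nor)
    ]


def select_key_components(scores, q_threshold: float = 0.01) -> list:
    """Key component group: Q strictly above threshold, Q descending."""
    kept = [s for s in scores if s.Q > q_threshold]
    return sorted(kept, key=lambda s: (-s.Q, s.component_id))


def score_components(net: CTNetwork, frm_node_sets=None) -> list:
    """Full ranking pipeline: restrict, order, gain, normalise, score."""
    ordered = rank_by_target_count(net, frm_node_sets)
    t_all: set = set()
    for _, targets in ordered:
        t_all |= targets
    gains = information_gain([t for _, t in ordered], t_all)
    return q_scores([c for c, _ in ordered], [len(t) for _, t in ordered], gains)
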