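"""Synthetic inputs with known ground truth for every pipeline stage.

Generators are deterministic for a fixed seed and cover: bipartite networks
with planted modules, disease-gene tables enriched in chosen modules,
gene-set collections built around planted module target sets (plus decoys
drawn from a background gene pool), and compound tables with an exact
drug-like fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .adme import RULE_IDS, ScreenConfig, evaluate_compound
from .core import (
    CompoundRecord,
    CTNetwork,
    DiseaseGeneTable,
    GeneSetCollection,
    comp_node,
    target_node,
)
from .mapeq import Partition


@dataclass(frozen=True)
class PlantedNetworkSpec:
    n_modules: int = 3
    components_per_module: int = 5
    targets_per_module: int = 10
    p_in: float = 0.6
    p_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_modules, self.components_per_module, self.targets_per_module) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")


def generate_planted_network(spec: PlantedNetworkSpec):
    """Planted-module bipartite network; returns ``(CTNetwork, Partition)``.

    Component-target pairs connect with ``p_in`` inside a module and
    ``p_out`` across modules.  Nodes left isolated are re-wired with one
    random within-module edge, so the ground truth stays exact.
    """
    rng = np.random.default_rng(spec.seed)
    comps, targs, module_of = [], [], {}
    for m in range(1, spec.n_modules + 1):
        for j in range(spec.components_per_module):
            cid = f"c{m}_{j}"
            comps.append(cid)
            module_of[comp_node(cid)] = m
        for j in range(spec.targets_per_module):
            tid = f"g{m}_{j}"
            targs.append(tid)
            module_of[target_node(tid)] = m
    edges = set()
    for c in comps:
        mc = module_of[comp_node(c)]
        for t in targs:
            prob = spec.p_in if module_of[target_node(t)] == mc else spec.p_out
            if rng.random() < prob:
                edges.add((c, t))
    # re-wire isolated nodes with one within-module edge
    degree = {n: 0 for n in comps + targs}
    for c, t in edges:
        degree[c] += 1
        degree[t] += 1
    for c in comps:
        if degree[c] == 0:
            m = module_of[comp_node(c)]
            pool = [t for t in targs if module_of[target_node(t)] == m]
            t = pool[rng.integers(0, len(pool))]
            edges.add((c, t))
            degree[c] += 1
            degree[t] += 1
    for t in targs:
        if degree[t] == 0:
            m = module_of[target_node(t)]
            pool = [c for c in comps if module_of[comp_node(c)] == m]
            c = pool[rng.integers(0, len(pool))]
            edges.add((c, t))
            degree[t] += 1
    if not edges:
        raise ValueError("spec generated an empty network")
    net = CTNetwork.from_edges(sorted(edges))
    truth = Partition(dict(module_of), spec.n_modules)
    return net, truth


def generate_disease_table(net: CTNetwork, truth: Partition, enriched_module_ids=(),
                           effect_size: float = 10.0, seed: int = 0,
                           log_mean: float = 1.0, log_sigma: float = 0.5,
                           dispersion: float = 2.0) -> DiseaseGeneTable:
    """Disease-gene table whose relevance is shifted by ``effect_size`` for
    targets in the enriched modules.

    Relevance is log-normal; evidence counts are negative-binomial with mean
    tied to relevance (over-dispersed, positively correlated).
    """
    enriched = set(enriched_module_ids)
    known = set(range(1, truth.m + 1))
    unknown = enriched - known
    if unknown:
        raise ValueError(f"unknown module id(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for t in sorted(net.targets):
        module = truth.assignment.get(target_node(t))
        base = float(rng.lognormal(mean=log_mean, sigma=log_sigma))
        rel = base + (effect_size if module in enriched else 0.0)
        mean_ev = 1.0 + 0.5 * rel
        p_nb = dispersion / (dispersion + mean_ev)
        ev = float(rng.negative_binomial(dispersion, p_nb))
        rows.append((t, rel, ev))
    return DiseaseGeneTable(tuple(rows))


def generate_genesets(net: CTNetwork, truth: Partition, n_pathways: int = 6,
                      overlap_frac: float = 0.8, decoy_frac: float = 0.5,
                      seed: int = 0, n_background: int = 100) -> GeneSetCollection:
    """Gene sets built around planted module target sets plus random decoys.

    Each module pathway takes ``overlap_frac`` of the module's targets and
    fills the remainder from a disjoint background gene pool; decoys are
    drawn from the background pool alone.  ``overlap_frac = 1`` reproduces
    module target sets exactly.
    """
    if not 0.0 < overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in (0, 1]")
    if not 0.0 <= decoy_frac <= 1.0:
        raise ValueError("decoy_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    background = [f"bg{i:04d}" for i in range(n_background)]
    module_targets = {m: [] for m in range(1, truth.m + 1)}
    for t in sorted(net.targets):
        m = truth.assignment.get(target_node(t))
        if m is not None:
            module_targets[m].append(t)
    n_decoy = int(round(n_pathways * decoy_frac))
    n_module = n_pathways - n_decoy
    typical = max(2, int(np.median([len(v) for v in module_targets.values()]) or 2))
    sets = {}
    mods = sorted(m for m in module_targets if module_targets[m])
    for i in range(n_module):
        m = mods[i % len(mods)]
        pool = module_targets[m]
        n_take = int(round(overlap_frac * len(pool)))
        take = sorted(rng.choice(pool, size=n_take, replace=False))
        fill = []
        n_fill = len(pool) - n_take
        if n_fill > 0:
            fill = sorted(rng.choice(background, size=n_fill, replace=False))
        sets[f"PW{i:03d}"] = (f"module {m} pathway {i}", frozenset(take + fill))
    for i in range(n_module, n_pathways):
        size = min(typical, len(background))
        take = sorted(rng.choice(background, size=size, replace=False))
        sets[f"PW{i:03d}"] = (f"decoy pathway {i}", frozenset(take))
    return GeneSetCollection(sets)


_DRUGLIKE_SAMPLERS = {
    "mw": lambda rng: float(rng.uniform(200.0, 480.0)),
    "hbd": lambda rng: int(rng.integers(0, 6)),
    "hba": lambda rng: int(rng.integers(0, 11)),
    "logp": lambda rng: float(rng.uniform(-1.5, 4.5)),
    "rotatable_bonds": lambda rng: int(rng.integers(0, 11)),
    "bioavailability": lambda rng: float(rng.uniform(0.3, 0.55)),
    "gi_absorption": lambda rng: "high",
}

_VIOLATORS = {
    "mw": lambda rng: float(rng.uniform(550.0, 900.0)),
    "hbd": lambda rng: int(rng.integers(6, 12)),
    "hba": lambda rng: int(rng.integers(11, 20)),
    "logp": lambda rng: float(rng.choice([rng.uniform(-6.0, -2.5), rng.uniform(5.5, 9.0)])),
    "rotatable_bonds": lambda rng: int(rng.integers(11, 20)),
    "bioavailability": lambda rng: float(rng.choice([rng.uniform(0.0, 0.25), rng.uniform(0.6, 1.0)])),
    "gi_absorption": lambda rng: "low",
}


def generate_compound_table(n: int, druglike_frac: float, seed: int = 0, ids=None):
    """Compound table with exactly ``round(n * druglike_frac)`` passing records.

    Returns ``(records, planted_violations)`` where the dict maps each
    failing compound id to the rule(s) deliberately violated.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= druglike_frac <= 1.0:
        raise ValueError("druglike_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if ids is None:
        ids = [f"cpd{i:04d}" for i in range(n)]
    ids = list(ids)
    if len(ids) != n:
        raise ValueError("ids length must equal n")
    n_pass = int(round(n * druglike_frac))
    pass_flags = np.zeros(n, dtype=bool)
    pass_flags[rng.permutation(n)[:n_pass]] = True
    records, violations = [], {}
    cfg = ScreenConfig()
    for i, cid in enumerate(ids):
        fields = {k: sampler(rng) for k, sampler in _DRUGLIKE_SAMPLERS.items()}
        if not pass_flags[i]:
            n_break = int(rng.integers(1, 3))
            broken = sorted(rng.choice(list(RULE_IDS), size=n_break, replace=False))
            for rule in broken:
                fields[rule] = _VIOLATORS[rule](rng)
            violations[cid] = broken
        rec = CompoundRecord(compound_id=cid, name=f"compound {cid}", **fields)
        ok, _ = evaluate_compound(rec, cfg)
        assert ok == bool(pass_flags[i]), "construction must match the screen"
        records.append(rec)
    return records, violations


PRESETS = {
    "small": dict(n_modules=3, components_per_module=5, targets_per_module=10,
                  p_in=0.6, p_out=0.05, n_pathways=6, decoy_frac=0.5,
                  overlap_frac=0.9, n_background=120, enriched_modules=(1, 2),
                  effect_size=15.0, druglike_frac=0.8),
    "medium": dict(n_modules=5, components_per_module=8, targets_per_module=15,
                   p_in=0.5, p_out=0.03, n_pathways=12, decoy_frac=0.5,
                   overlap_frac=0.9, n_background=200, enriched_modules=(1, 2, 3),
                   effect_size=15.0, druglike_frac=0.8),
}


def generate_bundle(preset: str = "small", seed: int = 0) -> dict:
    """End-to-end fixture bundle exercising every pipeline stage."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    spec = PlantedNetworkSpec(
        n_modules=cfg["n_modules"],
        components_per_module=cfg["components_per_module"],
        targets_per_module=cfg["targets_per_module"],
        p_in=cfg["p_in"],
        p_out=cfg["p_out"],
        seed=seed,
    )
    net, truth = generate_planted_network(spec)
    disease = generate_disease_table(
        net, truth, enriched_module_ids=cfg["enriched_modules"],
        effect_size=cfg["effect_size"], seed=seed + 1,
    )
    genesets = generate_genesets(
        net, truth, n_pathways=cfg["n_pathways"], overlap_frac=cfg["overlap_frac"],
        decoy_frac=cfg["decoy_frac"], seed=seed + 2,
        n_background=cfg["n_background"],
    )
    comp_ids = sorted(net.components)
    compounds, violations = generate_compound_table(
        n=len(comp_ids), druglike_frac=cfg["druglike_frac"], seed=seed + 3,
        ids=comp_ids,
    )
    return {
        "spec": spec,
        "network": net,
        "truth": truth,
        "disease": disease,
        "genesets": genesets,
        "compounds": compounds,
        "planted_violations": violations,
        "enriched_modules": list(cfg["enriched_modules"]),
    }
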