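"""Domain types and readers/writers for every format the pipeline touches.

The central object is :class:`CTNetwork`, a strictly bipartite graph linking
components (compounds) to targets (genes/proteins).  Component and target id
namespaces are kept disjoint internally by prefixing node labels with ``C:``
and ``T:`` — compound names and gene symbols can collide textually.

All tabular formats are plain TSV; gene sets use the standard GMT layout
(set id, set name, then member genes, tab-separated).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

COMP_PREFIX = "C:"
TARGET_PREFIX = "T:"


class BipartitenessError(ValueError):
    """An edge joins two nodes on the same side of the bipartition."""


def comp_node(component_id: str) -> str:
    """Internal (prefixed) label of a component node."""
    return COMP_PREFIX + str(component_id)


def target_node(target_id: str) -> str:
    """Internal (prefixed) label of a target node."""
    return TARGET_PREFIX + str(target_id)


def strip_prefix(node: str) -> str:
    """Remove the ``C:``/``T:`` namespace prefix from an internal label."""
    if node.startswith(COMP_PREFIX) or node.startswith(TARGET_PREFIX):
        return node[2:]
    return node


def is_component_node(node: str) -> bool:
    return node.startswith(COMP_PREFIX)


def is_target_node(node: str) -> bool:
    return node.startswith(TARGET_PREFIX)


# ---------------------------------------------------------------------------
# Compound records
# ---------------------------------------------------------------------------

_GI_VALUES = {"high", "low"}


@dataclass(frozen=True)
class CompoundRecord:
    """Physicochemical descriptors of one compound.

    Descriptor fields may be ``None`` (missing): downstream screening raises
    a named error rather than silently failing.  When present, descriptors
    must satisfy the obvious sanity ranges.
    """

    compound_id: str
    name: str
    mw: float | None = None
    hbd: int | None = None
    hba: int | None = None
    logp: float | None = None
    rotatable_bonds: int | None = None
    bioavailability: float | None = None
    gi_absorption: str | None = None
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.mw is not None and not self.mw > 0:
            raise ValueError(f"{self.compound_id}: mw must be > 0, got {self.mw}")
        for fname in ("hbd", "hba", "rotatable_bonds"):
            v = getattr(self, fname)
            if v is not None and v < 0:
                raise ValueError(f"{self.compound_id}: {fname} must be >= 0, got {v}")
        if self.bioavailability is not None and not 0.0 <= self.bioavailability <= 1.0:
            raise ValueError(
                f"{self.compound_id}: bioavailability must be in [0, 1], "
                f"got {self.bioavailability}"
            )
        if self.gi_absorption is not None and self.gi_absorption not in _GI_VALUES:
            raise ValueError(
                f"{self.compound_id}: gi_absorption must be one of {sorted(_GI_VALUES)}"
            )


_COMPOUND_COLUMNS = [
    "compound_id",
    "name",
    "mw",
    "hbd",
    "hba",
    "logp",
    "rotatable_bonds",
    "bioavailability",
    "gi_absorption",
]


def load_compound_table(path) -> list[CompoundRecord]:
    """Read a compound property TSV into a list of :class:`CompoundRecord`."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "name": str})
    missing = [c for c in _COMPOUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"compound table {path} lacks columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CompoundRecord(
                compound_id=str(d["compound_id"]),
                name=str(d["name"]),
                mw=_opt_float(d["mw"]),
                hbd=_opt_int(d["hbd"]),
                hba=_opt_int(d["hba"]),
                logp=_opt_float(d["logp"]),
                rotatable_bonds=_opt_int(d["rotatable_bonds"]),
                bioavailability=_opt_float(d["bioavailability"]),
                gi_absorption=None if _is_na(d.get("gi_absorption")) else str(d["gi_absorption"]),
                smiles=None if _is_na(d.get("smiles")) else str(d["smiles"]),
            )
        )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=_COMPOUND_COLUMNS + ["smiles"])
    df.to_csv(path, sep="\t", index=False)


def _is_na(v) -> bool:
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


def _opt_float(v) -> float | None:
    return None if _is_na(v) else float(v)


def _opt_int(v) -> int | None:
    return None if _is_na(v) else int(v)


# ---------------------------------------------------------------------------
# Component-target network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CTNetwork:
    """Strictly bipartite component-target network.

    ``edges`` holds ``(component_id, target_id, weight)`` triples using the
    raw (unprefixed) ids; weights default to 1 and must be positive.
    """

    components: frozenset
    targets: frozenset
    edges: tuple

    def __post_init__(self) -> None:
        overlap = set(self.components) & set(self.targets)
        if overlap:
            raise BipartitenessError(
                f"ids appear on both sides of the bipartition: {sorted(overlap)[:5]}"
            )
        seen = set()
        for c, t, w in self.edges:
            if c not in self.components:
                raise BipartitenessError(f"edge ({c}, {t}): {c!r} is not a declared component")
            if t not in self.targets:
                raise BipartitenessError(f"edge ({c}, {t}): {t!r} is not a declared target")
            if (c, t) in seen:
                raise ValueError(f"duplicate edge ({c}, {t})")
            if not w > 0:
                raise ValueError(f"edge ({c}, {t}): weight must be positive, got {w}")
            seen.add((c, t))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "CTNetwork":
        """Build a network from (component, target[, weight]) tuples.

        Duplicate edges are collapsed (first weight wins) with a warning.
        """
        comps, targs, out, seen = set(), set(), [], set()
        n_dup = 0
        for e in edges:
            c, t = str(e[0]), str(e[1])
            w = float(e[2]) if len(e) > 2 and e[2] is not None else 1.0
            if (c, t) in seen:
                n_dup += 1
                continue
            seen.add((c, t))
            comps.add(c)
            targs.add(t)
            out.append((c, t, w))
        if n_dup:
            warnings.warn(f"collapsed {n_dup} duplicate edge(s)", stacklevel=2)
        return cls(frozenset(comps), frozenset(targs), tuple(out))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        """Undirected graph with namespaced node labels."""
        g = nx.Graph()
        g.add_nodes_from(comp_node(c) for c in self.components)
        g.add_nodes_from(target_node(t) for t in self.targets)
        g.add_weighted_edges_from(
            (comp_node(c), target_node(t), w) for c, t, w in self.edges
        )
        return g

    def component_targets(self) -> dict:
        """Mapping component id -> set of its target ids."""
        out: dict = {c: set() for c in self.components}
        for c, t, _ in self.edges:
            out[c].add(t)
        return out

    def restrict(self, nodes: Iterable[str]) -> "CTNetwork":
        """Sub-network induced by prefixed node labels ``nodes``."""
        keep = set(nodes)
        comps = {c for c in self.components if comp_node(c) in keep}
        targs = {t for t in self.targets if target_node(t) in keep}
        edges = tuple((c, t, w) for c, t, w in self.edges if c in comps and t in targs)
        return CTNetwork(frozenset(comps), frozenset(targs), edges)


def load_ct_network(path) -> CTNetwork:
    """Load an edge-list TSV with ``component``/``target`` (optional ``weight``) columns.

    Raises :class:`BipartitenessError` if any id occurs in both the component
    and target columns, naming the first offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "component" not in cols or "target" not in cols:
        raise ValueError(
            f"{path}: header must declare 'component' and 'target' columns, "
            f"found {list(df.columns)}"
        )
    ccol, tcol = cols["component"], cols["target"]
    wcol = cols.get("weight")
    comp_ids = set(df[ccol])
    conflict = df[tcol].isin(comp_ids)
    if conflict.any():
        i = int(conflict.idxmax())
        raise BipartitenessError(
            f"{path} row {i + 2}: id {df[tcol].iloc[i]!r} appears in both the "
            "component and target columns"
        )
    edges = []
    for i in range(len(df)):
        w = 1.0
        if wcol is not None and not _is_na(df[wcol].iloc[i]):
            w = float(df[wcol].iloc[i])
        edges.append((df[ccol].iloc[i], df[tcol].iloc[i], w))
    return CTNetwork.from_edges(edges)


def write_ct_network(net: CTNetwork, path) -> None:
    """Write an edge-list TSV that :func:`load_ct_network` reads back."""
    rows = sorted(net.edges)
    df = pd.DataFrame(rows, columns=["component", "target", "weight"])
    df.to_csv(path, sep="\t", index=False)


def write_sif(net: CTNetwork, path) -> None:
    """Cytoscape SIF export: one ``component<TAB>interacts<TAB>target`` line per edge."""
    with open(path, "w") as fh:
        for c, t, _ in sorted(net.edges):
            fh.write(f"{c}\tinteracts\t{t}\n")


def degree_summary(net: CTNetwork, top_k: int = 3) -> dict:
    """Mean degree per side plus the ``top_k`` highest-degree nodes per side."""
    if not net.components or not net.targets or net.n_edges == 0:
        raise ValueError("degree_summary requires a non-empty network")
    cdeg: dict = {c: 0 for c in net.components}
    tdeg: dict = {t: 0 for t in net.targets}
    for c, t, _ in net.edges:
        cdeg[c] += 1
        tdeg[t] += 1
    top = lambda d: sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return {
        "n_components": len(net.components),
        "n_targets": len(net.targets),
        "n_edges": net.n_edges,
        "mean_component_degree": net.n_edges / len(net.components),
        "mean_target_degree": net.n_edges / len(net.targets),
        "top_components": top(cdeg),
        "top_targets": top(tdeg),
    }


# ---------------------------------------------------------------------------
# Disease-gene table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseGeneTable:
    """Per-gene disease annotations: relevance score and evidence count."""

    rows: tuple  # of (gene, relevance_score, n_evidence)

    def __post_init__(self) -> None:
        genes = [g for g, _, _ in self.rows]
        if len(genes) != len(set(genes)):
            raise ValueError("disease table: one row per gene required")
        for g, r, e in self.rows:
            if not (math.isfinite(r) and math.isfinite(e)) or r < 0 or e < 0:
                raise ValueError(f"disease table: bad scores for {g!r}: ({r}, {e})")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def genes(self) -> set:
        return {g for g, _, _ in self.rows}

    def relevance(self) -> dict:
        return {g: r for g, r, _ in self.rows}

    def evidence(self) -> dict:
        return {g: e for g, _, e in self.rows}

    def mean_relevance(self) -> float:
        return sum(r for _, r, _ in self.rows) / len(self.rows)

    def mean_evidence(self) -> float:
        return sum(e for _, _, e in self.rows) / len(self.rows)


def load_disease_table(path) -> DiseaseGeneTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "relevance_score", "n_evidence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rows = tuple(
        (str(g), float(r), float(e))
        for g, r, e in zip(df["gene"], df["relevance_score"], df["n_evidence"])
    )
    return DiseaseGeneTable(rows)


def write_disease_table(table: DiseaseGeneTable, path) -> None:
    df = pd.DataFrame(list(table.rows), columns=["gene", "relevance_score", "n_evidence"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene-set collection (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping pathway id -> (pathway name, frozen gene set)."""

    sets: Mapping

    def __post_init__(self) -> None:
        for pid, (name, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes_of(self, pathway_id: str) -> frozenset:
        return self.sets[pathway_id][1]

    def name_of(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]

    def all_genes(self) -> set:
        out: set = set()
        for _, (_, genes) in self.sets.items():
            out |= genes
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneSetCollection":
        return cls({str(k): (str(v[0]), frozenset(map(str, v[1]))) for k, v in d.items()})


def load_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: GMT rows need >= 3 fields")
            pid, name, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if pid in sets:
                raise ValueError(f"{path} line {lineno}: duplicate pathway id {pid!r}")
            sets[pid] = (name, frozenset(genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(collection.sets):
            name, genes = collection.sets[pid]
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------


def to_jsonable(obj):
    """Recursively convert dataclasses/sets/tuples into JSON-serialisable data."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(to_jsonable(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def dump_json(obj, path, **meta) -> None:
    """Write ``obj`` as JSON with an embedded provenance block."""
    payload = to_jsonable(obj)
    if meta:
        if not isinstance(payload, dict):
            payload = {"result": payload}
        payload["provenance"] = to_jsonable(meta)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
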