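"""Hypergeometric over-representation analysis and motif validation metrics.

``enrich`` tests each gene set for over-representation of a query gene list
within a universe (default: all collection genes plus the query) using the
exact upper hypergeometric tail, with Benjamini-Hochberg step-up adjustment
across tested sets.  Validation metrics compare motif gene sets against the
full network and a disease-gene table: pathway coverage, reference-pathway
proportion, and relevance/evidence summaries against "high-reliable" gene
sets (genes strictly above the table-wide mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DiseaseGeneTable, GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int  # overlap count
    K: int  # pathway size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(f"{self.pathway_id}: inconsistent counts")
        if not (0 <= self.p_raw <= 1 and 0 <= self.p_adj <= 1):
            raise ValueError(f"{self.pathway_id}: p-values outside [0, 1]")
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError(f"{self.pathway_id}: adjusted p below raw p")


@dataclass(frozen=True)
class ValidationReport:
    mean_relevance: float
    mean_evidence: float
    relevance_threshold: float  # table-wide mean relevance
    evidence_threshold: float  # table-wide mean evidence
    n_annotated: int
    p_vs_relevance_set: float | None = None
    p_vs_evidence_set: float | None = None
    pathway_coverage: float | None = None
    reference_pathway_proportion: float | None = None

    def __post_init__(self) -> None:
        for prop in (self.pathway_coverage, self.reference_pathway_proportion):
            if prop is not None and not 0.0 <= prop <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"inconsistent counts: k={k} > min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def enrich(query_genes, collection: GeneSetCollection, universe=None) -> list:
    """One-sided over-representation test per pathway with k >= 1.

    The universe defaults to all collection genes union the query.  Query
    genes outside an explicit universe are dropped with a warning.  Results
    are sorted by adjusted then raw p-value.
    """
    query = {str(g) for g in query_genes}
    if universe is None:
        universe = collection.all_genes() | query
    else:
        universe = {str(g) for g in universe}
        if not universe:
            raise ValueError("empty universe")
        outside = query - universe
        if outside:
            warnings.warn(
                f"dropping {len(outside)} query gene(s) outside the universe",
                stacklevel=2,
            )
            query &= universe
    if not universe:
        raise ValueError("empty universe")
    if not query:
        return []
    N = len(universe)
    n = len(query)
    rows = []
    for pid, (name, genes) in sorted(collection):
        genes_u = genes & universe
        k = len(query & genes_u)
        if k < 1:
            continue
        rows.append((pid, name, k, len(genes_u), hypergeom_p(k, len(genes_u), n, N)))
    if not rows:
        return []
    adj = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(pathway_id=pid, pathway_name=name, k=k, K=K, n=n, N=N,
                         p_raw=p, p_adj=float(a))
        for (pid, name, k, K, p), a in zip(rows, adj)
    ]
    return sorted(results, key=lambda r: (r.p_adj, r.p_raw, r.pathway_id))


def results_table(results) -> pd.DataFrame:
    cols = ["pathway_id", "pathway_name", "k", "K", "n", "N", "p_raw", "p_adj"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)


def filter_pathways(results, min_count: int = 12, exclusion_terms=()) -> list:
    """Keep results with overlap strictly above ``min_count`` whose name
    matches no exclusion term (case-insensitive substring)."""
    terms = [t.lower() for t in exclusion_terms]
    kept = []
    for r in results:
        if r.k <= min_count:
            continue
        name = r.pathway_name.lower()
        if any(t in name for t in terms):
            continue
        kept.append(r)
    return kept


def _significant_ids(genes, collection, universe, alpha) -> set:
    return {r.pathway_id for r in enrich(genes, collection, universe)
            if r.p_adj < alpha}


def pathway_coverage(frm_genes, ct_genes, collection: GeneSetCollection,
                     universe=None, alpha: float = 0.05) -> float:
    """Fraction of the full network's significant pathways recovered by the
    motif gene set (significance at BH-adjusted ``alpha``)."""
    frm_genes, ct_genes = set(frm_genes), set(ct_genes)
    if not frm_genes or not ct_genes:
        raise ValueError("both gene sets must be non-empty")
    sig_ct = _significant_ids(ct_genes, collection, universe, alpha)
    if not sig_ct:
        raise ValueError("the full network yields no significant pathways; "
                         "coverage is undefined")
    sig_frm = _significant_ids(frm_genes, collection, universe, alpha)
    return len(sig_frm & sig_ct) / len(sig_ct)


def reference_pathway_proportion(frm_genes, target_genes, disease_genes,
                                 collection: GeneSetCollection, universe=None,
                                 alpha: float = 0.05) -> float:
    """Proportion of reference pathways (significant for both the target and
    the disease gene sets) also significant for the motif gene set."""
    reference = (
        _significant_ids(set(target_genes), collection, universe, alpha)
        & _significant_ids(set(disease_genes), collection, universe, alpha)
    )
    if not reference:
        raise ValueError("empty reference pathway set")
    sig_frm = _significant_ids(set(frm_genes), collection, universe, alpha)
    return len(sig_frm & reference) / len(reference)


def high_reliable_sets(disease: DiseaseGeneTable):
    """Genes strictly above the table-wide mean relevance / evidence.

    Returns ``(set_by_relevance, set_by_evidence, thresholds)`` where
    ``thresholds`` is ``{"relevance": mean, "evidence": mean}``.
    """
    if len(disease) == 0:
        raise ValueError("empty disease table")
    mean_rel = disease.mean_relevance()
    mean_ev = disease.mean_evidence()
    by_rel = {g for g, r, _ in disease.rows if r > mean_rel}
    by_ev = {g for g, _, e in disease.rows if e > mean_ev}
    return by_rel, by_ev, {"relevance": mean_rel, "evidence": mean_ev}


def frm_disease_summary(frm_genes, disease: DiseaseGeneTable,
                        high_sets=None) -> ValidationReport:
    """Relevance/evidence means of annotated motif genes plus two-sided
    rank-sum comparisons against the high-reliable sets."""
    frm_genes = set(frm_genes)
    relevance = disease.relevance()
    evidence = disease.evidence()
    annotated = sorted(frm_genes & disease.genes)
    if not annotated:
        raise ValueError("no motif genes are annotated in the disease table")
    if high_sets is None:
        high_sets = high_reliable_sets(disease)
    by_rel, by_ev, thresholds = high_sets
    rel_vals = [relevance[g] for g in annotated]
    ev_vals = [evidence[g] for g in annotated]

    def _ranksum(sample, ref_genes, table):
        ref = [table[g] for g in sorted(ref_genes)]
        if not ref or not sample:
            return None
        return float(stats.ranksums(sample, ref).pvalue)

    return ValidationReport(
        mean_relevance=float(np.mean(rel_vals)),
        mean_evidence=float(np.mean(ev_vals)),
        relevance_threshold=thresholds["relevance"],
        evidence_threshold=thresholds["evidence"],
        n_annotated=len(annotated),
        p_vs_relevance_set=_ranksum(rel_vals, by_rel, relevance),
        p_vs_evidence_set=_ranksum(ev_vals, by_ev, evidence),
    )
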