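"""Hypergeometric pathway over-representation with a -ln(p) score.

Given a query gene list (e.g. treatment-related mutated genes), a
pathway gene set and a background universe, the over-representation
p-value is the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

with N the universe size, K the pathway size within the universe, n the
query size and k the observed overlap.  The enrichment score is -ln(p),
the convention used by gene-set enrichment suites such as Partek
(a score of 3.0 corresponds to p = 0.05).

The background universe is a modelling choice: by default the caller
passes the set of all genes carrying at least one annotated variant in
the cohort, but any fixed catalog universe works.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import EnrichmentResult, GeneSet


def enrich(
    query_genes: Iterable[str],
    gene_set: GeneSet,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric upper-tail over-representation of one gene set."""
    query = frozenset(query_genes)
    uni = frozenset(universe)
    if not uni:
        raise ValueError("universe is empty")
    if not query:
        raise ValueError("query gene list is empty")
    if not query <= uni:
        missing = sorted(query - uni)[:5]
        raise ValueError(f"query genes not in universe: {missing}")
    members = gene_set.members & uni
    if not members:
        raise ValueError(
            f"gene set {gene_set.name!r} shares no genes with the universe"
        )
    overlap = query & members
    k, K, n, N = len(overlap), len(members), len(query), len(uni)
    # upper tail P(X >= k); sf(k-1) is exact for the discrete distribution
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 5e-324), 1.0)  # guard: p in (0, 1] so -ln(p) is finite
    return EnrichmentResult(
        pathway=gene_set.name,
        overlap_genes=frozenset(overlap),
        k=k,
        K=K,
        n=n,
        N=N,
        p_value=p,
        significant=p <= alpha,
    )


def enrich_all(
    query_genes: Iterable[str],
    catalog: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Test every catalog set; sort by descending score, ties by name.

    ``fdr=True`` applies Benjamini-Hochberg and marks significance on
    the adjusted p-values (raw p-values are still reported).
    """
    query = frozenset(query_genes)
    uni = frozenset(universe)
    results = [
        enrich(query, gs, uni, alpha=alpha)
        for gs in catalog
        if gs.members & uni
    ]
    if fdr and results:
        rejected, _, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        results = [
            EnrichmentResult(
                pathway=r.pathway,
                overlap_genes=r.overlap_genes,
                k=r.k,
                K=r.K,
                n=r.n,
                N=r.N,
                p_value=r.p_value,
                significant=bool(sig),
            )
            for r, sig in zip(results, rejected)
        ]
    return sorted(results, key=lambda r: (-r.score, r.pathway))


def emt_second_pass(
    per_patient_genes: Mapping[str, Iterable[str]],
    emt_catalog: Sequence[GeneSet],
) -> dict[str, dict[str, frozenset[str]]]:
    """Overlap of every EMT-tagged pathway with each patient's gene list.

    This second pass records overlaps regardless of enrichment
    significance — a pathway with a single mutated gene still appears.
    Returns {pathway: {patient: overlap genes}} with empty overlaps
    omitted.
    """
    out: dict[str, dict[str, frozenset[str]]] = {}
    for gs in emt_catalog:
        per_patient: dict[str, frozenset[str]] = {}
        for patient, genes in per_patient_genes.items():
            overlap = frozenset(genes) & gs.members
            if overlap:
                per_patient[patient] = overlap
        if per_patient:
            out[gs.name] = per_patient
    return out


def shared_pathways(
    per_patient_results: Mapping[str, Sequence[EnrichmentResult]],
    mode: str = "significant",
) -> set[str]:
    """Pathways common to every patient.

    ``mode='significant'`` intersects each patient's significant
    pathways; ``mode='overlap'`` intersects pathways with any overlap
    (k >= 1).  Requires at least two patients.
    """
    if len(per_patient_results) < 2:
        raise ValueError("shared_pathways requires at least two patients")
    if mode == "significant":
        keep = lambda r: r.significant  # noqa: E731
    elif mode == "overlap":
        keep = lambda r: r.k >= 1  # noqa: E731
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sets = [
        {r.pathway for r in results if keep(r)}
        for results in per_patient_results.values()
    ]
    return set.intersection(*sets)
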