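"""Four-category origin classification of genes inside a sex-linked region.

Genes are classified from homology evidence with a fixed precedence:

1. *ancestral* — a syntenic hit to one of the putative ancestral
   chromosomes (the pre-sex-chromosome copies of the fused chromosome);
2. *acquired* — otherwise, any hit to a non-ancestral chromosome
   (an autosome), i.e. the gene was copied in from elsewhere;
3. *specific* — no homologous sequence anywhere;
4. *duplicated* — applied last: within each set of genes linked by
   within-SLR paralog pairs, every member except one is re-labelled
   duplicated, whatever its step 1–3 category.

Synteny evidence outranks BLAST evidence (collinearity is assessed first,
BLAST only mops up the remainder), and BLAST hits below the identity
threshold (default 70%) are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .formats_io import GeneRecord, HomologyHit

CATEGORIES = ("ancestral", "acquired", "duplicated", "specific")


@dataclass
class OriginClassification:
    """Per-gene categories plus summary counts (a partition of the input)."""

    categories: dict[str, str]  # gene_id -> category
    evidence: dict[str, list[str]]  # gene_id -> supporting subject ids
    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def __post_init__(self):
        if not self.counts:
            self.counts = {c: 0 for c in CATEGORIES}
            for cat in self.categories.values():
                self.counts[cat] += 1
        self.total = sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g,
                    "category": cat,
                    "evidence": ",".join(self.evidence.get(g, [])),
                }
                for g, cat in sorted(self.categories.items())
            ]
        )


def _paralog_components(
    pairs: list[tuple[str, str]], gene_ids: set[str]
) -> list[set[str]]:
    """Connected components of the within-SLR paralog graph (chains merge)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        for g in (a, b):
            if g not in gene_ids:
                raise ValueError(
                    f"paralog pair member {g!r} is not an SLR gene"
                )
            parent.setdefault(g, g)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for g in parent:
        comps.setdefault(find(g), set()).add(g)
    return [c for c in comps.values() if len(c) > 1]


def classify_origins(
    slr_genes: list[GeneRecord],
    synteny_hits: list[HomologyHit],
    blast_hits: list[HomologyHit],
    ancestral_chroms: set[str],
    slr_paralog_pairs: list[tuple[str, str]] | None = None,
    identity_threshold: float = 70.0,
) -> OriginClassification:
    """Classify every SLR gene into ancestral/acquired/duplicated/specific.

    ``ancestral_chroms`` names the putative ancestral chromosome copies; any
    other subject chromosome is treated as an autosome. Hits whose query is
    not an SLR gene are ignored. Within each paralog component the member
    with the smallest start coordinate keeps its homology-derived category;
    the rest become ``duplicated`` (deterministic positional rule).
    """
    gene_ids = {g.gene_id for g in slr_genes}
    starts = {g.gene_id: g.interval.start for g in slr_genes}

    syn_by_gene: dict[str, list[HomologyHit]] = {g: [] for g in gene_ids}
    blast_by_gene: dict[str, list[HomologyHit]] = {g: [] for g in gene_ids}
    for h in synteny_hits:
        if h.query_id in gene_ids:
            syn_by_gene[h.query_id].append(h)
    for h in blast_hits:
        if h.query_id in gene_ids and h.identity > identity_threshold:
            blast_by_gene[h.query_id].append(h)

    categories: dict[str, str] = {}
    evidence: dict[str, list[str]] = {}
    for g in gene_ids:
        syn_anc = [h for h in syn_by_gene[g] if h.subject_chrom in ancestral_chroms]
        if syn_anc:
            categories[g] = "ancestral"
            evidence[g] = sorted(h.subject_id for h in syn_anc)
            continue
        # BLAST hits to an ancestral chromosome also witness ancestry, but
        # collinearity-backed calls take precedence in evidence ordering
        blast_anc = [
            h for h in blast_by_gene[g] if h.subject_chrom in ancestral_chroms
        ]
        if blast_anc:
            categories[g] = "ancestral"
            evidence[g] = sorted(h.subject_id for h in blast_anc)
            continue
        autosomal = [
            h
            for h in syn_by_gene[g] + blast_by_gene[g]
            if h.subject_chrom not in ancestral_chroms
        ]
        if autosomal:
            categories[g] = "acquired"
            evidence[g] = sorted(h.subject_id for h in autosomal)
        else:
            categories[g] = "specific"
            evidence[g] = []

    for comp in _paralog_components(slr_paralog_pairs or [], gene_ids):
        keeper = min(comp, key=lambda g: (starts[g], g))
        for g in comp - {keeper}:
            categories[g] = "duplicated"
            evidence[g] = sorted((evidence.get(g) or []) + [f"paralog_of:{keeper}"])

    return OriginClassification(categories=categories, evidence=evidence)
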