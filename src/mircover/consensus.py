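"""Per-miRNA evidence tallies and multi-target coverage ranking.

A miRNA is summarised over a candidate gene set by counting, across all of
its evidence records restricted to that set:

* ``n_sources`` — distinct databases/tools supporting the miRNA;
* ``n_validated_genes`` / ``n_predicted_genes`` — genes with at least one
  validated-class / predicted-class record (these ARE the validated and
  predicted scores: a miRNA earns one point per candidate gene covered);
* ``positive_evidence`` / ``negative_evidence`` — validated-class record
  counts by reported direction, and their difference ``net_evidence``;
* ``integrated_score`` — a multi-source confidence aggregate: the sum over
  covered genes of the best per-source confidence for that (miRNA, gene)
  pair.  This is a documented surrogate for proprietary integrated scores
  exported by consensus databases; it lives in [0, |gene set|] and is
  order-compatible with coverage.

Ranking keeps miRNAs whose any-class gene coverage reaches ``min_coverage``
and sorts by (validated score, predicted score, net evidence, integrated
score) descending with a lexicographic id tie-break, so the order is total
and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .model import EvidenceTable, GeneSet, SourceClass, Direction, canonical_gene, canonical_mirna


@dataclass(frozen=True)
class MiRNASummary:
    """Tallies and scores for one miRNA over a candidate gene set."""

    mirna_id: str
    n_sources: int
    n_predicted_genes: int
    n_validated_genes: int
    positive_evidence: int
    negative_evidence: int
    net_evidence: int
    predicted_score: int
    validated_score: int
    integrated_score: float
    coverage: int  # genes with evidence of either class

    FIELDS = (
        "mirna_id",
        "integrated_score",
        "n_sources",
        "n_predicted_genes",
        "positive_evidence",
        "negative_evidence",
        "net_evidence",
        "n_validated_genes",
    )

    def as_row(self) -> Tuple:
        """Summary as a tuple in report column order."""
        return tuple(getattr(self, f) for f in self.FIELDS)


@dataclass
class RankedList:
    """Deterministically ordered miRNA summaries plus the criteria used."""

    summaries: List[MiRNASummary]
    ranking_key: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.summaries)

    def __iter__(self):
        return iter(self.summaries)

    def mirna_ids(self) -> List[str]:
        return [s.mirna_id for s in self.summaries]


def net_evidence(positive: int, negative: int) -> int:
    """Net validated evidence: positive minus negative record counts."""
    if positive < 0 or negative < 0:
        raise ValueError(f"evidence counts must be non-negative, got ({positive}, {negative})")
    return positive - negative


def summarize_mirna(table: EvidenceTable, gene_set: GeneSet, mirna_id: str) -> MiRNASummary:
    """Tally all evidence for one miRNA over the candidate gene set.

    Records for genes outside the gene set are ignored; a miRNA absent from
    the table yields an all-zero summary.  Identifier comparison is
    case-insensitive.
    """
    want = canonical_mirna(mirna_id)
    genes = set(gene_set.genes)

    sources = set()
    validated_genes = set()
    predicted_genes = set()
    covered_genes = set()
    positive = negative = 0
    best_conf: Dict[str, float] = {}

    for rec in table:
        if canonical_mirna(rec.mirna_id) != want:
            continue
        gene = canonical_gene(rec.gene_id)
        if gene not in genes:
            continue
        sources.add(rec.source_name)
        covered_genes.add(gene)
        if rec.confidence > best_conf.get(gene, 0.0):
            best_conf[gene] = rec.confidence
        if rec.source_class is SourceClass.VALIDATED:
            validated_genes.add(gene)
            if rec.direction is Direction.POSITIVE:
                positive += 1
            else:
                negative += 1
        else:
            predicted_genes.add(gene)

    return MiRNASummary(
        mirna_id=mirna_id,
        n_sources=len(sources),
        n_predicted_genes=len(predicted_genes),
        n_validated_genes=len(validated_genes),
        positive_evidence=positive,
        negative_evidence=negative,
        net_evidence=net_evidence(positive, negative),
        predicted_score=len(predicted_genes),
        validated_score=len(validated_genes),
        # summed in gene-set order so the value is independent of row order
        integrated_score=sum(best_conf[g] for g in gene_set.genes if g in best_conf),
        coverage=len(covered_genes),
    )


def integrated_score(table: EvidenceTable, gene_set: GeneSet, mirna_id: str) -> float:
    """Sum over covered genes of the best per-source confidence (in [0, |genes|])."""
    return summarize_mirna(table, gene_set, mirna_id).integrated_score


def _sort_key(s: MiRNASummary):
    return (
        -s.validated_score,
        -s.predicted_score,
        -s.net_evidence,
        -s.integrated_score,
        canonical_mirna(s.mirna_id),
    )


def rank_mirnas(
    table: EvidenceTable,
    gene_set: GeneSet,
    min_coverage: int = 2,
    top_k: int = 3,
) -> RankedList:
    """Rank miRNAs by simultaneous multi-gene coverage over the candidate set.

    miRNAs covering fewer than ``min_coverage`` genes (evidence of either
    class) are excluded; the remainder are sorted by validated score, then
    predicted score, net evidence, integrated score (all descending) and
    finally miRNA id, and truncated to ``top_k``.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if top_k < 0:
        raise ValueError("top_k must be >= 0")

    summaries = [summarize_mirna(table, gene_set, m) for m in table.mirna_ids()]
    kept = [s for s in summaries if s.coverage >= min_coverage]
    kept.sort(key=_sort_key)
    return RankedList(
        summaries=kept[:top_k],
        ranking_key={
            "filter": f"coverage >= {min_coverage} (either evidence class)",
            "sort": [
                "validated_score desc",
                "predicted_score desc",
                "net_evidence desc",
                "integrated_score desc",
                "mirna_id asc",
            ],
            "top_k": top_k,
        },
    )
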