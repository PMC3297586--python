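"""SGA candidate filtering and screen bookkeeping.

The screen's candidate list is reduced by a fixed cascade of filters:
(i) keep negative interactions significant at p < 0.05, (ii) keep large
effects (score below -0.3), (iii) keep genes hit by at least two
distinct query genes, (iv) keep genes with a human homolog (BLAST
expect value below 1e-5).  All threshold comparisons are strict,
matching the "less than" convention; each filter is a contraction and
idempotent.  Validation outcomes (retests that failed, plus newly
identified interactions) are then merged into the final pair set, and
the network is summarized with integer-rounded percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError, InvalidRecordError, SchemaError
from .plate_io import HomologyRecord

logger = logging.getLogger(__name__)

ALLELE_CLASSES = ("deletion", "ts", "damp")


@dataclass(frozen=True)
class SgaRecord:
    """One query x array-gene screen measurement.

    ``score`` is the E-C interaction value (experimental minus control;
    negative = aggravating) and ``p_value`` its screen significance.
    """

    query_id: str
    gene_id: str
    score: float
    p_value: float
    allele_class: str = "deletion"
    essential: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidRecordError(
                f"p-value {self.p_value} for ({self.query_id}, {self.gene_id}) "
                "not in [0, 1]"
            )
        if self.allele_class not in ALLELE_CLASSES:
            raise InvalidRecordError(f"unknown allele class {self.allele_class!r}")


@dataclass(frozen=True)
class ValidationOutcome:
    """Retest result for one pair: confirmed from the screen, or newly found."""

    query_id: str
    gene_id: str
    confirmed: bool
    newly_identified: bool = False

    def __post_init__(self) -> None:
        if self.confirmed and self.newly_identified:
            raise InvalidRecordError(
                "an outcome cannot be both screen-confirmed and newly identified"
            )


@dataclass
class NetworkSummary:
    n_genes: int
    n_interactions: int
    n_essential_interactions: int
    pct_essential: int
    n_genes_with_homolog: int
    pct_homolog: int


def round_half_up(x: float) -> int:
    """Integer rounding with ties away from zero toward +inf (.5 rounds up)."""
    return int(math.floor(x + 0.5))


def _pct(numerator: int, denominator: int) -> int:
    return round_half_up(100.0 * numerator / denominator) if denominator else 0


# --- filter cascade ---------------------------------------------------------


def filter_significant_negative(
    records: Iterable[SgaRecord], p_threshold: float = 0.05
) -> list[SgaRecord]:
    """Keep negative-score records with p strictly below the threshold."""
    return [r for r in records if r.score < 0 and r.p_value < p_threshold]


def filter_magnitude(
    records: Iterable[SgaRecord], threshold: float = -0.3
) -> list[SgaRecord]:
    """Keep records with score strictly below the magnitude threshold."""
    return [r for r in records if r.score < threshold]


def filter_multi_query(
    records: Iterable[SgaRecord], min_queries: int = 2
) -> list[SgaRecord]:
    """Keep records of genes hit by at least ``min_queries`` distinct queries.

    Query counting happens on this filter's own input, so its result
    depends on the filters applied before it; the pipeline order is
    significance -> magnitude -> multi-query -> homolog.
    """
    records = list(records)
    queries_per_gene: dict[str, set[str]] = {}
    for r in records:
        queries_per_gene.setdefault(r.gene_id, set()).add(r.query_id)
    return [r for r in records if len(queries_per_gene[r.gene_id]) >= min_queries]


def human_homolog_genes(
    homology: Iterable[HomologyRecord],
    e_threshold: float = 1e-5,
    taxon: str = "human",
) -> set[str]:
    """Genes whose best expect value in the given taxon is strictly below threshold."""
    best: dict[str, float] = {}
    for rec in homology:
        if rec.taxon != taxon:
            continue
        best[rec.gene_id] = min(best.get(rec.gene_id, math.inf), rec.best_expect)
    return {gene for gene, e in best.items() if e < e_threshold}


def filter_homolog(
    records: Iterable[SgaRecord],
    homology: Iterable[HomologyRecord],
    e_threshold: float = 1e-5,
) -> list[SgaRecord]:
    """Keep records of genes with a human homolog below the expect threshold.

    Genes absent from the homology table count as no-match and are
    dropped with a logged warning.
    """
    records = list(records)
    homology = list(homology)
    known = {rec.gene_id for rec in homology}
    keep = human_homolog_genes(homology, e_threshold)
    for gene in sorted({r.gene_id for r in records} - known):
        logger.warning("gene %s absent from homology table; treated as no-match", gene)
    return [r for r in records if r.gene_id in keep]


def run_filter_cascade(
    records: Iterable[SgaRecord],
    homology: Iterable[HomologyRecord],
    p_threshold: float = 0.05,
    magnitude_threshold: float = -0.3,
    min_queries: int = 2,
    e_threshold: float = 1e-5,
) -> dict[str, list[SgaRecord]]:
    """Apply the full cascade in order, returning each stage's survivors."""
    stages: dict[str, list[SgaRecord]] = {}
    stages["significant_negative"] = filter_significant_negative(records, p_threshold)
    stages["magnitude"] = filter_magnitude(stages["significant_negative"], magnitude_threshold)
    stages["multi_query"] = filter_multi_query(stages["magnitude"], min_queries)
    stages["homolog"] = filter_homolog(stages["multi_query"], homology, e_threshold)
    return stages


# --- validation merge and summary -------------------------------------------


def reconstruction_pairs(
    queries: Iterable[str], genes: Iterable[str]
) -> list[tuple[str, str]]:
    """Every (query, gene) double to reconstruct for validation."""
    return sorted((q, g) for q in set(queries) for g in set(genes))


def merge_validation(
    candidates: Iterable[tuple[str, str]],
    outcomes: Iterable[ValidationOutcome],
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Merge retest outcomes into the final interaction set.

    Final set = candidates minus unconfirmed pairs plus newly identified
    pairs.  Returns the sorted final pairs and an accounting dict with
    n_input, n_failed, n_new, n_final and pct_failed; the invariant
    n_final = n_input - n_failed + n_new holds by construction.
    """
    cand = set(candidates)
    failed: set[tuple[str, str]] = set()
    new: set[tuple[str, str]] = set()
    for o in outcomes:
        pair = (o.query_id, o.gene_id)
        if o.newly_identified:
            new.add(pair)
            continue
        if pair not in cand:
            raise ConsistencyError(
                f"outcome for {pair} references a pair that was never a candidate"
            )
        if not o.confirmed:
            failed.add(pair)
    final = sorted((cand - failed) | new)
    counts = {
        "n_input": len(cand),
        "n_failed": len(failed),
        "n_new": len(new - cand),
        "n_final": len(final),
        "pct_failed": _pct(len(failed), len(cand)),
    }
    return final, counts


def summarize_network(
    edges: Iterable,
    homology: Iterable[HomologyRecord],
    essential_flags: Mapping[str, bool],
    e_threshold: float = 1e-5,
) -> NetworkSummary:
    """Count genes/interactions and the essential and homolog fractions.

    ``edges`` may be NetworkEdge objects or plain (query, gene) pairs.
    ``essential_flags`` must cover every gene in the network.
    """
    pairs: list[tuple[str, str]] = []
    for e in edges:
        if isinstance(e, tuple):
            pairs.append(e)
        else:
            pairs.append((e.query_id, e.gene_id))
    genes = sorted({g for _, g in pairs})
    for gene in genes:
        if gene not in essential_flags:
            raise SchemaError(f"essential_flags does not cover gene {gene!r}")
    n_essential = sum(1 for _, g in pairs if essential_flags[g])
    with_homolog = human_homolog_genes(homology, e_threshold)
    n_homolog = sum(1 for g in genes if g in with_homolog)
    return NetworkSummary(
        n_genes=len(genes),
        n_interactions=len(pairs),
        n_essential_interactions=n_essential,
        pct_essential=_pct(n_essential, len(pairs)),
        n_genes_with_homolog=n_homolog,
        pct_homolog=_pct(n_homolog, len(genes)),
    )
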