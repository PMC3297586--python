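"""Additive-neutrality interaction model and SL/SS edge classification.

Double-mutant fitness is modelled as

    Y_ij = mu + alpha_i + beta_j + epsilon_ij + error

where mu is wild-type fitness, alpha_i and beta_j are the single-mutant
effects of query i and array gene j, and epsilon_ij is the interaction
term.  Under additive neutrality non-interacting pairs have
epsilon_ij = 0; epsilon < 0 marks aggravating (synthetic sick)
interactions and epsilon > 0 alleviating ones.

The design is saturated (one parameter per distinct cell), so the exact
least-squares solution is the cell-mean estimator:

    mu_hat      = mean(WT)
    alpha_i_hat = mean(single i) - mu_hat
    beta_j_hat  = mean(single j) - mu_hat
    eps_ij_hat  = mean(double ij) - mean(single i) - mean(single j) + mu_hat

with SE(eps_hat) = s * sqrt(1/n_ij + 1/n_i + 1/n_j + 1/n_WT), s^2 the
pooled within-cell variance, a t statistic eps_hat / SE, two-sided
p-values on the residual degrees of freedom, and a Bonferroni correction
over all pairs tested at one temperature.  Analyses at different
temperatures are run separately and merged at classification time by
keeping each pair's more significant result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DuplicateRecordError,
    IncompleteDesignError,
    InvalidInputError,
    MissingViabilityError,
)
from .fitness import FitnessRecord, log_fitness, normalize_plates
from .plate_io import GrowthCurve, RandomSporeResult


@dataclass
class ModelFit:
    """Fitted additive model for one temperature."""

    temperature: float
    mu_hat: float
    alpha_hat: dict[str, float]
    beta_hat: dict[str, float]
    residual_variance: float
    residual_df: int


@dataclass
class InteractionEstimate:
    """One pair's interaction estimate with its inference summaries.

    ``se``, ``t_stat``, ``p_value`` and ``p_bonferroni`` are None when no
    inference is possible (no residual degrees of freedom, or zero
    pooled variance in a noise-free design).
    """

    query_id: str
    gene_id: str
    epsilon_hat: float
    se: float | None
    t_stat: float | None
    p_value: float | None
    p_bonferroni: float | None
    n_double: int
    temperature: float


@dataclass
class NetworkEdge:
    """One SL or SS edge of the genetic-interaction network."""

    query_id: str
    gene_id: str
    edge_class: str  # "SL" or "SS"
    strength: float | None
    provenance: str  # "random_spore", "growth_curve", or "sga"

    def __post_init__(self) -> None:
        if self.edge_class not in ("SL", "SS"):
            raise InvalidInputError(f"unknown edge class {self.edge_class!r}")
        if self.edge_class == "SS" and (
            self.strength is None or not math.isfinite(self.strength)
        ):
            raise InvalidInputError("SS edges must carry a finite strength")
        if self.edge_class == "SL" and self.provenance != "random_spore":
            raise InvalidInputError("SL edges must come from random-spore viability")


def fit_interaction_model(
    records: Iterable[FitnessRecord], temperature: float
) -> tuple[ModelFit, list[InteractionEstimate]]:
    """Fit the additive model to normalized fitness records at one temperature.

    Requires wild-type records and, for every double cell, the matching
    single-mutant cells.  Returns the model fit and one estimate per
    (query, gene) double cell, Bonferroni-corrected over all pairs at
    this temperature.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("no fitness records")
    for r in records:
        if not r.normalized:
            raise InvalidInputError("fit requires plate-normalized fitness records")
        if r.temperature != temperature:
            raise InvalidInputError(
                f"record at {r.temperature} degC in a {temperature} degC analysis"
            )

    cells: dict[tuple, list[float]] = {}
    for r in records:
        cells.setdefault(r.strain.cell(), []).append(r.fitness)
    if ("wt",) not in cells:
        raise IncompleteDesignError("no wild-type records in the design")

    means = {key: float(np.mean(vals)) for key, vals in cells.items()}
    counts = {key: len(vals) for key, vals in cells.items()}

    doubles = sorted(key for key in cells if key[0] == "d")
    for _, q, g in doubles:
        if ("q", q) not in cells or ("g", g) not in cells:
            raise IncompleteDesignError(
                f"double ({q}, {g}) lacks a matching single-mutant cell"
            )

    n_obs = sum(counts.values())
    residual_df = n_obs - len(cells)
    if residual_df >= 1:
        ss_within = sum(
            float(np.sum((np.asarray(vals) - means[key]) ** 2))
            for key, vals in cells.items()
        )
        s2 = ss_within / residual_df
    else:
        s2 = math.nan

    mu = means[("wt",)]
    alpha = {key[1]: means[key] - mu for key in cells if key[0] == "q"}
    beta = {key[1]: means[key] - mu for key in cells if key[0] == "g"}

    n_pairs = len(doubles)
    estimates: list[InteractionEstimate] = []
    for key in doubles:
        _, q, g = key
        eps = means[key] - means[("q", q)] - means[("g", g)] + mu
        se = t_stat = p_value = p_bonf = None
        if residual_df >= 1 and s2 > 0:
            se = math.sqrt(
                s2
                * (
                    1.0 / counts[key]
                    + 1.0 / counts[("q", q)]
                    + 1.0 / counts[("g", g)]
                    + 1.0 / counts[("wt",)]
                )
            )
            t_stat = eps / se
            p_value = float(2.0 * stats.t.sf(abs(t_stat), residual_df))
            p_bonf = min(1.0, p_value * n_pairs)
        estimates.append(
            InteractionEstimate(
                query_id=q,
                gene_id=g,
                epsilon_hat=eps,
                se=se,
                t_stat=t_stat,
                p_value=p_value,
                p_bonferroni=p_bonf,
                n_double=counts[key],
                temperature=temperature,
            )
        )

    fit = ModelFit(
        temperature=temperature,
        mu_hat=mu,
        alpha_hat=alpha,
        beta_hat=beta,
        residual_variance=s2,
        residual_df=residual_df,
    )
    return fit, estimates


def estimate_from_curves(
    curves: Iterable[GrowthCurve], temperature: float
) -> tuple[ModelFit, list[InteractionEstimate]]:
    """Convenience pipeline: log-AUC fitness -> plate normalization -> model fit."""
    fits = [log_fitness(c) for c in curves if c.temperature == temperature]
    return fit_interaction_model(normalize_plates(fits), temperature)


def _collapse_alleles(
    estimates: Sequence[InteractionEstimate],
) -> dict[tuple[str, str], InteractionEstimate]:
    """Reduce estimates to one per (query, gene).

    Multiple alleles of one gene at one temperature keep the strongest
    (most negative) epsilon; across temperatures the more significant
    (smaller p) result wins, falling back to the more negative epsilon
    when p-values are absent.
    """
    per_temp: dict[tuple[str, str, float], InteractionEstimate] = {}
    for est in estimates:
        key = (est.query_id, est.gene_id, est.temperature)
        held = per_temp.get(key)
        if held is None or est.epsilon_hat < held.epsilon_hat:
            per_temp[key] = est

    best: dict[tuple[str, str], InteractionEstimate] = {}
    for est in per_temp.values():
        key = (est.query_id, est.gene_id)
        held = best.get(key)
        if held is None:
            best[key] = est
            continue
        p_new = math.inf if est.p_value is None else est.p_value
        p_old = math.inf if held.p_value is None else held.p_value
        if p_new < p_old or (p_new == p_old and est.epsilon_hat < held.epsilon_hat):
            best[key] = est
    return best


def classify_interactions(
    estimates: Sequence[InteractionEstimate],
    spores: Sequence[RandomSporeResult],
    alpha: float = 0.05,
    use_bonferroni: bool = False,
) -> list[NetworkEdge]:
    """Build the SL/SS network from growth estimates and spore viability.

    A pair whose double mutant failed to grow under double selection is
    synthetic lethal (SL) regardless of growth-curve data.  A viable
    pair is synthetic sick (SS) iff its epsilon is negative and its
    (optionally Bonferroni-corrected) p-value is below ``alpha``;
    alleviating (positive-epsilon) interactions yield no edge.
    """
    viable: dict[tuple[str, str], bool] = {}
    for s in spores:
        key = (s.query_id, s.gene_id)
        if key in viable:
            raise DuplicateRecordError(f"duplicate random-spore record for {key}")
        viable[key] = s.double_viable

    best = _collapse_alleles(estimates)
    for key in best:
        if key not in viable:
            raise MissingViabilityError(
                f"pair {key} has growth estimates but no random-spore record"
            )

    edges: list[NetworkEdge] = []
    for key in sorted(viable):
        if not viable[key]:
            edges.append(
                NetworkEdge(
                    query_id=key[0],
                    gene_id=key[1],
                    edge_class="SL",
                    strength=None,
                    provenance="random_spore",
                )
            )
            continue
        est = best.get(key)
        if est is None:
            continue
        p_sel = est.p_bonferroni if use_bonferroni else est.p_value
        if est.epsilon_hat < 0 and p_sel is not None and p_sel < alpha:
            edges.append(
                NetworkEdge(
                    query_id=key[0],
                    gene_id=key[1],
                    edge_class="SS",
                    strength=abs(est.epsilon_hat),
                    provenance="growth_curve",
                )
            )
    return edges
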