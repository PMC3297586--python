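"""Additive-expectation tests for binary worm phenotypes, and brood summaries.

A genetic interaction in the worm assay is an excess of the observed
phenotype frequency in the mutant + RNAi condition over the additive
prediction.  The prediction is the sum of the mutant and wild-type
background frequencies plus the RNAi effect on wild type:

    predicted = mutant_control + wt_control + (wt_treated - wt_control)
              = mutant_control + wt_treated

(the wild-type background cancels algebraically).  Frequencies are
clamped to [0, 1]; count phenotypes (e.g. apoptotic corpses per gonad
arm) use the same expectation without the upper clamp.  "Clear
increase" is operationalized as an excess larger than k (default 2)
pooled standard errors, matching SEM error bars on the assay figures;
k is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidRecordError

SEM_MULTIPLIER_DEFAULT = 2.0


@dataclass(frozen=True)
class PvlAssayRecord:
    """Binary-phenotype counts for one genotype x RNAi condition."""

    genotype: str
    rnai: str
    n_scored: int
    n_affected: int

    def __post_init__(self) -> None:
        if self.n_scored <= 0:
            raise InvalidRecordError(
                f"{self.genotype}/{self.rnai}: n_scored must be positive"
            )
        if not 0 <= self.n_affected <= self.n_scored:
            raise InvalidRecordError(
                f"{self.genotype}/{self.rnai}: n_affected outside [0, n_scored]"
            )


@dataclass
class AdditiveCall:
    """Observed vs additive-predicted frequency for one RNAi condition."""

    rnai: str
    observed: float
    predicted: float
    observed_sem: float
    predicted_sem: float
    excess: float
    interaction: bool


@dataclass(frozen=True)
class BroodRecord:
    """Per-animal brood bookkeeping: eggs laid, embryo fates, male progeny."""

    genotype: str
    brood_size: int
    n_embryos: int
    n_arrested: int
    n_males: int
    n_progeny_scored: int

    def __post_init__(self) -> None:
        if min(self.brood_size, self.n_embryos, self.n_arrested, self.n_males,
               self.n_progeny_scored) < 0:
            raise InvalidRecordError("brood counts must be non-negative")
        if self.n_arrested > self.n_embryos:
            raise InvalidRecordError("n_arrested exceeds n_embryos")
        if self.n_males > self.n_progeny_scored:
            raise InvalidRecordError("n_males exceeds n_progeny_scored")


@dataclass
class BroodSummary:
    genotype: str
    n_animals: int
    mean_brood: float
    brood_sem: float | None
    pct_arrested: float
    arrested_sem_pct: float
    pct_males: float
    males_sem_pct: float


def phenotype_frequency(record: PvlAssayRecord) -> tuple[float, float]:
    """Phenotype frequency and its binomial SEM, sqrt(f(1-f)/n)."""
    f = record.n_affected / record.n_scored
    sem = math.sqrt(f * (1.0 - f) / record.n_scored)
    return f, sem


def predicted_additive(
    wt_control: float,
    mutant_control: float,
    wt_treated: float,
    clamp: bool = True,
) -> float:
    """Additive expectation for the mutant + RNAi condition.

    Sum of the two background levels plus the RNAi effect on wild type,
    which simplifies to mutant_control + wt_treated.  With ``clamp``
    (frequency phenotypes) the result is capped at 1; count phenotypes
    pass ``clamp=False``.
    """
    for name, value in (
        ("wt_control", wt_control),
        ("mutant_control", mutant_control),
        ("wt_treated", wt_treated),
    ):
        if value < 0:
            raise InvalidInputError(f"{name} must be non-negative (got {value})")
    predicted = mutant_control + wt_control + (wt_treated - wt_control)
    if clamp:
        predicted = min(predicted, 1.0)
    return predicted


def predicted_additive_with_sem(
    mutant_control: tuple[float, float],
    wt_treated: tuple[float, float],
    wt_control: float = 0.0,
    clamp: bool = True,
) -> tuple[float, float]:
    """Additive prediction with its SEM from the two contributing terms."""
    pred = predicted_additive(wt_control, mutant_control[0], wt_treated[0], clamp=clamp)
    sem = math.sqrt(mutant_control[1] ** 2 + wt_treated[1] ** 2)
    return pred, sem


def call_interaction(
    rnai: str,
    observed: tuple[float, float],
    predicted: tuple[float, float],
    k: float = SEM_MULTIPLIER_DEFAULT,
) -> AdditiveCall:
    """Call an interaction when observed exceeds predicted by > k pooled SEMs."""
    obs_f, obs_sem = observed
    pred_f, pred_sem = predicted
    excess = obs_f - pred_f
    pooled = math.sqrt(obs_sem**2 + pred_sem**2)
    return AdditiveCall(
        rnai=rnai,
        observed=obs_f,
        predicted=pred_f,
        observed_sem=obs_sem,
        predicted_sem=pred_sem,
        excess=excess,
        interaction=excess > k * pooled,
    )


def call_interactions_from_records(
    records: Sequence[PvlAssayRecord],
    wt_genotype: str = "wild_type",
    mutant_genotype: str = "mutant",
    control_rnai: str = "control",
    k: float = SEM_MULTIPLIER_DEFAULT,
) -> list[AdditiveCall]:
    """Run the additive test for every RNAi in a four-condition assay table.

    Expects, for each RNAi target, records for (wt, control), (mutant,
    control), (wt, rnai) and (mutant, rnai); control columns must be
    explicitly labelled with ``control_rnai``.
    """
    by_key = {(r.genotype, r.rnai): r for r in records}

    def freq(genotype: str, rnai: str) -> tuple[float, float]:
        key = (genotype, rnai)
        if key not in by_key:
            raise InvalidInputError(f"missing assay record for {key}")
        return phenotype_frequency(by_key[key])

    wt_ctrl = freq(wt_genotype, control_rnai)
    mut_ctrl = freq(mutant_genotype, control_rnai)
    targets = sorted({r.rnai for r in records} - {control_rnai})
    calls = []
    for rnai in targets:
        predicted = predicted_additive_with_sem(
            mut_ctrl, freq(wt_genotype, rnai), wt_control=wt_ctrl[0]
        )
        calls.append(
            call_interaction(rnai, freq(mutant_genotype, rnai), predicted, k=k)
        )
    return calls


def summarize_brood(
    records: Iterable[BroodRecord], genotype: str
) -> BroodSummary:
    """Mean brood with SEM, plus pooled embryonic-arrest and male percentages.

    Per-animal brood sizes give mean and SEM = sd/sqrt(n) (SEM absent
    for a single animal); arrest and male rates pool counts across
    animals and carry binomial SEMs, reported as percentages.
    """
    recs = [r for r in records if r.genotype == genotype]
    if not recs:
        raise InvalidInputError(f"no brood records for genotype {genotype!r}")
    broods = np.array([r.brood_size for r in recs], dtype=float)
    n = len(recs)
    mean_brood = float(np.mean(broods))
    brood_sem = float(np.std(broods, ddof=1) / math.sqrt(n)) if n >= 2 else None

    def pooled_pct(successes: int, total: int) -> tuple[float, float]:
        if total == 0:
            return 0.0, 0.0
        f = successes / total
        return 100.0 * f, 100.0 * math.sqrt(f * (1.0 - f) / total)

    pct_arr, sem_arr = pooled_pct(sum(r.n_arrested for r in recs),
                                  sum(r.n_embryos for r in recs))
    pct_m, sem_m = pooled_pct(sum(r.n_males for r in recs),
                              sum(r.n_progeny_scored for r in recs))
    return BroodSummary(
        genotype=genotype,
        n_animals=n,
        mean_brood=mean_brood,
        brood_sem=brood_sem,
        pct_arrested=pct_arr,
        arrested_sem_pct=sem_arr,
        pct_males=pct_m,
        males_sem_pct=sem_m,
    )


def conservation_rate(calls: Iterable[AdditiveCall]) -> tuple[int, int, int]:
    """(n_conserved, n_tested, integer percent) over one call per RNAi target."""
    calls = list(calls)
    n_tested = len(calls)
    n_conserved = sum(1 for c in calls if c.interaction)
    pct = int(math.floor(100.0 * n_conserved / n_tested + 0.5)) if n_tested else 0
    return n_conserved, n_tested, pct
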