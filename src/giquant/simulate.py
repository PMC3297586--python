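"""Synthetic data with known ground truth for every pipeline stage.

Generates plate-reader growth curves (logistic growth with lag, Gaussian
OD noise floored at zero), SGA-style score tables, random-spore
viability tables, and binomial worm phenotype assays.  Fitness effects —
single-mutant effects, pairwise interactions, plate offsets — are
injected on the log-AUC scale, the same scale the downstream model
estimates on, by multiplicatively scaling the noise-free curve so its
log area hits the intended target exactly.  All randomness flows from a
single seed through per-plate substreams, so any output is reproducible
bitwise.

Replicate structure follows the emulated assay design: fifteen
wild-type wells per 96-well plate and three wells per mutant strain,
with OD read every 30 minutes over 24 hours.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DuplicateRecordError,
    InvalidConfigError,
    InvalidInputError,
    LayoutError,
)
from .fitness import auc_simpson
from .plate_io import GrowthCurve, StrainLabel

WELLS_96 = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth-law parameters for one strain.

    initial_od and carrying_capacity are dimensionless absorbance (OD600),
    rate is 1/min, lag is minutes.
    """

    initial_od: float = 0.15
    carrying_capacity: float = 1.2
    rate: float = 0.01
    lag: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.initial_od < self.carrying_capacity:
            raise InvalidConfigError(
                "require 0 < initial_od < carrying_capacity "
                f"(got {self.initial_od}, {self.carrying_capacity})"
            )
        if self.rate <= 0:
            raise InvalidConfigError(f"rate must be positive (got {self.rate})")
        if self.lag < 0:
            raise InvalidConfigError(f"lag must be non-negative (got {self.lag})")


@dataclass
class TrueEffects:
    """Ground-truth fitness effects on the log-AUC scale.

    wt_fitness is the wild-type log-AUC target; query_effects and
    gene_effects are the single-mutant effects; interactions maps
    (query, gene) to the pairwise interaction effect (0 if absent);
    plate_offsets are additive per-plate shifts.
    """

    wt_fitness: float
    query_effects: dict[str, float] = field(default_factory=dict)
    gene_effects: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    plate_offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for q, g in self.interactions:
            if q not in self.query_effects or g not in self.gene_effects:
                raise InvalidConfigError(
                    f"interaction ({q}, {g}) references an undeclared query or gene"
                )

    def target_log_auc(self, strain: StrainLabel, plate_id: str = "") -> float:
        """Noise-free log-AUC target for one well."""
        target = self.wt_fitness + self.plate_offsets.get(plate_id, 0.0)
        if strain.query_id is not None:
            target += self.query_effects[strain.query_id]
        if strain.gene_id is not None:
            target += self.gene_effects[strain.gene_id]
        if strain.query_id is not None and strain.gene_id is not None:
            target += self.interactions.get((strain.query_id, strain.gene_id), 0.0)
        return target


@dataclass
class SimulationConfig:
    """Full description of one simulated growth-curve experiment."""

    seed: int
    true_effects: TrueEffects
    n_plates: int = 1
    wt_replicates_per_plate: int = 15
    mutant_replicates: int = 3
    noise_sd: float = 0.01
    sampling_interval: float = 30.0
    duration: float = 1440.0
    temperature: float = 30.0
    growth: GrowthParams = field(default_factory=GrowthParams)

    def __post_init__(self) -> None:
        if self.n_plates <= 0 or self.wt_replicates_per_plate <= 0 or self.mutant_replicates <= 0:
            raise InvalidConfigError("plate and replicate counts must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if self.sampling_interval <= 0 or self.duration <= 0:
            raise InvalidConfigError("sampling interval and duration must be positive")


def _time_grid(sampling_interval: float, duration: float) -> np.ndarray:
    n = int(math.floor(duration / sampling_interval + 1e-9)) + 1
    return np.arange(n, dtype=float) * sampling_interval


def logistic_od(params: GrowthParams, times: np.ndarray) -> np.ndarray:
    """Noise-free logistic curve: holds at initial_od until lag, then grows to K."""
    t = np.maximum(np.asarray(times, dtype=float) - params.lag, 0.0)
    k, x0 = params.carrying_capacity, params.initial_od
    return k / (1.0 + (k - x0) / x0 * np.exp(-params.rate * t))


def simulate_growth_curve(
    params: GrowthParams,
    noise_sd: float,
    seed: int,
    *,
    sampling_interval: float = 30.0,
    duration: float = 1440.0,
    plate_id: str = "sim",
    well: str = "A1",
    strain: StrainLabel | None = None,
    temperature: float = 30.0,
) -> GrowthCurve:
    """One well's logistic curve plus zero-mean Gaussian OD noise, floored at 0."""
    if sampling_interval <= 0 or duration <= 0:
        raise InvalidConfigError("sampling interval and duration must be positive")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be non-negative")
    times = _time_grid(sampling_interval, duration)
    values = logistic_od(params, times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.maximum(values, 0.0)
    return GrowthCurve(
        plate_id=plate_id,
        well=well,
        strain=strain or StrainLabel.wild_type(),
        temperature=temperature,
        times=times,
        values=values,
    )


def _plate_strains(config: SimulationConfig) -> list[StrainLabel]:
    effects = config.true_effects
    strains: list[StrainLabel] = []
    strains += [StrainLabel.wild_type()] * config.wt_replicates_per_plate
    for q in sorted(effects.query_effects):
        strains += [StrainLabel.query_single(q)] * config.mutant_replicates
    for g in sorted(effects.gene_effects):
        strains += [StrainLabel.array_single(g)] * config.mutant_replicates
    for q in sorted(effects.query_effects):
        for g in sorted(effects.gene_effects):
            strains += [StrainLabel.double(q, g)] * config.mutant_replicates
    return strains


def plate_layout(config: SimulationConfig) -> dict[str, StrainLabel]:
    """Well → strain assignment for one plate; raises if >96 wells are needed."""
    strains = _plate_strains(config)
    if len(strains) > len(WELLS_96):
        raise LayoutError(
            f"layout needs {len(strains)} wells but a plate has {len(WELLS_96)}"
        )
    return dict(zip(WELLS_96, strains))


def simulate_plate_set(
    config: SimulationConfig,
) -> tuple[list[GrowthCurve], TrueEffects]:
    """Simulate every plate of a growth-curve experiment.

    Each plate carries the full strain layout (wild type, every single
    mutant, every query × gene double).  A well's noise-free log-AUC
    equals wt_fitness plus the applicable single-mutant effects,
    interaction effect, and plate offset, realized by scaling the base
    logistic curve; Gaussian OD noise is then added and floored at 0.
    """
    layout = plate_layout(config)
    times = _time_grid(config.sampling_interval, config.duration)
    base = logistic_od(config.growth, times)
    log_auc0 = math.log(auc_simpson(times, base))

    wells = list(layout)
    scales = np.array(
        [
            math.exp(
                config.true_effects.target_log_auc(layout[w], plate_id="") - log_auc0
            )
            for w in wells
        ]
    )
    curves: list[GrowthCurve] = []
    for p in range(config.n_plates):
        plate_id = f"plate{p + 1}"
        offset_scale = math.exp(config.true_effects.plate_offsets.get(plate_id, 0.0))
        rng = np.random.default_rng([config.seed, p])
        noise = (
            rng.normal(0.0, config.noise_sd, size=(len(wells), times.size))
            if config.noise_sd > 0
            else np.zeros((len(wells), times.size))
        )
        matrix = np.maximum(scales[:, None] * offset_scale * base[None, :] + noise, 0.0)
        for i, w in enumerate(wells):
            curves.append(
                GrowthCurve(
                    plate_id=plate_id,
                    well=w,
                    strain=layout[w],
                    temperature=config.temperature,
                    times=times,
                    values=matrix[i],
                )
            )
    return curves, config.true_effects


def write_true_effects(effects: TrueEffects, path: str | Path) -> None:
    """Persist ground truth as a TSV for test harnesses and audits."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["kind", "id1", "id2", "value"])
        writer.writerow(["wt_fitness", "", "", repr(float(effects.wt_fitness))])
        for q in sorted(effects.query_effects):
            writer.writerow(["query", q, "", repr(float(effects.query_effects[q]))])
        for g in sorted(effects.gene_effects):
            writer.writerow(["gene", g, "", repr(float(effects.gene_effects[g]))])
        for q, g in sorted(effects.interactions):
            writer.writerow(
                ["interaction", q, g, repr(float(effects.interactions[(q, g)]))]
            )
        for p in sorted(effects.plate_offsets):
            writer.writerow(["plate_offset", p, "", repr(float(effects.plate_offsets[p]))])


def simulate_sga_table(
    n_null: int,
    true_hits: Sequence,
    seed: int,
    *,
    null_score_sd: float = 0.1,
) -> list:
    """An SGA score table: null records around zero plus declared hits verbatim.

    Null records get scores ~ Normal(0, null_score_sd) and p-values ~
    Uniform(0, 1).  ``true_hits`` may be SgaRecord instances or
    (query, gene, score, p) tuples, copied through unchanged.
    """
    from .screen import SgaRecord

    if n_null < 0:
        raise InvalidConfigError("n_null must be non-negative")
    records: list[SgaRecord] = []
    for hit in true_hits:
        if isinstance(hit, SgaRecord):
            records.append(hit)
        else:
            q, g, score, p = hit
            records.append(SgaRecord(query_id=q, gene_id=g, score=float(score), p_value=float(p)))
    for rec in records:
        if not math.isfinite(rec.score):
            raise InvalidInputError(f"non-finite score for ({rec.query_id}, {rec.gene_id})")

    rng = np.random.default_rng(seed)
    queries = ("q1", "q2", "q3")
    for i in range(n_null):
        records.append(
            SgaRecord(
                query_id=queries[i % len(queries)],
                gene_id=f"null{i:04d}",
                score=float(rng.normal(0.0, null_score_sd)),
                p_value=float(rng.uniform()),
            )
        )

    seen: set[tuple] = set()
    for rec in records:
        key = (rec.query_id, rec.gene_id, rec.allele_class)
        if key in seen:
            raise DuplicateRecordError(f"duplicate (query, gene, allele) {key}")
        seen.add(key)
    return records


def simulate_pvl_assay(
    penetrance: Mapping[tuple[str, str], float],
    n_per_condition: int,
    seed: int,
) -> list:
    """Binomial phenotype counts for each (genotype, rnai) condition."""
    from .worm import PvlAssayRecord

    if n_per_condition <= 0:
        raise InvalidConfigError("n_per_condition must be positive")
    for key, p in penetrance.items():
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError(f"penetrance for {key} not in [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    records = []
    for genotype, rnai in sorted(penetrance):
        p = penetrance[(genotype, rnai)]
        records.append(
            PvlAssayRecord(
                genotype=genotype,
                rnai=rnai,
                n_scored=n_per_condition,
                n_affected=int(rng.binomial(n_per_condition, p)),
            )
        )
    return records
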