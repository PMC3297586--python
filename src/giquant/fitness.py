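"""Growth-curve fitness: log area under the OD curve, plate-normalized.

Strain fitness is the natural logarithm of the area under the optical
density time series, integrated by composite Simpson's rule.  Fitness
values are then normalized for plate effects by an additive shift on the
log scale so that every plate's wild-type mean equals the grand
wild-type mean; within-plate differences are preserved exactly and the
operation is idempotent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DegenerateCurveError,
    FormatError,
    InsufficientDataError,
    InvalidInputError,
    NormalizationError,
)
from .plate_io import ROLE_WILD_TYPE, GrowthCurve, StrainLabel


@dataclass
class FitnessRecord:
    """Per-well log-AUC fitness; the interaction model's response."""

    strain: StrainLabel
    plate_id: str
    temperature: float
    fitness: float
    normalized: bool = False
    well: str = ""


def auc_simpson(times: Sequence[float], values: Sequence[float]) -> float:
    """Area under the curve by composite Simpson's rule.

    Consecutive pairs of intervals are integrated with the (possibly
    non-uniform) three-point Simpson formula; if the number of intervals
    is odd the final interval falls back to the trapezoid rule.  Exact
    for quadratics on uniform grids with an even interval count.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise InvalidInputError("times and values must be 1-D and equal length")
    if t.size < 3:
        raise InsufficientDataError("Simpson integration needs at least 3 points")
    if not np.all(np.diff(t) > 0):
        raise FormatError("times must be strictly increasing")

    n_intervals = t.size - 1
    total = 0.0
    for i in range(0, n_intervals - 1, 2):
        h0 = t[i + 1] - t[i]
        h1 = t[i + 2] - t[i + 1]
        total += (h0 + h1) / 6.0 * (
            (2.0 - h1 / h0) * y[i]
            + (h0 + h1) ** 2 / (h0 * h1) * y[i + 1]
            + (2.0 - h0 / h1) * y[i + 2]
        )
    if n_intervals % 2 == 1:
        total += 0.5 * (t[-1] - t[-2]) * (y[-1] + y[-2])
    return float(total)


def log_fitness(curve: GrowthCurve) -> FitnessRecord:
    """Fitness of one well: natural log of its Simpson AUC."""
    area = auc_simpson(curve.times, curve.values)
    if area <= 0:
        raise DegenerateCurveError(
            f"well {curve.well} on {curve.plate_id}: AUC {area} is not positive"
        )
    return FitnessRecord(
        strain=curve.strain,
        plate_id=curve.plate_id,
        temperature=curve.temperature,
        fitness=math.log(area),
        normalized=False,
        well=curve.well,
    )


def normalize_plates(records: Iterable[FitnessRecord]) -> list[FitnessRecord]:
    """Remove additive plate effects using the wild-type wells.

    Each record is shifted by (grand wild-type mean − its plate's
    wild-type mean), so afterwards every plate's wild-type mean equals
    the grand wild-type mean.  All records must share one temperature
    and every plate must contain at least one wild-type well.
    """
    records = list(records)
    if not records:
        return []
    temperatures = {r.temperature for r in records}
    if len(temperatures) > 1:
        raise InvalidInputError(
            f"normalize_plates got mixed temperatures {sorted(temperatures)}; "
            "analyses are run separately per temperature"
        )

    wt_by_plate: dict[str, list[float]] = {}
    plates = {r.plate_id for r in records}
    for r in records:
        if r.strain.role == ROLE_WILD_TYPE:
            wt_by_plate.setdefault(r.plate_id, []).append(r.fitness)
    for plate in sorted(plates):
        if plate not in wt_by_plate:
            raise NormalizationError(f"plate {plate} has no wild-type wells")

    all_wt = [f for vals in wt_by_plate.values() for f in vals]
    grand = float(np.mean(all_wt))
    shift = {plate: grand - float(np.mean(vals)) for plate, vals in wt_by_plate.items()}
    return [
        replace(r, fitness=r.fitness + shift[r.plate_id], normalized=True)
        for r in records
    ]


# --- TSV export / import ----------------------------------------------------


def write_fitness_table(records: Sequence[FitnessRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["plate", "well", "role", "query", "gene", "temperature", "fitness", "normalized"]
        )
        for r in sorted(records, key=lambda r: (r.plate_id, r.well)):
            writer.writerow(
                [
                    r.plate_id,
                    r.well,
                    r.strain.role,
                    r.strain.query_id or "",
                    r.strain.gene_id or "",
                    repr(float(r.temperature)),
                    repr(float(r.fitness)),
                    "true" if r.normalized else "false",
                ]
            )


def read_fitness_table(path: str | Path) -> list[FitnessRecord]:
    from .plate_io import _read_rows, _require_columns  # reuse parsing helpers

    path = Path(path)
    header, rows = _read_rows(path)
    _require_columns(
        header,
        ["plate", "well", "role", "query", "gene", "temperature", "fitness", "normalized"],
        path,
    )
    idx = {name: header.index(name) for name in header}
    records = []
    for _lineno, row in rows:
        records.append(
            FitnessRecord(
                strain=StrainLabel(
                    role=row[idx["role"]],
                    query_id=row[idx["query"]] or None,
                    gene_id=row[idx["gene"]] or None,
                ),
                plate_id=row[idx["plate"]],
                temperature=float(row[idx["temperature"]]),
                fitness=float(row[idx["fitness"]]),
                normalized=row[idx["normalized"]].lower() == "true",
                well=row[idx["well"]],
            )
        )
    return records
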