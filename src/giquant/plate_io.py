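"""Readers and writers for plate-reader exports and screen tables.

The pipeline's on-disk formats are deliberately plain: wide delimited
time-series files (first column = time in minutes, one column per well),
TSV tables for SGA scores / homology calls / random-spore viability /
worm phenotype counts, and networks in TSV, SIF or GraphML.  The
delimiter is auto-detected between comma and tab.  Writers are
byte-stable for a fixed input ordering so outputs can be diffed across
runs.

Missing OD cells are an error, never interpolated: silently filling a
gap would bias the area under the curve downstream.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DuplicateRecordError,
    FormatError,
    InvalidInputError,
    InvalidRecordError,
    MissingWellError,
    SchemaError,
)

logger = logging.getLogger(__name__)

# Strain roles ---------------------------------------------------------------

ROLE_WILD_TYPE = "wild_type"
ROLE_QUERY_SINGLE = "query_single"
ROLE_ARRAY_SINGLE = "array_single"
ROLE_DOUBLE = "double"
_ROLES = (ROLE_WILD_TYPE, ROLE_QUERY_SINGLE, ROLE_ARRAY_SINGLE, ROLE_DOUBLE)


@dataclass(frozen=True)
class StrainLabel:
    """Identity of a well's strain: wild type, single mutant, or double mutant.

    ``wild_type`` carries neither id, ``query_single`` only ``query_id``,
    ``array_single`` only ``gene_id``, and ``double`` both.
    """

    role: str
    query_id: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise InvalidRecordError(f"unknown strain role {self.role!r}")
        has_q, has_g = self.query_id is not None, self.gene_id is not None
        expected = {
            ROLE_WILD_TYPE: (False, False),
            ROLE_QUERY_SINGLE: (True, False),
            ROLE_ARRAY_SINGLE: (False, True),
            ROLE_DOUBLE: (True, True),
        }[self.role]
        if (has_q, has_g) != expected:
            raise InvalidRecordError(
                f"role {self.role!r} is inconsistent with "
                f"query_id={self.query_id!r}, gene_id={self.gene_id!r}"
            )

    @classmethod
    def wild_type(cls) -> "StrainLabel":
        return cls(ROLE_WILD_TYPE)

    @classmethod
    def query_single(cls, query_id: str) -> "StrainLabel":
        return cls(ROLE_QUERY_SINGLE, query_id=query_id)

    @classmethod
    def array_single(cls, gene_id: str) -> "StrainLabel":
        return cls(ROLE_ARRAY_SINGLE, gene_id=gene_id)

    @classmethod
    def double(cls, query_id: str, gene_id: str) -> "StrainLabel":
        return cls(ROLE_DOUBLE, query_id=query_id, gene_id=gene_id)

    def cell(self) -> tuple:
        """Design-cell key used by the interaction model."""
        if self.role == ROLE_WILD_TYPE:
            return ("wt",)
        if self.role == ROLE_QUERY_SINGLE:
            return ("q", self.query_id)
        if self.role == ROLE_ARRAY_SINGLE:
            return ("g", self.gene_id)
        return ("d", self.query_id, self.gene_id)


@dataclass
class GrowthCurve:
    """One well's OD time series with its strain, plate and temperature identity."""

    plate_id: str
    well: str
    strain: StrainLabel
    temperature: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise InvalidRecordError("times and values must be one-dimensional")
        if len(self.times) != len(self.values):
            raise InvalidRecordError("times and values differ in length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise FormatError(
                f"times for well {self.well} on {self.plate_id} are not "
                "strictly increasing"
            )
        if np.any(self.values < 0):
            raise InvalidRecordError("OD values must be non-negative")


@dataclass(frozen=True)
class RandomSporeResult:
    """Viability of one double mutant under double selection."""

    query_id: str
    gene_id: str
    double_viable: bool


@dataclass(frozen=True)
class HomologyRecord:
    """Best BLAST expect value for one gene in one target taxon.

    ``best_expect`` is infinite when no match was found.
    """

    gene_id: str
    best_expect: float
    taxon: str = "human"
    homolog_name: str | None = None

    def __post_init__(self) -> None:
        if self.best_expect < 0:
            raise InvalidRecordError("best_expect must be non-negative")


# --- delimited-file helpers -------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        for line in fh:
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: file has no data lines")


def _read_rows(path: Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header, [(line_number, row), ...]) skipping blanks and # comments."""
    delim = _sniff_delimiter(path)
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            row = next(csv.reader([line], delimiter=delim))
            if header is None:
                header = [c.strip() for c in row]
            else:
                rows.append((lineno, [c.strip() for c in row]))
    if header is None:
        raise FormatError(f"{path}: file has no data lines")
    return header, rows


def _num(text: str, path: Path, lineno: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: unparseable numeric value {text!r} in column {column!r}"
        ) from None


def _intval(text: str, path: Path, lineno: int, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: unparseable integer {text!r} in column {column!r}"
        ) from None


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _boolval(text: str, path: Path, lineno: int, column: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise FormatError(
        f"{path}:{lineno}: unparseable boolean {text!r} in column {column!r}"
    )


# --- growth-curve time series ----------------------------------------------


def read_plate_timeseries(
    path: str | Path,
    plate_map: Mapping[str, StrainLabel],
    plate_id: str,
    temperature: float,
) -> list[GrowthCurve]:
    """Parse a wide time-series export into one :class:`GrowthCurve` per mapped well.

    The first column is time in minutes; remaining columns are named by
    well.  Wells present in the file but absent from ``plate_map`` are
    ignored with a logged warning; a mapped well missing from the file is
    an error.
    """
    path = Path(path)
    header, rows = _read_rows(path)
    if len(header) < 2:
        raise FormatError(f"{path}: expected a time column plus at least one well")
    well_cols = {name: i for i, name in enumerate(header[1:], start=1)}

    times = np.array(
        [_num(row[0], path, lineno, header[0]) for lineno, row in rows], dtype=float
    )
    if len(times) >= 2 and not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: time column is not strictly increasing")

    for well in well_cols:
        if well not in plate_map:
            logger.warning("%s: unmapped well %s ignored", path, well)

    curves: list[GrowthCurve] = []
    for well in sorted(plate_map):
        if well not in well_cols:
            raise MissingWellError(f"{path}: mapped well {well} absent from file")
        col = well_cols[well]
        values = np.empty(len(rows))
        for k, (lineno, row) in enumerate(rows):
            if col >= len(row) or row[col] == "":
                raise FormatError(f"{path}:{lineno}: missing OD cell for well {well}")
            values[k] = _num(row[col], path, lineno, well)
        curves.append(
            GrowthCurve(
                plate_id=plate_id,
                well=well,
                strain=plate_map[well],
                temperature=temperature,
                times=times,
                values=values,
            )
        )
    return curves


def write_plate_timeseries(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    """Write one plate's curves as a wide TSV (time column + one column per well)."""
    path = Path(path)
    if not curves:
        raise InvalidInputError("no curves to write")
    times = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, times):
            raise InvalidInputError("curves on one plate must share a time grid")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["time"] + [c.well for c in curves])
        for k in range(len(times)):
            writer.writerow([repr(float(times[k]))] + [repr(float(c.values[k])) for c in curves])


def write_plate_map(plate_map: Mapping[str, StrainLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["well", "role", "query", "gene"])
        for well in sorted(plate_map):
            s = plate_map[well]
            writer.writerow([well, s.role, s.query_id or "", s.gene_id or ""])


def read_plate_map(path: str | Path) -> dict[str, StrainLabel]:
    path = Path(path)
    header, rows = _read_rows(path)
    _require_columns(header, ["well", "role", "query", "gene"], path)
    idx = {name: header.index(name) for name in header}
    plate_map: dict[str, StrainLabel] = {}
    for lineno, row in rows:
        well = row[idx["well"]]
        if well in plate_map:
            raise DuplicateRecordError(f"{path}:{lineno}: duplicate well {well}")
        plate_map[well] = StrainLabel(
            role=row[idx["role"]],
            query_id=row[idx["query"]] or None,
            gene_id=row[idx["gene"]] or None,
        )
    return plate_map


# --- typed tables -----------------------------------------------------------

TABLE_SCHEMAS = ("sga", "homology", "random_spore", "pvl", "brood", "apoptosis")


def _require_columns(header: Sequence[str], required: Iterable[str], path: Path) -> None:
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_table(path: str | Path, schema: str) -> list:
    """Read a delimited table and return typed, validated records.

    Supported schemas and their required columns:

    ``sga``
        query, gene, score, p (optional: allele_class, essential)
    ``homology``
        gene, best_expect (optional: taxon, homolog; an empty expect cell
        means "no match" and becomes infinity)
    ``random_spore``
        query, gene, double_viable
    ``pvl``
        genotype, rnai, n_scored, n_affected
    ``brood``
        genotype, brood_size, n_embryos, n_arrested, n_males, n_progeny_scored
    ``apoptosis``
        genotype, rnai, corpses
    """
    path = Path(path)
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}")
    header, rows = _read_rows(path)
    idx = {name: header.index(name) for name in header}

    def get(row: list[str], col: str) -> str:
        i = idx[col]
        return row[i] if i < len(row) else ""

    if schema == "sga":
        from .screen import SgaRecord

        _require_columns(header, ["query", "gene", "score", "p"], path)
        records = []
        seen: set[tuple] = set()
        for lineno, row in rows:
            allele = get(row, "allele_class") if "allele_class" in idx else ""
            rec = SgaRecord(
                query_id=get(row, "query"),
                gene_id=get(row, "gene"),
                score=_num(get(row, "score"), path, lineno, "score"),
                p_value=_num(get(row, "p"), path, lineno, "p"),
                allele_class=allele or "deletion",
                essential=_boolval(get(row, "essential"), path, lineno, "essential")
                if "essential" in idx and get(row, "essential")
                else False,
            )
            key = (rec.query_id, rec.gene_id, rec.allele_class)
            if key in seen:
                raise DuplicateRecordError(
                    f"{path}:{lineno}: duplicate (query, gene, allele) {key}"
                )
            seen.add(key)
            records.append(rec)
        return records

    if schema == "homology":
        _require_columns(header, ["gene", "best_expect"], path)
        records = []
        for lineno, row in rows:
            raw = get(row, "best_expect")
            expect = math.inf if raw == "" else _num(raw, path, lineno, "best_expect")
            records.append(
                HomologyRecord(
                    gene_id=get(row, "gene"),
                    best_expect=expect,
                    taxon=(get(row, "taxon") or "human") if "taxon" in idx else "human",
                    homolog_name=(get(row, "homolog") or None) if "homolog" in idx else None,
                )
            )
        return records

    if schema == "random_spore":
        _require_columns(header, ["query", "gene", "double_viable"], path)
        records = []
        seen = set()
        for lineno, row in rows:
            key = (get(row, "query"), get(row, "gene"))
            if key in seen:
                raise DuplicateRecordError(
                    f"{path}:{lineno}: duplicate (query, gene) {key}"
                )
            seen.add(key)
            records.append(
                RandomSporeResult(
                    query_id=key[0],
                    gene_id=key[1],
                    double_viable=_boolval(
                        get(row, "double_viable"), path, lineno, "double_viable"
                    ),
                )
            )
        return records

    if schema == "pvl":
        from .worm import PvlAssayRecord

        _require_columns(header, ["genotype", "rnai", "n_scored", "n_affected"], path)
        return [
            PvlAssayRecord(
                genotype=get(row, "genotype"),
                rnai=get(row, "rnai"),
                n_scored=_intval(get(row, "n_scored"), path, lineno, "n_scored"),
                n_affected=_intval(get(row, "n_affected"), path, lineno, "n_affected"),
            )
            for lineno, row in rows
        ]

    if schema == "brood":
        from .worm import BroodRecord

        required = [
            "genotype",
            "brood_size",
            "n_embryos",
            "n_arrested",
            "n_males",
            "n_progeny_scored",
        ]
        _require_columns(header, required, path)
        return [
            BroodRecord(
                genotype=get(row, "genotype"),
                brood_size=_intval(get(row, "brood_size"), path, lineno, "brood_size"),
                n_embryos=_intval(get(row, "n_embryos"), path, lineno, "n_embryos"),
                n_arrested=_intval(get(row, "n_arrested"), path, lineno, "n_arrested"),
                n_males=_intval(get(row, "n_males"), path, lineno, "n_males"),
                n_progeny_scored=_intval(
                    get(row, "n_progeny_scored"), path, lineno, "n_progeny_scored"
                ),
            )
            for lineno, row in rows
        ]

    # apoptosis: per-animal corpse counts per gonad arm (non-negative reals)
    _require_columns(header, ["genotype", "rnai", "corpses"], path)
    records = []
    for lineno, row in rows:
        corpses = _num(get(row, "corpses"), path, lineno, "corpses")
        if corpses < 0:
            raise FormatError(f"{path}:{lineno}: negative corpse count")
        records.append(
            {"genotype": get(row, "genotype"), "rnai": get(row, "rnai"), "corpses": corpses}
        )
    return records


# --- network output ---------------------------------------------------------

NETWORK_FORMATS = ("tsv", "sif", "graphml")


def write_network(edges: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write SL/SS network edges, sorted by (query, gene) for byte stability.

    TSV carries every field; SIF encodes the class as the relation token
    (``query SL gene``); GraphML carries class, strength and provenance
    as edge attributes.
    """
    path = Path(path)
    if format not in NETWORK_FORMATS:
        raise InvalidInputError(f"unknown network format {format!r}")
    ordered = sorted(edges, key=lambda e: (e.query_id, e.gene_id))

    if format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["query", "gene", "class", "strength", "provenance"])
            for e in ordered:
                writer.writerow(
                    [
                        e.query_id,
                        e.gene_id,
                        e.edge_class,
                        "" if e.strength is None else repr(float(e.strength)),
                        e.provenance,
                    ]
                )
        return

    if format == "sif":
        with open(path, "w") as fh:
            for e in ordered:
                fh.write(f"{e.query_id} {e.edge_class} {e.gene_id}\n")
        return

    import networkx as nx

    graph = nx.Graph()
    for e in ordered:
        attrs = {"interaction_class": e.edge_class, "provenance": e.provenance}
        if e.strength is not None:
            attrs["strength"] = float(e.strength)
        graph.add_edge(e.query_id, e.gene_id, **attrs)
    nx.write_graphml(graph, path)


def read_network(path: str | Path) -> list:
    """Read back a TSV network written by :func:`write_network`."""
    from .interaction import NetworkEdge

    path = Path(path)
    header, rows = _read_rows(path)
    _require_columns(header, ["query", "gene", "class", "strength", "provenance"], path)
    idx = {name: header.index(name) for name in header}
    edges = []
    for lineno, row in rows:
        raw = row[idx["strength"]] if idx["strength"] < len(row) else ""
        edges.append(
            NetworkEdge(
                query_id=row[idx["query"]],
                gene_id=row[idx["gene"]],
                edge_class=row[idx["class"]],
                strength=None if raw == "" else _num(raw, path, lineno, "strength"),
                provenance=row[idx["provenance"]],
            )
        )
    return edges
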