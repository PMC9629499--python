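"""Strain trait database: parsing, extremophily classification, survey stats.

Each record carries an isolate's cardinal growth data (optimum and range
for temperature, pH, salinity and pressure), its adaptation labels, and
electron-donor usage by compound class.  Optima reported as a range (e.g.
30-35 C) are reduced to their midpoint before classification.  Missing
values ("ND", not determined) exclude a strain from classification for
that parameter.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

log = logging.getLogger(__name__)

__all__ = [
    "PARAMS",
    "DONOR_CLASSES",
    "TEMPERATURE_LABELS",
    "PH_LABELS",
    "ALL_LABELS",
    "StrainRecord",
    "AdaptationThresholds",
    "StrainTableError",
    "parse_strain_table",
    "write_strain_table",
    "optimum_midpoint",
    "classify_adaptations",
    "is_polyextremophile",
    "summarize_counts",
    "envelope_extrema",
    "sweet_spot_stats",
    "donor_use_crosstab",
]

PARAMS = ("T", "pH", "NaCl", "P")
TEMPERATURE_LABELS = ("psychrophile", "thermophile", "hyperthermophile")
PH_LABELS = ("acidophile", "alkaliphile")
ALL_LABELS = TEMPERATURE_LABELS + PH_LABELS + ("halophile", "piezophile")

#: electron-donor compound classes used in the survey cross-tabs
DONOR_CLASSES = (
    "carboxylates",
    "alcohols_phenols",
    "sugars",
    "amines_amino_acids_proteins",
    "aldehydes_esters_ketones",
    "hydrogen",
    "other",
)
USED, NOT_USED, UNTESTED = "used", "tested-not-used", "untested"


class StrainTableError(ValueError):
    """Malformed or inconsistent strain-table content."""


Optimum = float | tuple[float, float]  # a scalar or an ordered (lo, hi) pair


def optimum_midpoint(value: Optimum) -> float:
    """Midpoint of an optimum pair (e.g. (30, 35) -> 32.5); identity on a scalar."""
    if isinstance(value, tuple):
        lo, hi = value
        if lo > hi:
            raise ValueError(f"inverted optimum pair: {value}")
        return (lo + hi) / 2.0
    return float(value)


@dataclass(frozen=True)
class StrainRecord:
    """One isolate's cardinal growth data, labels, and substrate usage.

    ``*_opt`` is a scalar or an ordered pair; ``*_min``/``*_max`` are the
    growth-range endpoints.  Any of these may be None (not determined).
    """

    name: str
    domain: str = ""
    taxon_class: str = ""
    family: str = ""
    labels: frozenset[str] = frozenset()
    T_opt: Optimum | None = None
    T_min: float | None = None
    T_max: float | None = None
    pH_opt: Optimum | None = None
    pH_min: float | None = None
    pH_max: float | None = None
    NaCl_opt: Optimum | None = None
    NaCl_min: float | None = None
    NaCl_max: float | None = None
    P_opt: Optimum | None = None
    P_min: float | None = None
    P_max: float | None = None
    donors: dict = field(default_factory=dict)  # donor class -> used/tested-not-used/untested
    acceptors: dict = field(default_factory=dict)
    habitat: str = ""
    origin: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        # Published tables occasionally print an optimum outside the printed
        # range; records carry the data as reported and the inconsistency is
        # surfaced via validate() / a warning rather than refused.
        for problem in self.validate():
            log.warning("%s", problem)

    def validate(self) -> list[str]:
        """Internal-consistency problems (range_min <= optimum <= range_max)."""
        problems = []
        for p in PARAMS:
            opt, lo, hi = (getattr(self, f"{p}_opt"), getattr(self, f"{p}_min"),
                           getattr(self, f"{p}_max"))
            if opt is not None and lo is not None and hi is not None:
                mid = optimum_midpoint(opt)
                if not (lo <= mid <= hi):
                    problems.append(
                        f"{self.name}: {p} optimum {opt} outside range ({lo}, {hi})"
                    )
        return problems

    def optimum(self, param: str) -> float | None:
        """Midpoint optimum for a parameter, or None if not determined."""
        opt = getattr(self, f"{param}_opt")
        return None if opt is None else optimum_midpoint(opt)

    def donor_status(self, donor_class: str) -> str:
        return self.donors.get(donor_class, UNTESTED)


@dataclass(frozen=True)
class AdaptationThresholds:
    """Cutoffs on cardinal optima defining each extremophilic adaptation.

    Temperature bands are non-overlapping: psychrophile T_opt < 20 C,
    thermophile 50 <= T_opt < 72 C, hyperthermophile T_opt >= 72 C.
    """

    psychrophile_T_below: float = 20.0
    thermophile_T_from: float = 50.0
    hyperthermophile_T_from: float = 72.0
    acidophile_pH_below: float = 5.0
    alkaliphile_pH_from: float = 9.0
    halophile_NaCl_from: float = 5.0
    piezophile_P_from: float = 10.0

    def __post_init__(self) -> None:
        if not (
            self.psychrophile_T_below
            <= self.thermophile_T_from
            < self.hyperthermophile_T_from
        ):
            raise ValueError("temperature bands must be ordered and non-overlapping")
        if not self.acidophile_pH_below < self.alkaliphile_pH_from:
            raise ValueError("acidophile cutoff must lie below alkaliphile cutoff")


def classify_adaptations(
    rec: StrainRecord, th: AdaptationThresholds = AdaptationThresholds()
) -> frozenset[str]:
    """Adaptation labels earned by a strain's cardinal optima (midpoints).

    Parameters that are not determined yield no label; at most one
    temperature and one pH label are possible.
    """
    labels = set()
    t = rec.optimum("T")
    if t is not None:
        if t < th.psychrophile_T_below:
            labels.add("psychrophile")
        elif t >= th.hyperthermophile_T_from:
            labels.add("hyperthermophile")
        elif t >= th.thermophile_T_from:
            labels.add("thermophile")
    ph = rec.optimum("pH")
    if ph is not None:
        if ph < th.acidophile_pH_below:
            labels.add("acidophile")
        elif ph >= th.alkaliphile_pH_from:
            labels.add("alkaliphile")
    nacl = rec.optimum("NaCl")
    if nacl is not None and nacl >= th.halophile_NaCl_from:
        labels.add("halophile")
    p = rec.optimum("P")
    if p is not None and p >= th.piezophile_P_from:
        labels.add("piezophile")
    return frozenset(labels)


def is_polyextremophile(labels: frozenset[str]) -> bool:
    """Extremophilic with respect to more than one parameter."""
    return len(labels) >= 2


# ---------------------------------------------------------------------------
# table I/O

_HEADER = (
    ["name", "domain", "taxon_class", "family", "labels"]
    + [f"{p}_{k}" for p in PARAMS for k in ("opt", "min", "max")]
    + [f"donor_{c}" for c in DONOR_CLASSES]
    + ["habitat", "origin", "notes"]
)


def _parse_cell(text: str, *, where: str) -> float | tuple[float, float] | None:
    """Parse a numeric cell: 'ND'/blank -> None, 'lo - hi' -> pair, else float."""
    text = (text or "").strip()
    if text in ("", "ND", "nd", "NA", "NaN"):
        return None
    # a range like "30 - 35" or "-1.8 - 19": split on a spaced hyphen so
    # leading minus signs survive
    if " - " in text:
        parts = text.split(" - ")
        if len(parts) != 2:
            raise StrainTableError(f"{where}: cannot parse range {text!r}")
        lo, hi = (_parse_cell(p, where=where) for p in parts)
        if lo is None or hi is None:
            return lo if hi is None else hi  # half-open range, e.g. "1.5 - ND"
        return (lo, hi)
    try:
        return float(text)
    except ValueError:
        raise StrainTableError(f"{where}: malformed numeric field {text!r}") from None


def _scalar(value, *, where: str) -> float | None:
    if isinstance(value, tuple):
        raise StrainTableError(f"{where}: expected a single value, got range {value}")
    return value


def _merge(a: StrainRecord, b: StrainRecord, *, where: str) -> StrainRecord:
    """Merge two rows for the same strain (e.g. listed in two sections)."""
    updates: dict = {"labels": a.labels | b.labels}
    for f in [x for p in PARAMS for x in (f"{p}_opt", f"{p}_min", f"{p}_max")]:
        va, vb = getattr(a, f), getattr(b, f)
        if va is not None and vb is not None and va != vb:
            raise StrainTableError(
                f"{where}: conflicting {f} for {a.name!r}: {va} vs {vb}"
            )
        updates[f] = va if va is not None else vb
    donors = dict(b.donors)
    donors.update({k: v for k, v in a.donors.items() if v != UNTESTED})
    updates["donors"] = donors
    updates["notes"] = "; ".join(x for x in (a.notes, b.notes) if x)
    return replace(a, **updates)


def parse_strain_table(path: str | Path) -> list[StrainRecord]:
    """Read a strain table (TSV or CSV by extension) into StrainRecords.

    Accepts either a ``labels`` column (semicolon-separated) or a
    ``section`` column naming one adaptation per row; rows repeating a
    strain name are merged into a single record carrying all labels.
    """
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    records: dict[str, StrainRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for lineno, row in enumerate(reader, start=2):
            where = f"{path.name}:{lineno}"
            labels = set()
            if row.get("labels"):
                labels |= {s.strip() for s in row["labels"].split(";") if s.strip()}
            if row.get("section") and row["section"].strip():
                labels.add(row["section"].strip())
            fields: dict = {}
            for p in PARAMS:
                fields[f"{p}_opt"] = _parse_cell(row.get(f"{p}_opt", ""), where=where)
                fields[f"{p}_min"] = _scalar(
                    _parse_cell(row.get(f"{p}_min", ""), where=where), where=where
                )
                fields[f"{p}_max"] = _scalar(
                    _parse_cell(row.get(f"{p}_max", ""), where=where), where=where
                )
            donors = {}
            for c in DONOR_CLASSES:
                status = (row.get(f"donor_{c}") or UNTESTED).strip() or UNTESTED
                if status not in (USED, NOT_USED, UNTESTED):
                    raise StrainTableError(f"{where}: bad donor status {status!r}")
                donors[c] = status
            rec = StrainRecord(
                name=row["name"].strip(),
                domain=(row.get("domain") or "").strip(),
                taxon_class=(row.get("taxon_class") or "").strip(),
                family=(row.get("family") or "").strip(),
                labels=frozenset(labels),
                donors=donors,
                habitat=(row.get("habitat") or "").strip(),
                origin=(row.get("origin") or "").strip(),
                notes=(row.get("notes") or "").strip(),
                **fields,
            )
            if rec.name in records:
                rec = _merge(records[rec.name], rec, where=where)
            records[rec.name] = rec
    return list(records.values())


def _format_cell(value) -> str:
    if value is None:
        return "ND"
    if isinstance(value, tuple):
        return f"{value[0]:g} - {value[1]:g}"
    return f"{value:g}"


def write_strain_table(db: list[StrainRecord], path: str | Path) -> None:
    """Write records in the same dialect parse_strain_table reads."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(_HEADER)
        for rec in db:
            row = [rec.name, rec.domain, rec.taxon_class, rec.family,
                   ";".join(sorted(rec.labels))]
            for p in PARAMS:
                row += [
                    _format_cell(getattr(rec, f"{p}_opt")),
                    _format_cell(getattr(rec, f"{p}_min")),
                    _format_cell(getattr(rec, f"{p}_max")),
                ]
            row += [rec.donor_status(c) for c in DONOR_CLASSES]
            row += [rec.habitat, rec.origin, rec.notes]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# survey statistics

def summarize_counts(
    db: list[StrainRecord], th: AdaptationThresholds = AdaptationThresholds()
) -> dict[str, int]:
    """Unique-strain counts per adaptation label, plus the polyextremophile,
    extremophile and total tallies."""
    counts = {label: 0 for label in ALL_LABELS}
    counts["polyextremophile"] = 0
    counts["extremophile"] = 0
    counts["total"] = len(db)
    for rec in db:
        labels = classify_adaptations(rec, th)
        for label in labels:
            counts[label] += 1
        if labels:
            counts["extremophile"] += 1
        if is_polyextremophile(labels):
            counts["polyextremophile"] += 1
    return counts


def envelope_extrema(
    db: list[StrainRecord],
) -> tuple[float | None, float | None, float | None, float | None]:
    """(T_min, T_max, pH_min, pH_max) over all records' growth-range endpoints."""
    if not db:
        raise ValueError("empty strain database")
    t_lo = [r.T_min for r in db if r.T_min is not None]
    t_hi = [r.T_max for r in db if r.T_max is not None]
    p_lo = [r.pH_min for r in db if r.pH_min is not None]
    p_hi = [r.pH_max for r in db if r.pH_max is not None]
    return (
        min(t_lo) if t_lo else None,
        max(t_hi) if t_hi else None,
        min(p_lo) if p_lo else None,
        max(p_hi) if p_hi else None,
    )


def sweet_spot_stats(
    db: list[StrainRecord],
    T_interval: tuple[float, float] = (20.0, 40.0),
    pH_interval: tuple[float, float] = (6.0, 8.0),
) -> tuple[int, int, int]:
    """Occupancy of the mesophilic/circumneutral growth-optimum sweet spot.

    Returns (strains with T optimum in [20, 40] C, strains with pH optimum
    in [6, 8], strains with at least one optimum known that fall in
    neither interval).
    """
    n_T = n_pH = n_outside = 0
    for rec in db:
        t, ph = rec.optimum("T"), rec.optimum("pH")
        in_T = t is not None and T_interval[0] <= t <= T_interval[1]
        in_pH = ph is not None and pH_interval[0] <= ph <= pH_interval[1]
        n_T += in_T
        n_pH += in_pH
        if (t is not None or ph is not None) and not (in_T or in_pH):
            n_outside += 1
    return n_T, n_pH, n_outside


def donor_use_crosstab(
    db: list[StrainRecord],
    by_adaptation: bool = False,
    th: AdaptationThresholds = AdaptationThresholds(),
) -> dict:
    """Per donor-class (used, tested) tallies, overall or per adaptation group.

    ``tested`` counts strains with status used or tested-not-used; untested
    strains are excluded from the denominator.  With ``by_adaptation`` the
    tallies are repeated per adaptation label (a strain with several labels
    contributes to each of its groups), with non-extremophiles under
    ``"none"`` and the overall tallies under ``"all"``.
    """

    def tally(records: list[StrainRecord]) -> dict[str, tuple[int, int]]:
        out = {}
        for c in DONOR_CLASSES:
            used = sum(r.donor_status(c) == USED for r in records)
            tested = sum(r.donor_status(c) != UNTESTED for r in records)
            out[c] = (used, tested)
        return out

    if not by_adaptation:
        return tally(db)
    groups: dict[str, list[StrainRecord]] = {"all": list(db), "none": []}
    for rec in db:
        labels = classify_adaptations(rec, th)
        if not labels:
            groups["none"].append(rec)
        for label in labels:
            groups.setdefault(label, []).append(rec)
    return {g: tally(records) for g, records in groups.items()}
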