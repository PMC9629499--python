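"""Project strain growth envelopes onto a thermodynamic habitability grid.

Answers two questions the survey poses: do any reported growth conditions
exceed the thermodynamic growth threshold of their redox couple, and which
growth-favourable (pH, T) cells are intersected by no known strain's
growth envelope (the apparently unoccupied favourable regions)?

Range extremes are evaluated pairing each extreme with the strain's
optimum in the other parameter (pH_min and pH_max at T_opt; T_min and
T_max at pH_opt), not extreme-with-extreme.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .habitability import FAVOURABLE, HabitabilityGrid, favourable_region
from .strains import StrainRecord

log = logging.getLogger(__name__)

__all__ = [
    "StrainPlacement",
    "OverlayReport",
    "locate_strain",
    "flag_exceedances",
    "empty_favourable_regions",
    "build_overlay_report",
]


@dataclass(frozen=True)
class StrainPlacement:
    """A strain's optimum cell plus the classes at its range-extreme points."""

    name: str
    cell: tuple[float, float]  # (pH, T_C) of the optimum's cell
    optimum_class: str
    extreme_classes: dict[str, str] = field(default_factory=dict)

    @property
    def exceeds(self) -> bool:
        """True if any evaluated point falls outside the growth-favourable class."""
        classes = [self.optimum_class, *self.extreme_classes.values()]
        return any(c != FAVOURABLE for c in classes)


def locate_strain(grid: HabitabilityGrid, rec: StrainRecord) -> tuple[tuple[float, float], str]:
    """Nearest grid cell to a strain's (pH, T) optimum and its class.

    Requires both optima; raises if the optimum lies outside grid bounds.
    """
    ph, t = rec.optimum("pH"), rec.optimum("T")
    if ph is None or t is None:
        raise ValueError(f"{rec.name}: both pH and T optima required to locate strain")
    try:
        i, j = grid.cell_index(ph, t)
    except ValueError as exc:
        raise ValueError(f"{rec.name}: {exc}") from exc
    cell = (float(grid.pH_values[i]), float(grid.T_values[j]))
    return cell, str(grid.classes[i, j])


def _clip(v: float, lo: float, hi: float) -> float:
    return min(max(v, lo), hi)


def _placement(grid: HabitabilityGrid, rec: StrainRecord) -> StrainPlacement:
    cell, opt_class = locate_strain(grid, rec)
    ph_opt, t_opt = rec.optimum("pH"), rec.optimum("T")
    points = {
        "pH_min@T_opt": (rec.pH_min, t_opt),
        "pH_max@T_opt": (rec.pH_max, t_opt),
        "T_min@pH_opt": (ph_opt, rec.T_min),
        "T_max@pH_opt": (ph_opt, rec.T_max),
    }
    extreme_classes = {}
    for tag, (ph, t) in points.items():
        if ph is None or t is None:
            continue
        # evaluation points may sit just outside the grid extent; clip to it
        ph = _clip(ph, grid.pH_values[0], grid.pH_values[-1])
        t = _clip(t, grid.T_values[0], grid.T_values[-1])
        i, j = grid.cell_index(ph, t)
        extreme_classes[tag] = str(grid.classes[i, j])
    return StrainPlacement(
        name=rec.name, cell=cell, optimum_class=opt_class, extreme_classes=extreme_classes
    )


def place_strains(
    grid: HabitabilityGrid, db: list[StrainRecord]
) -> list[StrainPlacement]:
    """Placements for every strain with both optima; others skipped with a warning."""
    placements = []
    for rec in db:
        if rec.optimum("pH") is None or rec.optimum("T") is None:
            log.warning("skipping %s: missing pH or T optimum", rec.name)
            continue
        placements.append(_placement(grid, rec))
    return placements


def flag_exceedances(
    db: list[StrainRecord], grid: HabitabilityGrid
) -> list[str]:
    """Strains whose optimum or any paired range extreme is not growth-favourable."""
    return [p.name for p in place_strains(grid, db) if p.exceeds]


def _range_interval(rec: StrainRecord, param: str) -> tuple[float, float] | None:
    """Growth interval along one axis: range endpoints, falling back to the optimum."""
    opt = rec.optimum(param)
    lo, hi = getattr(rec, f"{param}_min"), getattr(rec, f"{param}_max")
    if lo is None and hi is None and opt is None:
        return None
    pts = [p for p in (lo, hi, opt) if p is not None]
    return (min(pts), max(pts))


def empty_favourable_regions(
    db: list[StrainRecord], grid: HabitabilityGrid
) -> set[tuple[float, float]]:
    """Growth-favourable cells intersected by no strain's growth-range rectangle.

    A strain's rectangle is pH_range x T_range; a strain missing one axis
    entirely constrains cells only along its known axis (it covers the full
    grid extent along the unknown one).
    """
    half_ph, half_t = grid.spec.pH_step / 2, grid.spec.T_step / 2
    empty = set()
    for (ph, t) in favourable_region(grid):
        occupied = False
        for rec in db:
            ph_iv = _range_interval(rec, "pH")
            t_iv = _range_interval(rec, "T")
            if ph_iv is None and t_iv is None:
                continue
            ph_ok = ph_iv is None or (ph_iv[0] <= ph + half_ph and ph_iv[1] >= ph - half_ph)
            t_ok = t_iv is None or (t_iv[0] <= t + half_t and t_iv[1] >= t - half_t)
            if ph_ok and t_ok:
                occupied = True
                break
        if not occupied:
            empty.add((ph, t))
    return empty


@dataclass
class OverlayReport:
    """Per-strain placements, exceedance list, and unoccupied favourable cells."""

    donor: str
    acceptor: str
    placements: list[StrainPlacement]
    exceedances: list[str]
    empty_cells: set[tuple[float, float]]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "donor": self.donor,
            "acceptor": self.acceptor,
            "strains": [
                {
                    "name": p.name,
                    "cell": list(p.cell),
                    "optimum_class": p.optimum_class,
                    "extreme_classes": p.extreme_classes,
                }
                for p in self.placements
            ],
            "exceedances": self.exceedances,
            "empty_favourable_cells": sorted(list(c) for c in self.empty_cells),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_overlay_report(
    db: list[StrainRecord], grid: HabitabilityGrid
) -> OverlayReport:
    placements = place_strains(grid, db)
    return OverlayReport(
        donor=grid.donor,
        acceptor=grid.acceptor,
        placements=placements,
        exceedances=[p.name for p in placements if p.exceeds],
        empty_cells=empty_favourable_regions(db, grid),
    )
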