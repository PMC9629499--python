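"""Per-electron Gibbs energy of iron reduction over a pH-temperature grid.

Builds the habitability map for one donor/mineral couple: below pH 3 the
ferric acceptor is treated as aqueous Fe3+ (ferric oxides are unstable at
low pH) and the couple's aqueous reaction is used; at pH 3 and above the
mineral reaction is used.  Each cell is classified against a maintenance
-energy threshold of -20 kJ per electron transferred: values at or below
-20 are favourable for growth, values strictly between -20 and 0 can
support survival and maintenance only, and values at or above 0 are
thermodynamically infeasible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .thermo import (
    ActivityModel,
    MINERAL_ACCEPTORS,
    Reaction,
    SpeciesTable,
    balance_reaction,
    celsius_to_kelvin,
    delta_g_per_electron,
)

__all__ = [
    "GridSpec",
    "FavourabilityThresholds",
    "HabitabilityGrid",
    "FAVOURABLE",
    "MAINTENANCE_ONLY",
    "INFEASIBLE",
    "acceptor_phase",
    "classify_favourability",
    "build_grid",
    "grid_argmin",
    "favourable_region",
]

FAVOURABLE = "favourable"
MAINTENANCE_ONLY = "maintenance-only"
INFEASIBLE = "infeasible"

#: pH below which ferric iron is assumed aqueous, regardless of acceptor
AQUEOUS_PH_CUTOFF = 3.0


@dataclass(frozen=True)
class GridSpec:
    """pH and temperature axes of the habitability space (T in Celsius)."""

    pH_min: float = 0.0
    pH_max: float = 14.0
    pH_step: float = 0.5
    T_min: float = -10.0
    T_max: float = 130.0
    T_step: float = 5.0

    def __post_init__(self) -> None:
        if self.pH_step <= 0 or self.T_step <= 0:
            raise ValueError("grid steps must be positive")
        if not (0 <= self.pH_min < self.pH_max <= 14):
            raise ValueError("pH bounds must lie within 0-14")
        if not (-10 <= self.T_min < self.T_max <= 130):
            raise ValueError("temperature bounds must lie within -10-130 C")

    @property
    def pH_values(self) -> np.ndarray:
        n = int(round((self.pH_max - self.pH_min) / self.pH_step)) + 1
        return self.pH_min + self.pH_step * np.arange(n)

    @property
    def T_values(self) -> np.ndarray:
        n = int(round((self.T_max - self.T_min) / self.T_step)) + 1
        return self.T_min + self.T_step * np.arange(n)


@dataclass(frozen=True)
class FavourabilityThresholds:
    """Energetic class boundaries in kJ per electron transferred."""

    growth_threshold: float = -20.0
    feasibility_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.growth_threshold < self.feasibility_threshold:
            raise ValueError("growth threshold must lie below feasibility threshold")


def acceptor_phase(pH: float) -> str:
    """Phase of the ferric acceptor at a given pH: 'aqueous' iff pH < 3."""
    if not 0 <= pH <= 14:
        raise ValueError(f"pH out of range: {pH}")
    return "aqueous" if pH < AQUEOUS_PH_CUTOFF else "mineral"


def classify_favourability(
    g: float, th: FavourabilityThresholds = FavourabilityThresholds()
) -> str:
    """Energetic class of a per-electron Gibbs energy value."""
    if not np.isfinite(g):
        raise ValueError(f"non-finite per-electron Gibbs energy: {g}")
    if g <= th.growth_threshold:
        return FAVOURABLE
    if g < th.feasibility_threshold:
        return MAINTENANCE_ONLY
    return INFEASIBLE


@dataclass
class HabitabilityGrid:
    """Per-electron Gibbs energies and favourability classes over pH x T.

    ``values`` is indexed [i_pH, j_T] in kJ per electron; ``classes`` and
    ``phases`` are parallel string arrays.
    """

    donor: str
    acceptor: str
    spec: GridSpec
    thresholds: FavourabilityThresholds
    values: np.ndarray
    classes: np.ndarray
    phases: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def pH_values(self) -> np.ndarray:
        return self.spec.pH_values

    @property
    def T_values(self) -> np.ndarray:
        return self.spec.T_values

    def cell_index(self, pH: float, T_C: float) -> tuple[int, int]:
        """Nearest cell to a (pH, T) point; boundary ties go to the lower index."""
        pHs, Ts = self.pH_values, self.T_values
        if not (pHs[0] <= pH <= pHs[-1]) or not (Ts[0] <= T_C <= Ts[-1]):
            raise ValueError(f"point (pH={pH}, T={T_C} C) outside grid bounds")
        # distance round-down: midpoint between two cells belongs to the lower one
        i = int(np.searchsorted(pHs, pH - self.spec.pH_step / 2, side="left"))
        j = int(np.searchsorted(Ts, T_C - self.spec.T_step / 2, side="left"))
        return min(i, len(pHs) - 1), min(j, len(Ts) - 1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per cell (pH, T_C, dG_per_e_kJ, class, phase)."""
        i, j = np.meshgrid(
            np.arange(len(self.pH_values)), np.arange(len(self.T_values)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "pH": self.pH_values[i.ravel()],
                "T_C": self.T_values[j.ravel()],
                "dG_per_e_kJ": self.values.ravel(),
                "class": self.classes.ravel(),
                "phase": self.phases.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the long-format CSV preceded by a JSON metadata header line."""
        path = Path(path)
        header = {
            "donor": self.donor,
            "acceptor": self.acceptor,
            "growth_threshold_kJ_per_e": self.thresholds.growth_threshold,
            "feasibility_threshold_kJ_per_e": self.thresholds.feasibility_threshold,
            **self.metadata,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            self.to_frame().to_csv(fh, index=False)

    def plot(self, ax=None):
        """Three-class heatmap (favourable / maintenance-only / infeasible)."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        if ax is None:
            _, ax = plt.subplots()
        order = [FAVOURABLE, MAINTENANCE_ONLY, INFEASIBLE]
        codes = np.vectorize(order.index)(self.classes)
        cmap = ListedColormap(["#2ca02c", "#d62728", "#000000"])
        ax.pcolormesh(self.pH_values, self.T_values, codes.T, cmap=cmap, vmin=0, vmax=2)
        ax.set_xlabel("pH")
        ax.set_ylabel("temperature (\N{DEGREE SIGN}C)")
        ax.set_title(f"{self.donor} / {self.acceptor}")
        return ax


def build_grid(
    donor: str,
    acceptor: str,
    spec: GridSpec = GridSpec(),
    act: ActivityModel | None = None,
    thresholds: FavourabilityThresholds = FavourabilityThresholds(),
    table: SpeciesTable | None = None,
) -> HabitabilityGrid:
    """Evaluate a donor/mineral couple over the pH-temperature grid.

    ``acceptor`` must be a mineral (goethite, hematite or ferrihydrite);
    cells below pH 3 automatically switch to the same donor's aqueous-Fe3+
    reaction.
    """
    if acceptor not in MINERAL_ACCEPTORS:
        raise ValueError(
            f"grid acceptor must be a ferric mineral {MINERAL_ACCEPTORS}, got {acceptor!r}"
        )
    if table is None:
        table = SpeciesTable.default()
    if act is None:
        act = ActivityModel()

    mineral_rxn = balance_reaction(donor, acceptor, table)
    aqueous_rxn = balance_reaction(donor, "ferric-aqueous", table)

    pHs, Ts = spec.pH_values, spec.T_values
    values = np.empty((len(pHs), len(Ts)))
    classes = np.empty_like(values, dtype=object)
    phases = np.empty_like(values, dtype=object)
    for i, pH in enumerate(pHs):
        phase = acceptor_phase(pH)
        rxn = aqueous_rxn if phase == "aqueous" else mineral_rxn
        for j, T_C in enumerate(Ts):
            try:
                g = delta_g_per_electron(rxn, celsius_to_kelvin(T_C), pH, act, table)
            except Exception as exc:  # attach cell coordinates to any thermo error
                raise type(exc)(f"at cell (pH={pH}, T={T_C} C): {exc}") from exc
            values[i, j] = g
            classes[i, j] = classify_favourability(g, thresholds)
            phases[i, j] = phase
    return HabitabilityGrid(
        donor=donor,
        acceptor=acceptor,
        spec=spec,
        thresholds=thresholds,
        values=values,
        classes=classes,
        phases=phases,
        metadata={"activities": dict(act.activities)},
    )


def grid_argmin(
    grid: HabitabilityGrid, restrict_to_phase: str | None = None
) -> tuple[float, float, float]:
    """(pH, T_C, value) of the minimum cell; ties go to lower pH, then lower T."""
    mask = (
        np.ones_like(grid.values, dtype=bool)
        if restrict_to_phase is None
        else grid.phases == restrict_to_phase
    )
    if not mask.any():
        raise ValueError("no grid cells in the requested phase")
    best = None
    for i, pH in enumerate(grid.pH_values):
        for j, T_C in enumerate(grid.T_values):
            if not mask[i, j]:
                continue
            v = grid.values[i, j]
            if best is None or v < best[2]:
                best = (pH, T_C, v)
    return best


def favourable_region(grid: HabitabilityGrid) -> set[tuple[float, float]]:
    """Set of (pH, T_C) coordinates of all growth-favourable cells."""
    idx = np.argwhere(grid.classes == FAVOURABLE)
    return {(grid.pH_values[i], grid.T_values[j]) for i, j in idx}
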