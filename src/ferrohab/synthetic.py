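"""Synthetic strain databases with the survey's statistical structure.

The generator emulates the observed cross-shaped distribution of growth
optima in (T, pH) space: a dense mesophilic/circumneutral sweet spot,
arms along the temperature axis at neutral pH and along the pH axis at
mesophilic temperature, and a rare acidophilic-hyperthermophile corner
population.  It is a transparent stand-in for the real survey, not a
model stated by any source of real data: every record it emits is
synthetic.

Optima are drawn from a truncated-normal mixture; growth ranges are the
optimum plus/minus log-normal half-widths; donor usage is assigned
adaptation-dependently (by default every hyperthermophile tested on
hydrogen uses it); salinity and pressure data carry realistic
missing-value rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.stats import truncnorm

from .strains import (
    DONOR_CLASSES,
    NOT_USED,
    UNTESTED,
    USED,
    AdaptationThresholds,
    StrainRecord,
    classify_adaptations,
    parse_strain_table,
)

__all__ = ["COMPONENTS", "MixtureComponent", "SyntheticConfig",
           "generate_database", "make_table1_fixture"]

T_BOUNDS = (-10.0, 130.0)
PH_BOUNDS = (0.0, 14.0)


@dataclass(frozen=True)
class MixtureComponent:
    """Location/scale of one (T_opt, pH_opt) mixture component, Celsius/pH units."""

    T_loc: float
    T_scale: float
    pH_loc: float
    pH_scale: float


#: the cross-shaped mixture: sweet spot, four arms, and the rare corner
COMPONENTS = {
    "sweet_spot": MixtureComponent(30.0, 5.0, 7.0, 0.5),
    "cold_arm": MixtureComponent(12.0, 4.0, 7.0, 0.5),
    "hot_arm": MixtureComponent(70.0, 12.0, 7.0, 0.7),
    "acid_arm": MixtureComponent(30.0, 5.0, 2.8, 0.8),
    "alkali_arm": MixtureComponent(35.0, 8.0, 9.5, 0.4),
    "acid_hot_corner": MixtureComponent(85.0, 8.0, 2.8, 0.8),
}

# Default weights follow the surveyed fractions: ~57% non-extremophile,
# temperature arm dominant among extremophiles, corner populations rare.
DEFAULT_WEIGHTS = {
    "sweet_spot": 0.57,
    "cold_arm": 0.03,
    "hot_arm": 0.27,
    "acid_arm": 0.06,
    "alkali_arm": 0.04,
    "acid_hot_corner": 0.03,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey generator."""

    n_strains: int = 141
    seed: int = 0
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    components: dict[str, MixtureComponent] = field(
        default_factory=lambda: dict(COMPONENTS)
    )
    # log-normal half-width parameters (log-space mean, sigma)
    T_halfwidth_log: tuple[float, float] = (np.log(10.0), 0.4)
    pH_halfwidth_log: tuple[float, float] = (np.log(1.3), 0.4)
    # probability that a parameter is reported at all
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {"pH": 0.05, "NaCl": 0.60, "P": 0.90}
    )
    halophile_rate: float = 0.03  # marginal, among strains with NaCl data
    piezophile_rate: float = 0.015
    # donor usage: per-class probability of having been tested, and of use
    donor_tested_prob: dict[str, float] = field(
        default_factory=lambda: {
            "carboxylates": 0.85,
            "alcohols_phenols": 0.6,
            "sugars": 0.45,
            "amines_amino_acids_proteins": 0.35,
            "aldehydes_esters_ketones": 0.11,
            "hydrogen": 0.55,
            "other": 0.1,
        }
    )
    donor_use_prob: dict[str, float] = field(
        default_factory=lambda: {
            "carboxylates": 0.8,
            "alcohols_phenols": 0.68,
            "sugars": 0.5,
            "amines_amino_acids_proteins": 0.55,
            "aldehydes_esters_ketones": 0.4,
            "hydrogen": 0.6,
            "other": 0.3,
        }
    )
    hydrogen_use_prob_hyperthermophile: float = 1.0
    thresholds: AdaptationThresholds = field(default_factory=AdaptationThresholds)

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()}")
        if set(self.weights) - set(self.components):
            raise ValueError("weight key without a matching component")
        for name, comp in self.components.items():
            if comp.T_scale <= 0 or comp.pH_scale <= 0:
                raise ValueError(f"non-positive scale in component {name!r}")
        for p, rate in self.missing_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missing rate for {p} outside [0, 1]")


def _trunc_normal(rng: np.random.Generator, loc: float, scale: float,
                  bounds: tuple[float, float]) -> float:
    a, b = (bounds[0] - loc) / scale, (bounds[1] - loc) / scale
    return float(truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))


def generate_database(
    cfg: SyntheticConfig, return_components: bool = False
) -> list[StrainRecord] | tuple[list[StrainRecord], list[str]]:
    """Draw a reproducible synthetic strain database from the mixture model.

    With ``return_components`` the true component of each strain is
    returned alongside, for parameter-recovery checks.
    """
    rng = np.random.default_rng(cfg.seed)
    names = list(cfg.weights)
    weights = np.array([cfg.weights[n] for n in names], dtype=float)
    records: list[StrainRecord] = []
    component_truth: list[str] = []
    for k in range(cfg.n_strains):
        comp_name = names[int(rng.choice(len(names), p=weights))]
        comp = cfg.components[comp_name]
        t_opt = round(_trunc_normal(rng, comp.T_loc, comp.T_scale, T_BOUNDS), 1)
        ph_opt = round(_trunc_normal(rng, comp.pH_loc, comp.pH_scale, PH_BOUNDS), 2)

        mu_t, sd_t = cfg.T_halfwidth_log
        t_lo = round(max(T_BOUNDS[0], t_opt - rng.lognormal(mu_t, sd_t)), 1)
        t_hi = round(min(T_BOUNDS[1], t_opt + rng.lognormal(mu_t, sd_t)), 1)
        mu_p, sd_p = cfg.pH_halfwidth_log
        ph_lo = round(max(PH_BOUNDS[0], ph_opt - rng.lognormal(mu_p, sd_p)), 2)
        ph_hi = round(min(PH_BOUNDS[1], ph_opt + rng.lognormal(mu_p, sd_p)), 2)

        ph_missing = rng.random() < cfg.missing_rates.get("pH", 0.0)

        nacl_opt = nacl_lo = nacl_hi = None
        if rng.random() >= cfg.missing_rates.get("NaCl", 1.0):
            if rng.random() < cfg.halophile_rate:
                nacl_opt = round(float(rng.uniform(5.0, 15.0)), 1)
            else:
                nacl_opt = round(float(rng.uniform(0.0, 4.0)), 1)
            nacl_lo = round(max(0.0, nacl_opt - float(rng.uniform(1, 5))), 1)
            nacl_hi = round(nacl_opt + float(rng.uniform(1, 5)), 1)

        p_opt = p_lo = p_hi = None
        if rng.random() >= cfg.missing_rates.get("P", 1.0):
            if rng.random() < cfg.piezophile_rate:
                p_opt = round(float(rng.uniform(10.0, 30.0)), 1)
            else:
                p_opt = round(float(rng.uniform(0.1, 5.0)), 1)
            p_lo = round(max(0.0, p_opt - float(rng.uniform(0.1, 5))), 1)
            p_hi = round(p_opt + float(rng.uniform(5, 30)), 1)

        hyperthermophilic = t_opt >= cfg.thresholds.hyperthermophile_T_from
        donors = {}
        for c in DONOR_CLASSES:
            if rng.random() >= cfg.donor_tested_prob.get(c, 0.0):
                donors[c] = UNTESTED
                continue
            use_p = cfg.donor_use_prob.get(c, 0.0)
            if c == "hydrogen" and hyperthermophilic:
                use_p = cfg.hydrogen_use_prob_hyperthermophile
            donors[c] = USED if rng.random() < use_p else NOT_USED

        rec = StrainRecord(
            name=f"Synthostrain sp. SYN-{k + 1:04d}",
            domain="synthetic",
            T_opt=t_opt,
            T_min=t_lo,
            T_max=t_hi,
            pH_opt=None if ph_missing else ph_opt,
            pH_min=None if ph_missing else ph_lo,
            pH_max=None if ph_missing else ph_hi,
            NaCl_opt=nacl_opt,
            NaCl_min=nacl_lo,
            NaCl_max=nacl_hi,
            P_opt=p_opt,
            P_min=p_lo,
            P_max=p_hi,
            donors=donors,
            habitat="synthetic",
            notes=f"synthetic; component={comp_name}",
        )
        rec = replace(rec, labels=classify_adaptations(rec, cfg.thresholds))
        records.append(rec)
        component_truth.append(comp_name)
    if return_components:
        return records, component_truth
    return records


def make_table1_fixture() -> list[StrainRecord]:
    """The packaged transcription of the survey's extremophile table.

    One record per unique strain; strains listed under several adaptation
    sections are merged into a single record carrying all labels, and
    not-determined entries are missing values.
    """
    with resources.as_file(
        resources.files("ferrohab.data").joinpath("table1_strains.tsv")
    ) as p:
        return parse_strain_table(p)
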