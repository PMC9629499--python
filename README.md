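# ferrohab

Thermodynamic habitability mapping for microbial iron reduction, paired
with a strain-trait database engine for extremophilic iron-reducing
isolates.

Dissimilatory iron reduction — respiration with Fe(III) as the terminal
electron acceptor, producing Fe(II) — is among the most widespread and
ancient microbial metabolisms, and a leading candidate for life beyond
Earth. `ferrohab` asks where in pH–temperature space this metabolism is
energetically possible, and compares that prediction with where
iron-reducing microorganisms have actually been found to grow. It is aimed
at geomicrobiologists, astrobiologists and bioenergetics modellers.

## What it computes

**Energetics.** For six environmentally relevant redox couples — acetate or
H₂ oxidation coupled to reduction of goethite (FeO(OH)), hematite (Fe₂O₃)
or ferrihydrite (Fe(OH)₃) — the Gibbs free energy of reaction under
non-standard conditions is

&nbsp;&nbsp;ΔG_r = ΔG°_r(T) + RT ln Q

with R = 8.31 J K⁻¹ mol⁻¹, Q the concentration-based reaction quotient
(solids and water at unit activity, a(H⁺) = 10⁻ᵖᴴ), and ΔG°_r(T)
extrapolated from 298.15 K by the constant-enthalpy (van 't Hoff)
approximation. Values are normalised per electron transferred (8 e⁻ for
complete acetate oxidation to HCO₃⁻, 2 e⁻ for H₂). Reactions are balanced
automatically from elemental composition; e.g. acetate with hematite is

&nbsp;&nbsp;4 Fe₂O₃ + CH₃COO⁻ + 15 H⁺ ⇌ 8 Fe²⁺ + 8 H₂O + 2 HCO₃⁻.

Below pH 3, ferric oxides are unstable, so every couple switches to the
aqueous-Fe³⁺ reaction there. Each cell of a pH 0–14 × −10–130 °C grid is
classified against a maintenance-energy threshold: ΔG_r ≤ −20 kJ/e⁻ is
favourable for growth, −20 < ΔG_r < 0 supports survival/maintenance only,
and ΔG_r ≥ 0 is infeasible.

**Survey analytics.** A strain table parser, cardinal-growth midpoint
rules, configurable extremophily cutoffs (psychrophile T_opt < 20 °C,
thermophile ≥ 50 °C, hyperthermophile ≥ 72 °C, acidophile pH_opt < 5,
alkaliphile ≥ 9, halophile ≥ 5 % NaCl, piezophile ≥ 10 MPa),
polyextremophile detection, envelope extrema, sweet-spot occupancy and
electron-donor cross-tabulations. A transcription of the published
extremophile table ships as a fixture; a seeded synthetic generator
emulates the survey's cross-shaped (T, pH) optimum distribution so every
downstream stage is testable without downloads.

**Overlay.** Strain growth envelopes are projected onto a habitability
grid to flag strains whose reported growth conditions exceed the
thermodynamic growth threshold, and to enumerate favourable-but-unoccupied
(pH, T) cells.

## Worked example

```python
import ferrohab as fh

# energetics of the least favourable couple at the most alkaline reported
# growth conditions (pH 10.7 at 45 degrees C)
rxn = fh.balance_reaction("hydrogen", "goethite")
g = fh.delta_g_per_electron(rxn, fh.celsius_to_kelvin(45), pH=10.7)
print(rxn)                      # H2(aq) + 2 goethite + 4 H+ = 2 Fe2+ + 4 H2O
print(round(g, 2))              # 52.41  -> infeasible (>= 0 kJ per electron)

grid = fh.build_grid("hydrogen", "goethite")
print(fh.grid_argmin(grid, restrict_to_phase="mineral"))
# (3.0, -10.0, -51.39): the most favourable mineral-phase cell is the
# lowest-pH, lowest-temperature corner — pH 3 at -10 degrees C

db = fh.make_table1_fixture()
print(fh.summarize_counts(db)["acidophile"])   # 14
print(fh.envelope_extrema(db))                 # (-2.0, 121.0, 1.0, 10.7)
print(fh.flag_exceedances(db, grid))           # includes Fuchsiella ferrireducens
```

The numbers mean: oxidising H₂ with goethite at pH 10.7/45 °C would
*cost* 52 kJ per electron — no organism can grow from it, yet one strain
(*Fuchsiella ferrireducens* Z-7101) grows there, which the overlay
flags. Thermodynamics alone would instead favour cold acidic brines
(pH 3, −10 °C, −51 kJ/e⁻), where no iron reducer has ever been isolated.

A CLI mirrors the library: `ferrohab grid|classify|overlay|simulate --help`.

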