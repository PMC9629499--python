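# Methods

## Thermodynamic model

For each redox couple the Gibbs free energy of reaction is evaluated as
ΔG_r = ΔG°_r(T) + RT ln Q and divided by the number of electrons
transferred. Conventions:

- **Gas constant.** R is fixed at 8.31 J K⁻¹ mol⁻¹ (not 8.314) so that
  results are reproducible against the survey literature that uses this
  rounding.
- **Stoichiometry.** Reactions are not hard-coded: the coefficient vector
  is the one-dimensional rational nullspace of the element-and-charge
  conservation matrix over a fixed participant set (donor, ferric
  acceptor, Fe²⁺, H₂O, H⁺, plus HCO₃⁻ for acetate, which is assumed
  completely oxidised). The solution is normalised to one formula unit of
  donor and oriented so Fe²⁺ is produced; n_electrons equals the Fe²⁺
  coefficient (one electron per Fe(III)→Fe(II) conversion), giving 8 for
  acetate and 2 for H₂. Uniqueness of the nullspace is asserted at run
  time, so an ill-posed participant set fails loudly.
- **Temperature extrapolation.** ΔG°_r(T) = ΔH°_r(298) − T·ΔS°_r(298)
  with ΔS°_r = (ΔH°_r − ΔG°_r)/298.15 — the constant-enthalpy
  (van 't Hoff / Gibbs–Helmholtz) approximation. Heat-capacity
  polynomials would need species data beyond the packaged table; over the
  −10–130 °C range the constant-ΔH approximation is standard practice for
  survey-level bioenergetics. It is exact at 298.15 K by construction.
- **Activities.** Concentration-based quotient, no ionic-strength
  correction. Solids and liquid water are forced to unit activity;
  a(H⁺) is always 10⁻ᵖᴴ. Defaults for aqueous species are typical anoxic
  porewater values: acetate, HCO₃⁻, Fe²⁺, Fe³⁺ at 10⁻³; dissolved H₂ at
  10⁻⁴. All are overridable per call or via the CLI config. Hydrogen is
  modelled as H₂(aq); using an H₂(g) convention instead would shift the
  hydrogen couples by a constant (the dissolution free energy scaled by
  RT and the activity ratio) without affecting any monotonicity result.
- **Species table.** `data/species.csv` is the source of truth, one
  provenance entry per row (NBS tables, USGS Bulletin 2131, and the
  Amend & Shock compilation for H₂(aq)). Users can substitute their own
  table; every public function threads it through. With a different
  ferrihydrite free energy the absolute values shift by up to a few
  kJ/e⁻; the signs of the pH and temperature trends do not, because they
  are fixed by the H⁺ stoichiometry and the sign of ΔS°_r.

## Habitability grid

Default axes: pH 0–14 in 0.5 steps, −10–130 °C in 5 °C steps (29 × 29
cells). The published heatmaps do not state their cell size; the
resolution is configurable and every grid-level conclusion asserted in
tests is monotonicity-based, hence resolution-robust. Below pH 3 ferric
oxides are unstable, so cells with pH < 3 use the same donor's
aqueous-Fe³⁺ reaction ("below 3" read strictly: the pH 3 column is
mineral, which also makes it the most favourable mineral column).
Favourability classes use a maintenance-energy threshold of −20 kJ per
electron: g ≤ −20 favourable, −20 < g < 0 maintenance-only, g ≥ 0
infeasible. Boundary values (−20 and 0 exactly) are assigned to
favourable and infeasible respectively; sources do not state inclusivity,
and the choice only matters for measure-zero cells.

Because mineral-couple reactions consume H⁺ while the aqueous-Fe³⁺
reactions release it, per-electron ΔG_r is exactly linear and increasing
in pH within the mineral region (slope RT ln10 · n_H⁺/n_e) and decreasing
within the aqueous region. Together with negative reaction entropies for
the mineral couples this places the mineral-phase minimum at the
lowest-pH, lowest-temperature cell — pH 3, −10 °C — for all six couples.

## Strain database

- Optima given as ranges (e.g. 30–35 °C) are reduced to their midpoint
  before classification; "ND" maps to a missing value, which excludes the
  strain from classification for that parameter only.
- Default cutoffs (psychrophile < 20 °C; thermophile ≥ 50 °C;
  hyperthermophile ≥ 72 °C; acidophile < 5; alkaliphile ≥ 9; halophile
  ≥ 5 % w/v NaCl; piezophile ≥ 10 MPa) are configuration, not constants.
  They were chosen so that boundary strains in the packaged fixture fall
  on the correct side (a 73 °C optimum is hyperthermophilic, a 47.5 °C
  optimum is not thermophilic, pH 4.5 is acidophilic but pH 5.0 is not).
  A polyextremophile is any strain with two or more labels.
- The packaged fixture transcribes the published extremophile table, one
  row per printed row; strains listed under several adaptation sections
  are merged into one record carrying all labels. Three cardinal values
  that appear only in the survey's prose (not in the table) are included
  with a note in the `notes` column, because the overlay analysis needs
  both coordinates for the strains concerned. One printed row is
  internally inconsistent (an optimum above its own range maximum);
  records therefore *surface* consistency problems via `validate()` and a
  warning instead of refusing to load published data. Conflicting
  duplicate values for the same strain are still a hard error.
- `envelope_extrema` uses growth-range endpoints only (that is how the
  surveyed extremes of −2 °C, 121 °C, pH 1.0 and pH 10.7 are defined);
  `sweet_spot_stats` counts optimum midpoints inside T ∈ [20, 40] °C and
  pH ∈ [6, 8], and counts a strain as "outside both" only if at least one
  optimum is known and none falls in its interval.

## Overlay

Range extremes are evaluated paired with the optimum of the other
parameter — (pH_min, T_opt), (pH_max, T_opt), (T_min, pH_opt),
(T_max, pH_opt) — plus the optimum itself; extreme-with-extreme pairing
would test conditions no study reports. Strains missing either optimum
are skipped with a warning. For unoccupied-region analysis a strain
covers the axis-aligned rectangle of its growth ranges (falling back to
the optimum where a range is absent); a strain with one axis entirely
unknown constrains cells only along its known axis. Consequently, with
the extremophile fixture — where most strains carry data for a single
parameter — only cells at *combined* extremes remain unoccupied, which is
precisely the pattern of interest. Nearest-cell assignment sends
boundary-equidistant points to the lower-index cell.

Note that with the packaged generic formation values a handful of
acidophilic-hyperthermophile range extremes also exceed the growth
threshold on the least favourable couple (H₂/goethite); this is sensitive
to the goethite formation energy and the activity defaults, unlike the
robustly infeasible high-pH/high-T exceedance.

## Synthetic generator

Emulates the survey's cross-shaped distribution of growth optima: a
mixture over (T_opt, pH_opt) with truncated-normal components — a dense
mesophilic/circumneutral sweet spot (30 °C, pH 7), a cold arm (12 °C), a
hot arm (70 °C) spanning thermophiles and hyperthermophiles, acid
(pH 2.8) and alkali (pH 9.5) arms at mesophilic temperature, and a rare
acidophilic-hyperthermophile corner (85 °C, pH 2.8). Default weights
0.57/0.03/0.27/0.06/0.04/0.03 follow the surveyed fractions (57 %
non-extremophile, temperature adaptations dominant, corner populations
rare). Growth ranges are the optimum ± log-normal half-widths (medians
10 °C and 1.3 pH units); salinity and pressure are missing at realistic
rates (60 % and 90 %) with small marginal halophile/piezophile
probabilities; donor usage is drawn per compound class with
adaptation-dependent probabilities, including the survey's observation
that every hyperthermophile tested on hydrogen uses it (probability 1.0
by default). All draws come from one seeded NumPy generator, so a fixed
seed reproduces the table byte-for-byte.

What the generator does **not** emulate: phylogenetic structure, habitat
and geography, correlations between range width and adaptation, reporting
heterogeneity between laboratories, and the discreteness of published
rounding. Tests that pass on synthetic data therefore demonstrate
pipeline correctness and statistical recovery, not fidelity of any
biological conclusion to the real survey.

## Problem sizes and numerics

Default grids are 841 cells per couple (5 046 cells across the six
couples), evaluated exactly rather than interpolated; the full test suite
and the reproduction script each run in well under a minute. Parameter
recovery uses n = 2 000 synthetic strains against a 3-binomial-standard-
error band. Tie-breaking in `grid_argmin` is lexicographic (lower pH,
then lower temperature); all equality assertions on derived energies use
relative tolerances ≤ 1e-9 except where a value is exact by construction.

## Known limitations

- No ionic-strength/activity-coefficient model, no heat-capacity
  integration, no magnetite or Fe(III)–organic complexes, no kinetics:
  the map is a baseline energetic limit, not a rate prediction.
- Absolute per-electron values inherit the uncertainty of the formation
  data, most notably for ferrihydrite (a poorly crystalline phase with a
  wide reported free-energy range).
- The extremophile fixture covers only strains extremophilic in at least
  one parameter; whole-survey statistics (141 strains, sweet-spot counts)
  require the user-supplied complete database.
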