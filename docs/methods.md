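# Methods

## Model overview

The package simulates vegetation carbon in China's arbor forests as a
collection of even-aged cohorts. A cohort is one species × use class ×
age-bin patch with four carbon pools (stem, root, foliage, branch) in
MgC/ha on a fixed area in Mha. Units are chosen so the stock identity is a
bare product: 1 MgC/ha × 1 Mha = 1 MtC. Stocks are year-end states; the
annual sink of year *t* is S_t = C_t − C_{t−1}, and a cumulative sink over
2019–2060 is the stock difference C_2060 − C_2018 (42 annual sinks).

### Annual cohort step

Stem volume follows a Chapman–Richards curve V(a) = v_max(1−e^(−ka))^m,
the standard monotone-asymptotic form of empirical stand growth models.
Each year, in order:

1. **Increment.** The stem pool gains `wood_density × cf_stem × ΔV` where
   ΔV = V(a+1) − V(a); soft organs gain in proportion to their share of
   the total biomass increment (`organ_share`, summing to 1), each with
   its own carbon fraction from the organ-content table.
2. **Turnover.** Foliage, branch and root pools shed their annual
   turnover fraction.
3. **Mortality.** A stem-mortality fraction removes carbon from every
   pool.
4. **Management.** At a thinning age the scheduled fraction of all pools
   is removed; at the rotation age everything is removed and the stand is
   replanted at age 0 in the same year, keeping area constant. Removals
   split into stemwood (to products, share 1 − residue_fraction) and
   residue available as bioenergy feedstock (default residue_fraction
   0.4). Public-welfare cohorts carry no regime and never harvest.

Turnover and mortality carbon leaves the accounting: litter and soil
pools are deliberately not modelled because every reported quantity is
vegetation carbon. Every step satisfies the balance Δpools·area =
increment − turnover − mortality − harvest to float precision, which the
test suite asserts at 1e-9 relative.

### National assembly

Existing forests: each of the 19 dominant species contributes one cohort
per use class per age bin, with the class split from the 2018 inventory.
Commercial bin ages are reduced modulo the species rotation so initial
states are consistent with the logging cycle; initial pools come from a
spin-up from bare ground under the same regime (so thinned stands start
thinned).

New afforestation: coverage targets (26% by 2035, 30.7% by 2050) are
converted to forest-area targets against a fixed land area, the increment
spread equally over each planning window — 2019–2035 (17 years, ≈1.7
Mha/yr) and 2036–2050 (15 years, ≈3.0 Mha/yr) — and each year's area
allocated across species proportional to 2018 area shares. New cohorts
enter at age 0 in their plant year and grow that year. Nothing is planted
after 2050; stands keep growing to 2060.

The land area defaults to 960.1 Mha with coverage-target areas rounded to
the printed 0.1 Mha. This constant is a calibration: it is the value that
reproduces all three printed area targets simultaneously (249.6 Mha in
2035, 294.8 Mha in 2050, hence 254.2 Mha of arbor forest by 2050); 960.0
Mha would give 294.7/254.1.

The 19 species cover 161.8 of 179.9 Mha of arbor forest. The published
accounting scales to all arbor forests by a proportional remainder — its
existing-forest stocks are 7344.8/6876.9 × the 19-species stocks at
printed precision — and the pipeline applies the same constant when
reporting all-arbor totals, carrying the 18.1 Mha remainder explicitly in
area bookkeeping.

### Fuel substitution

Harvest residue carbon converts to dry fuel mass through the species stem
carbon fraction (residues are woody biomass): FI = residue_C / cf_stem.
Per gas j, avoided emissions are GHGmit_j = E_sj − E_aj with E_aj =
FI·ef_aj and E_sj = FI·(EC_a/EC_s)(η_a/η_s)·ef_sj. Defaults: biomass
15 MJ/kg; anthracite 29 MJ/kg; efficiencies 0.25 (coal stove), 0.15
(traditional cookstove), 0.25 (improved stove). These defaults are
plausibility-based, not inventory values; notably they reproduce the
published improved/traditional mitigation ratio of 1.92.

Per-gas masses aggregate to CO₂-equivalent with GWP-100 CH₄ = 21 and
N₂O = 310 (the second-assessment vintage consistent with the classical
bioenergy accounting this follows); CO and TNMOC are tracked but carry
zero weight by default, and the GWP set is configurable. Carbon mass is
CO₂e × 12/44. Per-gas mitigation can be negative — biomass stoves emit
more CH₄ per kg than coal stoves — and is never floored; CO₂ mitigation
is strictly positive for any positive fuel input because the biomass CO₂
factor is zero (carbon neutrality on a sustained growth/harvest cycle).

## Synthetic parameters and calibration

Growth parameters are not printed anywhere in the inventory; the
generator stands in for them with one seeded pseudo-random stream.

Each species maps to an archetype with parameter ranges:

| archetype | k (1/yr) | rotation (yr) | examples |
|---|---|---|---|
| fast broadleaf | 0.055–0.09 | 8–22 | eucalyptus, poplar |
| broadleaf | 0.022–0.038 | 36–50 | quercus, mixed broadleaf |
| mixed | 0.026–0.045 | 31–40 | conifer/broadleaf mixtures |
| fast conifer | 0.040–0.065 | 23–30 | Chinese fir, masson pine |
| slow conifer | 0.016–0.028 | 50–61 | fir, spruce, larch |

Wood density, organ shares, turnover (foliage 0.08–0.40/yr by archetype;
branch 0.02–0.04; root 0.02–0.06) and mortality (0.002–0.007/yr) are
drawn per species. One thinning removes 15% of pools at 40% of the
rotation.

**Density calibration.** Each species receives a 2018 density target
seeded from its unit-area stock volume (dense mature stands high, sparse
plantations low), then all targets are iteratively rescaled and clipped
so that (i) each lies strictly inside the published 2018 range
28.4–144.3 MgC/ha and (ii) the area-weighted national stock equals the
published 19-species total of 6876.9 MtC. Because every pool is exactly
linear in v_max, the asymptotic volume that meets a target under the
generated age structure and management solves in closed form from one
unit-v_max spin-up; the solution is verified by re-simulation to 1e-6.
The k ranges above were chosen so the calibrated forests remain far from
their asymptote in 2018, reproducing the published regime of stocks
roughly doubling by 2060; with faster curves the same 2018 densities
would imply nearly saturated stands and an implausibly weak future sink.

**Age structure.** Five bins at deterministic midpoint ages (0.15, 0.40,
0.70, 1.00, 1.35 × the archetype's upper rotation bound), with shares
0.55·y, 0.45·y, 0.40·(1−y), 0.35·(1−y), 0.25·(1−y) for a young+middle
share y = 0.639 nationally (per-species overrides supported, e.g. ~0.8
for the fast-maturing broadleaf species).

**What the generator does not emulate.** Calibration pins the 2018 state,
not the published per-species trajectories: simulated 2060 densities and
sinks are outcomes of the archetype draws, in the published ballpark
(existing-forest mean annual sink ≈ 200 vs 170.8 MtC/a published;
mitigation averages ≈ 32/61 vs 36.1/69.3 MtC/a) but not matched pointwise.
A handful of fast-growing species overshoot the published 2060 density
maximum of 212.2 MgC/ha. Passing tests therefore demonstrate the
bookkeeping, calibration machinery and substitution calculus, not
predictive skill for real stands. Because density targets fold whole-tree
biomass into a stem-volume curve, calibrated v_max values are curve
scales, not literal stand volumes.

## Numerical choices

- Year convention: a cohort planted in year y is stepped once within y;
  stocks are year-end states. Felled stands replant the same year.
- Tie-break in the climate-reference province rule: first occurrence in
  input order wins.
- Printed-number comparisons round half away from zero to one decimal;
  identity tolerances allow 0.05 per rounded summand (0.95 for a
  19-term column sum).
- Species grouped in one organ-content row ("Spruce, Fir") are expanded
  so each of the 19 species carries its own carbon-fraction record.
- Degenerate inputs raise: empty province lists, zero areas, year gaps in
  sink series, non-increasing coverage targets, thinning ages at or past
  the rotation.
- The published tables contain small internal inconsistencies (row sums
  off by 0.1 MtC; two different 2018 totals, 6876.9 MtC for the 19
  species vs 7344.8 MtC for all arbor forests). Both totals are carried
  as distinct inputs; identity checks flag, and tolerate, exactly the
  printed-rounding discrepancies.

## Known limitations

- No soil, litter or product-pool dynamics; mitigation covers only the
  stove-substitution pathway (no electricity generation, no lifecycle
  emissions of harvest and transport, no wood-for-material substitution).
- No climate response, CO₂ fertilization or disturbance (fire, pests).
- National-scale mitigation magnitudes depend on fuel energy contents and
  stove efficiencies that the inventory accounting never printed; they
  are configurable defaults here, so mitigation levels are indicative
  while the structural properties (linearity in fuel input, stove
  ordering, zero for public-welfare scenarios) are exact.
- The afforestation allocation distributes all new area over the 19
  dominant species rather than the full species mix.
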