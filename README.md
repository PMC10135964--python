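# inspeq

Quantitative solution-speciation toolkit for very highly charged
phosphate ligands (inositol poly-/pyrophosphates) and their H⁺/K⁺/Mg²⁺
equilibria:

- **`inspeq.chem_model`** — species data model (stoichiometry +
  cumulative log β) with packaged, validated ligand models
  (`insp8`, `pcp_insp5`, `insp6`) in a human-editable text format.
- **`inspeq.equilibrium`** — mass-balance speciation solver (damped
  Newton on log₁₀ free concentrations, overflow-safe in log space) and
  species-distribution diagrams over pH grids.
- **`inspeq.nmr_titration`** — fast-exchange ³¹P shift forward model,
  formation-constant refinement by variable projection (limiting shifts
  solved linearly per trial constant vector), σ/χ² model selection, and
  per-step Δδ protonation-site analysis.
- **`inspeq.conformer_thermo`** — axial/equatorial conformer ratios from
  peak integrals, van't Hoff regression (ΔH⁰, ΔS⁰ ± SE),
  Gibbs-Helmholtz axial-fraction prediction, pH* → pH conversion.
- **`inspeq.itc_binding`** — one-site ITC isotherm simulator (Wiseman
  model with injection-displacement corrections) and fitter with
  ΔG/−TΔS decomposition.
- **`inspeq.synthetic_data`** — seeded generators (PCG64 via
  `numpy.random.default_rng`) for titration, conformer-series and ITC
  datasets, including a clearly labelled *synthetic* demo shift basis.
- **`inspeq.io` / `inspeq.cli`** — CSV dialects and the `inspeq`
  command-line interface.

## CLI examples

```bash
# species-distribution diagram, most-abundant species at pH 7.4
inspeq speciate --model insp8 --ltot 1e-3 --ktot 0.15 --mgtot 1e-3 \
    --ph-min 3 --ph-max 12.5 --ph-step 0.1 --out diagram.csv

# percent axial conformer by Gibbs-Helmholtz
inspeq axfrac --dh -7.2 --ds -0.025 --temp 310

# D2O pH-meter reading to pH
inspeq phstar --value 7.5

# synthetic titration -> constant refinement
inspeq simulate titration --model insp8 --protonation-only --noise-sd 0.02 \
    --seed 1 --out tit.csv
inspeq fit-titration --data tit.csv --model insp8 --refine protonation --ltot 1e-3

# van't Hoff analysis of a conformer-ratio table
inspeq simulate conformer --dh -17.1 --ds -0.063 --noise-sd 0.05 \
    --replicates 2 --seed 1 --out series.csv
inspeq vanthoff --data series.csv

# one-site ITC: simulate and fit
inspeq itc-sim --kd 373e-9 --dh -3.5 --out iso.csv
inspeq itc-fit --data iso.csv
```

Commands that write files refuse to overwrite without `--force` and
drop a `<out>.log.json` run log (inputs, parameters, seed, version).

## Conventions and limitations

- Formation constants are cumulative log₁₀ β on the molar concentration
  scale in a constant ionic medium; no activity corrections, and no
  temperature correction when a model is used away from its stated
  medium temperature.
- Protons are buffered (pH is an input); no hydroxo species, no
  precipitation or multi-ligand competition.
- The demo limiting-shift basis is fabricated for qualitative realism
  (upfield on protonation, downfield on metal binding) and is labelled
  synthetic; it is not measured data.
- R = 1.987204×10⁻³ kcal/(mol·K); ΔG = RT ln K_d with a 1 M standard
  state; 25 °C ≡ 298.15 K.
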