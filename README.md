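# astroflux

Constraint-based simulation of astrocyte metabolism under three scenarios —
healthy, palmitate-induced inflammation, and tibolone treatment — built on a
small, fully analyzable synthetic astrocyte network.

The package provides:

- **`astroflux.model`** — domain types for compartmentalized metabolic
  networks (`Metabolite`, `Reaction`, `MetabolicModel`), stoichiometric-matrix
  assembly, reaction-kind classification (exchange / transport /
  intracellular / pseudo), and model validation (id syntax, elemental/charge
  balance, orphan metabolites).
- **`astroflux.io`** — reaction-formula parsing/printing
  (`"1 glc_D[e] -> 2 lac_L[e]"`, Unicode or ASCII arrows), an SBML Level 3
  (core + fbc) reader/writer, and TSV readers/writers for expression tables,
  media, and flux / fold-change reports.
- **`astroflux.fba`** — the LP core on scipy/HiGHS: FBA, lexicographic FBA,
  parsimonious (canonical) flux vectors, flux variability, blocked-reaction
  detection, and reaction knockouts.
- **`astroflux.constraints`** — expression-proportional bounds via GPR scores
  (AND = min, OR = sum), addition-cost gap filling, and medium application
  (uptake = negative exchange flux).
- **`astroflux.scenarios`** — scenario construction, robustness curves and
  IC50 extraction, fold-change comparison with the ≥2-fold filter, knockout
  classification (pro-inflammatory / anti-inflammatory / treatment-essential
  / neutral), subsystem activity summaries, and the end-to-end pipeline.
- **`astroflux.synth`** — the synthetic toy astrocyte generator. Every export
  objective competes for a finitely regenerated mitochondrial cofactor pool
  that palmitate β-oxidation drains, so each objective declines linearly to
  zero at a configurable forced uptake `inhibition_u0`; the IC50 of every
  robustness curve is u0/2 in closed form. Yields are the classical lumped
  2 lactate and 36 ATP per glucose. The ten-reaction tibolone set ships as a
  packaged TSV, plus a five-reaction estradiol stub whose relief reaction
  makes the treatment effect measurable (and abolishable by knocking out the
  tibolone exchange `T1`).

## CLI

```bash
astroflux synth --outdir toy            # write the toy model (SBML + TSV), medium, expression
astroflux simulate synthetic --objective DM_atp          # plain FBA
astroflux robustness synthetic --n 1000 --outdir rob     # curves + IC50
astroflux compare fluxes_a.tsv fluxes_b.tsv --out fc.tsv # fold changes
astroflux knockouts --out ko.tsv                         # knockout screen
astroflux run --outdir run --seed 1                      # full pipeline
```

`astroflux run` executes constrain → gap-fill → prune blocked → healthy FBA →
robustness/IC50 → inflammatory scenario → treatment scenario → fold changes →
knockout classification, writing deterministic TSV/JSON reports and a log.
A YAML config (`--config`) can override any `PipelineConfig` field
(grid size, threshold, seeds, objective, medium/expression paths, ...).

## Conventions

- Flux units are mmol·gDW⁻¹·h⁻¹; default bounds ±1000 (irreversible 0–1000).
- Uptake is negative flux on an exchange reaction; medium caps become
  exchange lower bounds.
- A reaction is reversible iff its lower bound is negative.
- Exchange-id dialects (`EXhdca(e)`, `EX_hdca_e`, `EX_hdca(e)`) are accepted
  as aliases wherever exchange ids are looked up.
- Canonical flux vectors are parsimonious: total absolute flux is minimized
  among (lexicographic) optima, making cross-scenario comparisons
  deterministic.
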