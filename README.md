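# ooperm

Water and cryoprotectant permeability analysis for *Xenopus* oocyte
volumetry: a Kedem–Katchalsky (K-K) simulator and fitter, slope-based
permeability estimators, Boyle–van't Hoff utilities, radiolabel-uptake
arithmetic, aquaporin mutant-sequence bookkeeping, and a synthetic-data
generator.

## What it does

- **`ooperm.model`** — two-compartment osmometer model of the oocyte
  (osmotically inactive fraction, free-water concentration basis) with a
  three-parameter K-K ODE system (Lp, Ps, σ, including the solvent-drag
  term). Simulates shrink/swell trajectories under step changes in bath
  composition; closed-form Boyle–van't Hoff equilibria; the
  Pf = Lp·RT/Vw conversion.
- **`ooperm.volumetry`** — slope-based estimators on observed or
  simulated trajectories: Pf from hypotonic swelling
  (`V0·d(V/V0)/dt / (S·Vw·Δosm)`), Ps from isotonic solute substitution
  (`d(V/V0)/dt / (S/V0)`), and early-window linear Lp under a hypertonic
  impermeant step; batch summaries (mean, SEM, fold change).
- **`ooperm.kkfit`** — bounded trust-region least squares recovering
  (Lp, Ps, σ) from a single shrink–swell trajectory, with a
  deterministic multistart grid, curvature-based standard errors, and a
  σ identifiability profile.
- **`ooperm.uptake`** — scintillation-count arithmetic: intracellular
  concentration `((cpm_t − cpm_t0)/cpm_per_µl)·C_bath/V_final`, isotonic
  tracer uptake rates, and model-predicted concentrations for
  cross-validation against the simulator.
- **`ooperm.seqtools`** — point-mutation grammar (`H53A/G54H/T85A`),
  NPA/NPT/NPS pore-motif scanning, loop annotations, and verification of
  the packaged mutant loop-fragment table (15 constructs rebuilt from WT).
- **`ooperm.synthetic`** — seeded generator of noisy trajectory batches
  with lognormal inter-oocyte variability and Poisson count tables;
  counter-based substreams make any subset reproducible.

## CLI

The `ooperm` entry point exposes the pipeline stages:

```sh
# simulate a 10-min 1.3 M ethylene glycol challenge
ooperm simulate --lp 2.64 --ps 0.02549 --sigma 0.8 \
    --osm-impermeant-mosm 200 --permeant-id ethylene_glycol \
    --conc-permeant-molar 1.3 --out traj.csv

# fit (Lp, Ps, sigma) back from the trajectory
ooperm fit-kk --traj traj.csv --protocol protocol.json --out fit.csv

# slope-based estimates
ooperm pf --traj hypo.csv --osm-in-mosm 200 --osm-out-mosm 20
ooperm lp --traj sucrose.csv --osm-bath-mosm 1460 --cutoff-min 2

# uptake, sequences, synthetic data
ooperm uptake --counts counts.csv --v-final-ul 0.98
ooperm mutate --fasta loops.fasta --mut T85A --offset 77 --out mut.fasta
ooperm motifs --fasta mut.fasta
ooperm verify-table2
ooperm synth --spec batch.json --out bundle/
ooperm run --config pipeline.json --out results/
```

`protocol.json` example for `fit-kk`:

```json
{
  "diameter_cm": 0.12,
  "osm_impermeant_mosm": 200.0,
  "permeant_id": "ethylene_glycol",
  "conc_permeant_molar": 1.3,
  "vb_fraction": 0.75,
  "free": ["Lp", "Ps", "sigma"]
}
```

## Units and conventions

Internal canonical units are cm, cm³, min, atm, mol, K. Lp is accepted
and reported in µm/(min·atm); Ps in cm/min. Osmolarities are mOsm,
permeant concentrations mol/L, treated as ideal. The osmotically
inactive volume defaults to 75% of the initial oocyte volume, the
isotonic reference to 200 mOsm, and temperature to 293.15 K.

Two membrane-area conventions coexist: the slope formulas for Pf/Ps/Lp
use the folded area (9× the apparent sphere area, the published
convention), while the K-K simulator and fitter default to the apparent
area (`area_basis="apparent"`), which yields equilibration timescales of
minutes as observed experimentally; `area_basis="folded"` is available
everywhere.

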