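# dosagecomp

Population-genetic models of sex-chromosome dosage-compensation evolution,
plus a transcriptome analysis pipeline that uses expression variability as an
inverse proxy for selection strength.

After Y/W degradation, expression of a dose-sensitive X/Z-linked gene evolves
by the recurrent fixation of small-effect cis-regulatory mutations whose male
and female effects are correlated. The package provides:

- **`dosagecomp.popgen_core`** — model parameters, the bivariate mutation
  kernel, the linearized fixation probability of a sex-linked mutant
  (additive and dominant variants), and the expected per-substitution drift.
- **`dosagecomp.trajectories`** — exact (eigen-solution) and numeric expected
  dynamics, the `tau = 2*mu*t/30` time rescaling, gradual Y/W-decay and
  dominance variants, stationary variance at mutation–selection–drift
  equilibrium, and recovery-time utilities.
- **`dosagecomp.sde_engine`** — Euler–Maruyama replicate ensembles of the
  expression diffusion, and X/Z effective-size formulas under harem polygyny
  (`N_eX = 9N_f/(6+2*eta)`, `N_eZ = 9N_f/(6+4*eta)`).
- **`dosagecomp.wf_oracle`** — an individual-based Wright–Fisher simulator of
  a single sex-linked locus (hemizygous heterogametic sex, Gaussian
  stabilizing selection), used as the brute-force oracle for fixation
  probabilities and as an origin–fixation simulator.
- **`dosagecomp.synthetic_transcriptome`** — a negative-binomial RNA-seq
  count simulator (2 sexes x tissues x replicates; autosomal and Z-linked
  genes in three strata) with planted selection -> dispersion and
  selection-axes -> dosage-compensation links, so pipeline inferences can be
  checked against ground truth.
- **`dosagecomp.expression_pipeline`** — TMM normalization (autosomal
  reference), RPKM, expression filtering, shrunken NB-dispersion (BCV)
  estimation, projection onto concordant/male-bias selection axes, sex-bias
  filtering, dosage-compensation regressions, paired Wilcoxon tests and
  strata analyses.

## CLI

A single `dosagecomp` entry point with subcommands:

```sh
# deterministic expected trajectory (TSV: t, tau, z_m, z_f)
dosagecomp trajectory --s-m 1 --s-f 0.1 --rho 0.8 --ne 1125 \
    --grid 0 400000 801 --out traj.tsv

# stochastic replicate ensemble; Ne derived from the mating system
dosagecomp sde --system ZW --eta 10 --n-f 1000 --reps 100 \
    --t-end 20000 --seed 1 --out ensemble.tsv

# Wright-Fisher fixation-probability estimate (JSON)
dosagecomp wf-fixation --n 50 --ne 75 --z-m -0.2 --delta-m 0.02 \
    --reps 200000 --seed 1

# synthetic dataset, then the analysis pipeline
dosagecomp synth --seed 1 --out-dir data/
dosagecomp analyze --counts data/counts.tsv --annot data/annotation.tsv \
    --samples data/samples.tsv --out-dir results/
```

`analyze` writes TSV tables (TMM factors, M:F ratios, BCV, selection axes,
model coefficient tables, Z:AA ratios) plus a `report.json` run summary.

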