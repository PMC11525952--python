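# oligoconf

Toolkit for the computational workflow behind cold-ion spectroscopy of
protonated peptide oligomers: reinforcement-learning conformational
search, interaction-fingerprint family clustering, harmonic IR
prediction/matching, free-energy crossover analysis between
charge-solvated and zwitterionic conformers, and isotope-envelope
assignment of oligomer size and charge from ESI mass spectra.

## Modules

| Module | What it does |
|---|---|
| `peptide_model` | Build oligomer topologies (e.g. n×Phe-Phe) with explicit protonation states; H-bond, proton–π, free-OH and UV-constraint predicates |
| `conformer_generator` | PPO-trained torsion-space policy (pure-numpy MLPs) generating low-energy, diverse conformers; advantage-plateau stopping |
| `dedup_tfd` | Torsion-fingerprint-deviation metric and greedy uniqueness filtering |
| `energy_opt` | MMFF94/toy energy backends, BFGS minimizer with monotone energy traces, numerical Hessians, external-optimizer adapter |
| `families` | Cluster conformers by H-bond/proton–π/charge-location fingerprint; retain per-family minima under an energy cutoff (default 10 kcal/mol) |
| `ir_spectra` | Harmonic stick spectra, region-wise scaling (0.955 / 0.983 split at 2500 cm⁻¹), Gaussian broadening, cosine matching, free-OH diagnostic |
| `thermo` | RRHO thermochemistry and ΔG(T) crossover temperature (bisection + grid verification) |
| `massspec` | Formula arithmetic, monoisotopic/average m/z, exact isotope-envelope convolution, NNLS mixture decomposition |
| `pipeline` / `cli` | Orchestration (generate → dedupe → optimize → cluster → spectra), synthetic fixture bundles, `oligoconf` CLI |

## CLI

```bash
oligoconf fixture  --seed 1 --out fx/                 # synthetic fixture bundle
oligoconf train    --landscape fx/landscape.json --checkpoint ckpt.json --seed 1
oligoconf generate --landscape fx/landscape.json --checkpoint ckpt.json \
                   --count 100 --seed 2 --out samples.json
oligoconf dedupe   --in samples.json --out unique.json --threshold 0.05
oligoconf optimize --landscape fx/landscape.json --in unique.json --out opt.json
oligoconf pipeline --seed 1 --count 50 --out run/     # all stages, one report
oligoconf ms assign --mz 938 --monomer C18H20N2O3
oligoconf ms fit    --envelope fx/envelope.csv --component 3:1 --component 6:2
oligoconf thermo   --freq-file a.csv --freq-file b.csv --trange 10:400
oligoconf spectra  --sticks sticks.csv --trace trace.csv --out match.json
```

## Notes

- Internal energetics are force-field level (MMFF94); quantum-chemistry
  optimization is delegated to the `external_optimize` adapter contract.
- All stochastic operations take explicit seeds; a pipeline run is
  bit-reproducible from its master seed.
- Synthetic fixtures (toy double-well torsion landscapes with analytic
  minima/basins, traces built from known stick spectra, envelope mixtures
  with known fractions) make every stage testable offline.
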