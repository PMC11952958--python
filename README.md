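# oligoscope

Integrative structural analysis of how a protein complex binds and
oligomerizes along double-stranded RNA — built around the NF45–NF90 /
dsRNA system, but generic over any protein–duplex assembly problem with the
same evidence types.

NF45–NF90 is an abundant heterodimeric dsRNA-binding complex (dimerization
through paired DZF domains, RNA engagement through tandem dsRBDs in NF90).
Deciding whether such a complex merely decorates a duplex or packs into
higher-order filaments requires combining several weak, indirect
measurements. This package implements that evidence chain as a tested
library plus numbered analysis drivers:

- **Solution scattering (SEC–SAXS)** — frame averaging and solvent
  subtraction; Guinier analysis, I(q) ≈ I₀·exp(−q²R_g²/3); the pair-distance
  distribution P(r) and maximum dimension D_max by regularized indirect
  Fourier transform (non-negative, zero-anchored histogram basis,
  second-difference smoothing, L-curve choice of α); dimensionless Kratky
  plots ((qR_g)²·I/I₀ vs qR_g); molecular weight from the volume of
  correlation V_c = I(0)/∫q·I(q)dq; coarse-grained Debye curves
  I(q) = ΣᵢΣⱼ fᵢfⱼ·sin(qd)/(qd) from coordinates; and sparse multi-state
  fits (non-negative weights, reduced χ², fewest states within 5% of the
  best fit).
- **Quantitative cross-linking MS** — fold-change classification of
  cross-linking features into condition-enriched and common classes
  (threshold 2 by default), Cα–Cα distance mapping at the 24 Å EDC contract
  with crystallographic symmetry expansion for shortest realizable
  distances, and head-to-head scoring of assembly hypotheses (single copy
  vs lateral oligomer).
- **Population-variant constraint** — the per-domain missense depletion
  statistic V_d/V_p (domain variant density over whole-protein density;
  values < 1 flag constrained domains).
- **Stoichiometry & geometry** — Gaussian-mixture detection of
  mass-photometry peaks; integer (protein, RNA) composition assignment;
  the steric footprint interval from maximal-occupancy observations
  (each "at most k pairs on L bp" constrains the footprint f to
  L/(k+1) < f ≤ L/k, intersected over observations); lateral oligomer
  model building with clash checks; bead-on-string particle statistics.
- **Synthetic data** — seeded generators for every input type with
  machine-readable truth records, so each analysis stage is tested as a
  parameter-recovery problem.

## Worked example

```bash
python analysis/01_synthesize_inputs.py --seed 1
python analysis/02_saxs_profiles.py
python analysis/03_crosslink_quant.py
python analysis/04_variant_depletion.py
python analysis/05_stoichiometry_footprint.py
```

The drivers print (seed 1):

```
sphere_curve: Rg 39.1 Å (truth 38.7), Dmax 100 Å (truth 100), Kratky peak at qRg=1.66
dumbbell_curve: Rg 41.4 Å (truth 42.9), Dmax 112 Å (truth 120), Kratky peak at qRg=3.94
categories: {'common': 10, 'B-enriched': 5, 'A-enriched': 5}
recovered 5/5 planted RNA-enriched features
assembly ranking: lateral_dimer satisfies 100% of interface links; the single copy satisfies 0%
V_d/V_p for the planted domain: 0.43 (expected 0.50); whole protein: 1.00
  peak  110.0 kDa (39%) -> (1 protein, 0 RNA)
  peak  144.6 kDa (32%) -> (1 protein, 1 RNA)
  peak  254.3 kDa (20%) -> (2 protein, 1 RNA)
  peak  364.1 kDa (10%) -> (3 protein, 1 RNA)
footprint per bound pair: (18, 25] bp = (51, 70] Å of A-form duplex
bead spacing 164 ± 10 Å over n=200 gaps
```

Reading these: the sphere's D_max is recovered exactly and its Guinier R_g
matches R·√(3/5); cross-linking features with a planted four-fold intensity
change in the RNA-bound condition are all classified RNA-enriched; links
that are geometrically impossible inside one heterodimer become satisfied
between adjacent copies of a lateral assembly — the signature of
oligomerization along the duplex; mass peaks resolve compositions up to
three proteins per duplex; and the occupancy observations pin the per-pair
footprint to (18, 25] bp.

The same operations are exposed on the command line
(`oligoscope {saxs,clms,varcons,oligo,synth,run} …`), including a YAML
pipeline runner (`oligoscope run config.yaml`) that validates stage
configs strictly and stamps reports with the config hash and seed.

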