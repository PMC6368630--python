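# classf-switch

Analyses around a conserved molecular switch in Class F G-protein-coupled
receptors — the ten Frizzleds (FZD1–10) and Smoothened (SMO). A basic
residue at the bottom of transmembrane helix 6 (R/K^6.32 in
Ballesteros–Weinstein generic numbering) hydrogen-bonds to the TM7 backbone
and forms a π-cation interaction with W^7.55, holding the receptor in an
inactive conformation; mutating it biases receptors toward an active-like
state. This package re-implements the desk-scale computational pipeline
behind that story for structural bioinformaticians and receptor
pharmacologists:

- **generic numbering** — map receptor sequence positions to `helix.offset`
  labels from per-helix anchors and propagate labels across aligned
  paralogs (`classf_switch.generic_numbering`);
- **variation scoring** — aggregate somatic (cancer) and germ-line
  (population) missense counts per generic position and score each site
  with the relative variation score
  `RelVar_i = ln((CV_i/max_j CV_j + 1)/(NV_i/max_j NV_j + 1))`,
  bounded by ±ln 2, positive where cancer variation exceeds natural
  variation (`classf_switch.variation`);
- **contact fingerprints** — heavy-atom contact detection (4.5 Å cutoff,
  sequence separation > 4, interhelical), hydrogen-bond / π-cation typing,
  presence–absence matrices across structure ensembles, and Kabsch
  superposition (`classf_switch.contacts`);
- **trajectory metrics** — per-frame inter-residue distances (e.g. the
  TM3–TM6 activation coordinate 3.50–6.34), normalized distance
  distributions, per-replicate scalars, and the unpaired pooled-variance
  t test between conditions (`classf_switch.trajectory`);
- **pharmacology statistics** — t/F p-values, one-way ANOVA with Fisher
  LSD, net BRET, and 3/4-parameter and bell-shaped concentration-response
  fits reporting logEC50 (`classf_switch.pharm`);
- **synthetic data** — seeded generators for every input above, with
  planted ground truth (`classf_switch.simulate`).

Real cohort databases, deposited crystal structures and microsecond MD
trajectories are out of scope; the generators emulate their statistical
structure so every stage is testable offline.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
data (each writes tables under `results/`):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_variation_scoring.py
```

prints, among other lines:

```
top 5 positions by RelVar: 6.32, 1.29, 2.34, 5.34, 4.31
planted hotspot 6.32: rank 1, RelVar = 0.3448 (bound is ln 2 = 0.6931)
```

The generator planted a 10× cancer enrichment at position 6.32 of a
50-position receptor family; the score ranks it first. `RelVar = 0.34`
means the max-normalized cancer count at 6.32 exceeds its max-normalized
population count by a factor `e^0.34 ≈ 1.4` on the (count+1) scale.
Continuing,

```sh
python analysis/04_trajectory_comparison.py
```

```
min_distance: WT mean 5.619 (n=3), MUT mean 8.835 (n=4); t = -12.624, df = 5, P = 5.54e-05
```

— with 3 wild-type and 4 mutant replicates the pooled t test runs on
df = 5, and the wild type reaches smaller TM3–TM6 minimum distances, i.e.
the more closed, inactive-like conformation. `03_contact_fingerprint.py`
prints the 6.32-vs-TM7/TM2 presence–absence matrix across a five-structure
ensemble, and `05_dose_response.py` fits four-parameter logistic curves to
two noisy agonist curves a planted 10-fold potency apart and reports the
fitted ΔlogEC50 (single-curve estimates scatter by roughly ±0.2 log units
at 5 % noise; the suite checks the 100-seed average).

A thin CLI wraps the same stages, e.g.

```sh
classf-switch simulate variants --seed 1 --out-dir work
classf-switch relvar --cancer work/cancer_variants.tsv \
    --population work/population_variants.tsv --maps work/segment_map.tsv
```

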