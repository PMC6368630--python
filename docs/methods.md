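# Methods

This note documents the models, defaults, numerical choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Generic residue numbering

Generic labels are `helix.offset` (helix 1–7 for the transmembrane bundle,
8 for helix 8; offsets zero-padded to two digits). A `SegmentMap` anchors
each helix segment at a 1-based sequence position; labels within a segment
are pure sequence offsets from the anchor, with no structure-based bulge
or gap correction — the anchorings this package targets (e.g. a TM6 span
whose endpoints are 20 residues and 20 offsets apart) are strictly
consecutive, so offset arithmetic is exact there.

Label propagation across a multiple alignment transfers the reference's
column labels to each target's ungapped positions. Gapped target columns
yield no label: interpolating across an indel would assert a
correspondence the alignment does not contain. A consequence is that a
mid-helix insertion in a target splits that helix into two segments; the
map invariants therefore allow several segments per helix provided their
sequence spans and their offset ranges are each disjoint and consistently
ordered. (A stricter "one segment per helix" rule would make propagation
impossible on realistic alignments.)

Sequence positions are 1-based author numbering throughout, matching PDB
`resSeq`.

## Relative variation score

For per-generic-position cancer counts `CV_i` and population counts
`NV_i`,

    RelVar_i = ln( (CV_i / max_j CV_j + 1) / (NV_i / max_j NV_j + 1) )

Natural log is used; the base only rescales the score and cannot change a
sign or a ranking. Because max-normalized counts lie in [0, 1], the score
is bounded by ±ln 2, antisymmetric under swapping the tables, and
invariant to rescaling either table. An all-zero table leaves the
max-normalizer undefined and is an error rather than a silently patched
formula.

Counting is family-wide: records from all receptors are summed at shared
generic labels (per-receptor tables are also returned). Only missense
substitutions at mapped positions count; synonymous, nonsense and
unmapped records are tallied in a skip report so that input mass is
conserved. Whether `count` holds unique variant sites or total mutation
occurrences is the caller's convention; the arithmetic supports either.

Hotspot ranking sorts by score descending, breaking ties by higher cancer
count and then lexicographic label. Conservation of an alignment column
is `1 − H/ln 20` with `H` the Shannon entropy (natural log) of the
amino-acid frequencies, gaps excluded; columns with under 50 % coverage
(configurable) are flagged.

## Contact detection and typing

A residue pair is in contact when any two heavy atoms lie within 4.5 Å
(configurable). The cutoff is a deliberate simplification of
tessellation-based contact definitions used by some web services: a single
distance threshold is transparent and exactly testable, at the cost that
fingerprints on real crystal structures may differ in detail from
tessellation-derived ones. Same-chain pairs four or fewer residues apart
are disregarded, and when generic labels are available same-helix pairs
are dropped so only interhelical contacts remain. Detection uses a k-d
tree; the tests hold it equal to an independent all-pairs scan.

Hydrogen bonds are typed by a distance-only criterion (donor/acceptor N/O
heavy atoms ≤ 3.5 Å): crystal structures carry no hydrogens, so an angle
term would be guesswork. π-cation interactions require a cation center
(Arg guanidinium centroid over CZ/NH1/NH2, Lys NZ) within 6.0 Å of an
aromatic ring centroid; Trp uses its six-membered ring by default (the
five-membered ring can be enabled). Residues missing the atoms a
criterion needs simply evaluate absent.

Superposition is pairwise least-squares (Kabsch via SVD, with the
determinant correction for proper rotations) over shared Cα atoms by
default, replacing multiple structural alignment: in this pipeline
superposition serves visualization and RMSD reporting only, and Kabsch is
exactly testable. Fewer than three shared atoms or a collinear selection
is an error.

## Trajectory metrics

The activation coordinate is the inter-residue distance between generic
positions (default 3.50–6.34, the TM3–TM6 pair), measured Cα–Cα by
default; closest-heavy-atom and side-chain-centroid rules are available
since the defining atoms are not standardized. Distributions use
half-open bins whose edges are multiples of the bin width starting at
`floor(min/width)·width`, normalized to sum to 1.

Each replicate reduces to scalar metrics: minimum distance, and the
fraction of frames strictly below / at-or-above a threshold. The
threshold has no canonical default and is a required analysis parameter;
the bundled study conditions use 10.5 Å, midway between the planted
condition means. Conditions are compared with the unpaired
pooled-variance Student t test: the reported bookkeeping
(df = n₁ + n₂ − 2, e.g. 5 for groups of 3 and 4) identifies the pooled,
not Welch, test. Identical constant groups give t = 0, p = 1; zero pooled
variance with unequal means is an error.

## Pharmacology statistics

p-values come from the t and F distributions (`2·SF(|t|)`, `SF(F)`),
floored at the smallest positive double and printed as `<1e-15` below
1e-15. One-way ANOVA reports F on (k−1, N−k) df; Fisher LSD post-hoc
p-values are *unadjusted* pairwise t tests on the pooled within-group mean
square — that is the definition of LSD, so many-group comparisons inflate
family-wise error by design. Net BRET is the acceptor/donor emission
ratio of donor+acceptor cells minus the donor-only ratio.

Concentration-response models (x = log10 dose):

- threePL: `bottom + (top−bottom)/(1+10^(logEC50−x))` (Hill slope fixed
  at 1),
- fourPL: Hill slope free,
- bell: `bottom + rise/(1+10^(m₁−x)) − fall/(1+10^(m₂−x))` — an ascending
  and a descending unit-slope logistic sharing one baseline, the simplest
  biphasic parameterization; the named model in curve-fitting software is
  not published with a unique parameterization, so this one is chosen and
  documented.

logEC50 is base-10 (a 10-fold potency shift is ΔlogEC50 = 1.0). Fitting
is least squares (`scipy.optimize.curve_fit`) with deterministic
multi-start initialization — a grid of logEC50 starts spanning the dose
range (5 by default; all ordered midpoint pairs for the bell model) — to
avoid local minima. Non-convergence is flagged on the result, not raised;
fewer distinct doses than parameters is an error.

## Synthetic data: what it emulates and what it does not

All generators run off one `numpy.random.default_rng(seed)`; identical
(seed, config) reproduce byte-identical outputs, and ground truth is
returned and embedded as `# key: value` headers.

- **Variant tables** — 50 generic positions across 7 helices, per-position
  counts Poisson(base rate 5), with one hotspot whose cancer count is
  Poisson(enrichment × base rate); enrichment 10 is the bundled condition.
  The population table is an exchangeable null. Real cohorts differ:
  mutation rates vary by position and context, cohort sizes are far
  larger, and somatic/germline sampling is not Poisson-homogeneous — so
  recovery tests show the score's behavior under clean enrichment, not
  cohort realism. Note a structural property of the score: when the
  hotspot's own population count happens to reach the population maximum,
  RelVar at the hotspot collapses toward 0; under the bundled conditions
  direct simulation puts the probability that the planted hotspot ranks
  first at ≈ 0.95, so single-digit failure counts per 100 replicates are
  expected behavior of the score, not of the implementation.
- **Alignments** — per-column categorical draws with configurable
  consensus probability and number of alternatives; no phylogenetic
  correlation, so conservation scores are unbiased but their sampling
  variance is smaller than on a real tree.
- **Helix bundles** — ideal Cα helices (2.3 Å radius, 1.5 Å rise, 100°
  twist) antiparallel on a circle with 12.2 Å adjacent-axis spacing;
  planted contacts add pseudo side-chain atoms placed exactly 4.0 Å
  apart, and the generator verifies that every non-planted interhelical
  pair stays beyond cutoff + 0.5 Å (raising on geometric infeasibility),
  so the planted set is exactly the detectable set. Real helix bundles
  have side-chain packing, kinks and loops these fixtures deliberately
  lack.
- **Trajectories** — per-frame distances i.i.d. Normal(mean, sd)
  truncated at zero, default 3 wild-type replicates at 9 Å vs 4 mutant
  replicates at 12 Å, sd 1 Å, 1000 frames. Real MD distance series are
  autocorrelated; an optional AR(1) coefficient (default 0) exists for
  sensitivity checks. With i.i.d. frames the per-replicate metrics are
  effectively noise-free, so the t test's power under the planted shift
  is near 1 — passing the power suite shows calibration of the pipeline,
  not MD realism.
- **Dose-response** — model-evaluated curves over 8 log-spaced doses
  (10⁻¹¹–10⁻⁵ M) plus Gaussian noise, default sd 0.05 of a unit-top
  curve (5 % of top).

## Problem sizes

The bundled suites use 100-seed recovery runs, 500-seed null calibration,
20-bundle contact audits and 1000-frame replicates — sizes chosen so the
full pipeline (generation through statistics) re-runs from scratch in
minutes on one CPU while leaving the statistical assertions well
determined.

## Known limitations

- No structure-based numbering corrections, class A/B schemes, or
  numbering database lookups.
- No mmCIF or binary trajectory formats (DCD/XTC); structures and
  trajectories travel as PDB or delimited text.
- No significance test for hotspot enrichment: the score is descriptive.
- The Fisher LSD p-values are intentionally unadjusted (see above).
- The hydrogen-bond criterion ignores geometry beyond distance; the
  π-cation criterion uses centroids only (no ring-normal angle).
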