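# Methods

## Scope

`epishift` implements two analysis arms around one scientific question:
how a missense substitution in a multidomain plasma glycoprotein
(β2-glycoprotein I, W335S in Domain V) changes which parts of the
molecule are presented to solvent, membranes and antibodies across its
conformational ensemble — and, upstream of that, how a single-locus
causal-genetics chain (fine-mapping, Mendelian randomization,
colocalization, criteria-based prioritization) singles out such a variant
from a GWAS signal. Residue numbering throughout includes the signal
peptide (the Domain V tryptophan is residue 335; studies that drop the
signal peptide call it W316).

## Structural arm

### Geometry kernels

* **Superposition / RMSD.** Optimal proper rotations come from the
  Kabsch/SVD solution (`scipy.spatial.transform.Rotation.align_vectors`,
  det = +1 enforced, so mirror images are never matched). RMSD is
  reported either raw or after superposition; masks default to all atoms,
  with a Cα-only helper for backbone work.
* **Radius of gyration.** √(Σwᵢ|rᵢ−r̄|²/Σwᵢ), unit or atomic-mass
  weights.
* **SASA.** Shrake–Rupley with a deterministic golden-spiral lattice
  (default 960 points, probe 1.4 Å — water). Per-atom area is the
  accessible-point fraction times 4π(r+probe)²; neighbour search is
  cut off at rᵢ+rⱼ+2·probe. The lattice is not rotated with the body, so
  areas drift ≤0.5% under rigid motion at 960 points; there is no RNG, so
  results are bit-stable. Per-residue areas sum member atoms (all atoms
  present in the file — no heavy-atom filtering). Tests check an isolated
  sphere against the closed form (1%) and random clusters against a
  2×10⁵-point Monte-Carlo rejection oracle (2%).

### Ensemble analysis

All labelled trajectories are concatenated over one topology so a single
PCA basis describes every repeat and model. Alignment is a two-pass
mean-structure fit (fit all frames to frame 1, recompute the mean, refit)
— deterministic and idempotent. Coordinate PCA runs on flattened Cα
coordinates (full SVD); eigenvalue sum equals total aligned variance and
full-rank reconstruction is exact to 1e-8, both asserted.

Conformations are clustered by average-linkage agglomeration on Euclidean
distance in the first 4 principal components, cut to a fixed cluster
count (default 6 to mirror the source analysis; 3 for the synthetic
world's three states). Cluster ids are relabelled in first-occurrence
order, so the partition — not the labelling — is the invariant object.
Display names ("O-Shape", "J-Shape 1", …) are caller-supplied: shape
semantics are assigned by inspection, not inferred.

A k-means elbow rule suggests the cluster count: the k maximising the
second difference of **log** within-cluster sum of squares (10 restarts,
fixed seed). Log curvature is scale-invariant; the raw-inertia version
degenerately picks k=2 whenever the first split dominates, even for three
well-separated states. A flat curve is logged as low-confidence.

Cluster midpoints are the member frames nearest the PC-space centroid
(ties → lowest index); profiles report RMSD-to-midpoint (after
superposition), radius of gyration and per-model occupancy. The
occupancy timecourse bins frames by time per model and reports the
fraction outside a reference cluster, with the half-departure time (first
bin midpoint at fraction ≥ 0.5) as a scalar transition-speed summary.

### Exposure and antigenicity

Per-residue SASA is averaged within each (model, cluster) stratum. Motif
exposure is the **sum of member-residue mean SASA** (the loop treated as
a unit); percent deltas are relative changes of that sum, either against
a reference cluster of the same model (conformational change) or against
the same cluster of a reference model (variant effect). Negative =
more buried. Dispersion is the per-frame sd; no inferential statistics
are attached — the quantities are descriptive, like the source analysis.

Antigenicity mirrors the exposure pipeline on per-residue scores.
Scores come either from CSV exports of an external structure-based
epitope predictor (imported and validated, never recomputed — the
predictor is a trained neural model outside this package's scope) or
from a transparent **surrogate**: relative solvent exposure, residue SASA
divided by its isolated-sphere maximum, in [0, 1]. The surrogate is
monotone in SASA by construction; it makes the sampling → averaging →
delta machinery testable offline and is clearly labelled via
`scorer_tag` in every output. Frames are sampled uniformly without
replacement per stratum (default 100, explicit seed).

## Causal-genetics arm

* **Wald ratio.** With one instrumental variant, ratio = β_out/β_exp and
  se = se_out/|β_exp| — the first-order NOME approximation (the
  instrument-exposure association treated as measured without error);
  two-sided normal p; instrument strength F = (β_exp/se_exp)².
  The bootstrap oracle resamples only the outcome effect, matching NOME.
* **Colocalization.** Wakefield log-ABF per variant and trait:
  labf = ½(log(1−r) + r·z²), r = W²/(W²+se²), with effect-prior sd
  W = 0.2 (quantitative) / 0.15 (binary) and priors p1 = p2 = 1e-4,
  p12 = 1e-5 — the conventions of the standard single-signal ABF
  framework, CLI-exposed. Hypothesis sums H0…H4 accumulate in log space
  (log-sum-exp; H3 via a log-difference), per-variant PP4 is the
  normalized exp(labf₁+labf₂). Verdicts: PP4 > 0.9 shared, 0.5–0.9
  suggestive. The multi-signal extension is out of scope: its inputs
  require an external fine-mapping fit.
* **Credible sets.** Variants sorted by decreasing PIP (ties
  lexicographic), accumulated to the coverage level; minimality holds by
  construction and is property-tested. PIPs are consumed as input — the
  variational fine-mapping algorithms that produce them are out of scope.
* **LD.** Squared Pearson correlation of dosages; monomorphic variants
  are rejected by name.
* **Prioritization.** Non-coding variants need ≥2 of: narrow-peak-backed
  regulatory overlap (gapped-peak-only overlap is recorded but not
  counted), a predicted enhancer→gene link, association with *increased*
  target expression, and QTL colocalization. Coding non-synonymous
  variants are prioritized directly with the deleterious predictor
  fraction attached. All four flags are externally-looked-up inputs.
* **Harmonization.** Swapped allele pairs flip β and EAF; strand-ambiguous
  pairs (A/T, C/G) warn and are kept, with an EAF sanity check when both
  frequencies are informative.

## Synthetic world

### Conformer generator

A 60-residue, two-beads-per-residue chain (backbone bead r = 1.9 Å, side
bead r = 2.0 Å at ≤2.5 Å offset, 3.8 Å backbone spacing). Three idealized
planar states: a circle (O), a line with the last ⌈n/6⌉ residues bent 90°
(J), and a line with two opposite 90° bends (S) at 0.43n/0.83n — bend
positions chosen to maximize the minimum pairwise separation (aligned
RMSD: O–J 48 Å, J–S 25 Å, O–S 34 Å), making the three states genuinely
well-separated.

Each circular-start repeat follows O→J→S under two logistic switches.
The per-repeat switch is **near-two-state** (rate 0.02 frames) — single
molecules flip cooperatively — while the switch *time* is jittered
±15 frames per repeat, so the ensemble-level departure from the circular
state is gradual. The variant model's midpoints sit 20 frames after the
wild type's (90 vs 70 of 200 frames, 0.1 ns/frame): the planted "slower
transition". Linear-start repeats stay pinned at J. Gaussian noise
(σ = 0.5 Å) perturbs backbone beads; side beads are then placed exactly
on their planted directions from the noisy backbone, preserving the
offset bound in every frame.

Side-bead placement encodes the planted residue-level phenotype. Each
bead has a direction interpolated among the outward chain normal, the
chain tangent (occluded by backbone neighbours) and ±z out of the chain
plane (maximally exposed; signs alternate along a motif so neighbouring
side beads do not shadow each other), plus an offset scale ≤ 1 that can
sink the bead into its backbone bead. Wild type: neutral tilt everywhere
*except* the functional loop, whose side beads are fully exposed — the
phospholipid-insertion loop's tryptophan points into solvent in the real
wild type; that is its function. Variant: the loop is buried along a
monotone placement path and the epitope motif is exposed along another,
each **calibrated by bisection against actual SASA** on the noiseless
extended geometry until the planted targets are hit (−30% loop burial,
+10% motif exposure; achieved −30.1%/+10.0%). The planted deltas are
therefore real, measurable properties of the generated structures, not
labels. Ground truth records per-frame state labels, per-residue classes
and both planted and achieved fractions.

What a green test establishes: the analysis pipeline recovers planted
state structure and exposure changes from noisy coordinates. What it does
not: anything about force fields, solvent, kinetics beyond a logistic
switch, or the real protein's cluster count (~6) and within-cluster RMSD
(~10 Å) — those are properties of the real trajectories, out of reach at
desk scale.

### GWAS generator

Dosages come from thresholding a latent Gaussian field per haplotype
(liability-threshold; Hardy–Weinberg by construction). Two deliberate
refinements over the naive AR(1) latent chain:

1. **Smooth MAF field.** MAFs vary smoothly along the region (an AR(1)
   latent mapped into the MAF range). iid MAFs are mathematically
   inconsistent with ρ = 0.9 dosage LD — the Fréchet bound caps the
   correlation of indicators with mismatched marginals (e.g. at 0.27 for
   MAF 0.05 vs 0.42). Real high-LD variants share haplotypes and hence
   frequencies; the source's own 18-variant credible set all sits at
   EAF 0.05–0.06.
2. **Calibrated latent correlations.** Thresholding attenuates
   correlation, so each pair's latent correlation is solved (bisection on
   the bivariate-normal indicator correlation, quadrature-evaluated) to
   make realized dosage LD match ρ^|i−j|; the assembled matrix is
   eigenvalue-clipped to PSD and sampled by Cholesky. Measured mean
   absolute deviation from the target: 0.047 at n = 5000.

Traits are simulated in two independent cohorts (two-sample setting):
y = β·g_causal + N(0, 1−ve) with β scaled so the causal variant explains
1% of variance (n = 5000, 50 variants by default); per-variant marginal
regressions give β/se/p. The distinct-causal mode draws trait 2's causal
variant ≥20 positions away (LD ρ²⁰ ≈ 0.12).

## Numerical choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` with seed sequences; derived seeds stay
  below 2³¹); SASA and clustering are RNG-free.
* Credible-set accumulation uses a 1e-12 tolerance on the coverage
  comparison; coloc's H3 log-difference clamps to −∞ on underflow.
* Degenerate inputs: superposition rejects <3 or collinear atoms; PCA
  refuses unaligned ensembles; empty strata and monomorphic variants are
  errors naming the offender; a reference cluster empty for one model is
  a warning, not an error.
* Percent exposure change is undefined (flagged, absolute change still
  reported) when the reference mean is zero.

## Known limitations

* The planar toy chain bounds how buried a residue can get; burial
  targets beyond ~35% of an exposed reference are clamped with a warning.
* The SASA lattice is body-fixed, so areas are not exactly
  rotation-invariant (≤0.5% at 960 points).
* Single-signal colocalization only; regions with multiple causal
  signals per trait need the conditional/fine-mapped extension.
* The antigenicity surrogate is exposure, not immunogenicity: it ranks
  residues exactly like SASA and cannot reproduce sequence- or
  physics-driven epitope effects of a trained predictor.
* Strand-ambiguous variants are kept (warned), matching common practice
  for EAF-informative data; palindromic variants near EAF 0.5 remain
  genuinely unresolvable.
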