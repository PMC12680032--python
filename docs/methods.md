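# Methods

## Scope and model

`smrlink` implements the computational core of a linked single-cell
biophysics + transcriptomics workflow for B-cell malignancies measured on a
suspended microchannel resonator (SMR): (i) an Earth Mover's Distance (EMD)
"mass response" statistic with a resampling decision rule that calls ex
vivo drug sensitivity from three single-cell buoyant-mass distributions,
(ii) a gene–biophysics association pipeline (QC, normalization, gene
filtering, Spearman correlation, cross-gene z-scoring, permutation null
bounds), and (iii) the buoyant-mass → density conversion. Because the
patient and PDX measurements this kind of study rests on are not publicly
available, a synthetic-data generator reproduces their statistical
structure so that every stage is testable end to end.

## Buoyant mass and density

The SMR measures buoyant mass `m_b = V(ρ − ρ_fluid) = m(1 − ρ_fluid/ρ)`
(pg, μm³, g/cm³; the identity 1 pg/μm³ = 1 g/cm³ closes the units). With a
paired volume measurement, density is `ρ = ρ_fluid + m_b/V` and total mass
`m = ρV`. The measurement buffer density defaults to 1.005 g/cm³; a cell
with `m_b = 0` is neutrally buoyant at exactly that density. The round trip
ρ → (m, m_b) → ρ is exact to 1e−12 relative tolerance. Distribution
summaries (median, IQR) use numpy's linear-interpolation quantiles
("type 7") and record the convention in the output.

## Mass response, θ, and the decision rule

For drug-treated masses X, a DMSO vehicle replicate Y, and a DMSO reference
Z (viable cells only when a viability flag is present):

    MassResponse(X) = EMD(X, Z) / Σᵢ Zᵢ = Σᵢ |X₍ᵢ₎ − Z₍ᵢ₎| / Σᵢ Z₍ᵢ₎
    θ(X, Y, Z)      = MassResponse(X) − MassResponse(Y)

The sorted (order-statistic) pairing is the optimal 1D transport coupling,
so `EMD/N` equals the 1-Wasserstein distance between the empirical
measures; this is verified in tests against a brute-force transportation
linear program. The statistic is dimensionless, non-negative, and invariant
under common rescaling; θ subtracts the replicate-level divergence the
vehicle shows against the reference, which at thousands of cells per arm
would otherwise register as "significant" drift.

**Unequal arm sizes.** The formula presumes equal N. Real runs differ, so a
`harmonize` step reduces both samples to N = min of the sizes, by default
by evaluating both empirical quantile functions on the midpoint probability
grid p_j = (j − ½)/N (Hazen convention: order statistic i at (i − ½)/n,
linear interpolation, clamped tails). This choice is deterministic and has
the property that equal-size samples pass through unchanged. A seeded
without-replacement `subsample` policy is available for exact equal-N
semantics. Within θ, all three samples share one target length so the
reference term is identical in both mass responses.

**Significance.** θ is compared to a resampled null built under the
no-effect hypothesis, where the drug and vehicle arms are exchangeable.
Each of the `n_boot` null rounds (default 10,000) randomly splits the
pooled drug+vehicle masses back into two arms of the original sizes, keeps
the reference arm fixed (both mass responses are measured against the same
reference, so inference is conditional on it), and recomputes θ. The
replicates are studentized by their standard deviation and the observed θ
is ranked among them on the same t scale with the add-one estimator
p = (1 + #{θ* ≥ θ_obs})/(n_boot + 1); one-sided "greater" is the default
alternative because the biological claim is a drug-induced mass reduction.
The without-replacement split makes the test exactly level-α under
exchangeability; measured at 300 cells/arm over 1000 simulated null
triplets it rejects at 0.04–0.05 with null p-values uniform (KS < 0.05).

Two alternative null schemes are provided for comparison.
`null_scheme="pooled"` resamples the two arms from the pool *with*
replacement (slightly conservative, true level ≈ 0.04).
`null_scheme="resample_all"` resamples all three arms from themselves and
centers the θ* replicates at their mean; this scheme does not impose the
null and — as is known for naive resampling of non-smooth Wasserstein-type
statistics — is markedly conservative here (measured type-I ≈ 0.015 at
α = 0.05, with non-uniform null p-values). It is retained as an option and
documented as such, not used by default.

`n_boot < 200` is refused (unstable tail); a fully degenerate triplet (all
masses identical) returns p = 1. Results are bit-identical for a fixed
seed.

## Gene–biophysics association

1. **Cell QC.** A cell is removed when its total count is below 1000 or its
   mitochondrial fraction (genes matched by symbol prefix, default `MT-`)
   exceeds 20% — both strict inequalities, so a cell at exactly 1000 reads
   or exactly 20% is retained. The filter is idempotent and reports each
   removed cell with its reason.
2. **Model-specific gene exclusion.** Genes expressed (raw count > 0) in
   fewer than 10% of cells in *any* model are dropped before cross-model
   correlation, removing sex/immunoglobulin-type idiosyncrasies; exactly
   10% in every model is retained.
3. **Normalization.** Counts-per-10,000 per cell, then ln(1 + x); the scale
   factor is configurable.
4. **Spearman correlation.** Per-gene rho against each biophysical
   covariate, average-rank ties (identical to `scipy.stats.spearmanr`,
   cross-checked in tests), vectorized as a rank-Pearson matrix product so
   the 10,000-iteration permutation null is tractable. Constant genes yield
   NaN and are excluded downstream.
5. **z-scores and selection.** The gene-wise rho distribution is
   standardized across genes (mean/sample-sd) and genes with z > 2.5
   (strict) are selected per covariate. Cross-gene standardization — rather
   than a per-gene Fisher transform — is the default because a common 2.5
   cutoff applied to two differently distributed correlates (mass and
   stiffness) is only comparable after placing both rho distributions on a
   common scale; a Fisher variant (`method="fisher"`) is provided and
   preserves the ranking.
6. **Combined ranking.** Descending average of the two z-scores, ties
   broken lexicographically by gene symbol for determinism.
7. **Permutation bounds.** The per-cell biophysical vector is permuted over
   cells (default 10,000 iterations; 1000 in the fast analyses) and the
   per-gene 95th percentile of the signed null rho is reported as an
   empirical upper bound. Signed (not absolute) percentiles are the
   default; mass and stiffness nulls use independent permutation streams.
   Under an independent null ≈ 5% of genes exceed their bound.

No multiple-testing correction is applied at the z > 2.5 gate; the gate is
a nomination step, not an FDR-controlled discovery list.

## Synthetic data

**Linked datasets** (default 3 models × ~167 cells = 500 cells, 2000
genes; a 500 × 9442 preset mirrors the published platform scale but is not
needed for testing). Per cell: model, cell-cycle phase from per-model
(G0/G1, S, G2/M) fractions (0.65/0.20/0.15), buoyant mass = model median ×
phase multiplier (1, 1.3, 1.7) × lognormal(σ = 0.25) noise, and an
independent lognormal stiffness — independence gives the near-zero
mass–stiffness R² (measured ≈ 0.002 at 500 cells, matching the order
observed on the platform). Model mass medians default to 59/47/44 pg,
lymphoma-cell magnitudes consistent with ~800–1100 μm³ cells a few percent
denser than the buffer. Counts are negative binomial (var = μ + 0.5μ²) via
gamma–Poisson mixing, with lognormal library sizes (median 50,000 for the
2000-gene matrix — Smart-seq2-like depth scaled to the reduced gene count)
and Beta(2, 38) mitochondrial fractions spread over 13 `MT-` genes.
Designated gene subsets have their log-mean coupled linearly to the
standardized log-mass and/or log-stiffness covariate. The default coupling
(`effect_size` = 0.3 log-fold per SD) was calibrated once so the realized
injected-gene Spearman |rho| is ≈ 0.3 at the default dimensions, the
regime in which the z > 2.5 gate recovers ≥ 80% of 30 injected genes with
few false positives. A 5% fraction of cells is made deliberately
low-quality (< 1000 reads or > 20% mitochondrial); because count noise
could pull a designated cell back over a gate, the designation is enforced
deterministically after sampling (integer rescaling of the offending
cell's counts), keeping the QC ground truth exact.

**Drug triplets** (default 1000 cells/arm, lognormal median 60 pg,
σ = 0.25). Reference and vehicle are i.i.d. draws, with the vehicle median
perturbed by a small lognormal replicate jitter (σ = 0.01, emulating
replicate-to-replicate drift); the drug arm's median is multiplied by
1 − 0.20 for "sensitive" samples and is untouched for "resistant" ones.
The jitter's effect on the resistant rejection rate is negligible at this
magnitude (measured ≈ 0.04–0.06 at α = 0.05).

What the generator does **not** emulate: transcriptome covariance
structure, batch effects, doublets, cell-cycle coupling of expression (the
cycle drives mass only), or empirical SMR noise. Passing tests therefore
demonstrate the correctness and calibration of the *procedures* under the
stated generative assumptions, not performance on real patient data.

## Problem sizes and numerical choices

The repeated-simulation studies use 1000 null repeats at 300 cells/arm and
n_boot = 2000 for calibration, 200 repeats at 1000 cells/arm for power,
20 seeds for the recovery and decorrelation studies, and 1000 permutation
iterations for null-coverage checks — sizes at which every headline
quantity is stable to well under its tolerance and the full suite runs in
minutes on one CPU. All experiment seeds derive from a single integer via
`numpy.random.SeedSequence` spawning; every stochastic stage is
bit-reproducible given its seed. Floating-point output uses ≥ 12
significant digits (events files use 17, round-tripping float64 exactly).

## Known limitations

- The decision rule tests a single drug-vs-vehicle contrast; screening many
  drugs would need multiplicity control the workflow deliberately omits.
- The quantile-interpolation harmonization slightly smooths heavy tails at
  very small N; the subsample policy avoids this at the cost of randomness.
- Cross-gene z-scoring makes selection relative: planting many strong
  associations inflates the rho spread and raises the effective selection
  bar.
- The permutation bound is marginal per gene, not family-wise.
- Whether the two DMSO replicates should be treated as paired in the
  resampling is unresolved; arms are resampled independently.
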