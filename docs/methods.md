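# Methods

## Exchange model

Each non-proline residue *i* exchanges as a single exponential under the
EX2 limit:

    D_i(t) = 1 − exp(−(k_int,i / P_i,eff) · t)

with intrinsic rate `k_int,i` (1/s) and effective protection factor
`P_i,eff ≥ 1`. Ligand effects are additive on log10 P over named structural
regions and scaled by fractional occupancy:

    log10 P_i,eff = log10 P_i,baseline + occupancy · Σ_regions∋i Δlog10P

Fractions are Dmax-normalised (relative to full exchange), so the D2O
fraction of the labelling mix and back-exchange losses cancel; they matter
only in "raw centroid" mode, where %D values are mapped onto
(undeuterated, observed, Dmax) centroid triples that invert exactly through
the uptake formula `%D = 100·(m_obs − m_0)/(m_Dmax − m_0)`. Using the
empirically back-exchanged Dmax control as the 100% reference *is* the
back-exchange correction; no separate factor is applied.

Peptide observations are the mean exchanged fraction over the peptide's
exchangeable residues (first two residues and prolines excluded) × 100,
plus Gaussian replicate noise, clipped to [0, 100].

### Default construct and parameters

- 254 residues numbered 265–518; helices H1–H12 plus a β-sheet region (BSR)
  at fixed spans; random sequence with prolines placed explicitly at 5% so
  exclusion rules are exercised.
- Baseline log10 P drawn per residue around region means (SD 0.3, clipped at
  0): structured core ≈ 1.8–2.2, loops 1.0, BSR 1.5, and H10–H12 ≈ 0.4–0.5
  so the activation-helix region exchanges fast (essentially fully
  deuterated by 10 s in the apo state) while the core spreads across the
  time course.
- log10 k_int uniform on [−1, 1.5] (0.1–30 1/s), the physical regime of
  unstructured amides near neutral pH, rather than sequence-dependent rate
  tables: the analysis uses only relative protection, and keeping k_int fast
  makes a region's observed speed protection-determined, which is what gives
  the 10 s timepoint its diagnostic value for H12. (A wider, slower window
  would park artificial slow amides inside the "fast" helix and smear its
  signal onto the 4-hr timepoint.)
- Time courses: 8 points (0, 10, 30, 110, 380, 1270, 4270, 14400 s) for the
  full mode; (10 s, 4 hr) for the screen. The 0 s row is the undeuterated
  reference, not a curve point.
- Replicates: 3 (time course) / 5 (screen); replicate noise 1.5 percentage
  points of %D — a typical HDX replicate precision; real replicate SDs for
  this system are not published, so this is a stated assumption.
- Occupancy 1.0 (single saturating concentration, as in the screen design).

### Compound library

38 compounds in three classes (13 agonists, 13 partial agonists, 12 inverse
agonists by largest-remainder rounding). Every binder carries a binding
signature (Δlog10P: BSR 1.5±0.15, H3 1.2±0.15, H7 1.2±0.15, H2 0.8±0.12);
agonists add H12 2.0±0.15, H4 1.2±0.15, H10 1.2±0.15; partial agonists add
H12 0.7±0.10; inverse agonists add nothing; effects truncated at 0.

### Paired vehicle arms

Screens are simulated as N separate differential experiments, each carrying
its own vehicle control (the `experiment` column of the uptake table), the
way screening data are actually acquired and exported. A shared-control
layout is also supported but couples all compound-versus-vehicle contrasts
through one noise draw, which can flip many compounds at once at a single
noisy cell.

### Assay links

Each functional assay is linear in a planted regional-stabilization score —
the noise-free regional Δ%D: AlphaScreen (RLU) vs H12 at 10 s, thermal shift
(ΔTm, °C) vs BSR at 10 s, cell reporter (fold change) vs H2 at 4 hr. Noise
is tuned to a target population R² (0.64 / 0.54 / 0.51 respectively) via
`sd(e) = |slope| · SD(score) · sqrt((1−R²)/R²)` over the realized library,
so downstream correlation estimates have a known population value.

### What the generator does and does not emulate

It emulates: overlapping peptic maps (54 peptides, ~98% coverage of 254
residues), class-structured region-specific protection, two-timepoint
screening with replicate noise, and activity readouts with controlled
signal-to-noise. It does not emulate: EX1/bimodal kinetics, isotope
envelopes or spectral peaks, sequence-dependent intrinsic rates, concerted
inter-region motions beyond the class structure (e.g. a per-compound
binding-strength factor that would correlate BSR/H3/H7/H2 jitter), pH/
temperature dependence, or partial occupancy kinetics. Passing tests
therefore certify the statistical machinery under a faithful EX2 signal
model, not peak-level data processing or exotic exchange regimes.

## Statistical conventions

- Δ%D = mean %D(compound) − mean %D(vehicle) per peptide-timepoint; Welch
  two-sample two-tailed t-test (no equal-variance assumption; the underlying
  report says only "t-test"). Cells need ≥2 replicates per arm for a
  p-value; with zero variance in both arms, p = 1 for equal means (flagged)
  and p = 0 otherwise. Missing cells stay missing, never zero.
- Benjamini–Hochberg families: per compound across its peptide-timepoint
  family for perturbation calls (each compound's signature is one family; a
  global scope is available); per assay for activity correlations; the
  upper triangle of pairs for covariation. Family boundaries are not fully
  specified by the source analysis; these choices match the screening
  narrative and are configurable.
- Screening filter: keep a peptide-timepoint cell iff ≥15 compounds (or
  ≥15/38 as a fraction for other library sizes) are significant at FDR
  < 0.05. Counting is per cell, not per peptide ("either timepoint"), which
  reproduces the "peptide-timepoints combinations" bookkeeping. An optional
  |Δ%D| magnitude threshold (e.g. 5 pp) exists but defaults to off — the
  source text is ambiguous about whether one was applied, and "FDR <0.05%"
  is read as FDR < 0.05.
- Activity correlation: OLS of activity on Δ%D; Pearson r² reported;
  significant at adjusted p < 0.05, "predictive" at R² > 0.4. Constant
  columns or n < 3 are flagged undefined and excluded from the BH family.
- Covariation: both timepoints of every kept peptide enter as separate
  columns, labelled `start-end(charge)@timepoint`; complete-case across
  compounds; display mask at adjusted p < 0.01; the grid is symmetric with
  unit diagonal (anticorrelation gives r² = 1 by construction).
- Clustering: Ward linkage on Euclidean distances between Δ%D signatures
  (Ward is stated by the source; Euclidean is its standard companion);
  peptide-timepoints with any missing value are dropped by default
  (mean-imputation optional); SciPy's lowest-index tie-break makes trees
  deterministic for a fixed input order.
- Outliers: points outside the 95% prediction interval
  `ŷ(x₀) ± t₀.₉₇₅,ₙ₋₂ · s · sqrt(1 + 1/n + (x₀−x̄)²/Sxx)`; n ≥ 4 required.
- Consolidation weights: w = 1/n_exchangeable. Only the direction ("shorter
  peptides weighted more heavily") is documented by the source; inverse
  exchangeable length is the simplest monotone choice and the weight
  function is pluggable. Coverage uses full peptide spans; consolidation
  uses exchangeable subsets.
- Numerics: %D written with 6 significant digits; all simulator randomness
  behind one integer seed (child streams via `SeedSequence`); byte-identical
  reruns for identical seeds.

## Problem sizes used in the test suite

Oracle-equivalence checks run 1000 random instances each; type-I and
correlation-recovery checks use 50 simulated 38-compound screens;
planted-effect and clustering-recovery checks use 20; the shared unit-test
study uses 12 compounds. The whole suite completes in about a minute.

## Known limitations

- The correlation-recovery band (sample R² within ±0.12 of 0.64 at n = 38)
  sits at ≈1.6σ of the sampling distribution of a sample R², so even an
  unbiased estimator meets it in only ~88% of draws; the pipeline's
  estimator is unbiased to within +0.02 with SD ≈ 0.07.
- Boundary peptides sharing one or two exchangeable residues with a
  perturbed region receive a strongly diluted planted effect and may
  legitimately fall below detectability; region-recovery statements are
  therefore made for peptides whose planted effect is at least 5 pp.
- The HDX-Workbench header shim covers common export layouts only; real
  exports may need additional aliases.
- No EC50 fitting, mixed-effects HDX models, hybrid significance limits,
  spectral simulation, or structure rendering (per-residue B-factor lists
  are exported for external painting tools).
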