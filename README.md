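# hdxscreen

Differential hydrogen-deuterium exchange mass spectrometry (HDX-MS) turns a
protein's backbone-amide exchange kinetics into a residue-resolved readout of
structure and dynamics: amides protected by structure exchange slowly
(observed rate `k_obs = k_int / P` for intrinsic rate `k_int` and protection
factor `P`), and a bound ligand shows up as a change in percent deuterium
incorporation (Δ%D) of the peptic peptides covering its binding site and any
allosterically coupled regions.

`hdxscreen` is a pipeline for *screening* compound libraries this way, built
for the nuclear-receptor use case (a ligand-binding domain whose C-terminal
activation helix H12 orders upon agonist binding) but generic in its
machinery. It provides, as composable library modules and a CLI:

- **uptake** — centroid m/z → %D conversion against undeuterated and
  maximally deuterated (Dmax) reference spectra (the empirical back-exchange
  correction), replicate uptake curves, exchangeable-residue bookkeeping
  (first two residues and prolines excluded);
- **differential** — per peptide-timepoint Δ%D versus vehicle with Welch
  t-tests, Benjamini–Hochberg FDR adjustment, and the screening filter that
  keeps peptide-timepoints where ≥15 of 38 compounds (or a configurable
  fraction) perturb exchange significantly at FDR < 0.05;
- **consolidation** — residue-level averaging of overlapping peptides with
  inverse-length weighting (shorter peptides weigh more), coverage maps, and
  B-factor-style per-residue exports for structure painting;
- **screening_stats** — per peptide-timepoint linear regression of assay
  activity (AlphaScreen RLU, thermal shift ΔTm, cell-reporter fold change) on
  Δ%D with the adjusted-p < 0.05 / R² > 0.4 significance and predictiveness
  conventions, all-pairs covariation correlograms (adjusted p < 0.01 mask),
  Ward hierarchical clustering of compound exchange signatures, and 95%
  prediction-interval outlier flagging;
- **exchange_model** — a forward simulator of the whole study: protection-
  factor exchange kinetics, a 54-peptide / ~98%-coverage peptic map over a
  254-residue construct, a 38-compound library in three pharmacological
  classes (agonist / partial agonist / inverse agonist) with region-specific
  planted effects, and functional-assay readouts linearly coupled (with tuned
  noise) to planted regional-stabilization scores — so every downstream stage
  is testable against known ground truth;
- **io / cli** — CSV dialects (including an HDX-Workbench-style header shim),
  FASTA, YAML run configs, and the `hdxscreen` command.

## Worked example

Simulate a default two-timepoint (10 s / 4 hr) screen and analyse it:

```bash
hdxscreen simulate --out sim --seed 1
hdxscreen screen --uptake sim/uptake.csv --activities sim/activities.csv \
    --fasta sim/construct.fasta --out results
```

which prints `wrote 4 files to sim` and `wrote 11 files to results`. The
same run through the library (seed 1) gives:

```text
peptides: 54        sequence coverage: 98.0 %
kept peptide-timepoints: 32 of 108   (15-of-38 filter at FDR < 0.05)
top AlphaScreen correlate: H12 peptide at 10 s, R^2 = 0.692
Ward k=3 cut vs planted classes: adjusted Rand index = 1.00
```

Read: of 108 peptide-timepoint cells, 32 carry reproducible ligand
perturbations; coactivator-recruitment activity is best predicted by
protection of the activation helix H12 at the 10 s timepoint (the generator
plants a population R² of 0.64 there, and 0.692 is the sample estimate at
n = 38); and clustering the Δ%D signatures recovers the three planted
pharmacological classes exactly — inverse agonists protect only the
orthosteric pocket (β-sheet region, H3, H7), partial agonists add weak H12
protection, agonists strongly protect H12/H4/H10.

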