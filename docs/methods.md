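# Methods

## The measurement

`ighrep` implements a molecular-barcoded immune repertoire sequencing
pipeline for the antibody heavy-chain (IGH) transcript, and the statistic it
was designed to deliver: the **activated B cell sequence (ABS) level** of a
blood sample.

The biology behind the statistic: a naive B cell expresses unmutated IgM at
low copy number; once activated (which requires T-cell help and is therefore
suppressed by calcineurin inhibitors), a B cell class-switches to
IgG/IgA/IgE (or IgD), accumulates somatic hypermutation in its V region, and
expresses its IGH transcript at much higher levels. Counting the
transcripts that look "activated" therefore reads out the net activity of
the adaptive immune system — which is exactly what post-transplant
immunosuppression tries to push down, and what escapes suppression during
acute allograft rejection.

Concretely, for one sample:

1. Every original IGH mRNA molecule is tagged during library preparation
   with a 16-nt unique identifier (UID), 8 nt carried by each mate of the
   read pair. All reads sharing a UID derive from one molecule.
2. Reads are grouped by UID; a per-position majority vote over each group
   yields one consensus read pair per molecule, correcting sequencing errors
   whenever the group has coverage ≥ 2. Coverage-1 groups pass through
   uncorrected but still count as molecules — the UID makes the assay
   quantitative at the molecule level.
3. The forward consensus (framework-3 V window + CDR3) is aligned against a
   germline V-segment set; mismatches of the best hit give the somatic
   mutation rate. The reverse consensus is aligned against the five
   constant-region references; the best hit names the isotype.
4. Samples are subsampled to a common depth of 4,000 aligned consensus
   molecules (below: discarded). This is essential, not cosmetic: a clone's
   "highly expressed" status depends on the number of molecules sampled, so
   the ABS level is only defined at a fixed depth.
5. Molecules with identical forward consensus and isotype are combined into
   a clone whose molecule count is its expression level. Then

   ABS = (# highly-expressed clones that are class-switched or mutated IgM) /
         (total molecules),

   where highly expressed means ≥ 2 molecules, class-switched means
   IgA/IgD/IgE/IgG, and mutated IgM means a V mutation rate at or above a
   configurable floor (default 0.01, closed bound; the assay itself does not
   pin this constant).

Cohort-level diagnostics compare per-sample ABS levels against clinical
metadata: Pearson correlation with tacrolimus trough levels (Fisher r-to-z
interval), one-sided Mann-Whitney U tests between rejection categories, the
c-statistic against the cell-free donor-DNA (cfdDNA) comparator with a
percentile bootstrap, sensitivity/specificity/PPV/NPV at a fixed ABS
threshold (default 0.023) with continuity-corrected Wilson intervals, and
single-exponential fits of ABS trends before and after rejection events.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `subsample_depth` | 4,000 | molecules | common depth making ABS comparable across samples |
| `highly_expressed_min` | 2 | molecules/clone | "more than one molecule" defines activated-level expression |
| `mutated_igm_min_rate` | 0.01 | mutations/base | V mutation rate at which IgM counts as hypermutated (closed bound) |
| `abs_threshold` | 0.023 | ABS units | positive rejection call at score ≥ threshold |
| `cfddna_threshold` | 1.0 | % donor DNA | comparator label: elevated cfdDNA |
| `max_primer_mismatches` | 2 | bases | primer-region tolerance during UID extraction |
| aligner scores | +1/−1/−2/−1 | — | match/mismatch/gap-open/gap-extend; open covers the first gapped base |
| `min_identity`, `min_len` | 0.80, 40 | — | best-hit acceptance; below either → molecule is Unaligned |
| bootstrap | 2,000 reps | — | percentile interval for the c-statistic |

Numerical/tie-break choices (all deterministic): consensus votes break ties
by highest summed Phred quality, then lexicographically smallest base;
best-hit alignment ties go to the earlier reference in the set; traceback
prefers diagonal > vertical > horizontal; subsampling seeds derive from a
CRC32 hash of (global seed, sample id); positive calls use a closed bound
(score ≥ threshold). Mann-Whitney p-values use the exact no-ties null when
n₁·n₂ ≤ 400 and the data are tie-free, otherwise the tie-corrected normal
approximation. Degenerate inputs fail loudly: empty clone tables, zero
molecules, single-class label vectors, non-positive values in the
exponential fit (its log-linear initialisation requires positivity);
perfect correlations return a degenerate Fisher interval at ±1. No
multiple-testing correction is applied to the four group comparisons; they
are reported raw.

## The synthetic-data generator

No external sequencing data are required: `ighrep.simulate` generates
germline references, ground-truth repertoires, and paired reads, so every
stage is testable against known truth.

* **References** — random V segments (120 nt) and constant regions (100 nt)
  with pairwise global identity < 80%, plus one 20-nt primer per reference
  (pairwise Hamming ≥ 8). These stand in for curated germline databases;
  identity below the annotation cutoff makes best-hit assignment
  unambiguous by construction.
* **Clones** — each of `n_clones` (default 3,600, giving ≈ 6,000 molecules)
  is activated with probability 0.15. Activated clones draw an isotype from
  a class-switch-weighted distribution (an IgM draw is a mutated-IgM
  memory/plasmablast clone) and molecule counts from a truncated zipf law
  with exponent 1.8; naive clones are IgM, mutated with probability 0.10,
  with zipf exponent 3.0 (mostly singletons). The heavy tail is a modelling
  choice — the field observes a small minority of highly expressed
  sequences, but no published clone-size law exists for this assay, so the
  exponents are configuration, not a claim.
* **Mutations** — mutated clones carry ≥ 1 V substitutions at a per-base
  rate drawn from U(0.02, 0.10) (the realistic SHM range), planted in the
  interior of the primed 48-nt V window (3-base margin) and capped at 15% of
  the window. The margin keeps local-alignment end-trimming from hiding a
  planted substitution and the cap keeps truth alignable under the 80%
  identity contract — both are conditions on the generator, chosen so that
  ground truth is exactly recoverable at zero noise.
* **Reads** — each molecule yields 1 + Poisson(3) read pairs; every base of
  both mates (UID and primer included) substitutes independently with
  probability 0.001 (Illumina-class error after standard quality
  filtering). Qualities are constant ('I'): consensus is count-based and
  qualities only matter for its tie-break. UID errors create spurious
  coverage-1 groups (~6% extra molecules at these settings) exactly as they
  do in real UMI data; the pipeline does not network-collapse near-identical
  UIDs, so this inflation is part of what the recovery tests measure.
* **Cohort** — 12 patients × 8 sampling days over ~8.5 months; 6 carry one
  planted rejection episode (day 150–230). The activated fraction decays
  from a post-operative peak (0.30) to a maintenance floor (0.02) with a
  20-day time constant, ramps up linearly over the 60 days before the event,
  and clears exponentially (20-day constant) after it — matching the
  observed dynamics of induction, maintenance, rejection, and treatment.
  Tacrolimus troughs ramp up over ~5 days after dosing starts, plateau near
  12.5 ng/ml, and taper after month 6; samples within ±45 days of the event
  carry elevated cfdDNA (>1.2%) and 1R/2R biopsy grades and constitute the
  planted positive labels.

What the generator does **not** model: V(D)J recombination machinery and
junction diversity (clone identity is a random CDR3), indels and chimeric
reads, amplification bias, UID-network errors beyond uniform substitution,
context-dependent hypermutation hotspots, and clonal lineage structure.
Tests passing on this generator therefore demonstrate the pipeline's
correctness under substitution-type noise and heavy-tailed expression — not
robustness to indels or PCR artifacts, which the consensus stage explicitly
does not handle (length-discordant UID groups are dropped and counted).

## Evaluating recovery at matched depth

Because "highly expressed" is a property of sampled counts, the ABS of a
repertoire read at 6,000 molecules and the ABS of the same repertoire read
at 4,000 differ systematically — this is the very reason the protocol fixes
the depth. Parameter-recovery checks therefore compare the pipeline
estimate at depth 4,000 against the *expected noise-free ABS at the same
depth*, computed in closed form from the hypergeometric marginals of each
true clone's retained count (`expected_true_abs_at_depth`). The tolerance
is 4 standard errors of the subsampling distribution, estimated from 200
reseeded subsamples of the sample's own molecule table.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic data
at the following scales, chosen to exercise every stage at realistic depth
while keeping a full run in the minutes range on one core: single-sample
checks at 300–1,500 clones; parameter recovery over 50 samples of ≈ 6,000
molecules (≈ 24,000 read pairs each); the cohort study at 12 patients × 8
samples of ≈ 5,000 molecules, run twice to verify byte-identical artifacts.
The aligner is an exact affine-gap Smith-Waterman compiled with numba
(integer scoring); an independent plain-Python dynamic program serves as its
oracle in tests, never as the production path.

## Known limitations

* UID collisions (two molecules drawing the same 16-mer) are logged but not
  split; at 6,000 molecules per sample the expected impact is ≪ 1 molecule.
* Consensus assumes fixed-length trimmed reads; indel-bearing groups would
  be discarded rather than realigned.
* "Mutated IgM" depends on a rate floor the assay does not define; 0.01 is
  a documented default, and conclusions that hinge on it should sweep it.
* The ABS-vs-tacrolimus correlation is computed over individual samples;
  binning samples by trough level (with SEM bars) before correlating is a
  presentation choice the package does not impose.
* The exponential trend fits pool pre-/post-event samples across patients
  rather than fitting per-patient mixed effects.
* Pooling across samples never merges clones between samples or patients —
  IGH sequences are personal; pooled ratios are sums of numerators over
  sums of molecules. (Both conventions are arguable for pooled reporting;
  the per-sample convention is the one implemented.)
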