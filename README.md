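# ighrep

Molecular-barcoded B-cell immune repertoire sequencing pipeline and
the **activated B cell sequence (ABS) level** — a read-out of net
immunosuppression and a noninvasive marker of acute allograft rejection.

## The problem

After organ transplantation, immunosuppressive dosing is steered mostly by
drug trough levels, which say little about how suppressed the immune system
actually is. The antibody heavy-chain (IGH) transcript offers a direct
read-out: activated B cells express *high levels* of *class-switched*
(IgG/IgA/IgE/IgD) or *hypermutated* IGH transcripts, while naive B cells
express unmutated IgM at low levels. Counting activated-looking transcripts
in blood therefore measures adaptive immune activity — which falls under
effective immunosuppression and rises before and during acute rejection.

`ighrep` is for computational immunologists and method developers who want a
fully testable implementation of that assay's analysis chain: from paired
reads carrying 16-nt unique molecular identifiers (UIDs), through consensus
error correction, V/isotype annotation, depth normalisation, and clone
collapsing, to cohort-level diagnostic statistics.

## The statistic

For one sample subsampled to a fixed depth of N = 4,000 aligned consensus
molecules, with clones defined by identical (forward consensus, isotype):

```
ABS = #{ clones with ≥ 2 molecules that are class-switched or mutated IgM } / N
```

Cohort diagnostics: Pearson r with tacrolimus trough level (Fisher r-to-z
CI), one-sided Mann-Whitney U between rejection groups, the c-statistic
(ROC area) against cell-free donor-DNA (cfdDNA) labels with percentile
bootstrap CI, sensitivity/specificity/PPV/NPV at a fixed ABS threshold
(default 0.023) with continuity-corrected Wilson score intervals, and
single-exponential fits y = a·exp(b·t) of pre-/post-rejection ABS trends.

Everything runs on synthetic data: `ighrep.simulate` generates germline
references, ground-truth repertoires with heavy-tailed clone sizes, UID-
tagged paired reads with sequencing errors, and a 12-patient longitudinal
cohort with planted rejection episodes. See `docs/methods.md` for the model
and its assumptions.

## Worked example

Simulate one blood sample, then run the stages by hand:

```
$ ighrep simulate --out sim --seed 4 --n-clones 2600 --per-base-error 0.001
wrote 17109 read pairs for 4297 molecules (0 UID collisions), true ABS 0.0519

$ ighrep consensus sim/reads_R1.fastq sim/reads_R2.fastq \
    --refs sim/refs --out cons.tsv --config cfg.yaml
4538 UID groups from 17109 pairs

$ ighrep annotate cons.tsv --refs sim/refs --out mols.tsv --config cfg.yaml
4538 aligned, 0 unaligned

$ ighrep summarize mols.tsv --sample-id S1 --out sum --config cfg.yaml
S1: ABS level 0.0535
```

(`cfg.yaml` here sets `subsample_depth: 2000` so the small sample passes the
depth filter.) Reading the numbers: 4,297 true molecules became 4,538 UID
groups — the ~6% excess are reads whose UID itself caught a sequencing
error, each founding a spurious coverage-1 group; this inflation is a real
property of UMI data that the pipeline inherits. All consensus pairs
annotate to a V segment and isotype, and after subsampling to 2,000
molecules, 107 highly expressed class-switched or mutated-IgM clones give an
ABS level of 0.0535, close to the generator's true 0.0519 — a sample in the
"active" range (maintenance-phase baseline sits near 0.02, and 0.023 is the
default rejection-call threshold). The per-level isotype composition in
`sum/summary.json` shows the expected picture: singleton molecules dominated
by unmutated IgM, expanded clones dominated by IgG/IgA.

`ighrep run` drives the same stages over a sample sheet plus clinical
metadata and additionally writes `cohort_summary.csv`, `statistics.json`
(group tests, c-statistic, threshold metrics, trend fits), `roc_curve.tsv`,
and a `manifest.json` with config and output checksums — identical inputs,
seeds and configuration reproduce byte-identical artifacts.

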