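"""End-to-end pipeline: reads → consensus → annotation → clones → cohort stats.

`run_sample` takes one sample's paired reads through consensus building,
annotation, depth normalisation, and clone collapsing. `run_pipeline` drives
a whole cohort, writes every artifact (per-sample clone tables and
summaries, cohort CSV, statistics report, ROC and fit tables) plus a run
manifest with configuration and output checksums: identical inputs, seeds
and configuration produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_table
from .config import PipelineConfig
from .consensus import consensus_from_batch
from .diagnostics import (
    CAT_CFDDNA,
    CAT_MILD,
    CAT_MODSEV,
    CAT_NONE,
    binary_metrics_at_threshold,
    classify_rejection,
    fit_exponential_trend,
    mann_whitney_one_sided,
    pearson_with_fisher_ci,
    roc_c_statistic,
)
from .io import read_paired_fastq, sha256_file, write_json, write_tsv
from .metrics import (
    SampleDiscarded,
    collapse_clones,
    subsample_molecules,
    summarize_sample,
)
from .reads import ReadBatch
from .simulate import GermlineRefs


@dataclass
class SampleInput:
    """One sample's reads: FASTQ paths, an in-memory batch, or a lazy loader."""

    sample_id: str
    fastq1: Optional[Union[str, Path]] = None
    fastq2: Optional[Union[str, Path]] = None
    batch: Optional[ReadBatch] = None
    loader: Optional[Callable[[], ReadBatch]] = None

    def load(self) -> ReadBatch:
        if self.batch is not None:
            return self.batch
        if self.loader is not None:
            return self.loader()
        if self.fastq1 is None or self.fastq2 is None:
            raise ValueError(f"sample {self.sample_id}: no reads provided")
        return ReadBatch.from_pairs(read_paired_fastq(self.fastq1, self.fastq2))


def subsample_seed_for(config: PipelineConfig, sample_id: str) -> int:
    """Per-sample subsampling seed: stable hash of (global seed, sample id)."""
    return zlib.crc32(f"{config.seed}:{sample_id}".encode()) & 0x7FFFFFFF


@dataclass
class SampleResult:
    """Artifacts of one sample run (``discarded`` set when under depth)."""

    sample_id: str
    tallies: Dict[str, int]
    molecules: pd.DataFrame
    clones: Optional[pd.DataFrame] = None
    summary: Optional[dict] = None
    discarded: bool = False


def run_sample(
    sample: SampleInput, refs: GermlineRefs, config: PipelineConfig
) -> SampleResult:
    """Consensus → annotate → subsample → collapse → summarize one sample."""
    config.validate()
    batch = sample.load()
    primer_sets = (
        [p for _, p in refs.v_primers],
        [p for _, p in refs.c_primers],
    )
    consensus, tallies = consensus_from_batch(
        batch,
        primer_sets,
        uid_len_each=config.uid_len_each,
        max_primer_mismatches=config.max_primer_mismatches,
    )
    molecules, ann_tallies = annotate_table(
        consensus,
        refs,
        params=config.aligner,
        mutated_min_rate=config.mutated_igm_min_rate,
    )
    tallies = {**tallies, **ann_tallies}
    try:
        subsampled = subsample_molecules(
            molecules,
            depth=config.subsample_depth,
            seed=subsample_seed_for(config, sample.sample_id),
            sample_id=sample.sample_id,
        )
    except SampleDiscarded:
        return SampleResult(
            sample_id=sample.sample_id,
            tallies=tallies,
            molecules=molecules,
            discarded=True,
        )
    clones = collapse_clones(subsampled)
    summary = summarize_sample(
        clones, sample.sample_id, highly_expressed_min=config.highly_expressed_min
    ).to_dict()
    return SampleResult(
        sample_id=sample.sample_id,
        tallies=tallies,
        molecules=molecules,
        clones=clones,
        summary=summary,
    )


def _first_event_day(meta: pd.DataFrame, cfddna_threshold: float) -> Optional[int]:
    """Day of a patient's first moderate-to-severe or cfdDNA-flagged sample."""
    days = []
    for _, rec in meta.iterrows():
        cats = classify_rejection(
            rec["biopsy_grade"], rec["cfddna_pct"], cfddna_threshold
        )
        if CAT_MODSEV in cats or CAT_CFDDNA in cats:
            days.append(int(rec["day"]))
    return min(days) if days else None


def cohort_statistics(cohort: pd.DataFrame, config: PipelineConfig) -> dict:
    """Cohort-level report from the joined summary + metadata table.

    Expects columns: sample_id, patient, day, abs_level, tacrolimus,
    biopsy_grade, cfddna_pct. Computes rejection-group Mann-Whitney
    comparisons, the ROC/c-statistic and threshold metrics against the
    cfdDNA comparator, the ABS-vs-tacrolimus correlation, and pooled
    pre-/post-rejection exponential trends (times aligned to each patient's
    first rejection event).
    """
    stats: dict = {"n_samples": int(len(cohort))}
    cats = [
        classify_rejection(g, c, config.cfddna_threshold)
        for g, c in zip(cohort["biopsy_grade"], cohort["cfddna_pct"])
    ]
    abs_vals = cohort["abs_level"].to_numpy(dtype=float)
    none_mask = np.array([CAT_NONE in c for c in cats])
    group_tests = {}
    for cat in (CAT_MILD, CAT_MODSEV, CAT_CFDDNA):
        mask = np.array([cat in c for c in cats])
        if mask.any() and none_mask.any():
            u, p = mann_whitney_one_sided(abs_vals[mask], abs_vals[none_mask])
            group_tests[cat] = {"n": int(mask.sum()), "U": u, "p_one_sided": p}
        else:
            group_tests[cat] = {"n": int(mask.sum()), "U": None, "p_one_sided": None}
    stats["group_comparisons"] = {
        "reference_group": CAT_NONE,
        "n_reference": int(none_mask.sum()),
        "tests": group_tests,
    }

    labels = np.array([CAT_CFDDNA in c for c in cats])
    roc_points = None
    if labels.any() and (~labels).any():
        auc, lo, hi, roc_points = roc_c_statistic(
            abs_vals,
            labels,
            n_boot=config.bootstrap_reps,
            seed=config.bootstrap_seed,
        )
        stats["c_statistic_vs_cfddna"] = {"auc": auc, "ci95": [lo, hi]}
        stats["metrics_at_threshold"] = binary_metrics_at_threshold(
            abs_vals, labels, threshold=config.abs_threshold
        ).to_dict()
    else:
        stats["c_statistic_vs_cfddna"] = None
        stats["metrics_at_threshold"] = None
    stats["_roc_points"] = roc_points

    tac = cohort["tacrolimus"].to_numpy(dtype=float)
    ok = np.isfinite(tac) & np.isfinite(abs_vals)
    if ok.sum() >= 4 and np.std(tac[ok]) > 0 and np.std(abs_vals[ok]) > 0:
        r, lo, hi = pearson_with_fisher_ci(abs_vals[ok], tac[ok])
        stats["pearson_abs_vs_tacrolimus"] = {"r": r, "ci95": [lo, hi], "n": int(ok.sum())}
    else:
        stats["pearson_abs_vs_tacrolimus"] = None

    pre_pts: List[tuple] = []
    post_pts: List[tuple] = []
    for patient, meta in cohort.groupby("patient"):
        event = _first_event_day(meta, config.cfddna_threshold)
        if event is None:
            continue
        for _, rec in meta.iterrows():
            t = int(rec["day"]) - event
            if config.pre_window_days[0] <= t <= config.pre_window_days[1]:
                pre_pts.append((t, float(rec["abs_level"])))
            elif config.post_window_days[0] < t <= config.post_window_days[1]:
                post_pts.append((t, float(rec["abs_level"])))

    def _fit(points: List[tuple]) -> Optional[dict]:
        if len(points) < 3 or any(v <= 0 for _, v in points):
            return None
        fit = fit_exponential_trend([t for t, _ in points], [v for _, v in points])
        return {"a": fit.a, "b_per_day": fit.b, "rss": fit.rss, "n": fit.n}

    stats["exponential_fit_pre_rejection"] = _fit(pre_pts)
    stats["exponential_fit_post_rejection"] = _fit(post_pts)
    return stats


def run_pipeline(
    config: PipelineConfig,
    samples: Sequence[SampleInput],
    refs: GermlineRefs,
    metadata: pd.DataFrame,
    outdir: Union[str, Path],
) -> dict:
    """Run every stage for every sample and write all artifacts + manifest."""
    config.validate()
    out = Path(outdir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    manifest_samples: Dict[str, dict] = {}
    summaries: List[dict] = []

    for sample in samples:
        try:
            result = run_sample(sample, refs, config)
        except Exception as err:
            raise RuntimeError(
                f"pipeline failed at sample {sample.sample_id}: {err}"
            ) from err
        entry = {"tallies": result.tallies, "discarded": result.discarded}
        manifest_samples[sample.sample_id] = entry
        if result.discarded:
            continue
        sdir = out / "samples" / sample.sample_id
        sdir.mkdir(parents=True, exist_ok=True)
        clones_path = sdir / "clones.tsv"
        write_tsv(
            result.clones,
            clones_path,
            comment="sequence_key=forward consensus; molecule_count=UID groups per clone",
        )
        summary_path = sdir / "summary.json"
        write_json(result.summary, summary_path)
        outputs[str(clones_path.relative_to(out))] = sha256_file(clones_path)
        outputs[str(summary_path.relative_to(out))] = sha256_file(summary_path)
        summaries.append(result.summary)

    summary_df = pd.DataFrame(
        summaries,
        columns=[
            "sample_id",
            "total_molecules",
            "n_sequences",
            "n_highly_expressed",
            "abs_numerator",
            "abs_level",
        ],
    )
    cohort = summary_df.merge(metadata, on="sample_id", how="inner")
    cohort = cohort.sort_values(["patient", "day"], ignore_index=True)
    cohort_path = out / "cohort_summary.csv"
    cohort.to_csv(cohort_path, index=False)
    outputs["cohort_summary.csv"] = sha256_file(cohort_path)

    stats = None
    if len(cohort) >= 4:
        stats = cohort_statistics(cohort, config)
        roc_points = stats.pop("_roc_points")
        if roc_points is not None:
            roc_path = out / "roc_curve.tsv"
            write_tsv(
                roc_points, roc_path, comment="threshold in ABS units; fpr/tpr fractions"
            )
            outputs["roc_curve.tsv"] = sha256_file(roc_path)
        fit_rows = [
            {"phase": phase, **fit}
            for phase, fit in (
                ("pre_rejection", stats["exponential_fit_pre_rejection"]),
                ("post_rejection", stats["exponential_fit_post_rejection"]),
            )
            if fit is not None
        ]
        if fit_rows:
            fits_path = out / "trend_fits.tsv"
            write_tsv(
                pd.DataFrame(fit_rows),
                fits_path,
                comment="y = a*exp(b*t), t in days relative to the rejection event",
            )
            outputs["trend_fits.tsv"] = sha256_file(fits_path)
        stats_path = out / "statistics.json"
        write_json(stats, stats_path)
        outputs["statistics.json"] = sha256_file(stats_path)

    manifest = {
        "tool": "ighrep",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "inputs": {
            s.sample_id: (
                {
                    "fastq1": sha256_file(s.fastq1),
                    "fastq2": sha256_file(s.fastq2),
                }
                if s.fastq1 is not None
                else "in-memory"
            )
            for s in samples
        },
        "samples": manifest_samples,
        "outputs": outputs,
    }
    write_json(manifest, out / "manifest.json")
    return manifest
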