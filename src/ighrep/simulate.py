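"""Synthetic IGH repertoires with molecular barcodes and sequencing noise.

The generator emulates the measurement chain of a UID-barcoded B-cell
heavy-chain (IGH) assay: a repertoire of B-cell clones, each with an isotype,
an optional load of somatic hypermutation in its V segment, and a number of
mRNA molecules; every molecule is tagged with a random 16-nt unique identifier
(UID, 8 nt carried by each mate) and sequenced as a variable number of paired
reads with uniform per-base substitution error.

Biological picture: naive B cells express unmutated IgM at low copy number;
activated B cells (plasmablasts) express class-switched (IgD/IgG/IgA/IgE) or
mutated-IgM transcripts at high copy number. The activated-B-cell-sequence
(ABS) level of a repertoire is the fraction of molecules-normalised highly
expressed (>=2 molecules) class-switched or mutated-IgM clones, the
statistic the downstream pipeline estimates.

Read layout (fixed by construction, mirrors primer chemistry):

    mate 1:  [8 nt UID half][V-FR3 primer][V-window + CDR3 payload]
    mate 2:  [8 nt UID half][C-region primer][constant-region payload]

The simulator produces everything the pipeline consumes — germline reference
FASTA sets, paired FASTQ, and a ground-truth clone table — so each stage can
be tested against known truth without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .align import decode, encode
from .reads import ReadBatch

ISOTYPES: Tuple[str, ...] = ("IgM", "IgD", "IgG", "IgA", "IgE")
#: isotypes produced by class-switch recombination (everything but IgM)
CLASS_SWITCHED: frozenset = frozenset({"IgD", "IgG", "IgA", "IgE"})

UID_TOTAL_LEN = 16


class ReferenceGenerationError(RuntimeError):
    """Raised when distinct references cannot be generated at the given length."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated repertoire sample.

    Defaults describe a realistic post-transplant blood sample sequenced
    deeply enough for UID consensus calling: ~6,000 IGH molecules, a 15%
    activated-clone fraction, heavy-tailed per-clone molecule counts, mean
    coverage of 4 reads per molecule and a 0.1% per-base substitution rate
    (Illumina after standard quality filtering).
    """

    n_clones: int = 3600
    #: isotype distribution of *activated* clones; an activated IgM draw is a
    #: mutated-IgM (memory/plasmablast) clone. Naive clones are always IgM.
    isotype_probs: Tuple[float, ...] = (0.15, 0.05, 0.45, 0.30, 0.05)
    p_activated: float = 0.15
    #: truncated zipf exponents of the per-clone molecule-count law
    count_zipf_a_naive: float = 3.0
    count_zipf_a_activated: float = 1.8
    count_max: int = 50
    igm_mutated_prob: float = 0.10
    mutation_rate_range: Tuple[float, float] = (0.02, 0.10)
    #: reads per molecule = 1 + Poisson(mean)
    reads_per_molecule_poisson_mean: float = 3.0
    per_base_error: float = 0.001
    read_len: int = 100
    uid_len_each: int = 8
    primer_len: int = 20
    cdr3_len: int = 24
    n_v: int = 4
    v_len: int = 120
    c_len: int = 100
    seed: int = 0

    @property
    def payload_len(self) -> int:
        return self.read_len - self.uid_len_each - self.primer_len

    @property
    def v_window(self) -> int:
        """Bases of germline V covered by the forward payload."""
        return self.payload_len - self.cdr3_len

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if abs(sum(self.isotype_probs) - 1.0) > 1e-9 or len(self.isotype_probs) != 5:
            raise ValueError("isotype_probs must be 5 probabilities summing to 1")
        for p in (self.p_activated, self.igm_mutated_prob, self.per_base_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.mutation_rate_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("mutation_rate_range must be ordered and in [0, 1]")
        if self.v_window < 10:
            raise ValueError("read layout leaves too little V sequence")
        if self.v_len < self.v_window:
            raise ValueError("v_len shorter than the primed V window")
        if self.c_len < self.payload_len:
            raise ValueError("c_len shorter than the reverse payload")
        if self.count_max < 1:
            raise ValueError("count_max must be >= 1")


@dataclass(frozen=True)
class GermlineRefs:
    """Reference sets: V segments, constant regions, and primer pools."""

    v_segments: Tuple[Tuple[str, str], ...]
    c_regions: Tuple[Tuple[str, str], ...]  # keyed by isotype
    v_primers: Tuple[Tuple[str, str], ...]
    c_primers: Tuple[Tuple[str, str], ...]

    @property
    def v_ids(self) -> List[str]:
        return [i for i, _ in self.v_segments]


@dataclass
class TrueRepertoire:
    """Ground truth for one simulated sample."""

    clones: pd.DataFrame  # clone_id, v_segment, isotype, activated, mutated,
    #                       n_mutations, sequence, molecule_count
    molecules: pd.DataFrame  # clone_id, uid
    refs: GermlineRefs
    config: SimConfig
    uid_collisions: int = 0

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def _global_identity(a: str, b: str) -> float:
    """Identity fraction of a global alignment (Needleman-Wunsch)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    counts = aligner.align(a, b)[0].counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / cols if cols else 0.0


def make_germline_refs(
    n_v: int,
    v_len: int = 120,
    seed: int = 0,
    *,
    c_len: int = 100,
    primer_len: int = 20,
    max_identity: float = 0.80,
    max_attempts: int = 50,
) -> GermlineRefs:
    """Generate mutually distinct germline V and constant-region references.

    Stand-in for curated germline databases: random sequences whose pairwise
    global-alignment identity is below ``max_identity`` (default 80%), which
    makes best-hit annotation unambiguous. Also draws one primer per V
    segment and per constant region (pairwise Hamming distance >= 8).
    Deterministic for a fixed seed; raises :class:`ReferenceGenerationError`
    if distinctness cannot be achieved within ``max_attempts`` redraws.
    """
    if n_v < 1:
        raise ValueError("n_v must be >= 1")
    if v_len < 60:
        raise ValueError("v_len must be >= 60")
    rng = np.random.default_rng(seed)

    def draw_set(n: int, length: int) -> List[str]:
        for _ in range(max_attempts):
            seqs = [_random_seq(rng, length) for _ in range(n)]
            ok = all(
                _global_identity(seqs[i], seqs[j]) < max_identity
                for i in range(n)
                for j in range(i + 1, n)
            )
            if ok:
                return seqs
        raise ReferenceGenerationError(
            f"could not draw {n} references of length {length} "
            f"with pairwise identity < {max_identity:.0%}"
        )

    def draw_primers(n: int) -> List[str]:
        for _ in range(max_attempts):
            prim = [_random_seq(rng, primer_len) for _ in range(n)]
            enc = [encode(p) for p in prim]
            ok = all(
                (enc[i] != enc[j]).sum() >= 8
                for i in range(n)
                for j in range(i + 1, n)
            )
            if ok:
                return prim
        raise ReferenceGenerationError("could not draw distinct primers")

    v = draw_set(n_v, v_len)
    c = draw_set(len(ISOTYPES), c_len)
    vp = draw_primers(n_v)
    cp = draw_primers(len(ISOTYPES))
    return GermlineRefs(
        v_segments=tuple((f"IGHV{i + 1}", s) for i, s in enumerate(v)),
        c_regions=tuple(zip(ISOTYPES, c)),
        v_primers=tuple((f"IGHV{i + 1}", p) for i, p in enumerate(vp)),
        c_primers=tuple(zip(ISOTYPES, cp)),
    )


def _truncated_zipf_pmf(a: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1, dtype=float)
    w = k ** (-a)
    return w / w.sum()


def sample_true_repertoire(
    cfg: SimConfig, refs: GermlineRefs, rng: Optional[np.random.Generator] = None
) -> TrueRepertoire:
    """Draw a ground-truth repertoire of clones and barcoded molecules.

    Activated clones draw their isotype from ``cfg.isotype_probs`` (an IgM
    draw is a mutated-IgM clone) and their molecule count from the heavier
    zipf law; naive clones are IgM, mutated with ``igm_mutated_prob``
    (memory-like), and use the lighter count law. Mutated clones carry at
    least one V substitution, planted in the interior of the primed V window
    (3-base margin) so that every planted substitution is observable in the
    aligned region.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_clones
    activated = rng.random(n) < cfg.p_activated
    iso_idx = rng.choice(len(ISOTYPES), size=n, p=np.asarray(cfg.isotype_probs))
    isotype = np.array(ISOTYPES)[iso_idx]
    isotype[~activated] = "IgM"
    mutated = activated | ((rng.random(n) < cfg.igm_mutated_prob) & ~activated)
    v_idx = rng.integers(0, len(refs.v_segments), size=n)
    rates = rng.uniform(*cfg.mutation_rate_range, size=n)

    pmf_naive = _truncated_zipf_pmf(cfg.count_zipf_a_naive, cfg.count_max)
    pmf_act = _truncated_zipf_pmf(cfg.count_zipf_a_activated, cfg.count_max)
    counts = np.empty(n, dtype=np.int64)
    kvals = np.arange(1, cfg.count_max + 1)
    n_act = int(activated.sum())
    counts[activated] = rng.choice(kvals, size=n_act, p=pmf_act)
    counts[~activated] = rng.choice(kvals, size=n - n_act, p=pmf_naive)

    w = cfg.v_window
    margin = min(3, max(0, (w - 1) // 2))
    interior = np.arange(margin, w - margin)
    # cap the planted load at 15% of the window: SHM beyond that is not
    # biologically plausible and would defeat the 80%-identity annotation
    # contract by construction
    mut_cap = max(1, int(0.15 * interior.size))
    v_windows = [encode(seq)[-w:] for _, seq in refs.v_segments]
    sequences: List[str] = []
    n_mut = np.zeros(n, dtype=np.int64)
    for i in range(n):
        seq = v_windows[v_idx[i]].copy()
        if mutated[i]:
            k = max(1, min(rng.binomial(interior.size, rates[i]), mut_cap))
            pos = rng.choice(interior, size=k, replace=False)
            seq[pos] = (seq[pos] + rng.integers(1, 4, size=k)) % 4
            n_mut[i] = k
        cdr3 = rng.integers(0, 4, size=cfg.cdr3_len).astype(np.uint8)
        sequences.append(decode(np.concatenate([seq, cdr3])))

    clones = pd.DataFrame(
        {
            "clone_id": np.arange(n),
            "v_segment": [refs.v_segments[j][0] for j in v_idx],
            "isotype": isotype,
            "activated": activated,
            "mutated": mutated,
            "n_mutations": n_mut,
            "sequence": sequences,
            "molecule_count": counts,
        }
    )

    total = int(counts.sum())
    uid_codes = rng.integers(0, 4**UID_TOTAL_LEN, size=total, dtype=np.int64)
    collisions = total - len(np.unique(uid_codes))
    shifts = np.arange(UID_TOTAL_LEN - 1, -1, -1, dtype=np.int64) * 2
    digits = ((uid_codes[:, None] >> shifts[None, :]) & 3).astype(np.uint8)
    uid_strings = [decode(row) for row in digits]
    molecules = pd.DataFrame(
        {"clone_id": np.repeat(np.arange(n), counts), "uid": uid_strings}
    )
    return TrueRepertoire(
        clones=clones,
        molecules=molecules,
        refs=refs,
        config=cfg,
        uid_collisions=int(collisions),
    )


def synthesize_reads(
    rep: TrueRepertoire,
    cfg: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> ReadBatch:
    """Sequence a repertoire: paired reads with UIDs and substitution errors.

    Every molecule yields ``1 + Poisson(mean)`` read pairs; every base of both
    mates (UID and primer included) is substituted independently with
    probability ``per_base_error``. Qualities are constant 'I' (Phred 40):
    the consensus step is count-based, qualities matter only for its
    documented tie-break.
    """
    cfg = cfg or rep.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if cfg.payload_len <= 0:
        raise ValueError("read_len leaves no payload after UID and primer")

    clone_of = rep.molecules["clone_id"].to_numpy()
    n_mol = len(clone_of)
    uid_mat = np.stack([encode(u) for u in rep.molecules["uid"]])
    w = cfg.payload_len

    iso_index = {iso: k for k, iso in enumerate(ISOTYPES)}
    v_index = {vid: k for k, (vid, _) in enumerate(rep.refs.v_segments)}
    clone_seq = np.stack([encode(s) for s in rep.clones["sequence"]])
    if clone_seq.shape[1] != w:
        raise ValueError("clone sequence length does not match read payload")
    v_primer_mat = np.stack([encode(p) for _, p in rep.refs.v_primers])
    c_primer_mat = np.stack([encode(p) for _, p in rep.refs.c_primers])
    c_payload = np.stack([encode(s)[:w] for _, s in rep.refs.c_regions])
    clone_v = rep.clones["v_segment"].map(v_index).to_numpy()
    clone_iso = rep.clones["isotype"].map(iso_index).to_numpy()

    mate1 = np.concatenate(
        [
            uid_mat[:, : cfg.uid_len_each],
            v_primer_mat[clone_v[clone_of]],
            clone_seq[clone_of],
        ],
        axis=1,
    )
    mate2 = np.concatenate(
        [
            uid_mat[:, cfg.uid_len_each :],
            c_primer_mat[clone_iso[clone_of]],
            c_payload[clone_iso[clone_of]],
        ],
        axis=1,
    )
    coverage = 1 + rng.poisson(cfg.reads_per_molecule_poisson_mean, size=n_mol)
    seq1 = np.repeat(mate1, coverage, axis=0)
    seq2 = np.repeat(mate2, coverage, axis=0)
    for mat in (seq1, seq2):
        if cfg.per_base_error > 0:
            mask = rng.random(mat.shape) < cfg.per_base_error
            k = int(mask.sum())
            if k:
                mat[mask] = (mat[mask] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
    return ReadBatch(seq1=seq1, seq2=seq2)


def true_abs_level(rep: TrueRepertoire) -> float:
    """ABS level of the ground truth at full depth.

    Ratio of highly expressed (>=2 molecules) class-switched or mutated-IgM
    clones to the total number of molecules.
    """
    counts = rep.clones["molecule_count"].to_numpy()
    total = int(counts.sum())
    if total == 0:
        raise ValueError("repertoire has no molecules")
    switched = rep.clones["isotype"].isin(CLASS_SWITCHED).to_numpy()
    mut_igm = (rep.clones["isotype"] == "IgM").to_numpy() & rep.clones[
        "mutated"
    ].to_numpy()
    num = int(((counts >= 2) & (switched | mut_igm)).sum())
    return num / total


def expected_true_abs_at_depth(rep: TrueRepertoire, depth: int) -> float:
    """Expected ABS of the *truth* measured at a fixed subsampling depth.

    The ABS statistic depends on depth (a clone's "highly expressed" status is
    a property of the sampled molecule counts), which is exactly why the
    protocol subsamples every sample to a common depth before comparison.
    This evaluates E[ABS at `depth`] of the noise-free repertoire in closed
    form from the hypergeometric marginals of each clone's retained count.
    """
    counts = rep.clones["molecule_count"].to_numpy()
    total = int(counts.sum())
    if total == 0:
        raise ValueError("repertoire has no molecules")
    if depth >= total:
        return true_abs_level(rep)
    switched = rep.clones["isotype"].isin(CLASS_SWITCHED).to_numpy()
    mut_igm = (rep.clones["isotype"] == "IgM").to_numpy() & rep.clones[
        "mutated"
    ].to_numpy()
    eligible = counts[switched | mut_igm]
    uniq, mult = np.unique(eligible, return_counts=True)
    p0 = hypergeom.pmf(0, total, uniq, depth)
    p1 = hypergeom.pmf(1, total, uniq, depth)
    expected_num = float((mult * (1.0 - p0 - p1)).sum())
    return expected_num / depth


def write_truth_table(rep: TrueRepertoire, path) -> None:
    """Truth table TSV for parameter-recovery tests: one row per clone."""
    uid_lists = rep.molecules.groupby("clone_id")["uid"].apply(",".join)
    out = rep.clones.copy()
    out["uids"] = out["clone_id"].map(uid_lists)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Longitudinal cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """A simulated post-transplant cohort with planted rejection episodes.

    Each patient is sampled on a fixed day grid. The activated-clone fraction
    decays from an early post-operative peak toward a maintenance floor as
    immunosuppression takes hold; in rejection patients it ramps up linearly
    over ``ramp_days`` before the planted event day and clears exponentially
    after it (successful rejection treatment). Samples within
    ``label_window`` of the event are the planted positives, and their
    metadata carries elevated donor-DNA fractions and a 2R biopsy grade at
    the event itself.
    """

    n_patients: int = 12
    n_rejectors: int = 6
    sample_days: Tuple[int, ...] = (1, 30, 75, 120, 160, 190, 220, 255)
    event_day_range: Tuple[int, int] = (150, 230)
    label_window: Tuple[int, int] = (-45, 45)
    p_floor: float = 0.02
    p_init_amp: float = 0.28
    p_decay_days: float = 20.0
    rejection_bump: float = 0.35
    ramp_days: float = 60.0
    clear_days: float = 20.0
    cfddna_negative: Tuple[float, float] = (0.1, 0.8)
    cfddna_positive: Tuple[float, float] = (1.2, 4.0)
    #: trough builds from zero over a few days after dosing starts, holds at
    #: the plateau, then tapers after month six
    tacrolimus_plateau: float = 12.5
    tacrolimus_ramp_days: float = 5.0
    tacrolimus_taper_start: int = 180
    tacrolimus_taper_slope: float = 0.025  # ng/ml decline per day after taper
    tacrolimus_min: float = 5.0
    tacrolimus_sd: float = 0.8
    base: SimConfig = field(default_factory=lambda: SimConfig(n_clones=3300))


def _activation_level(ccfg: CohortConfig, day: int, event: Optional[int]) -> float:
    p = ccfg.p_floor + ccfg.p_init_amp * float(np.exp(-day / ccfg.p_decay_days))
    if event is not None:
        if day <= event:
            p += ccfg.rejection_bump * max(0.0, 1.0 - (event - day) / ccfg.ramp_days)
        else:
            p += ccfg.rejection_bump * float(np.exp(-(day - event) / ccfg.clear_days))
    return min(p, 0.6)


def simulate_cohort(
    ccfg: CohortConfig, seed: int = 0
) -> Tuple[pd.DataFrame, GermlineRefs, List[dict]]:
    """Plan a cohort: metadata plus per-sample generation recipes.

    Returns ``(metadata, refs, plan)``. ``metadata`` has one row per sample
    (patient, sample_id, day, tacrolimus, biopsy_grade, cfddna_pct, plus the
    planted ``rejection_window`` truth label and the sample's true activation
    level). ``plan`` holds one dict per sample with the per-sample
    :class:`SimConfig` and RNG seed; materialise reads lazily with
    :func:`realize_sample` to keep memory flat.
    """
    root = np.random.SeedSequence(seed)
    ref_seed, meta_seed, sample_seed = root.spawn(3)
    refs = make_germline_refs(
        ccfg.base.n_v,
        ccfg.base.v_len,
        seed=ref_seed,
        c_len=ccfg.base.c_len,
        primer_len=ccfg.base.primer_len,
    )
    rng = np.random.default_rng(meta_seed)
    sample_streams = sample_seed.spawn(ccfg.n_patients * len(ccfg.sample_days))

    rows = []
    plan: List[dict] = []
    k = 0
    for p in range(ccfg.n_patients):
        patient = f"P{p + 1:02d}"
        rejector = p < ccfg.n_rejectors
        event = int(rng.integers(*ccfg.event_day_range)) if rejector else None
        for day in ccfg.sample_days:
            sid = f"{patient}_d{day:03d}"
            p_act = _activation_level(ccfg, day, event)
            planted = event is not None and (
                ccfg.label_window[0] <= day - event <= ccfg.label_window[1]
            )
            if planted:
                cfddna = float(rng.uniform(*ccfg.cfddna_positive))
                grade = "2R" if abs(day - event) <= 20 else "1R"
            else:
                cfddna = float(rng.uniform(*ccfg.cfddna_negative))
                grade = "0"
            trough = ccfg.tacrolimus_plateau * (
                1.0 - float(np.exp(-day / ccfg.tacrolimus_ramp_days))
            ) - ccfg.tacrolimus_taper_slope * max(0, day - ccfg.tacrolimus_taper_start)
            tac = max(
                ccfg.tacrolimus_min if day > 7 else 0.0,
                trough + float(rng.normal(0.0, ccfg.tacrolimus_sd)),
            )
            cfg = dataclasses.replace(ccfg.base, p_activated=p_act)
            rows.append(
                {
                    "sample_id": sid,
                    "patient": patient,
                    "day": day,
                    "tacrolimus": round(tac, 2),
                    "biopsy_grade": grade,
                    "cfddna_pct": round(cfddna, 3),
                    "rejection_window": planted,
                    "event_day": event if event is not None else pd.NA,
                    "true_p_activated": p_act,
                }
            )
            plan.append({"sample_id": sid, "config": cfg, "seed": sample_streams[k]})
            k += 1
    return pd.DataFrame(rows), refs, plan


def realize_sample(
    entry: dict, refs: GermlineRefs
) -> Tuple[TrueRepertoire, ReadBatch]:
    """Materialise the repertoire and reads for one cohort plan entry."""
    rng = np.random.default_rng(entry["seed"])
    rep = sample_true_repertoire(entry["config"], refs, rng=rng)
    batch = synthesize_reads(rep, entry["config"], rng=rng)
    return rep, batch
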