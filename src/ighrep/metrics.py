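"""Depth normalisation, clone collapsing, and the ABS statistic.

Because the "highly expressed" status of a clone depends on how many
molecules were sampled, samples are only comparable at a common depth: each
sample is subsampled uniformly without replacement to a fixed number of
aligned consensus molecules (default 4,000), and samples that cannot reach
that depth are discarded. Molecules with identical forward consensus
sequence and isotype are assumed to come from the same B-cell clone and are
combined; the clone's molecule count is its expression level.

ABS level = (highly expressed clones that are class-switched or mutated IgM)
/ (total molecules). Highly expressed means represented by more than one
molecule (configurable).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import CLASS_SWITCHED


class SampleDiscarded(Exception):
    """Sample produced fewer aligned molecules than the required depth."""

    def __init__(self, sample_id: str, available: int, depth: int):
        self.sample_id = sample_id
        self.available = available
        self.depth = depth
        super().__init__(
            f"sample {sample_id}: {available} aligned molecules < depth {depth}"
        )


def default_subsample_seed(sample_id: str) -> int:
    """Stable per-sample subsampling seed derived from the sample id."""
    return zlib.crc32(sample_id.encode("utf-8")) & 0x7FFFFFFF


def subsample_molecules(
    molecules: pd.DataFrame,
    depth: int = 4000,
    seed: Optional[int] = None,
    sample_id: str = "",
) -> pd.DataFrame:
    """Uniform subsample (without replacement) to exactly ``depth`` molecules.

    Deterministic under ``seed`` (defaults to a hash of ``sample_id``).
    Raises :class:`SampleDiscarded` when fewer than ``depth`` molecules are
    available; a sample with exactly ``depth`` molecules is returned intact
    for any seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = len(molecules)
    if n < depth:
        raise SampleDiscarded(sample_id, n, depth)
    if n == depth:
        return molecules.reset_index(drop=True)
    rng = np.random.default_rng(
        default_subsample_seed(sample_id) if seed is None else seed
    )
    idx = np.sort(rng.choice(n, size=depth, replace=False))
    return molecules.iloc[idx].reset_index(drop=True)


def collapse_clones(molecules: pd.DataFrame) -> pd.DataFrame:
    """Combine molecules into clones keyed by (forward consensus, isotype).

    A clone's ``molecule_count`` is the number of UID groups combined; its
    ``mutated`` flag is the OR over member molecules (a clone whose V region
    carries hypermutation can still yield an unmutated-looking molecule only
    through error, so any mutated member marks the clone). The same forward
    sequence under two isotypes remains two clones.
    """
    if len(molecules) == 0:
        return pd.DataFrame(
            columns=["sequence_key", "isotype", "mutated", "v_segment", "molecule_count"]
        )
    grouped = (
        molecules.sort_values("uid", kind="mergesort")
        .groupby(["sequence_key", "isotype"], sort=True)
        .agg(
            mutated=("mutated", "any"),
            v_segment=("v_segment", "first"),
            molecule_count=("uid", "size"),
        )
        .reset_index()
    )
    return grouped[
        ["sequence_key", "isotype", "mutated", "v_segment", "molecule_count"]
    ]


def abs_level(clones: pd.DataFrame, highly_expressed_min: int = 2) -> float:
    """ABS level of a clone table.

    Numerator: clones with ``molecule_count >= highly_expressed_min`` whose
    isotype is class-switched (IgA/IgD/IgE/IgG) or that are mutated IgM.
    Denominator: total molecules.
    """
    if len(clones) == 0:
        raise ValueError("empty clone table")
    counts = clones["molecule_count"].to_numpy()
    total = int(counts.sum())
    he = counts >= highly_expressed_min
    switched = clones["isotype"].isin(CLASS_SWITCHED).to_numpy()
    mut_igm = (clones["isotype"] == "IgM").to_numpy() & clones["mutated"].to_numpy()
    return int((he & (switched | mut_igm)).sum()) / total


def isotype_label(isotype: pd.Series, mutated: pd.Series) -> pd.Series:
    """Display label splitting IgM into mutated/unmutated compartments."""
    lab = isotype.copy().astype(object)
    igm = isotype == "IgM"
    lab[igm & mutated.astype(bool)] = "IgM_mutated"
    lab[igm & ~mutated.astype(bool)] = "IgM_unmutated"
    return lab


def expression_histogram(clones: pd.DataFrame) -> pd.DataFrame:
    """Clones per (expression level, isotype label).

    One row per observed (molecule_count, label); ``n_clones`` sums to the
    number of clones.
    """
    if len(clones) == 0:
        return pd.DataFrame(columns=["molecule_count", "label", "n_clones"])
    df = clones.assign(label=isotype_label(clones["isotype"], clones["mutated"]))
    out = (
        df.groupby(["molecule_count", "label"], sort=True)
        .size()
        .rename("n_clones")
        .reset_index()
    )
    return out


def pool_samples(
    clone_tables: Sequence[pd.DataFrame], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Concatenate per-sample clone tables without cross-sample collapsing.

    IGH sequences are personal; identical sequences from different samples
    (or patients) are kept as distinct clones. Pooled ratios are therefore
    computed over summed numerators and summed molecules.
    """
    if len(clone_tables) == 0:
        raise ValueError("need at least one sample to pool")
    if len(clone_tables) != len(sample_ids):
        raise ValueError("one sample id per clone table")
    parts = [
        tab.assign(sample_id=sid) for tab, sid in zip(clone_tables, sample_ids)
    ]
    return pd.concat(parts, ignore_index=True)


def abs_subsampling_distribution(
    molecules: pd.DataFrame,
    depth: int = 4000,
    n_reseeds: int = 200,
    seed: int = 0,
    highly_expressed_min: int = 2,
) -> np.ndarray:
    """ABS levels over reseeded subsamples of one molecule table.

    Equivalent to ``abs_level(collapse_clones(subsample_molecules(...)))``
    per reseed (asserted by tests) but vectorised with bincounts, since the
    subsampling-noise estimate needs hundreds of reseeds per sample. A
    clone's mutated flag is the OR over its *sampled* members, exactly as in
    the slow path.
    """
    n = len(molecules)
    if n < depth:
        raise SampleDiscarded("", n, depth)
    clone_idx, _ = pd.factorize(
        molecules["sequence_key"] + "\x00" + molecules["isotype"], sort=True
    )
    n_clones = int(clone_idx.max()) + 1
    switched = molecules["isotype"].isin(CLASS_SWITCHED).to_numpy()
    igm = (molecules["isotype"] == "IgM").to_numpy()
    mol_mut = molecules["mutated"].to_numpy(dtype=bool)
    clone_switched = np.zeros(n_clones, dtype=bool)
    clone_switched[clone_idx[switched]] = True
    clone_igm = np.zeros(n_clones, dtype=bool)
    clone_igm[clone_idx[igm]] = True
    rng = np.random.default_rng(seed)
    out = np.empty(n_reseeds)
    for i in range(n_reseeds):
        take = rng.choice(n, size=depth, replace=False)
        counts = np.bincount(clone_idx[take], minlength=n_clones)
        mut = np.bincount(
            clone_idx[take[mol_mut[take]]], minlength=n_clones
        ) > 0
        he = counts >= highly_expressed_min
        num = int((he & (clone_switched | (clone_igm & mut))).sum())
        out[i] = num / depth
    return out


@dataclass(frozen=True)
class RepertoireSummary:
    """Per-sample summary of the collapsed repertoire."""

    sample_id: str
    total_molecules: int
    n_sequences: int
    n_highly_expressed: int
    abs_numerator: int
    abs_level: float
    #: {molecule_count: {isotype label: clones}}
    isotype_composition: Dict[int, Dict[str, int]]

    def validate(self) -> None:
        ok = (
            0
            <= self.abs_numerator
            <= self.n_highly_expressed
            <= self.n_sequences
            <= self.total_molecules
        )
        if not ok:
            raise ValueError("summary count ordering violated")
        if not 0.0 <= self.abs_level <= 1.0:
            raise ValueError("abs_level must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_molecules": self.total_molecules,
            "n_sequences": self.n_sequences,
            "n_highly_expressed": self.n_highly_expressed,
            "abs_numerator": self.abs_numerator,
            "abs_level": self.abs_level,
            "isotype_composition": {
                str(k): v for k, v in self.isotype_composition.items()
            },
        }


def summarize_sample(
    clones: pd.DataFrame, sample_id: str, highly_expressed_min: int = 2
) -> RepertoireSummary:
    """Summary statistics of one sample's clone table (invariants asserted)."""
    if len(clones) == 0:
        raise ValueError("empty clone table")
    counts = clones["molecule_count"].to_numpy()
    total = int(counts.sum())
    he = counts >= highly_expressed_min
    switched = clones["isotype"].isin(CLASS_SWITCHED).to_numpy()
    mut_igm = (clones["isotype"] == "IgM").to_numpy() & clones["mutated"].to_numpy()
    hist = expression_histogram(clones)
    composition: Dict[int, Dict[str, int]] = {}
    for level, sub in hist.groupby("molecule_count"):
        composition[int(level)] = dict(
            zip(sub["label"], sub["n_clones"].astype(int))
        )
    summary = RepertoireSummary(
        sample_id=sample_id,
        total_molecules=total,
        n_sequences=int(len(clones)),
        n_highly_expressed=int(he.sum()),
        abs_numerator=int((he & (switched | mut_igm)).sum()),
        abs_level=int((he & (switched | mut_igm)).sum()) / total,
        isotype_composition=composition,
    )
    summary.validate()
    return summary
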