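"""V-segment, mutation-rate, and isotype annotation of consensus molecules.

The forward consensus (V window + CDR3) is aligned against the germline
V-segment set: the best local hit names the V segment, and the mismatches of
that alignment are the molecule's somatic mutation load (mutation rate =
mismatches / aligned columns; gap columns count as one mismatch each). The
reverse consensus is aligned against the five constant-region references;
the best hit's label is the isotype. Molecules missing either hit are
Unaligned and are excluded from the aligned-molecule table (tallied in the
run log).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from .align import AlignmentHit, AlignParams, align_to_references
from .simulate import GermlineRefs


@dataclass(frozen=True)
class AnnotatedMolecule:
    """One consensus pair with full annotation."""

    uid: str
    v_segment: str
    mutation_count: int
    mutation_rate: float
    isotype: str
    sequence_key: str  # forward consensus; carries the CDR3
    coverage: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


def classify_mutated(mutation_rate: float, mutated_min_rate: float = 0.01) -> bool:
    """Somatic-hypermutation call: rate at or above the threshold (closed bound).

    The mutated/non-mutated distinction only affects the ABS numerator for
    IgM clones, but the flag is computed uniformly for all isotypes.
    """
    return mutation_rate >= mutated_min_rate


def annotate_molecule(
    uid: str,
    forward_consensus: str,
    reverse_consensus: str,
    coverage: int,
    v_refs: Sequence[Tuple[str, str]],
    c_refs: Sequence[Tuple[str, str]],
    params: AlignParams = AlignParams(),
) -> Optional[AnnotatedMolecule]:
    """Annotate one consensus pair; ``None`` (Unaligned) if either hit fails."""
    v_hit = align_to_references(forward_consensus, v_refs, params)
    if v_hit is None:
        return None
    c_hit = align_to_references(reverse_consensus, c_refs, params)
    if c_hit is None:
        return None
    return AnnotatedMolecule(
        uid=uid,
        v_segment=v_hit.reference_id,
        mutation_count=v_hit.mismatches,
        mutation_rate=v_hit.mismatches / v_hit.aligned_length,
        isotype=c_hit.reference_id,
        sequence_key=forward_consensus,
        coverage=coverage,
    )


def annotate_table(
    consensus: pd.DataFrame,
    refs: GermlineRefs,
    params: AlignParams = AlignParams(),
    mutated_min_rate: float = 0.01,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Annotate a consensus table; returns (aligned molecules, tallies).

    Alignments are memoised per distinct consensus sequence — members of an
    expanded clone share their sequence, so this saves most of the work on
    real-shaped data without changing any result.
    """
    v_refs = list(refs.v_segments)
    c_refs = list(refs.c_regions)
    v_cache: Dict[str, Optional[AlignmentHit]] = {}
    c_cache: Dict[str, Optional[AlignmentHit]] = {}

    def v_hit(seq: str) -> Optional[AlignmentHit]:
        if seq not in v_cache:
            v_cache[seq] = align_to_references(seq, v_refs, params)
        return v_cache[seq]

    def c_hit(seq: str) -> Optional[AlignmentHit]:
        if seq not in c_cache:
            c_cache[seq] = align_to_references(seq, c_refs, params)
        return c_cache[seq]

    rows = []
    n_unaligned = 0
    for uid, cov, fwd, rev in zip(
        consensus["uid"],
        consensus["coverage"],
        consensus["forward_consensus"],
        consensus["reverse_consensus"],
    ):
        vh = v_hit(fwd)
        if vh is None:
            n_unaligned += 1
            continue
        ch = c_hit(rev)
        if ch is None:
            n_unaligned += 1
            continue
        rate = vh.mismatches / vh.aligned_length
        rows.append(
            (
                uid,
                vh.reference_id,
                vh.mismatches,
                rate,
                ch.reference_id,
                fwd,
                int(cov),
                classify_mutated(rate, mutated_min_rate),
            )
        )
    molecules = pd.DataFrame(
        rows,
        columns=[
            "uid",
            "v_segment",
            "mutation_count",
            "mutation_rate",
            "isotype",
            "sequence_key",
            "coverage",
            "mutated",
        ],
    )
    tallies = {
        "consensus_pairs": int(len(consensus)),
        "aligned_molecules": int(len(molecules)),
        "unaligned": n_unaligned,
    }
    return molecules, tallies
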