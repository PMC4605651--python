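"""Dense in-memory container for paired reads.

Fixed-length paired reads are held as uint8 code matrices (A=0,C=1,G=2,T=3,
other=255) plus optional Phred quality matrices, which lets the UID
extraction and consensus stages run as vectorised numpy operations instead of
per-read Python. Ragged inputs fall back to the per-read code path in
:mod:`ighrep.consensus`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Tuple

import numpy as np

from .align import decode, encode

ReadPair = Tuple[str, str, str, str, str]  # name, seq1, qual1, seq2, qual2


@dataclass
class ReadBatch:
    """Paired reads as dense code matrices (one row per read pair)."""

    seq1: np.ndarray  # (n, L1) uint8 codes
    seq2: np.ndarray  # (n, L2) uint8 codes
    qual1: Optional[np.ndarray] = None  # (n, L1) Phred scores; None = constant
    qual2: Optional[np.ndarray] = None
    qual_char: str = "I"  # used when qual matrices are absent

    def __post_init__(self) -> None:
        if self.seq1.shape[0] != self.seq2.shape[0]:
            raise ValueError("mates must pair one-to-one")

    def __len__(self) -> int:
        return int(self.seq1.shape[0])

    def _qual_str(self, mat: Optional[np.ndarray], i: int, length: int) -> str:
        if mat is None:
            return self.qual_char * length
        return (mat[i] + 33).astype(np.uint8).tobytes().decode("ascii")

    def iter_pairs(self) -> Iterator[ReadPair]:
        l1, l2 = self.seq1.shape[1], self.seq2.shape[1]
        for i in range(len(self)):
            yield (
                f"read{i:08d}",
                decode(self.seq1[i]),
                self._qual_str(self.qual1, i, l1),
                decode(self.seq2[i]),
                self._qual_str(self.qual2, i, l2),
            )

    @classmethod
    def from_pairs(cls, pairs: Iterable[ReadPair]) -> "ReadBatch":
        """Build a batch from (name, seq1, qual1, seq2, qual2) tuples.

        Raises ``ValueError`` if read lengths are not uniform per mate.
        """
        s1, q1, s2, q2 = [], [], [], []
        for _name, a, qa, b, qb in pairs:
            s1.append(encode(a))
            q1.append(np.frombuffer(qa.encode("ascii"), dtype=np.uint8) - 33)
            s2.append(encode(b))
            q2.append(np.frombuffer(qb.encode("ascii"), dtype=np.uint8) - 33)
        if not s1:
            empty = np.zeros((0, 0), dtype=np.uint8)
            return cls(seq1=empty, seq2=empty.copy())
        if len({a.size for a in s1}) != 1 or len({b.size for b in s2}) != 1:
            raise ValueError("ragged read lengths; use the per-read path")
        return cls(
            seq1=np.stack(s1),
            seq2=np.stack(s2),
            qual1=np.stack(q1),
            qual2=np.stack(q2),
        )
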