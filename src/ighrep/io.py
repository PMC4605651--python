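"""File formats: paired FASTQ, reference FASTA sets, metadata CSV, TSV/JSON.

All tabular outputs are tab-separated with a leading ``#``-comment header
line naming the columns and units; JSON is written with sorted keys so that
identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import math
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .diagnostics import BIOPSY_GRADES
from .reads import ReadBatch, ReadPair
from .simulate import GermlineRefs


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_paired_fastq(path1: Union[str, Path], path2: Union[str, Path]) -> Iterator[ReadPair]:
    """Stream synchronized mate pairs from two FASTQ files (plain or gzip).

    Yields (name, seq1, qual1, seq2, qual2) in file order. Raises with the
    failing record index on desynchronized mates or malformed records.
    """
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        idx = 0
        while True:
            try:
                rec1 = next(it1, None)
            except ValueError as err:
                raise ValueError(f"malformed FASTQ record {idx} in {path1}: {err}")
            try:
                rec2 = next(it2, None)
            except ValueError as err:
                raise ValueError(f"malformed FASTQ record {idx} in {path2}: {err}")
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                longer = path2 if rec1 is None else path1
                raise ValueError(
                    f"desynchronized mates: record {idx} missing from the other "
                    f"file (extra records in {longer})"
                )
            yield rec1[0].split()[0], rec1[1], rec1[2], rec2[1], rec2[2]
            idx += 1


def write_paired_fastq(
    reads: Union[ReadBatch, Iterable[ReadPair]],
    path1: Union[str, Path],
    path2: Union[str, Path],
) -> int:
    """Write mate pairs to two FASTQ files; returns the pair count."""
    pairs = reads.iter_pairs() if isinstance(reads, ReadBatch) else reads
    n = 0
    buf1, buf2 = [], []
    for name, s1, q1, s2, q2 in pairs:
        buf1.append(f"@{name}/1\n{s1}\n+\n{q1}\n")
        buf2.append(f"@{name}/2\n{s2}\n+\n{q2}\n")
        n += 1
    with _open_text(path1, "wt") as h1:
        h1.write("".join(buf1))
    with _open_text(path2, "wt") as h2:
        h2.write("".join(buf2))
    return n


def _write_fasta(records: Sequence[Tuple[str, str]], path: Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records],
        str(path),
        "fasta",
    )


def _read_fasta(path: Path) -> Tuple[Tuple[str, str], ...]:
    return tuple((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))


def write_refs(refs: GermlineRefs, directory: Union[str, Path]) -> None:
    """Write the four reference FASTA files into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_fasta(refs.v_segments, d / "v_segments.fasta")
    _write_fasta(refs.c_regions, d / "c_regions.fasta")
    _write_fasta(refs.v_primers, d / "v_primers.fasta")
    _write_fasta(refs.c_primers, d / "c_primers.fasta")


def read_refs(directory: Union[str, Path]) -> GermlineRefs:
    """Read a reference directory written by :func:`write_refs`."""
    d = Path(directory)
    return GermlineRefs(
        v_segments=_read_fasta(d / "v_segments.fasta"),
        c_regions=_read_fasta(d / "c_regions.fasta"),
        v_primers=_read_fasta(d / "v_primers.fasta"),
        c_primers=_read_fasta(d / "c_primers.fasta"),
    )


METADATA_REQUIRED = ("patient", "day", "tacrolimus", "biopsy_grade", "cfddna_pct")


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read the clinical metadata CSV into typed sample records.

    Required columns: patient, day (post-transplant, day 1 = first
    postoperative day), tacrolimus (ng/ml; may be empty), biopsy_grade (one
    of 0/1R/2R/3R/NA or empty), cfddna_pct (% donor DNA; may be empty).
    A ``sample_id`` column is optional (default ``{patient}_d{day}``).
    Unparseable rows are dropped and reported in
    ``df.attrs["rejected_rows"]`` as (line number, message).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    rows = []
    rejected = []
    for i, rec in raw.iterrows():
        line_no = i + 2  # header is line 1
        try:
            day = int(rec["day"])
            grade = rec["biopsy_grade"].strip() or "NA"
            if grade not in BIOPSY_GRADES:
                raise ValueError(f"invalid biopsy grade {grade!r}")
            tac = float(rec["tacrolimus"]) if rec["tacrolimus"].strip() else math.nan
            cfd = float(rec["cfddna_pct"]) if rec["cfddna_pct"].strip() else math.nan
            if not math.isnan(cfd) and cfd < 0:
                raise ValueError("cfddna_pct must be >= 0")
            sid = (
                rec["sample_id"].strip()
                if "sample_id" in raw.columns and rec["sample_id"].strip()
                else f"{rec['patient']}_d{day:03d}"
            )
            rows.append(
                {
                    "sample_id": sid,
                    "patient": rec["patient"],
                    "day": day,
                    "tacrolimus": tac,
                    "biopsy_grade": grade,
                    "cfddna_pct": cfd,
                }
            )
        except (ValueError, KeyError) as err:
            rejected.append((line_no, str(err)))
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "patient", "day", "tacrolimus", "biopsy_grade", "cfddna_pct"],
    )
    df.attrs["rejected_rows"] = rejected
    return df


def write_tsv(df: pd.DataFrame, path: Union[str, Path], comment: str = "") -> None:
    """TSV with an optional leading '#' comment line naming units."""
    with open(path, "w") as h:
        if comment:
            h.write(f"# {comment}\n")
        df.to_csv(h, sep="\t", index=False)


def read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj, path: Union[str, Path]) -> None:
    with open(path, "w") as h:
        json.dump(obj, h, indent=2, sort_keys=True)
        h.write("\n")


def sha256_file(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
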