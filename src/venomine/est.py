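"""EST reading, six-frame translation and open-reading-frame detection.

Single-pass cDNA reads (ESTs) are treated as independent transcripts: no contig
assembly is attempted.  Translation uses the standard genetic code; stop codons
are rendered as ``'.'`` in all internal amino-acid strings, and codons containing
``N`` translate to ``'X'``.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

STOP = "."

#: Frame numbering: 1-3 forward with offsets 0-2, 4-6 on the reverse complement
#: with offsets 0-2.
FRAMES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class ESTRecord:
    """One nucleotide read over the alphabet {A, C, G, T, N}."""

    id: str
    nt_seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("EST record id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.nt_seq)


@dataclass(frozen=True)
class TranslatedFrame:
    """One of the six conceptual translations of a read.

    ``aa_seq`` uses the 20 residues plus 'X' (ambiguous) and '.' (stop).
    """

    est_id: str
    frame: int
    aa_seq: str


@dataclass(frozen=True)
class ORF:
    """A Met-to-stop (or Met-to-read-end) protein segment in one frame."""

    est_id: str
    frame: int
    start_aa: int
    end_aa: int  # exclusive index of the residue after the last coding residue
    has_stop: bool
    protein: str


def _normalize_nt(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in "ACGT":
            out.append(ch)
        elif ch == "U":
            out.append("T")
        elif ch.isalpha():
            out.append("N")
        else:
            raise ValueError(f"illegal nucleotide character {ch!r}")
    return "".join(out)


def read_fasta(path) -> list[ESTRecord]:
    """Read a nucleotide FASTA file into ESTRecords.

    Sequences are uppercased, U is mapped to T, other ambiguity codes to N.
    Raises on malformed files (naming the offending line) and on duplicate ids.
    """
    records: list[ESTRecord] = []
    seen: set[str] = set()
    rec_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if rec_id is None:
            return
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        records.append(ESTRecord(rec_id, _normalize_nt("".join(chunks))))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rec_id = line[1:].split()[0] if len(line) > 1 else ""
                if not rec_id:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                chunks = []
            else:
                if rec_id is None:
                    raise ValueError(
                        f"sequence data before any FASTA header at line {lineno}"
                    )
                try:
                    chunks.append(_normalize_nt(line))
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: {exc}") from None
    flush()
    return records


def _translate(nt: str) -> str:
    """Translate a nucleotide string, trimming any trailing partial codon."""
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    aa = str(Seq(nt[:usable]).translate())
    return aa.replace("*", STOP)


def six_frame_translate(record: ESTRecord) -> list[TranslatedFrame]:
    """Translate a read in all six frames (1-3 forward, 4-6 reverse complement)."""
    if record.length < 3:
        raise ValueError(f"read {record.id} shorter than one codon")
    fwd = record.nt_seq
    rev = str(Seq(fwd).reverse_complement())
    frames = []
    for frame, (strand, offset) in zip(
        FRAMES, [(fwd, 0), (fwd, 1), (fwd, 2), (rev, 0), (rev, 1), (rev, 2)]
    ):
        frames.append(TranslatedFrame(record.id, frame, _translate(strand[offset:])))
    return frames


def detect_orfs(
    frames: Iterable[TranslatedFrame],
    min_len: int = 40,
    longest_only: bool = True,
) -> list[ORF]:
    """Find Met-initiated ORFs in translated frames.

    Each stop-bounded segment contributes its maximal Met-to-stop ORF (the one
    starting at the first Met); with ``longest_only=False`` every nested Met
    start is reported as well.  Segments at the 3' end without a stop yield
    ``has_stop=False`` ORFs.  Only proteins of length >= ``min_len`` are kept.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    orfs: list[ORF] = []
    for fr in frames:
        seg_start = 0
        aa = fr.aa_seq
        n = len(aa)
        while seg_start <= n:
            stop_idx = aa.find(STOP, seg_start)
            if stop_idx == -1:
                seg_end, has_stop = n, False
            else:
                seg_end, has_stop = stop_idx, True
            segment = aa[seg_start:seg_end]
            met_positions = [i for i, ch in enumerate(segment) if ch == "M"]
            if not longest_only:
                starts = met_positions
            else:
                starts = met_positions[:1]
            for m in starts:
                protein = segment[m:]
                if len(protein) >= min_len:
                    orfs.append(
                        ORF(
                            est_id=fr.est_id,
                            frame=fr.frame,
                            start_aa=seg_start + m,
                            end_aa=seg_end,
                            has_stop=has_stop,
                            protein=protein,
                        )
                    )
            if stop_idx == -1:
                break
            seg_start = stop_idx + 1
    return orfs


@dataclass(frozen=True)
class LengthStats:
    n: int
    median: float
    histogram: tuple[tuple[int, int], ...]  # (bin start, count), 100-nt bins


def length_stats(records: Sequence[ESTRecord]) -> LengthStats:
    """Read-length summary: median and a histogram in 100-nt bins."""
    if not records:
        raise ValueError("length_stats requires at least one record")
    lengths = np.array([r.length for r in records])
    median = float(np.median(lengths))
    top = int(lengths.max()) // 100 + 1
    counts, edges = np.histogram(lengths, bins=np.arange(0, (top + 1) * 100, 100))
    hist = tuple(
        (int(edges[i]), int(c)) for i, c in enumerate(counts)
    )
    return LengthStats(n=len(records), median=median, histogram=hist)


def write_fasta(records: Iterable[ESTRecord], path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.nt_seq}\n")
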