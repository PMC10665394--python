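"""Cysteine families, subfamilies, dominant sequences and consensus matrices.

Mature venom toxins group naturally by the number of half-cystines (6C, 8C,
9C, 10C families; everything else is "other") and, within a family, into
subfamilies of highly homologous sequences.  Subfamily membership is
single-linkage clustering on global pairwise identity; a subfamily's dominant
sequence is the unique member with the highest supporting-transcript count.
Per-position residue frequency matrices (with small-sample-corrected
information content) summarize subfamily/family alignments the way sequence
logos do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

MAIN_FAMILIES = {6: "6C", 8: "8C", 9: "9C", 10: "10C"}


@dataclass(frozen=True)
class FamilyAssignment:
    toxin_id: str
    cys_count: int
    family: str
    subfamily: str | None = None
    is_dominant: bool = False
    transcript_count: int = 0
    #: 9C toxins carry an odd number of half-cystines, one necessarily unbound
    unbound_cysteine: bool = False


def assign_family(mature_seq: str, toxin_id: str = "") -> FamilyAssignment:
    """Family from the cysteine count of a mature chain."""
    if not mature_seq:
        raise ValueError("mature sequence must be non-empty")
    cys = mature_seq.count("C")
    family = MAIN_FAMILIES.get(cys, "other")
    return FamilyAssignment(
        toxin_id=toxin_id,
        cys_count=cys,
        family=family,
        unbound_cysteine=(cys % 2 == 1 and family != "other"),
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (gaps included)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    if a > b:  # symmetry regardless of tie-breaking inside the aligner
        a, b = b, a
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def pairwise_alignment(a: str, b: str) -> tuple[str, str]:
    """The gapped strings of the best global alignment of a and b."""
    aln = _ALIGNER.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def cluster_subfamilies(
    toxins: Mapping[str, str],
    threshold: float = 0.70,
) -> dict[str, list[str]]:
    """Single-linkage clustering of same-family toxins at identity >= threshold.

    Returns subfamily id -> member ids.  Subfamilies are numbered by
    (size descending, lexicographically smallest member), so the partition and
    its labels are invariant to input order.  A toxin below threshold to every
    other forms a singleton (orphan) subfamily.
    """
    ids = sorted(toxins)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(toxins[a], toxins[b]) >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda mem: (-len(mem), min(mem)))
    return {f"SF{k + 1}": sorted(members) for k, members in enumerate(ordered)}


def dominant_sequence(
    member_ids: Sequence[str],
    transcript_counts: Mapping[str, int],
) -> str | None:
    """The unique transcript-count maximum of a subfamily, or None on a tie."""
    if not member_ids:
        return None
    best = max(transcript_counts.get(m, 0) for m in member_ids)
    winners = [m for m in member_ids if transcript_counts.get(m, 0) == best]
    return winners[0] if len(winners) == 1 else None


# ---------------------------------------------------------------------------
# Multiple alignment (center-star) and frequency matrices

def center_star_align(seqs: Sequence[str]) -> list[str]:
    """A simple center-star multiple alignment.

    The center is the sequence with the highest summed identity to the rest;
    all pairwise alignments to the center are merged under the once-a-gap-
    always-a-gap rule.  Adequate for frequency matrices, not a substitute for
    a progressive aligner.
    """
    if not seqs:
        return []
    if len(seqs) == 1:
        return [seqs[0]]
    n = len(seqs)
    sums = [
        sum(pairwise_identity(seqs[i], seqs[j]) for j in range(n) if j != i)
        for i in range(n)
    ]
    c = int(np.argmax(sums))
    center = seqs[c]
    L = len(center)
    pairs = []  # (gapped_center, gapped_seq) per non-center sequence
    for j in range(n):
        if j == c:
            continue
        pairs.append((j, pairwise_alignment(center, seqs[j])))
    # insertions[k] = residues inserted before center position k (k == L: after end)
    insertions = [0] * (L + 1)
    for j, (gc, gs) in pairs:
        pos = 0
        ins = [0] * (L + 1)
        for ch in gc:
            if ch == GAP:
                ins[pos] += 1
            else:
                pos += 1
        for k in range(L + 1):
            insertions[k] = max(insertions[k], ins[k])

    def expand(gc: str, gs: str) -> str:
        # walk alignment columns, grouping insertion runs before each center pos
        out = []
        run: list[str] = []
        cols = list(zip(gc, gs))
        idx = 0
        for k in range(L + 1):
            # collect this run of insertions (center gaps) before center pos k
            got = 0
            while idx < len(cols) and cols[idx][0] == GAP:
                run.append(cols[idx][1])
                got += 1
                idx += 1
            out.append("".join(run) + GAP * (insertions[k] - got))
            run = []
            if k < L:
                out.append(cols[idx][1])
                idx += 1
        return "".join(out)

    rows = [None] * n
    center_row = []
    for k in range(L + 1):
        center_row.append(GAP * insertions[k])
        if k < L:
            center_row.append(center[k])
    rows[c] = "".join(center_row)
    for j, (gc, gs) in pairs:
        rows[j] = expand(gc, gs)
    width = len(rows[c])
    assert all(len(r) == width for r in rows)
    return rows


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-column residue counts and information content of an alignment."""

    length: int
    n_sequences: int
    symbols: str  # AA20 + gap
    counts: np.ndarray  # shape (len(symbols), length)
    information: np.ndarray  # bits per column


def frequency_matrix(aligned: Sequence[str]) -> FrequencyMatrix:
    """Column-wise residue counts plus small-sample-corrected information (bits)."""
    if not aligned:
        raise ValueError("no sequences")
    width = len(aligned[0])
    if any(len(row) != width for row in aligned):
        raise ValueError("aligned rows must have equal length")
    symbols = AA20 + GAP
    index = {ch: i for i, ch in enumerate(symbols)}
    counts = np.zeros((len(symbols), width), dtype=int)
    for row in aligned:
        for j, ch in enumerate(row):
            counts[index.get(ch, index[GAP]), j] += 1
    info = np.zeros(width)
    max_bits = math.log2(len(AA20))
    for j in range(width):
        col = counts[:-1, j]  # residues only; gaps carry no information
        n = int(col.sum())
        if n == 0:
            continue
        freqs = col[col > 0] / n
        entropy = float(-(freqs * np.log2(freqs)).sum())
        correction = (len(AA20) - 1) / (2 * math.log(2) * n)
        info[j] = min(max(max_bits - entropy - correction, 0.0), max_bits)
    return FrequencyMatrix(
        length=width,
        n_sequences=len(aligned),
        symbols=symbols,
        counts=counts,
        information=info,
    )


def classify_toxin_set(
    matures: Mapping[str, str],
    transcript_counts: Mapping[str, int] | None = None,
    identity_threshold: float = 0.70,
) -> list[FamilyAssignment]:
    """Full family/subfamily/dominant annotation for a set of mature toxins.

    Toxins are first binned by cysteine count; each main family is clustered
    into subfamilies, and every "other" toxin forms its own orphan group.
    Subfamily labels are prefixed by family (e.g. ``8C.SF1``).
    """
    counts = transcript_counts or {}
    by_family: dict[str, dict[str, str]] = {}
    base: dict[str, FamilyAssignment] = {}
    for tid in sorted(matures):
        fa = assign_family(matures[tid], toxin_id=tid)
        base[tid] = fa
        by_family.setdefault(fa.family, {})[tid] = matures[tid]
    out: list[FamilyAssignment] = []
    for family in sorted(by_family):
        members = by_family[family]
        if family == "other":
            partition = {f"orphan{k + 1}": [tid] for k, tid in enumerate(sorted(members))}
        else:
            partition = cluster_subfamilies(members, threshold=identity_threshold)
        for sf, ids in partition.items():
            dom = dominant_sequence(ids, counts)
            for tid in ids:
                fa = base[tid]
                out.append(
                    FamilyAssignment(
                        toxin_id=tid,
                        cys_count=fa.cys_count,
                        family=fa.family,
                        subfamily=f"{family}.{sf}",
                        is_dominant=(tid == dom),
                        transcript_count=counts.get(tid, 0),
                        unbound_cysteine=fa.unbound_cysteine,
                    )
                )
    out.sort(key=lambda fa: fa.toxin_id)
    return out
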