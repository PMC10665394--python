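"""Precursor segmentation and mature-variant enumeration.

Secreted toxin precursors carry an N-terminal signal peptide, usually a short
propeptide ending in a processing-protease quadruplet (XXKR or XXRR) and a
cysteine-rich mature chain.  After translation in venom glands the mature
chain may additionally lose C-terminal basic residues to carboxypeptidases,
and a then-exposed C-terminal glycine can be converted into an amide on the
preceding residue by peptidylglycine-alpha-amidating monooxygenase.  Because
those events cannot be predicted unambiguously, every plausible processed
form is enumerated as a separate mature variant.

The built-in signal-peptide predictor is a lightweight hydrophobicity
heuristic; externally produced cleavage-site predictions can be ingested from
TSV and take precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

# Kyte-Doolittle hydropathy
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: small residues favoured at the -1/-3 positions of signal-peptidase sites
SMALL_RESIDUES = frozenset("AGSCT")


@dataclass(frozen=True)
class SignalPrediction:
    id: str
    cleavage_site: int  # 0-based index of the first mature-side residue
    score: float
    source: str  # builtin | external


def predict_signal_cleavage(
    protein: str,
    protein_id: str = "",
    min_site: int = 15,
    max_site: int = 35,
    threshold: float = 0.5,
) -> SignalPrediction | None:
    """Heuristic signal-peptidase site prediction.

    Candidate cut sites between ``min_site`` and ``max_site`` are scored by
    the mean Kyte-Doolittle hydropathy of the 8-residue window upstream
    (normalized to [0, 1]) plus a bonus for small residues at the -1 and -3
    positions.  Returns the best-scoring site, or None when the best score
    falls below ``threshold`` or the protein is shorter than 25 residues.
    """
    if len(protein) < 25:
        return None
    best: tuple[float, int] | None = None
    hi = min(max_site, len(protein) - 5)
    for cut in range(min_site, hi + 1):
        window = protein[cut - 8 : cut]
        hyd = sum(KD.get(ch, 0.0) for ch in window) / len(window)
        score = 0.7 * min(max((hyd + 4.5) / 9.0, 0.0), 1.0)
        if protein[cut - 1] in SMALL_RESIDUES:
            score += 0.15
        if protein[cut - 3] in SMALL_RESIDUES:
            score += 0.15
        score = min(score, 1.0)
        if best is None or score > best[0]:
            best = (score, cut)
    if best is None or best[0] < threshold:
        return None
    return SignalPrediction(protein_id, best[1], round(best[0], 4), "builtin")


def ingest_signal_predictions(path) -> dict[str, SignalPrediction]:
    """Read externally produced cleavage-site predictions (TSV: id, cleavage_site).

    External predictions override the built-in heuristic downstream; duplicated
    ids keep the last row (with a warning).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if df.empty:
        return {}
    out: dict[str, SignalPrediction] = {}
    for row in df.itertuples(index=False):
        rid = str(row.id)
        if rid in out:
            warnings.warn(f"duplicate signal prediction for {rid!r}; keeping last")
        score = float(getattr(row, "score", 1.0)) if hasattr(row, "score") else 1.0
        out[rid] = SignalPrediction(rid, int(row.cleavage_site), score, "external")
    return out


def select_start_codon(
    protein: str,
    cleavage_site: int,
    primary: tuple[int, int] = (20, 27),
    fallback: tuple[int, int] = (15, 35),
) -> int | None:
    """Choose the initiator Met for a known signal-peptidase site.

    The nearest Met 20-27 residues upstream of the cleavage site is taken as
    the start codon; failing that, the nearest Met within 15-35 residues;
    otherwise None (the precursor is partial).
    """
    mets = [i for i, ch in enumerate(protein[:cleavage_site]) if ch == "M"]
    in_primary = [m for m in mets if primary[0] <= cleavage_site - m <= primary[1]]
    if in_primary:
        return max(in_primary)  # smallest distance d
    in_fallback = [m for m in mets if fallback[0] <= cleavage_site - m <= fallback[1]]
    if in_fallback:
        return max(in_fallback)
    return None


def find_propeptide_cleavage(protein: str, signal_end: int) -> tuple[int, bool]:
    """Locate the mature start after the XXKR/XXRR processing quadruplet.

    Scans between the signal-peptidase site and the first cysteine for
    quadruplets ending in KR or RR; the most C-terminal one that still
    precedes the first cysteine wins and the mature chain starts right after
    its arginine.  Without such a quadruplet (or without any downstream Cys,
    flagged by the second return value) the mature chain starts at the
    signal end — no propeptide.
    """
    first_cys = protein.find("C", signal_end)
    if first_cys == -1:
        return signal_end, True
    mature_start = signal_end
    for i in range(signal_end, first_cys - 3):
        quad = protein[i : i + 4]
        if "X" in quad:
            continue
        if quad[2:] in ("KR", "RR") and i + 4 <= first_cys:
            mature_start = i + 4
    return mature_start, False


@dataclass(frozen=True)
class ToxinPrecursor:
    """An annotated precursor: signal | propeptide | mature partition.

    ``protein`` starts at the chosen initiator Met (or at the first residue
    of a partial sequence); intervals are 0-based half-open within it.
    """

    id: str
    protein: str
    signal: tuple[int, int]
    propeptide: tuple[int, int]
    mature_start: int
    start_codon_aa: int  # index of the initiator Met in the original ORF protein
    completeness: str  # complete | partial

    @property
    def mature_seq(self) -> str:
        return self.protein[self.mature_start :]

    @property
    def signal_seq(self) -> str:
        return self.protein[self.signal[0] : self.signal[1]]

    @property
    def propeptide_seq(self) -> str:
        return self.protein[self.propeptide[0] : self.propeptide[1]]


def annotate_precursor(
    orf_protein: str,
    orf_id: str,
    has_stop: bool = True,
    signal: SignalPrediction | None = None,
    signal_threshold: float = 0.5,
) -> ToxinPrecursor | None:
    """Segment an ORF protein into signal / propeptide / mature regions.

    An external ``signal`` prediction, when given, overrides the built-in
    heuristic.  Returns None when no signal-peptidase site is found (the
    sequence cannot be a secreted toxin precursor under this model).
    """
    if signal is None:
        signal = predict_signal_cleavage(
            orf_protein, protein_id=orf_id, threshold=signal_threshold
        )
    if signal is None:
        return None
    cleavage = signal.cleavage_site
    if not 0 < cleavage < len(orf_protein):
        return None
    start = select_start_codon(orf_protein, cleavage)
    partial = start is None or not has_stop
    if start is None:
        start = 0
    protein = orf_protein[start:]
    cut = cleavage - start
    mature_start, no_cys = find_propeptide_cleavage(protein, cut)
    return ToxinPrecursor(
        id=orf_id,
        protein=protein,
        signal=(0, cut),
        propeptide=(cut, mature_start),
        mature_start=mature_start,
        start_codon_aa=start,
        completeness="partial" if (partial or no_cys) else "complete",
    )


@dataclass(frozen=True)
class MatureVariant:
    """One candidate processed form of a toxin's mature chain."""

    parent_id: str
    variant_id: str
    sequence: str
    amidated: bool
    provenance: str  # full | carboxypeptidase-trimmed | amidated

    #: monoisotopic mass shift of C-terminal amidation, for search engines
    AMIDATION_DELTA_DA = -0.98402


def generate_mature_variants(
    mature_seq: str,
    parent_id: str = "",
    trim_depth: int = 2,
) -> list[MatureVariant]:
    """Enumerate mature-toxin variants from C-terminal processing.

    Emits the untrimmed chain, up to ``trim_depth`` successive
    carboxypeptidase removals of trailing K/R (one variant each), and for
    every intermediate ending in Gly the amidated form with that Gly removed.
    Variants are deduplicated by (sequence, amidated flag).
    """
    if not mature_seq:
        raise ValueError("mature sequence must be non-empty")
    variants: list[MatureVariant] = []
    seen: set[tuple[str, bool]] = set()

    def add(seq: str, amidated: bool, provenance: str) -> None:
        if not seq:
            return
        key = (seq, amidated)
        if key in seen:
            return
        seen.add(key)
        variants.append(
            MatureVariant(
                parent_id=parent_id,
                variant_id=f"{parent_id}.v{len(variants) + 1}" if parent_id else f"v{len(variants) + 1}",
                sequence=seq,
                amidated=amidated,
                provenance=provenance,
            )
        )

    add(mature_seq, False, "full")
    if mature_seq.endswith("G"):
        add(mature_seq[:-1], True, "amidated")
    seq = mature_seq
    for _ in range(trim_depth):
        if not seq or seq[-1] not in "KR":
            break
        seq = seq[:-1]
        add(seq, False, "carboxypeptidase-trimmed")
        if seq.endswith("G"):
            add(seq[:-1], True, "amidated")
    return variants


def dedup_cds(precursors: Sequence[ToxinPrecursor]) -> list[tuple[ToxinPrecursor, int]]:
    """Collapse precursors with identical protein sequence, keeping read counts.

    The representative of each group is the member with the lexicographically
    smallest id, so the result is independent of input order.
    """
    groups: dict[str, list[ToxinPrecursor]] = {}
    for prec in precursors:
        groups.setdefault(prec.protein, []).append(prec)
    out = []
    for protein, members in groups.items():
        rep = min(members, key=lambda p: p.id)
        out.append((rep, len(members)))
    out.sort(key=lambda pair: pair[0].id)
    return out
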