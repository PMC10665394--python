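"""Proteomic validation of predicted toxins against peptide-spectrum matches.

The mature-variant database is digested in silico with up to four proteases
(trypsin, Lys-C, Glu-C, Asp-N, each with up to four missed cleavages), the
resulting theoretical peptides are pooled to decide which are unique to a
single toxin group, and observed PSM tables (already searched externally) are
filtered to 1% FDR by the target-decoy rule and mapped back onto the toxins:
a toxin is unambiguously identified when at least one of its unique peptides
is observed.  Per-toxin sequence coverage, isoform selection, C-terminal
amidation evidence and protease-set Venn comparisons complete the picture.

I and L are indistinguishable by mass and are collapsed (to L) in all
peptide-to-parent mapping by default.  Modifications other than C-terminal
amidation are ignored when matching observed peptides.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from venomine.precursor import MatureVariant

# ---------------------------------------------------------------------------
# Protease rules and digestion

@dataclass(frozen=True)
class ProteaseRule:
    name: str
    side: str  # "C" or "N" terminal side of the recognized residue
    residues: frozenset
    no_cut_before_P: bool = False


def make_protease(
    name: str,
    trypsin_proline_rule: bool = True,
    gluC_cleaves_D: bool = False,
) -> ProteaseRule:
    """The four supported specificities with their configurable variants."""
    if name == "trypsin":
        return ProteaseRule("trypsin", "C", frozenset("KR"), trypsin_proline_rule)
    if name == "lysC":
        return ProteaseRule("lysC", "C", frozenset("K"))
    if name == "gluC":
        residues = frozenset("ED") if gluC_cleaves_D else frozenset("E")
        return ProteaseRule("gluC", "C", residues)
    if name == "aspN":
        return ProteaseRule("aspN", "N", frozenset("D"))
    raise ValueError(f"unknown protease {name!r}")


PROTEASE_NAMES = ("trypsin", "lysC", "gluC", "aspN")


def cut_sites(rule: ProteaseRule, protein: str) -> list[int]:
    """Internal cleavage positions (0 < p < len) for a protease on a protein."""
    sites = []
    for p in range(1, len(protein)):
        if rule.side == "C":
            if protein[p - 1] in rule.residues and not (
                rule.no_cut_before_P and protein[p] == "P"
            ):
                sites.append(p)
        else:
            if protein[p] in rule.residues:
                sites.append(p)
    return sites


@dataclass(frozen=True)
class TheoreticalPeptide:
    sequence: str
    start: int
    end: int
    missed_cleavages: int
    is_cterm: bool


def digest(protein: str, rule: ProteaseRule, max_missed: int = 0) -> list[TheoreticalPeptide]:
    """All proteolytic peptides with at most ``max_missed`` internal sites.

    Zero-missed peptides partition the protein; peptides ending at the
    protein C-terminus are flagged ``is_cterm``.
    """
    if not protein:
        raise ValueError("empty protein")
    if not 0 <= max_missed <= 4:
        raise ValueError("max_missed must be within 0..4")
    bounds = [0] + cut_sites(rule, protein) + [len(protein)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            start, end = bounds[i], bounds[j]
            peptides.append(
                TheoreticalPeptide(
                    sequence=protein[start:end],
                    start=start,
                    end=end,
                    missed_cleavages=j - i - 1,
                    is_cterm=(end == len(protein)),
                )
            )
    return peptides


# ---------------------------------------------------------------------------
# Peptide indexing and uniqueness

def collapse_il(seq: str) -> str:
    return seq.replace("I", "L")


#: observable key of a peptide: (mass-collapsed sequence, C-terminally amidated)
PeptideKey = tuple[str, bool]


@dataclass
class PeptideEntry:
    sequence: str  # representative (un-collapsed) sequence
    parents: set = field(default_factory=set)  # toxin-group ids
    is_cterm: bool = False  # C-terminal in at least one parent variant
    cterm_parents: set = field(default_factory=set)

    @property
    def unique(self) -> bool:
        return len(self.parents) == 1


@dataclass
class PeptideIndex:
    """Pooled theoretical peptides of a variant database for one protease."""

    protease: str
    entries: dict  # PeptideKey -> PeptideEntry
    il_equivalent: bool = True

    def key_of(self, sequence: str, amidated: bool) -> PeptideKey:
        seq = collapse_il(sequence) if self.il_equivalent else sequence
        return (seq, amidated)

    def lookup(self, sequence: str, amidated: bool) -> PeptideEntry | None:
        return self.entries.get(self.key_of(sequence, amidated))


def build_peptide_index(
    db: Mapping[str, Sequence[MatureVariant]],
    rule: ProteaseRule,
    max_missed: int = 4,
    min_len: int = 1,
    il_equivalent: bool = True,
) -> PeptideIndex:
    """Digest every variant of every toxin group and pool the peptides.

    Parent sets are recorded at the toxin-group level, so isoform-shared
    peptides stay unique.  C-terminal peptides are indexed under both
    amidation states (search engines treat amidation as a variable
    modification), with ``cterm_parents`` tracking which groups can produce
    them.
    """
    index = PeptideIndex(protease=rule.name, entries={}, il_equivalent=il_equivalent)

    def entry(seq: str, amidated: bool) -> PeptideEntry:
        key = index.key_of(seq, amidated)
        if key not in index.entries:
            index.entries[key] = PeptideEntry(sequence=seq)
        return index.entries[key]

    for group_id in sorted(db):
        for variant in db[group_id]:
            for pep in digest(variant.sequence, rule, max_missed=max_missed):
                if len(pep.sequence) < min_len:
                    continue
                if pep.is_cterm:
                    # variable amidation: both observable forms, anchored to
                    # the variant's own amidation state for evidence counting
                    for amid in (False, True):
                        e = entry(pep.sequence, amid)
                        e.parents.add(group_id)
                        e.is_cterm = True
                        e.cterm_parents.add(group_id)
                else:
                    e = entry(pep.sequence, False)
                    e.parents.add(group_id)
    return index


def uniqueness_stats(
    db: Mapping[str, Sequence[MatureVariant]],
    rule: ProteaseRule,
    min_len: int = 5,
    max_missed: int = 0,
    il_equivalent: bool = True,
) -> tuple[int, int]:
    """(total, non-unique) theoretical peptides for a protease.

    Counts distinct peptide sequences of length >= ``min_len`` with at most
    ``max_missed`` missed cleavages, pooled across the variant database;
    non-unique means shared by more than one toxin group.
    """
    parents: dict[str, set] = defaultdict(set)
    for group_id in sorted(db):
        for variant in db[group_id]:
            for pep in digest(variant.sequence, rule, max_missed=max_missed):
                if len(pep.sequence) < min_len:
                    continue
                seq = collapse_il(pep.sequence) if il_equivalent else pep.sequence
                parents[seq].add(group_id)
    total = len(parents)
    non_unique = sum(1 for p in parents.values() if len(p) > 1)
    return total, non_unique


# ---------------------------------------------------------------------------
# PSM tables and FDR filtering

@dataclass(frozen=True)
class PSMRecord:
    peptide: str
    protease: str
    replicate: str
    score: float
    decoy: bool
    cterm_amidated: bool = False


def read_psm_table(path) -> list[PSMRecord]:
    """Read a PSM TSV: peptide, protease, replicate, score, decoy, cterm_amidated."""
    df = pd.read_csv(path, sep="\t")
    return [
        PSMRecord(
            peptide=str(r.peptide).upper(),
            protease=str(r.protease),
            replicate=str(r.replicate),
            score=float(r.score),
            decoy=bool(r.decoy),
            cterm_amidated=bool(getattr(r, "cterm_amidated", False)),
        )
        for r in df.itertuples(index=False)
    ]


def write_psm_table(psms: Iterable[PSMRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "peptide": p.peptide,
                "protease": p.protease,
                "replicate": p.replicate,
                "score": p.score,
                "decoy": int(p.decoy),
                "cterm_amidated": int(p.cterm_amidated),
            }
            for p in psms
        ]
    ).to_csv(path, sep="\t", index=False)


def fdr_filter(psms: Sequence[PSMRecord], alpha: float = 0.01) -> list[PSMRecord]:
    """Target-decoy FDR filtering at PSM level.

    Accepts all target PSMs with score >= t, where t is the most permissive
    score threshold at which (#decoys >= t) / (#targets >= t) <= alpha.
    Ties at the threshold are included; with no feasible threshold (or no
    targets) the result is empty.  Output order follows input order.
    """
    targets = [p for p in psms if not p.decoy]
    if not targets:
        return []
    scores = np.array([p.score for p in psms])
    decoys = np.array([p.decoy for p in psms])
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_cum = np.cumsum(decoys[order])
    t_cum = np.cumsum(~decoys[order])
    # candidate thresholds: positions where the next score differs (tie blocks end)
    n = len(s_sorted)
    feasible_t = None
    for i in range(n):
        if i + 1 < n and s_sorted[i + 1] == s_sorted[i]:
            continue
        if t_cum[i] > 0 and d_cum[i] / t_cum[i] <= alpha:
            feasible_t = s_sorted[i]  # keep lowering: most permissive wins
    if feasible_t is None:
        return []
    return [p for p in psms if not p.decoy and p.score >= feasible_t]


# ---------------------------------------------------------------------------
# Identification, coverage, isoforms

@dataclass
class IdentificationResult:
    toxin_id: str
    status: str  # unique_identified | group_evidence_only | not_detected
    chosen_isoform: str | None
    unique_peptides: set
    all_peptides: set
    coverage_unique: float
    coverage_all: float


def sequence_coverage(
    toxin_seq: str,
    peptide_seqs: Iterable[str],
    il_equivalent: bool = True,
) -> float:
    """Fraction of the toxin covered by the union of mapped peptide intervals."""
    if not toxin_seq:
        return 0.0
    hay = collapse_il(toxin_seq) if il_equivalent else toxin_seq
    covered = np.zeros(len(hay), dtype=bool)
    for pep in peptide_seqs:
        needle = collapse_il(pep) if il_equivalent else pep
        start = hay.find(needle)
        while start != -1:
            covered[start : start + len(needle)] = True
            start = hay.find(needle, start + 1)
    return float(covered.sum()) / len(hay)


def _observed_keys(
    accepted: Sequence[PSMRecord],
    index: PeptideIndex,
) -> set:
    return {index.key_of(p.peptide, p.cterm_amidated) for p in accepted}


def identify_toxins(
    accepted_psms: Sequence[PSMRecord],
    indexes: Mapping[str, PeptideIndex],
    db: Mapping[str, Sequence[MatureVariant]],
) -> tuple[list[IdentificationResult], list[PSMRecord]]:
    """Map accepted PSMs (replicates and proteases united) onto toxin groups.

    Returns per-group identification results plus the PSMs that matched no
    theoretical peptide of their protease (logged back to the caller,
    excluded from evidence).
    """
    unmatched: list[PSMRecord] = []
    observed: dict[str, dict] = {g: {"unique": set(), "all": set()} for g in db}
    observed_seqs: dict[str, dict] = {g: {"unique": set(), "all": set()} for g in db}
    for psm in accepted_psms:
        index = indexes.get(psm.protease)
        entry = index.lookup(psm.peptide, psm.cterm_amidated) if index else None
        if entry is None:
            unmatched.append(psm)
            continue
        key = index.key_of(psm.peptide, psm.cterm_amidated)
        for g in entry.parents:
            observed[g]["all"].add(key)
            observed_seqs[g]["all"].add(entry.sequence)
            if entry.unique:
                observed[g]["unique"].add(key)
                observed_seqs[g]["unique"].add(entry.sequence)
    results = []
    for g in sorted(db):
        uniq = observed[g]["unique"]
        allp = observed[g]["all"]
        if uniq:
            status = "unique_identified"
        elif allp:
            status = "group_evidence_only"
        else:
            status = "not_detected"
        isoform, cov_u, cov_a = select_isoform(
            db[g], observed_seqs[g]["unique"], observed_seqs[g]["all"]
        )
        results.append(
            IdentificationResult(
                toxin_id=g,
                status=status,
                chosen_isoform=isoform if allp else None,
                unique_peptides=uniq,
                all_peptides=allp,
                coverage_unique=cov_u,
                coverage_all=cov_a,
            )
        )
    return results, unmatched


def select_isoform(
    variants: Sequence[MatureVariant],
    unique_seqs: set,
    all_seqs: set,
) -> tuple[str | None, float, float]:
    """Choose one isoform per toxin group.

    The isoform with unique-peptide evidence wins; among several, the one
    with the highest unique-peptide coverage, then highest all-peptide
    coverage, then lexicographic variant id.  Returns (variant id, coverage
    by unique peptides, coverage by all peptides) for the chosen isoform.
    """
    if not variants:
        return None, 0.0, 0.0
    scored = []
    for v in variants:
        cov_u = sequence_coverage(v.sequence, unique_seqs)
        cov_a = sequence_coverage(v.sequence, all_seqs)
        has_unique = cov_u > 0
        scored.append((has_unique, cov_u, cov_a, v.variant_id))
    scored.sort(key=lambda t: (-t[0], -t[1], -t[2], t[3]))
    best = scored[0]
    return best[3], best[1], best[2]


# ---------------------------------------------------------------------------
# Amidation evidence

AMIDATION_CATEGORIES = (
    "confirmed_unique",
    "confirmed_nonunique_group",
    "ambiguous",
    "not_amidated",
    "undefined",
)


@dataclass(frozen=True)
class AmidationEvidence:
    toxin_id: str
    predicted: bool
    category: str
    n_amidated_psms: int
    n_plain_psms: int


def amidation_evidence(
    toxin_id: str,
    accepted_psms: Sequence[PSMRecord],
    indexes: Mapping[str, PeptideIndex],
    predicted: bool,
) -> AmidationEvidence:
    """Five-way amidation status of one toxin group from C-terminal PSMs.

    PSMs of amidated and plain forms of every C-terminal peptide mapping to
    the group are counted.  No C-terminal peptide observed -> undefined; both
    forms observed -> ambiguous; amidated only -> confirmed (via a unique or
    a group-shared peptide); plain only -> not amidated.
    """
    n_amid = 0
    n_plain = 0
    amid_unique = False
    for psm in accepted_psms:
        index = indexes.get(psm.protease)
        entry = index.lookup(psm.peptide, psm.cterm_amidated) if index else None
        if entry is None or toxin_id not in entry.cterm_parents or not entry.is_cterm:
            continue
        if psm.cterm_amidated:
            n_amid += 1
            if len(entry.cterm_parents) == 1:
                amid_unique = True
        else:
            n_plain += 1
    if n_amid == 0 and n_plain == 0:
        category = "undefined"
    elif n_amid > 0 and n_plain > 0:
        category = "ambiguous"
    elif n_amid > 0:
        category = "confirmed_unique" if amid_unique else "confirmed_nonunique_group"
    else:
        category = "not_amidated"
    return AmidationEvidence(
        toxin_id=toxin_id,
        predicted=predicted,
        category=category,
        n_amidated_psms=n_amid,
        n_plain_psms=n_plain,
    )


# ---------------------------------------------------------------------------
# Protease-set comparison (Venn regions)

def protease_set_comparison(sets: Mapping[str, set]) -> dict[tuple, int]:
    """Counts of every exclusive Venn region across >= 2 identification sets.

    Keys are sorted tuples of set names; the value counts elements belonging
    to exactly those sets and no others.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to compare")
    names = sorted(sets)
    regions: dict[tuple, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            regions[combo] = len(inside - outside)
    return regions
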