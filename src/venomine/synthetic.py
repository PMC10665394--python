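"""Ground-truth-labeled synthetic venomics data.

Generates (a) EST-like nucleotide reads encoding toxin precursors — signal
peptide, propeptide ending in an XXKR/XXRR quadruplet, a cysteine-rich mature
chain built to satisfy one of the bundled SRDA motifs, an optional GR/GKR
amidation cassette — alongside non-toxin reads and reads carrying frameshift
or premature-stop errors; and (b) multi-protease PSM tables obtained by
digesting a known toxin subset, with reversed-sequence decoys and configurable
per-toxin amidation status.

Every artifact is self-validated at generation time: mature chains are checked
against the motif engine, precursors against the segmentation code, PSM tables
against the identification and amidation logic.  Identical configuration
(including the seed) produces byte-identical output.

Defaults emulate the venom-gland EST study the pipeline models: a log-normal
read-length profile with median 457 nt, a 6C/8C/9C/10C family mix proportional
to 45/97/2/35, signal peptides of 18-25 residues and roughly a fifth of toxins
carrying a C-terminal amidation cassette.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from venomine import est, srda, families, precursor, proteomics
from venomine.precursor import MatureVariant
from venomine.proteomics import PSMRecord, make_protease, PROTEASE_NAMES

AA20 = families.AA20
SPACER_ALPHABET = "".join(sorted(set(AA20) - set("C")))
TAIL_ALPHABET = "".join(sorted(set(AA20) - set("CGKR")))
HYDROPHILIC = "DENQST"
CORE_HYDROPHOBIC = "FILV"  # deliberately excludes A: keeps -1/-3 bonus at the cut
CORE_SMALL = "AGS"
SUBSTITUTION_ALPHABET = "ADEFHNQSTVWY"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_STANDARD.stop_codons)


# ---------------------------------------------------------------------------
# Configuration and ground truth

@dataclass(frozen=True)
class PSMConfig:
    sampled_toxin_fraction: float = 0.85
    decoy_fraction: float = 0.5
    score_separation: float = 6.0
    target_score_mu: float = 10.0
    missed_cleavage_rate: float = 0.1
    replicate2_detect_prob: float = 0.7
    min_peptide_len: int = 5
    max_missed: int = 4


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_toxin_reads: int = 165
    n_nontoxin_reads: int = 90
    n_error_reads: int = 45
    family_mix: tuple = (("6C", 45 / 179), ("8C", 97 / 179), ("9C", 2 / 179), ("10C", 35 / 179))
    read_length_median: int = 457
    read_length_sigma: float = 0.25
    signal_len_range: tuple = (18, 25)
    propeptide_len_range: tuple = (6, 14)
    cassette_probs: tuple = (("", 0.60), ("GR", 0.15), ("GKR", 0.25))
    subfamily_size_p: float = 0.55  # geometric parameter for members per subfamily
    psm: PSMConfig = PSMConfig()


@dataclass(frozen=True)
class SynthToxin:
    """One distinct toxin with its full ground-truth annotation."""

    toxin_id: str
    family: str
    subfamily: str
    motif: str  # the construction motif its mature chain satisfies
    expected_winner: str  # first table motif that matches (precedence ground truth)
    signal: str
    propeptide: str
    core_mature: str  # mature chain after all C-terminal processing
    cassette: str  # "", "GR" or "GKR"
    transcript_count: int

    @property
    def mature_region(self) -> str:
        """The mature region of the precursor (before C-terminal processing)."""
        return self.core_mature + self.cassette

    @property
    def protein(self) -> str:
        return self.signal + self.propeptide + self.mature_region

    @property
    def predicted_amidated(self) -> bool:
        return "G" in self.cassette


@dataclass(frozen=True)
class ReadTruth:
    est_id: str
    kind: str  # toxin | nontoxin | error
    toxin_id: str | None
    frame: int | None  # frame carrying the planted ORF
    orf_start_aa: int | None  # index of the initiator Met in that frame
    protein: str | None  # planted precursor protein (uncorrupted)
    error_type: str | None = None


@dataclass
class SyntheticDataset:
    config: SynthConfig
    records: list  # ESTRecord
    read_truths: list  # ReadTruth
    toxins: list  # SynthToxin

    def variant_db(self, trim_depth: int = 2) -> dict[str, list[MatureVariant]]:
        """Mature-variant database keyed by toxin id."""
        return {
            t.toxin_id: precursor.generate_mature_variants(
                t.mature_region, parent_id=t.toxin_id, trim_depth=trim_depth
            )
            for t in self.toxins
        }


@dataclass(frozen=True)
class PSMTruth:
    sampled: frozenset  # toxin ids planted in the venom
    amidation_category: tuple  # ((toxin_id, category), ...) for amidation-predicted toxins
    isoform: tuple  # ((toxin_id, variant_id), ...) chosen true isoforms
    n_targets: int
    n_decoys: int


# ---------------------------------------------------------------------------
# Sequence-level generators

def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=int(n)))


def make_mature(family: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """A mature chain satisfying the family's cysteine framework.

    Returns (sequence, construction motif, expected precedence winner).  The
    skeleton is drawn to satisfy the corresponding general motif; spacers are
    filled with random non-Cys residues and the tail avoids G/K/R so that
    C-terminal processing stays fully controlled by the cassette.  The label
    is asserted against the motif engine before returning.
    """
    s = lambda: int(rng.integers(1, 10))
    # post-Cys tails are short in real toxins; 1..5 also keeps the tail plus a
    # GR/GKR cassette within the '#' token's single-digit spacer
    t = lambda: int(rng.integers(1, 6))
    first_is_six = bool(rng.random() < 0.6)
    s1 = 6 if first_is_six else int(rng.choice([3, 4, 5, 7, 8]))
    if family == "6C":
        plan = ["C", s1, "C", s(), "C", "C", s(), "C", s(), "C", t()]
        motif = "Cys#1" if first_is_six else "Cys#3"
        winner = motif
    elif family == "8C":
        plan = ["C", s1, "C", s(), "C", "C", s(), "C", 1, "C", s(), "C", 1, "C", t()]
        motif = "Cys#2" if first_is_six else "Cys#4"
        # the broad '*' semantics let the 6-Cys general motifs fire first
        winner = "Cys#1" if first_is_six else "Cys#3"
    elif family == "9C":
        plan = ["C", 6, "C", s(), "C", s(), "C", "C", s(), "C", s(), "C", s(), "C", s(), "C", t()]
        motif = "Cys#1"
        winner = "Cys#1"
    elif family == "10C":
        plan = ["C", 6, "C", s(), "C", s(), "C", "C", s(), "C", s(), "C", s(), "C", s(), "C", s(), "C", t()]
        motif = "Cys#1"
        winner = "Cys#1"
    else:
        raise ValueError(f"unknown family {family!r}")
    parts = []
    for i, item in enumerate(plan):
        if item == "C":
            parts.append("C")
        else:
            alphabet = TAIL_ALPHABET if i == len(plan) - 1 else SPACER_ALPHABET
            parts.append(_draw(rng, alphabet, item))
    seq = "".join(parts)
    # self-check against the engine and the family counter
    enc = srda.srda_encode(seq + ".")
    by_name = {m.name: m for m in srda.default_motifs()}
    assert srda.matches(enc, by_name[motif]), f"generated {seq} fails {motif}"
    assert families.assign_family(seq).family == family
    for m in srda.default_motifs():
        if srda.matches(enc, m):
            assert m.name == winner, f"{seq}: expected winner {winner}, got {m.name}"
            break
    return seq, motif, winner


def make_signal(rng: np.random.Generator, length: int) -> str:
    """A signal peptide whose built-in-predictor cut falls exactly at its end.

    Met, a short polar n-region, a hydrophobic core without A (so the -1/-3
    small-residue bonus fires only at the true site) and a 5-residue c-region
    with small residues exactly at the -1 and -3 positions.
    """
    core_len = length - 8
    c_region = (
        _draw(rng, "FLV", 1)
        + _draw(rng, "FLV", 1)
        + _draw(rng, CORE_SMALL, 1)
        + _draw(rng, "FLV", 1)
        + _draw(rng, CORE_SMALL, 1)
    )
    return "M" + _draw(rng, "NQKR", 2) + _draw(rng, CORE_HYDROPHOBIC, core_len) + c_region


def make_propeptide(rng: np.random.Generator, length: int) -> str:
    """A hydrophilic propeptide ending in an XXKR or XXRR quadruplet."""
    quad = _draw(rng, HYDROPHILIC, 2) + ("KR" if rng.random() < 0.5 else "RR")
    return _draw(rng, HYDROPHILIC, length - 4) + quad


def _assemble_precursor(
    rng: np.random.Generator,
    mature_region: str,
    cfg: SynthConfig,
) -> tuple[str, str]:
    """Draw (signal, propeptide) so the built-in pipeline recovers them exactly."""
    lo, hi = cfg.signal_len_range
    plo, phi = cfg.propeptide_len_range
    for _ in range(200):
        sig_len = int(rng.integers(lo, hi + 1))
        prop_len = int(rng.integers(plo, phi + 1))
        signal = make_signal(rng, sig_len)
        prop = make_propeptide(rng, prop_len)
        protein = signal + prop + mature_region
        pred = precursor.predict_signal_cleavage(protein)
        if pred is None or pred.cleavage_site != sig_len:
            continue
        mature_start, _ = precursor.find_propeptide_cleavage(protein, sig_len)
        if mature_start == sig_len + prop_len:
            return signal, prop
    raise RuntimeError("could not draw a recoverable signal/propeptide pair")


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform-synonymous-codon reverse translation, plus a stop codon."""
    codons = [
        _CODONS[aa][int(rng.integers(0, len(_CODONS[aa])))] for aa in protein
    ]
    codons.append(_STOP_CODONS[int(rng.integers(0, len(_STOP_CODONS)))])
    return "".join(codons)


_NT = "ACGT"


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return _draw(rng, _NT, n)


def _scrub_inframe_atg(utr: str, anchor: str) -> str:
    """Remove ATG codons in the CDS frame from a UTR.

    ``anchor='end'`` for a 5' UTR (frame anchored at its 3' end, where the CDS
    starts), ``anchor='start'`` for a 3' UTR.  Keeps the planted ORF the only
    Met-initiated segment of its frame.
    """
    chars = list(utr)
    if anchor == "end":
        positions = range(len(chars) - 3, -1, -3)
    else:
        positions = range(0, len(chars) - 2, 3)
    for pos in positions:
        if "".join(chars[pos : pos + 3]) == "ATG":
            chars[pos + 2] = "T"
    return "".join(chars)


def embed_cds(
    cds: str,
    rng: np.random.Generator,
    cfg: SynthConfig,
) -> tuple[str, int, int]:
    """Pad a CDS with UTRs to a log-normal read length and pick a strand.

    Returns (read, frame, orf_start_aa): the frame (1-6) whose translation
    contains the planted ORF and the 0-based index of its initiator Met.
    The 5' UTR carries no in-frame ATG, so the planted ORF is the first Met
    of its stop-bounded segment.
    """
    total = int(rng.lognormal(np.log(cfg.read_length_median), cfg.read_length_sigma))
    total = max(total, len(cds) + 12)
    pad = total - len(cds)
    n5 = int(rng.integers(3, pad - 2)) if pad > 5 else pad // 2
    n3 = pad - n5
    utr5 = _scrub_inframe_atg(_random_nt(rng, n5), "end")
    utr3 = _scrub_inframe_atg(_random_nt(rng, n3), "start")
    fwd = utr5 + cds + utr3
    orf_start_aa = n5 // 3
    if rng.random() < 0.5:
        return fwd, 1 + n5 % 3, orf_start_aa
    return str(Seq(fwd).reverse_complement()), 4 + n5 % 3, orf_start_aa


# ---------------------------------------------------------------------------
# Dataset generation

def _generate_toxins(cfg: SynthConfig, rng: np.random.Generator) -> list[SynthToxin]:
    fam_names = [f for f, _ in cfg.family_mix]
    fam_probs = np.array([p for _, p in cfg.family_mix])
    fam_probs = fam_probs / fam_probs.sum()
    cas_names = [c for c, _ in cfg.cassette_probs]
    cas_probs = np.array([p for _, p in cfg.cassette_probs])
    cas_probs = cas_probs / cas_probs.sum()

    toxins: list[SynthToxin] = []
    budget = cfg.n_toxin_reads
    sf_counter = 0
    tox_counter = 0
    cas_counts = np.zeros(len(cas_names))
    while budget > 0:
        sf_counter += 1
        family = str(rng.choice(fam_names, p=fam_probs))
        consensus, motif, winner = make_mature(family, rng)
        # largest-remainder quota over subfamilies: keeps the realized cassette
        # proportions (hence the amidation-predicted cluster count) on target
        deficit = cas_probs * sf_counter - cas_counts
        cas_idx = int(np.argmax(deficit))
        cas_counts[cas_idx] += 1
        cassette = cas_names[cas_idx]
        subfamily = f"{family}.g{sf_counter}"
        n_members = int(rng.geometric(cfg.subfamily_size_p))
        allowed = [
            i
            for i in range(1, max(len(consensus) - 12, 2))
            if consensus[i] != "C"
        ]
        n_members = max(1, min(n_members, len(allowed) // 2))
        positions = rng.choice(allowed, size=2 * n_members, replace=False)
        for m in range(n_members):
            if budget <= 0:
                break
            tox_counter += 1
            n_subs = 1 if rng.random() < 0.5 else 2
            seq = list(consensus)
            for p in positions[2 * m : 2 * m + n_subs]:
                current = seq[p]
                options = [a for a in SUBSTITUTION_ALPHABET if a != current]
                seq[p] = options[int(rng.integers(0, len(options)))]
            core = "".join(seq)
            # the cassette lengthens the tail spacer; the precedence winner
            # must be unchanged on the precursor's full mature region
            enc = srda.srda_encode(core + cassette + ".")
            first = next(
                (m.name for m in srda.default_motifs() if srda.matches(enc, m)), None
            )
            assert first == winner, f"{core + cassette}: winner {first}, expected {winner}"
            signal, prop = _assemble_precursor(rng, core + cassette, cfg)
            count = int(rng.integers(4, 9)) if m == 0 else int(rng.integers(1, 3))
            count = min(count, budget)
            budget -= count
            toxins.append(
                SynthToxin(
                    toxin_id=f"TOX{tox_counter:03d}",
                    family=family,
                    subfamily=subfamily,
                    motif=motif,
                    expected_winner=winner,
                    signal=signal,
                    propeptide=prop,
                    core_mature=core,
                    cassette=cassette,
                    transcript_count=count,
                )
            )
    return toxins


def _make_nontoxin_protein(rng: np.random.Generator) -> str:
    """A random non-secreted protein failing all bundled motifs (<= 4 Cys)."""
    motifs = srda.default_motifs()
    for _ in range(100):
        length = int(rng.integers(60, 121))
        body = list(_draw(rng, SPACER_ALPHABET, length))
        for p in rng.choice(length, size=int(rng.integers(0, 5)), replace=False):
            body[int(p)] = "C"
        protein = "M" + "".join(body)
        enc = srda.srda_encode(protein + ".")
        if not any(srda.matches(enc, m) for m in motifs):
            return protein
    raise RuntimeError("could not draw a motif-free non-toxin protein")


def _corrupt(cds: str, rng: np.random.Generator) -> tuple[str, str]:
    """Introduce one frameshift indel or one premature stop into a CDS."""
    kind = ["frameshift_del", "frameshift_ins", "premature_stop"][int(rng.integers(0, 3))]
    n_codons = len(cds) // 3
    mid_codon = int(rng.integers(n_codons // 4, n_codons // 2))
    if kind == "frameshift_del":
        p = mid_codon * 3
        return cds[:p] + cds[p + 1 :], kind
    if kind == "frameshift_ins":
        p = mid_codon * 3
        return cds[:p] + _random_nt(rng, 1) + cds[p:], kind
    p = mid_codon * 3
    stop = _STOP_CODONS[int(rng.integers(0, len(_STOP_CODONS)))]
    return cds[:p] + stop + cds[p + 3 :], kind


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate the full labeled EST dataset for a configuration."""
    rng = np.random.default_rng(cfg.seed)
    toxins = _generate_toxins(cfg, rng)

    motif_list = srda.default_motifs()

    def read_winner(read: str) -> str | None:
        record = est.ESTRecord("tmp", read)
        encodings = [
            enc
            for fr in est.six_frame_translate(record)
            for enc in srda.encode_frame(fr.aa_seq)
        ]
        for m in motif_list:
            if any(srda.matches(enc, m) for enc in encodings):
                return m.name
        return None

    entries: list[tuple[str, str, ReadTruth]] = []  # (kind, read, truth sans id)
    for t in toxins:
        cds = reverse_translate(t.protein, rng)
        for _ in range(t.transcript_count):
            # UTR junk in another frame can steal precedence; redraw until the
            # read classifies under the motif its mature chain was built for
            for _attempt in range(50):
                read, frame, start_aa = embed_cds(cds, rng, cfg)
                if read_winner(read) == t.expected_winner:
                    break
            else:
                raise RuntimeError(f"could not embed {t.toxin_id} cleanly")
            entries.append(
                (
                    read,
                    ReadTruth(
                        est_id="",
                        kind="toxin",
                        toxin_id=t.toxin_id,
                        frame=frame,
                        orf_start_aa=start_aa,
                        protein=t.protein,
                    ),
                )
            )
    motifs = srda.default_motifs()

    def read_is_motif_free(read: str) -> bool:
        record = est.ESTRecord("tmp", read)
        for fr in est.six_frame_translate(record):
            for enc in srda.encode_frame(fr.aa_seq):
                if any(srda.matches(enc, m) for m in motifs):
                    return False
        return True

    for _ in range(cfg.n_nontoxin_reads):
        for _attempt in range(50):
            protein = _make_nontoxin_protein(rng)
            cds = reverse_translate(protein, rng)
            read, frame, start_aa = embed_cds(cds, rng, cfg)
            # no frame of the read, not only the planted one, may hit a motif
            if read_is_motif_free(read):
                break
        else:
            raise RuntimeError("could not draw a motif-free non-toxin read")
        entries.append(
            (
                read,
                ReadTruth(
                    est_id="",
                    kind="nontoxin",
                    toxin_id=None,
                    frame=frame,
                    orf_start_aa=start_aa,
                    protein=protein,
                ),
            )
        )
    for i in range(cfg.n_error_reads):
        t = toxins[int(rng.integers(0, len(toxins)))]
        cds, error_type = _corrupt(reverse_translate(t.protein, rng), rng)
        read, frame, start_aa = embed_cds(cds, rng, cfg)
        entries.append(
            (
                read,
                ReadTruth(
                    est_id="",
                    kind="error",
                    toxin_id=t.toxin_id,
                    frame=None,
                    orf_start_aa=None,
                    protein=None,
                    error_type=error_type,
                ),
            )
        )

    order = rng.permutation(len(entries))
    records = []
    truths = []
    for new_idx, old_idx in enumerate(order):
        read, truth = entries[int(old_idx)]
        est_id = f"est{new_idx + 1:04d}"
        records.append(est.ESTRecord(est_id, read))
        truths.append(replace(truth, est_id=est_id))
    return SyntheticDataset(config=cfg, records=records, read_truths=truths, toxins=toxins)


# ---------------------------------------------------------------------------
# PSM table generation

def _cterm_peptide(
    sequence: str, rule, min_len: int, max_missed: int = 4
) -> str | None:
    """The toxin's C-terminal peptide for one protease: the fewest-missed-
    cleavage one reaching ``min_len``; None when no C-terminal peptide of
    observable length exists."""
    cterm = [
        p
        for p in proteomics.digest(sequence, rule, max_missed=max_missed)
        if p.is_cterm
    ]
    cterm.sort(key=lambda p: p.missed_cleavages)
    for p in cterm:
        if len(p.sequence) >= min_len:
            return p.sequence
    return None


def make_psm_table(
    db: Mapping[str, Sequence[MatureVariant]],
    predicted_amidated: Mapping[str, bool],
    config: PSMConfig,
    rng: np.random.Generator,
) -> tuple[list[PSMRecord], PSMTruth]:
    """Digest a sampled toxin subset into a decoy-containing PSM table.

    Target scores follow Normal(mu, 1) and decoy scores Normal(mu - score
    separation, 1).  C-terminal peptides are emitted amidated or plain per the
    toxin's assigned amidation category; within a group of toxins sharing
    their C-terminal peptides the category is assigned jointly, mirroring how
    shared C-termini can only ever be confirmed at the group level.
    """
    rules = {name: make_protease(name) for name in PROTEASE_NAMES}
    indexes = {
        name: proteomics.build_peptide_index(db, rule, max_missed=config.max_missed)
        for name, rule in rules.items()
    }
    all_ids = sorted(db)
    n_sampled = int(round(config.sampled_toxin_fraction * len(all_ids)))
    sampled = sorted(
        str(t) for t in rng.choice(all_ids, size=n_sampled, replace=False)
    )

    # isoform actually present in the venom, before category adjustment
    def amidated_variant(tid: str) -> MatureVariant | None:
        for v in db[tid]:
            if v.amidated:
                return v
        return None

    def full_variant(tid: str) -> MatureVariant:
        return db[tid][0]

    # ---- amidation categories, assigned per C-term-sharing cluster --------
    predicted_sampled = [t for t in sampled if predicted_amidated.get(t, False)]
    parent = {t: t for t in predicted_sampled}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cterm_info: dict[str, list[tuple[str, str, bool]]] = {}
    plain_cterm: dict[str, list[tuple[str, str]]] = {}
    for t in predicted_sampled:
        av = amidated_variant(t)
        infos = []
        for name, rule in rules.items():
            seq = _cterm_peptide(av.sequence, rule, config.min_peptide_len)
            if seq is None:
                continue
            entry = indexes[name].lookup(seq, True)
            if entry is None or t not in entry.cterm_parents:
                continue
            infos.append((name, seq, len(entry.cterm_parents) == 1))
        cterm_info[t] = infos
        plains = []
        for name, rule in rules.items():
            seq = _cterm_peptide(full_variant(t).sequence, rule, config.min_peptide_len)
            if seq is not None:
                plains.append((name, seq))
        plain_cterm[t] = plains
    # closure over shared C-terminal entries of observable length (any
    # variant, any missed-cleavage count): toxins whose C-termini can yield a
    # common observable peptide must carry one joint amidation category
    predicted_set = set(predicted_sampled)
    for index in indexes.values():
        for key, entry in index.entries.items():
            if len(key[0]) < config.min_peptide_len:
                continue
            members = sorted(entry.cterm_parents & predicted_set)
            for other in members[1:]:
                ra, rb = find(members[0]), find(other)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[str]] = {}
    for t in predicted_sampled:
        clusters.setdefault(find(t), []).append(t)

    categories: dict[str, str] = {}
    needed = ["confirmed_unique", "confirmed_nonunique_group", "ambiguous", "not_amidated", "undefined"]
    rotation = list(needed)
    for root in sorted(clusters):
        members = sorted(clusters[root])
        # every member must be able to realize the category on its own peptides
        all_unique = all(any(u for _, _, u in cterm_info[t]) for t in members)
        all_shared = all(any(not u for _, _, u in cterm_info[t]) for t in members)
        all_amid = all(bool(cterm_info[t]) for t in members)
        all_plain = all(bool(plain_cterm[t]) for t in members)

        def compatible(cat: str) -> bool:
            if cat == "confirmed_unique":
                return all_unique
            if cat == "confirmed_nonunique_group":
                return all_shared
            if cat == "ambiguous":
                return all_amid and all_plain
            if cat == "not_amidated":
                return all_plain
            return True  # undefined

        cat = next((c for c in needed if compatible(c)), None)
        if cat is not None:
            needed.remove(cat)
        else:
            for _ in range(len(rotation)):
                cat = rotation.pop(0)
                rotation.append(cat)
                if compatible(cat):
                    break
            else:
                cat = "undefined"
        for t in members:
            categories[t] = cat

    # ---- emission ----------------------------------------------------------
    psms: list[PSMRecord] = []
    isoforms: dict[str, str] = {}

    def emit(seq: str, protease: str, amidated: bool) -> None:
        for replicate in ("1", "2"):
            if replicate == "2" and rng.random() > config.replicate2_detect_prob:
                continue
            psms.append(
                PSMRecord(
                    peptide=seq,
                    protease=protease,
                    replicate=replicate,
                    score=float(rng.normal(config.target_score_mu, 1.0)),
                    decoy=False,
                    cterm_amidated=amidated,
                )
            )

    for t in sampled:
        cat = categories.get(t)
        if cat in ("confirmed_unique", "confirmed_nonunique_group", "ambiguous"):
            iso = amidated_variant(t) or full_variant(t)
        else:
            iso = full_variant(t)
        isoforms[t] = iso.variant_id
        # categories whose plain C-terminal PSM count must stay at zero
        cterm_controlled = cat in ("confirmed_unique", "confirmed_nonunique_group", "undefined")

        def cterm_informative(name: str, seq: str) -> bool:
            # a peptide that is C-terminal in *any* variant of the group
            # (e.g. a trimmed isoform) counts as C-terminal evidence
            entry = indexes[name].lookup(seq, False)
            return entry is not None and t in entry.cterm_parents

        # internal peptides
        for name, rule in rules.items():
            for pep in proteomics.digest(iso.sequence, rule, max_missed=1):
                if pep.is_cterm:
                    continue
                if len(pep.sequence) < config.min_peptide_len:
                    continue
                if cterm_controlled and cterm_informative(name, pep.sequence):
                    continue
                if pep.missed_cleavages == 0 or rng.random() < config.missed_cleavage_rate:
                    emit(pep.sequence, name, False)
        # C-terminal peptides per category
        if cat is None:  # amidation never predicted: plain C-terminus
            for name, rule in rules.items():
                seq = _cterm_peptide(full_variant(t).sequence, rule, config.min_peptide_len)
                if seq is not None:
                    emit(seq, name, False)
        elif cat == "undefined":
            pass
        else:
            if cat in ("confirmed_unique", "confirmed_nonunique_group", "ambiguous"):
                want_unique = cat == "confirmed_unique"
                for name, seq, uniq in cterm_info[t]:
                    if cat == "ambiguous" or uniq == want_unique:
                        emit(seq, name, True)
            if cat in ("ambiguous", "not_amidated"):
                for name, seq in plain_cterm[t]:
                    emit(seq, name, False)

    # guarantee every sampled toxin carries at least one unique peptide
    observed_unique: set = set()
    for p in psms:
        entry = indexes[p.protease].lookup(p.peptide, p.cterm_amidated)
        if entry is not None and entry.unique:
            observed_unique.add(next(iter(entry.parents)))
    for t in sampled:
        if t in observed_unique:
            continue
        rescued = False
        for name, rule in rules.items():
            for pep in proteomics.digest(
                isoform_sequence(db, isoforms[t]), rule, max_missed=config.max_missed
            ):
                if pep.is_cterm or len(pep.sequence) < config.min_peptide_len:
                    continue
                entry = indexes[name].lookup(pep.sequence, False)
                if entry is None or not entry.unique or t not in entry.parents:
                    continue
                if t in entry.cterm_parents and categories.get(t) in (
                    "confirmed_unique", "confirmed_nonunique_group", "undefined"
                ):
                    continue
                emit(pep.sequence, name, False)
                rescued = True
                break
            if rescued:
                break

    # decoys: reversed target peptides, checked against every index
    n_targets = len(psms)
    n_decoys = int(round(config.decoy_fraction * n_targets))
    decoys: list[PSMRecord] = []
    attempts = 0
    while n_targets > 0 and len(decoys) < n_decoys and attempts < 20 * n_decoys:
        attempts += 1
        src = psms[int(rng.integers(0, n_targets))]
        dseq = src.peptide[::-1]
        if any(indexes[n].lookup(dseq, False) for n in rules) or any(
            indexes[n].lookup(dseq, True) for n in rules
        ):
            continue
        decoys.append(
            PSMRecord(
                peptide=dseq,
                protease=src.protease,
                replicate=src.replicate,
                score=float(
                    rng.normal(config.target_score_mu - config.score_separation, 1.0)
                ),
                decoy=True,
                cterm_amidated=False,
            )
        )
    psms = psms + decoys

    truth = PSMTruth(
        sampled=frozenset(sampled),
        amidation_category=tuple(sorted(categories.items())),
        isoform=tuple(sorted(isoforms.items())),
        n_targets=n_targets,
        n_decoys=len(decoys),
    )
    _self_validate_psms(psms, indexes, db, predicted_amidated, truth)
    return psms, truth


def isoform_sequence(db: Mapping[str, Sequence[MatureVariant]], variant_id: str) -> str:
    for variants in db.values():
        for v in variants:
            if v.variant_id == variant_id:
                return v.sequence
    raise KeyError(variant_id)


def _self_validate_psms(psms, indexes, db, predicted_amidated, truth: PSMTruth) -> None:
    """Check the emitted table against the validation pipeline itself."""
    targets = [p for p in psms if not p.decoy]
    results, unmatched = proteomics.identify_toxins(targets, indexes, db)
    assert not unmatched, "generator emitted unmatchable target peptides"
    identified = {r.toxin_id for r in results if r.status == "unique_identified"}
    assert identified == set(truth.sampled), (
        "planted venom subset not uniquely identifiable: "
        f"missing {set(truth.sampled) - identified}, extra {identified - set(truth.sampled)}"
    )
    for tid, cat in truth.amidation_category:
        ev = proteomics.amidation_evidence(
            tid, targets, indexes, predicted_amidated.get(tid, False)
        )
        assert ev.category == cat, f"{tid}: planted {cat}, evidence gives {ev.category}"


def generate_psm_dataset(
    cfg: SynthConfig,
) -> tuple[SyntheticDataset, dict, list[PSMRecord], PSMTruth]:
    """Full synthetic venomics bundle: reads, variant DB, PSM table, truths."""
    ds = generate_dataset(cfg)
    db = ds.variant_db()
    predicted = {t.toxin_id: t.predicted_amidated for t in ds.toxins}
    rng = np.random.default_rng(cfg.seed + 10_000)
    psms, truth = make_psm_table(db, predicted, cfg.psm, rng)
    return ds, db, psms, truth
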