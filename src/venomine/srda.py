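"""Single-residue distribution analysis (SRDA) of cysteine frameworks.

A protein is reduced to its cysteine skeleton: runs of non-Cys residues become
spacer tokens carrying the run length, cysteines stay as ``C`` tokens, and a
terminal stop translates to a STOP token.  Toxin frameworks are then searched
with a small pattern language:

=====  ==========================================================
C      one cysteine
n      a spacer of exactly n residues (multi-digit literals allowed)
#      one spacer of 1-9 residues, or nothing directly before the stop
*      a gap in the search line: any run of C/spacer tokens, possibly empty
.      the stop symbol (translation termination)
n≠k    one spacer of any length except k (side condition, e.g. ``(n≠6)``)
=====  ==========================================================

Matching is token-level: the spacer literal ``6`` matches a spacer of exactly
six residues, never a digit inside a longer spacer such as 16.  ``*`` may
absorb cysteine tokens, which is what lets the 6-Cys general pattern also hit
8-, 9- and 10-Cys frameworks; a stricter single-spacer reading of ``*`` is
available via ``star_spans_cys=False``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

STOP_CH = "."

# ---------------------------------------------------------------------------
# Encoding

@dataclass(frozen=True)
class SRDAEncoding:
    """Tokenized cysteine-spacing representation of one protein segment.

    ``tokens`` are ``("C",)``, ``("S", n)`` with n >= 1, or ``("STOP",)``
    (at most one, terminal).  ``spans`` maps each token to its residue
    interval in the source segment; ``offset`` locates the segment within a
    larger translation.
    """

    tokens: tuple[tuple, ...]
    spans: tuple[tuple[int, int], ...]
    length: int  # residues encoded, excluding the stop symbol
    truncated: bool = False
    offset: int = 0

    def serialize(self) -> str:
        parts = []
        for tok in self.tokens:
            if tok[0] == "C":
                parts.append("C")
            elif tok[0] == "S":
                parts.append(str(tok[1]))
            else:
                parts.append(STOP_CH)
        return "".join(parts)

    def cys_positions(self) -> list[int]:
        return [s for tok, (s, _) in zip(self.tokens, self.spans) if tok[0] == "C"]


def srda_encode(seq: str, offset: int = 0) -> SRDAEncoding:
    """Encode an amino-acid string (optionally stop-terminated) as SRDA tokens.

    An internal stop truncates the encoding at the first stop symbol and sets
    ``truncated``.  'X' and every non-Cys residue count toward spacer lengths.
    """
    tokens: list[tuple] = []
    spans: list[tuple[int, int]] = []
    run_start = None
    truncated = False
    end = len(seq)
    stop_at = seq.find(STOP_CH)
    if stop_at != -1:
        truncated = stop_at < len(seq) - 1
        end = stop_at
    i = 0
    run_start = None
    for i in range(end):
        if seq[i] == "C":
            if run_start is not None:
                tokens.append(("S", i - run_start))
                spans.append((run_start, i))
                run_start = None
            tokens.append(("C",))
            spans.append((i, i + 1))
        else:
            if run_start is None:
                run_start = i
    if run_start is not None:
        tokens.append(("S", end - run_start))
        spans.append((run_start, end))
    if stop_at != -1:
        tokens.append(("STOP",))
        spans.append((end, end + 1))
    return SRDAEncoding(
        tokens=tuple(tokens),
        spans=tuple(spans),
        length=end,
        truncated=truncated,
        offset=offset,
    )


def srda_decode(encoding: SRDAEncoding) -> str:
    """Rebuild a skeleton sequence ('C' / 'x' / '.') from an encoding."""
    parts = []
    for tok in encoding.tokens:
        if tok[0] == "C":
            parts.append("C")
        elif tok[0] == "S":
            parts.append("x" * tok[1])
        else:
            parts.append(STOP_CH)
    return "".join(parts)


def encode_frame(aa_seq: str) -> list[SRDAEncoding]:
    """Encode a full frame translation as stop-terminated segments.

    The frame is split at stop symbols; each segment keeps its terminal stop
    (the last one may lack it) and remembers its residue offset in the frame.
    Empty segments (consecutive stops) are dropped.
    """
    encodings = []
    start = 0
    n = len(aa_seq)
    while start <= n:
        stop = aa_seq.find(STOP_CH, start)
        if stop == -1:
            seg = aa_seq[start:]
            if seg:
                encodings.append(srda_encode(seg, offset=start))
            break
        seg = aa_seq[start : stop + 1]
        if seg != STOP_CH:
            encodings.append(srda_encode(seg, offset=start))
        start = stop + 1
    return encodings


# ---------------------------------------------------------------------------
# Pattern language

@dataclass(frozen=True)
class MotifPattern:
    """One search formula: name, category and parsed pattern tokens.

    Pattern tokens: ("C",), ("LIT", n), ("HASH",), ("STAR",), ("NEQ", n),
    ("STOP",).
    """

    name: str
    category: str  # general | extended | partial
    tokens: tuple[tuple, ...]
    formula: str

    @property
    def anchored(self) -> bool:
        return bool(self.tokens) and self.tokens[-1][0] == "STOP"

    def serialize(self) -> str:
        parts = []
        neq = None
        for tok in self.tokens:
            kind = tok[0]
            if kind == "C":
                parts.append("C")
            elif kind == "LIT":
                parts.append(str(tok[1]))
            elif kind == "HASH":
                parts.append("#")
            elif kind == "STAR":
                parts.append("*")
            elif kind == "NEQ":
                parts.append("n")
                neq = tok[1]
            else:
                parts.append(STOP_CH)
        out = "".join(parts)
        if neq is not None:
            out += f" (n≠{neq})"
        return out


_SIDE_COND = re.compile(r"\s*\(n≠(\d+)\)\s*$")


def parse_motif(formula: str, name: str = "", category: str = "general") -> MotifPattern:
    """Parse a cysteine-distribution formula such as ``C6C*CC*C*C#.``."""
    body = formula
    neq_value = None
    m = _SIDE_COND.search(body)
    if m:
        neq_value = int(m.group(1))
        body = body[: m.start()]
    tokens: list[tuple] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "C":
            tokens.append(("C",))
            i += 1
        elif ch.isdigit():
            j = i
            while j < len(body) and body[j].isdigit():
                j += 1
            tokens.append(("LIT", int(body[i:j])))
            i = j
        elif ch == "#":
            tokens.append(("HASH",))
            i += 1
        elif ch == "*":
            tokens.append(("STAR",))
            i += 1
        elif ch == STOP_CH:
            tokens.append(("STOP",))
            i += 1
        elif ch == "n":
            if neq_value is None:
                raise ValueError(
                    f"'n' at position {i} without a side condition in {formula!r}"
                )
            tokens.append(("NEQ", neq_value))
            i += 1
        else:
            raise ValueError(f"illegal character {ch!r} at position {i} in {formula!r}")
    return MotifPattern(name=name, category=category, tokens=tuple(tokens), formula=formula)


# The published search table: name, category, formula — precedence order.
TABLE_MOTIFS: tuple[tuple[str, str, str], ...] = (
    ("Cys#1", "general", "C6C*CC*C*C#."),
    ("Cys#2", "general", "C6C*CC*C1C*C1C#."),
    ("Cys#3", "general", "CnC*CC*C*C#. (n≠6)"),
    ("Cys#4", "general", "CnC*CC*C1C*C1C#. (n≠6)"),
    ("extCys#2", "extended", "C#C*CC*C1C*C1C"),
    ("extCys#1", "extended", "C#C*CC*C*C"),
    ("partCys#1", "partial", "C*CC*C*C#."),
    ("partCys#2", "partial", "C*CC*C1C"),
)


def default_motifs() -> list[MotifPattern]:
    """The eight bundled motifs in precedence order."""
    return [parse_motif(f, name=n, category=c) for n, c, f in TABLE_MOTIFS]


def load_motifs(path) -> list[MotifPattern]:
    """Load motifs from a TSV config: name <tab> category <tab> formula, ordered."""
    motifs = []
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, category, formula = line.split("\t")
            motifs.append(parse_motif(formula, name=name, category=category))
    return motifs


# ---------------------------------------------------------------------------
# Matching

def _encoding_string(encoding: SRDAEncoding) -> tuple[str, list[int]]:
    """Serialize tokens for regex matching; spacers become ``<n>``.

    Returns the string and a char-index -> token-index map.
    """
    parts = []
    tok_of_char: list[int] = []
    for ti, tok in enumerate(encoding.tokens):
        if tok[0] == "C":
            s = "C"
        elif tok[0] == "S":
            s = f"<{tok[1]}>"
        else:
            s = STOP_CH
        parts.append(s)
        tok_of_char.extend([ti] * len(s))
    return "".join(parts), tok_of_char


def compile_pattern(pattern: MotifPattern, star_spans_cys: bool = True) -> re.Pattern:
    """Compile a motif to a regex over the token serialization.

    With ``star_spans_cys`` (default) '*' absorbs any run of C/spacer tokens;
    otherwise it matches at most one spacer token.
    """
    star_re = r"(?:C|<\d+>)*?" if star_spans_cys else r"(?:<\d+>)??"
    parts = []
    toks = pattern.tokens
    for idx, tok in enumerate(toks):
        kind = tok[0]
        if kind == "C":
            parts.append("C")
        elif kind == "LIT":
            parts.append(f"<{tok[1]}>")
        elif kind == "HASH":
            nxt = toks[idx + 1] if idx + 1 < len(toks) else None
            if nxt is not None and nxt[0] == "STOP":
                # digit 0: no trailing residues between the last Cys and the stop
                parts.append(r"(?:<[1-9]>)?")
            else:
                parts.append(r"(?:<[1-9]>)")
        elif kind == "NEQ":
            parts.append(rf"(?:<(?!{tok[1]}>)\d+>)")
        elif kind == "STAR":
            parts.append(star_re)
        else:  # STOP
            parts.append(r"\.")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class MotifMatch:
    motif: str
    token_span: tuple[int, int]
    residue_interval: tuple[int, int]  # within the source frame translation


def match_motif(
    encoding: SRDAEncoding,
    pattern: MotifPattern,
    star_spans_cys: bool = True,
) -> list[MotifMatch]:
    """All leftmost-shortest, non-overlapping matches of a motif in an encoding."""
    text, tok_of_char = _encoding_string(encoding)
    rx = compile_pattern(pattern, star_spans_cys=star_spans_cys)
    matches = []
    for m in rx.finditer(text):
        if m.end() == m.start():
            continue
        t0 = tok_of_char[m.start()]
        t1 = tok_of_char[m.end() - 1]
        r0 = encoding.spans[t0][0]
        r1 = encoding.spans[t1][1]
        matches.append(
            MotifMatch(
                motif=pattern.name,
                token_span=(t0, t1 + 1),
                residue_interval=(encoding.offset + r0, encoding.offset + r1),
            )
        )
    return matches


def matches(encoding: SRDAEncoding, pattern: MotifPattern, star_spans_cys: bool = True) -> bool:
    return bool(match_motif(encoding, pattern, star_spans_cys=star_spans_cys))


# ---------------------------------------------------------------------------
# Read classification with precedence and impact accounting

@dataclass(frozen=True)
class ReadClassification:
    est_id: str
    motif: str | None
    category: str | None
    frame: int | None
    residue_interval: tuple[int, int] | None
    encoded_line: str | None
    needs_homology_check: bool  # extended/partial hits await external verification


@dataclass
class ClassificationResult:
    reads: list[ReadClassification]
    impacts: dict[str, int]

    @property
    def n_candidates(self) -> int:
        return sum(self.impacts.values())


def classify_reads(
    frames_by_read: Mapping[str, Sequence],
    motifs: Sequence[MotifPattern] | None = None,
    star_spans_cys: bool = True,
) -> ClassificationResult:
    """Classify reads by the first motif (in table order) matching any frame.

    ``frames_by_read`` maps est_id to its TranslatedFrames.  Each read counts
    once, under the first motif of the precedence list that matches any of its
    six frame translations; ties across frames report the lowest frame number.
    """
    if motifs is None:
        motifs = default_motifs()
    reads: list[ReadClassification] = []
    impacts: dict[str, int] = {m.name: 0 for m in motifs}
    for est_id in frames_by_read:
        frames = sorted(frames_by_read[est_id], key=lambda fr: fr.frame)
        encodings = [(fr.frame, enc) for fr in frames for enc in encode_frame(fr.aa_seq)]
        hit = None
        for motif in motifs:
            for frame_no, enc in encodings:
                found = match_motif(enc, motif, star_spans_cys=star_spans_cys)
                if found:
                    hit = (motif, frame_no, found[0], enc)
                    break
            if hit:
                break
        if hit is None:
            reads.append(
                ReadClassification(est_id, None, None, None, None, None, False)
            )
        else:
            motif, frame_no, mm, enc = hit
            impacts[motif.name] += 1
            reads.append(
                ReadClassification(
                    est_id=est_id,
                    motif=motif.name,
                    category=motif.category,
                    frame=frame_no,
                    residue_interval=mm.residue_interval,
                    encoded_line=enc.serialize(),
                    needs_homology_check=motif.category in ("extended", "partial"),
                )
            )
    return ClassificationResult(reads=reads, impacts=impacts)
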