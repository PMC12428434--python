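"""Degenerate-motif annotation of the mitochondrial control region.

The control region (CR, D-loop) of fish mitogenomes carries short conserved
landmarks — termination-associated sequences (TAS), conserved sequence blocks
(CSB-D, -I, -II, -III), a T-homopolymer — and, inside the WANCY tRNA cluster,
the teleost light-strand-origin motif 5'-GCGGG-3'.  These are located here with
a small degenerate-pattern engine: a pattern is an ordered list of literal
k-mers, alternations of literals, and bounded wildcard gaps, written e.g.
``TAS = ATG N(8,9) CAT|TAT``.

Ns in the *scanned sequence* match only wildcard gaps, never literals.  All
overlapping matches are reported; at a given start, a variable-gap pattern
collapses to its shortest match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Literal:
    seq: str


@dataclass(frozen=True)
class Alternation:
    options: tuple[str, ...]


@dataclass(frozen=True)
class Gap:
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_len <= self.max_len):
            raise ValueError(f"bad gap bounds ({self.min_len},{self.max_len})")


Element = Literal | Alternation | Gap


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate query over DNA."""

    name: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if not any(isinstance(e, (Literal, Alternation)) for e in self.elements):
            raise ValueError("pattern needs at least one non-gap element")

    @property
    def min_length(self) -> int:
        return sum(
            len(e.seq) if isinstance(e, Literal)
            else min(map(len, e.options)) if isinstance(e, Alternation)
            else e.min_len
            for e in self.elements
        )

    @property
    def max_length(self) -> int:
        return sum(
            len(e.seq) if isinstance(e, Literal)
            else max(map(len, e.options)) if isinstance(e, Alternation)
            else e.max_len
            for e in self.elements
        )

    def spec_string(self) -> str:
        parts = []
        for e in self.elements:
            if isinstance(e, Literal):
                parts.append(e.seq)
            elif isinstance(e, Alternation):
                parts.append("|".join(e.options))
            else:
                parts.append(f"N({e.min_len},{e.max_len})")
        return f"{self.name} = " + " ".join(parts)


_GAP_RE = re.compile(r"^N\((\d+)(?:,(\d+))?\)$", re.IGNORECASE)


def parse_pattern(spec: str) -> MotifPattern:
    """Parse ``NAME = ATG N(8,9) CAT|TAT`` into a :class:`MotifPattern`."""
    if "=" not in spec:
        raise ValueError(f"pattern spec needs 'NAME = ...': {spec!r}")
    name, body = spec.split("=", 1)
    elements: list[Element] = []
    for token in body.split():
        m = _GAP_RE.match(token)
        if m:
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            elements.append(Gap(lo, hi))
        elif "|" in token:
            opts = tuple(o.upper() for o in token.split("|") if o)
            elements.append(Alternation(opts))
        else:
            elements.append(Literal(token.upper()))
    return MotifPattern(name=name.strip(), elements=tuple(elements))


def builtin_patterns() -> list[MotifPattern]:
    """The standard CR/OL queries used for teleost mitogenome landmarks."""
    specs = [
        "TAS = ATG N(8,9) CAT|TAT",
        "CSB-D = TTC|TTA N(11,11) TTC|CTC",
        "CSB-I = ATA N(15,15) ATA",
        "CSB-II = AAACCCC N(4,4) CCCCC",
        "CSB-III = AAACCCCC",
        "OL-motif = GCGGG",
    ]
    return [parse_pattern(s) for s in specs]


@dataclass(frozen=True)
class MotifHit:
    """One located motif instance (1-based inclusive coordinates)."""

    pattern: str
    start: int
    end: int
    matched_seq: str
    strand: str = "+"


def _match_at(seq: str, pos: int, elements: tuple[Element, ...],
              idx: int) -> int | None:
    """Return end offset (0-based exclusive) of the shortest match at pos."""
    if idx == len(elements):
        return pos
    e = elements[idx]
    if isinstance(e, Literal):
        if seq.startswith(e.seq, pos):
            return _match_at(seq, pos + len(e.seq), elements, idx + 1)
        return None
    if isinstance(e, Alternation):
        for opt in sorted(e.options, key=len):
            if seq.startswith(opt, pos):
                r = _match_at(seq, pos + len(opt), elements, idx + 1)
                if r is not None:
                    return r
        return None
    # Gap: shortest expansion first (collapse rule); gap bases may be any of
    # A/C/G/T/N — only literals refuse N.
    for glen in range(e.min_len, e.max_len + 1):
        if pos + glen > len(seq):
            break
        r = _match_at(seq, pos + glen, elements, idx + 1)
        if r is not None:
            return r
    return None


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def scan(seq: str, pattern: MotifPattern, both_strands: bool = False) -> list[MotifHit]:
    """All (overlapping) matches of ``pattern`` in ``seq``, leftmost first."""
    if not pattern.elements:
        raise ValueError("empty pattern")
    s = seq.upper()
    hits: list[MotifHit] = []
    for pos in range(len(s) - pattern.min_length + 1):
        end = _match_at(s, pos, pattern.elements, 0)
        if end is not None:
            hits.append(MotifHit(pattern.name, pos + 1, end, s[pos:end]))
    if both_strands:
        rc = s.translate(_REVCOMP)[::-1]
        n = len(s)
        for pos in range(len(rc) - pattern.min_length + 1):
            end = _match_at(rc, pos, pattern.elements, 0)
            if end is not None:
                hits.append(
                    MotifHit(pattern.name, n - end + 1, n - pos,
                             rc[pos:end], strand="-")
                )
        hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def find_t_homopolymer(seq: str, min_len: int = 6) -> list[tuple[int, int]]:
    """Maximal runs of T of length >= min_len, as (1-based start, length)."""
    return [
        (m.start() + 1, m.end() - m.start())
        for m in re.finditer("T{%d,}" % min_len, seq.upper())
    ]


@dataclass
class CRAnnotation:
    """Located CR landmarks plus the inferred VR3 start.

    ``vr3_start`` is the position immediately after the last CSB-III hit (the
    variable region carrying the tandem repeats begins there); ``None`` when no
    CSB-III was found.
    """

    hits: dict[str, list[MotifHit]] = field(default_factory=dict)
    t_runs: list[tuple[int, int]] = field(default_factory=list)
    vr3_start: int | None = None

    def counts(self) -> dict[str, int]:
        out = {name: len(h) for name, h in self.hits.items()}
        out["T-homopolymer"] = len(self.t_runs)
        return out

    def is_empty(self) -> bool:
        return not self.t_runs and all(not h for h in self.hits.values())


def annotate_cr(cr_seq: str,
                patterns: list[MotifPattern] | None = None,
                t_run_min: int = 6,
                both_strands: bool = False) -> CRAnnotation:
    """Scan a control-region sequence for every built-in landmark."""
    if not cr_seq:
        raise ValueError("empty sequence")
    pats = patterns if patterns is not None else builtin_patterns()
    hits = {p.name: scan(cr_seq, p, both_strands=both_strands) for p in pats}
    t_runs = find_t_homopolymer(cr_seq, min_len=t_run_min)
    vr3 = None
    if hits.get("CSB-III"):
        vr3 = hits["CSB-III"][-1].end + 1
    return CRAnnotation(hits=hits, t_runs=t_runs, vr3_start=vr3)


__all__ = [
    "Literal", "Alternation", "Gap", "MotifPattern", "MotifHit", "CRAnnotation",
    "parse_pattern", "builtin_patterns", "scan", "find_t_homopolymer",
    "annotate_cr",
]
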