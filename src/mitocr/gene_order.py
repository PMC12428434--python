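"""Mitogenome gene-order signatures and rearrangement classification.

The typical vertebrate mitogenome carries 37 genes (13 protein-coding genes,
22 tRNAs, 2 rRNAs) plus the control region and the light-strand origin, in a
deeply conserved circular order.  A genome's *signature* is that circular
token string rotated to a fixed anchor (tRNA-Phe, else 12S).  Differences
between two signatures are classified into the event vocabulary used for
comparative mitogenomics:

- duplication / loss: gene-copy-number differences;
- inversion: a shared gene switching its encoded strand;
- reshuffling: a gene displaced within its local neighbourhood (<= 3
  positions by default — the scale of the IQM / WANCY / His-Ser-Leu tRNA
  cluster swaps);
- translocation: displacement beyond that neighbourhood.

The decomposition is greedy and deterministic (duplications, then inversions,
then moves); it makes no minimal-event-count claim.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .genome_model import MitogenomeRecord, feature_length

#: tRNA one-letter codes keyed by amino-acid name fragment in feature names.
_TRNA_CODES = {
    "phe": "F", "val": "V", "leu(uur)": "L1", "ile": "I", "gln": "Q",
    "met": "M", "trp": "W", "ala": "A", "asn": "N", "cys": "C", "tyr": "Y",
    "ser(ucn)": "S2", "asp": "D", "lys": "K", "gly": "G", "arg": "R",
    "his": "H", "ser(agy)": "S1", "leu(cun)": "L2", "glu": "E", "thr": "T",
    "pro": "P",
}

#: Canonical vertebrate order: 37 genes + CR + OL = 39 tokens, anchored at F.
#: Strands as in teleost mitogenomes (ND6 and eight tRNAs plus OL on the
#: light strand).
CANONICAL_ORDER: tuple[tuple[str, str], ...] = (
    ("F", "+"), ("12S", "+"), ("V", "+"), ("16S", "+"), ("L1", "+"),
    ("ND1", "+"), ("I", "+"), ("Q", "-"), ("M", "+"), ("ND2", "+"),
    ("W", "+"), ("A", "-"), ("N", "-"), ("OL", "-"), ("C", "-"), ("Y", "-"),
    ("COX1", "+"), ("S2", "-"), ("D", "+"), ("COX2", "+"), ("K", "+"),
    ("ATP8", "+"), ("ATP6", "+"), ("COX3", "+"), ("G", "+"), ("ND3", "+"),
    ("R", "+"), ("ND4L", "+"), ("ND4", "+"), ("H", "+"), ("S1", "+"),
    ("L2", "+"), ("ND5", "+"), ("ND6", "-"), ("E", "-"), ("CYTB", "+"),
    ("T", "+"), ("P", "-"), ("CR", "+"),
)

GENE_VOCABULARY = frozenset(
    [sym for sym, _ in CANONICAL_ORDER] + ["NC"]
)


@dataclass(frozen=True)
class GeneToken:
    symbol: str
    strand: str
    occurrence: int = 1

    def __post_init__(self) -> None:
        base = self.symbol.split("#")[0]
        if base not in GENE_VOCABULARY:
            raise ValueError(f"unknown gene symbol {self.symbol!r}")

    def __str__(self) -> str:
        s = self.symbol if self.occurrence == 1 else f"{self.symbol}#{self.occurrence}"
        return s if self.strand == "+" else f"-{s}"


@dataclass(frozen=True)
class GeneOrderSignature:
    """Circular gene order normalised to start at tRNA-Phe (else 12S)."""

    tokens: tuple[GeneToken, ...]

    @property
    def anchor(self) -> GeneToken:
        return self.tokens[0]

    def __str__(self) -> str:
        return " ".join(str(t) for t in self.tokens)

    def symbols(self) -> tuple[str, ...]:
        return tuple(t.symbol for t in self.tokens)


def _normalize(pairs: Sequence[tuple[str, str]]) -> GeneOrderSignature:
    syms = [p[0] for p in pairs]
    if "F" in syms:
        k = syms.index("F")
    elif "12S" in syms:
        k = syms.index("12S")
    else:
        raise ValueError("no anchor gene (tRNA-Phe or 12S) present")
    rotated = list(pairs[k:]) + list(pairs[:k])
    seen: Counter = Counter()
    tokens = []
    for sym, strand in rotated:
        seen[sym] += 1
        tokens.append(GeneToken(symbol=sym, strand=strand, occurrence=seen[sym]))
    return GeneOrderSignature(tokens=tuple(tokens))


def canonical_vertebrate_order() -> GeneOrderSignature:
    """The typical vertebrate mitogenome gene order as a signature."""
    return _normalize(CANONICAL_ORDER)


def symbol_for_feature_name(name: str) -> str:
    """Map a feature-table gene name to its signature symbol."""
    base = name.split("#")[0].strip()
    low = base.lower()
    if low.startswith("trna") or low.startswith("trn"):
        frag = low.replace("trna", "").replace("trn", "").strip("-_ ^")
        frag = frag.replace("serr", "ser")  # tolerate table typos
        if frag in _TRNA_CODES:
            return _TRNA_CODES[frag]
        for key, code in _TRNA_CODES.items():
            if frag.startswith(key.split("(")[0]) and "(" not in key:
                return code
        raise ValueError(f"unrecognised tRNA name {name!r}")
    if "12s" in low:
        return "12S"
    if "16s" in low:
        return "16S"
    if low.startswith("control") or low in ("cr", "d-loop", "dloop"):
        return "CR"
    if low.startswith("ol"):
        return "OL"
    if low.startswith("nc"):
        return "NC"
    return base.upper()


def signature_of(rec: MitogenomeRecord, min_nc_length: int = 30) -> GeneOrderSignature:
    """Gene-order signature of a record; NC spacers < ``min_nc_length`` are
    ignored (they are alignment noise, not order-bearing tokens)."""
    pairs = []
    for f in rec.features:
        sym = symbol_for_feature_name(f.name)
        if sym == "NC" and feature_length(f, rec.length) < min_nc_length:
            continue
        pairs.append((sym, f.strand))
    if not pairs:
        raise ValueError("record has no features")
    return _normalize(pairs)


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str  # reshuffling | translocation | duplication | inversion | loss
    genes: tuple[str, ...]
    detail: str

    def __str__(self) -> str:
        return f"{self.kind}({','.join(self.genes)}): {self.detail}"


def _lcs_keep(a: list, b: list) -> set:
    """Elements of ``a`` kept by a longest common subsequence with ``b``."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i][j] = dp[i + 1][j + 1] + 1
            else:
                dp[i][j] = max(dp[i + 1][j], dp[i][j + 1])
    keep = set()
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            keep.add(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def diff_orders(
    a: GeneOrderSignature,
    b: GeneOrderSignature,
    reshuffle_window: int = 3,
) -> list[RearrangementEvent]:
    """Classify the differences of signature ``b`` relative to ``a``.

    Stages: copy-number differences (duplication/loss), strand flips
    (inversion), then the residual permutation gene-by-gene — a displaced gene
    within ``reshuffle_window`` positions of its original place is a
    reshuffling, anything farther a translocation.
    """
    events: list[RearrangementEvent] = []
    count_a = Counter(t.symbol for t in a.tokens)
    count_b = Counter(t.symbol for t in b.tokens)

    unstable: set[str] = set()
    for sym in sorted(set(count_a) | set(count_b)):
        ca, cb = count_a.get(sym, 0), count_b.get(sym, 0)
        if cb > ca:
            events.append(RearrangementEvent(
                "duplication", (sym,),
                f"{sym} present {cb}x vs {ca}x"))
            unstable.add(sym)
        elif cb < ca:
            events.append(RearrangementEvent(
                "loss", (sym,), f"{sym} present {cb}x vs {ca}x"))
            unstable.add(sym)

    strand_a = {(t.symbol, t.occurrence): t.strand for t in a.tokens}
    strand_b = {(t.symbol, t.occurrence): t.strand for t in b.tokens}
    for key in sorted(set(strand_a) & set(strand_b)):
        if key[0] in unstable:
            continue
        if strand_a[key] != strand_b[key]:
            events.append(RearrangementEvent(
                "inversion", (key[0],),
                f"{key[0]} switched strand {strand_a[key]}→{strand_b[key]}"))
            unstable.add(key[0])

    seq_a = [(t.symbol, t.occurrence) for t in a.tokens if t.symbol not in unstable]
    seq_b = [(t.symbol, t.occurrence) for t in b.tokens if t.symbol not in unstable]
    keep = _lcs_keep(seq_a, seq_b)
    pos_a = {g: i for i, g in enumerate(seq_a)}
    pos_b = {g: i for i, g in enumerate(seq_b)}
    n = max(len(seq_a), 1)
    for g in seq_a:
        if g in keep:
            continue
        i, j = pos_a[g], pos_b[g]
        disp = min(abs(i - j), n - abs(i - j))  # circular displacement
        genes = [g[0]]
        if disp == 1 and 0 <= j < len(seq_a):
            partner = seq_a[j][0]
            if partner != g[0]:
                genes.append(partner)
        kind = "reshuffling" if disp <= reshuffle_window else "translocation"
        events.append(RearrangementEvent(
            kind, tuple(genes),
            f"{g[0]} moved from position {i + 1} to {j + 1} (displacement {disp})"))
    return events


def group_arrangement_types(
    records: Sequence[MitogenomeRecord | GeneOrderSignature],
) -> list[tuple[str, GeneOrderSignature, list[str]]]:
    """Group genomes by identical signature; labels I, II, ... by first
    occurrence."""
    if not records:
        raise ValueError("no records")
    groups: dict[tuple, tuple[GeneOrderSignature, list[str]]] = {}
    order: list[tuple] = []
    for idx, rec in enumerate(records):
        if isinstance(rec, GeneOrderSignature):
            sig, rid = rec, f"genome{idx + 1}"
        else:
            sig, rid = signature_of(rec), rec.id
        key = tuple((t.symbol, t.strand, t.occurrence) for t in sig.tokens)
        if key not in groups:
            groups[key] = (sig, [])
            order.append(key)
        groups[key][1].append(rid)
    return [
        (_roman(i + 1), groups[key][0], groups[key][1])
        for i, key in enumerate(order)
    ]


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


__all__ = [
    "GeneToken", "GeneOrderSignature", "RearrangementEvent",
    "CANONICAL_ORDER", "GENE_VOCABULARY",
    "canonical_vertebrate_order", "symbol_for_feature_name", "signature_of",
    "diff_orders", "group_arrangement_types",
]
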