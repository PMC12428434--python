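"""Composition, skews, codon inventories and RSCU under the vertebrate
mitochondrial genetic code.

Skews follow the standard strand-asymmetry definitions
AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C).  The vertebrate
mitochondrial code (NCBI translation table 2) is the only built-in code:
AGA/AGG are stops, ATA is Met, TGA is Trp.  Mitochondrial open reading frames
frequently end in incomplete stop codons (T-- or TA-) completed by
polyadenylation; an incomplete tail counts as one codon in ``n_codons``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .genome_model import MitogenomeRecord, extract_feature_sequence

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]

#: codon → amino acid (one-letter), with '*' for stops; vertebrate mito code.
CODON_TO_AA: dict[str, str] = dict(_TABLE2.forward_table)
for _stop in _TABLE2.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE2.stop_codons)
SENSE_CODONS = tuple(sorted(c for c, a in CODON_TO_AA.items() if a != "*"))

#: amino acid → synonymous codon family (sense codons only), table 2.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_c], ())
for _aa in SYNONYMOUS_FAMILIES:
    SYNONYMOUS_FAMILIES[_aa] = tuple(
        c for c in SENSE_CODONS if CODON_TO_AA[c] == _aa
    )


@dataclass(frozen=True)
class CompositionStats:
    """Base composition and strand skews of one sequence (N excluded)."""

    length: int
    n_count: int
    pct_A: float
    pct_T: float
    pct_C: float
    pct_G: float
    pct_AT: float
    at_skew: float | None
    gc_skew: float | None


def composition(seq: str) -> CompositionStats:
    """Composition percentages and skews; N bases excluded from denominators.

    A skew whose denominator is zero (A+T = 0 or G+C = 0) is ``None``, never
    coerced to 0.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    counts = Counter(s)
    a, t, c, g = counts["A"], counts["T"], counts["C"], counts["G"]
    n = counts["N"]
    denom = a + t + c + g
    if denom == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionStats(
        length=len(s),
        n_count=n,
        pct_A=100 * a / denom,
        pct_T=100 * t / denom,
        pct_C=100 * c / denom,
        pct_G=100 * g / denom,
        pct_AT=100 * (a + t) / denom,
        at_skew=at_skew,
        gc_skew=gc_skew,
    )


@dataclass(frozen=True)
class CodonInventory:
    """Ordered codon decomposition of one CDS, with the incomplete tail."""

    codons: tuple[str, ...]
    incomplete_tail: str

    @property
    def counts(self) -> Counter:
        return Counter(self.codons)

    @property
    def n_codons(self) -> int:
        return len(self.codons) + (1 if self.incomplete_tail else 0)


def split_codons(cds: str) -> CodonInventory:
    """Split a reading-frame-1 CDS into complete triplets plus a 0–2 base tail."""
    s = cds.upper()
    k = len(s) // 3
    return CodonInventory(
        codons=tuple(s[3 * i: 3 * i + 3] for i in range(k)),
        incomplete_tail=s[3 * k:],
    )


def total_codons(genes: Iterable) -> int:
    """Total codon count over protein-coding genes: ceil(length/3) per gene.

    Accepts gene lengths in bp, or :class:`~mitocr.genome_model.Feature`
    objects (which must be PCGs).
    """
    total = 0
    for g in genes:
        if hasattr(g, "ftype"):
            if g.ftype != "PCG":
                raise ValueError(f"{g.name} is not a protein-coding gene")
            n = g.end - g.start + 1
        else:
            n = int(g)
        total += -(-n // 3)
    return total


def classify_start_stop(inv: CodonInventory) -> tuple[str, str]:
    """Start token (first codon) and stop token of a CDS inventory.

    Complete CDS → the final codon (TAA/TAG/AGA/AGG, or the raw codon if it is
    not a stop).  Incomplete CDS → ``T--``/``TA-``/``AG-`` for the recognised
    truncated stops, else the raw tail padded with dashes.
    """
    if not inv.codons:
        raise ValueError("empty codon inventory")
    start = inv.codons[0]
    tail = inv.incomplete_tail
    if not tail:
        return start, inv.codons[-1]
    if tail == "T":
        return start, "T--"
    if tail == "TA":
        return start, "TA-"
    if tail == "AG":
        return start, "AG-"
    return start, tail + "-" * (3 - len(tail))


def amino_acid_distribution(
    inventories: Iterable[CodonInventory],
) -> tuple[Counter, int, int]:
    """Translate complete codons under table 2.

    Returns ``(aa_counts, stop_count, skipped)``: amino-acid counts, stops
    tallied separately, and codons skipped for containing non-ACGT bases.
    """
    aa: Counter = Counter()
    stops = 0
    skipped = 0
    for inv in inventories:
        for codon in inv.codons:
            res = CODON_TO_AA.get(codon)
            if res is None:
                skipped += 1
            elif res == "*":
                stops += 1
            else:
                aa[res] += 1
    return aa, stops, skipped


@dataclass(frozen=True)
class RSCUTable:
    """Relative synonymous codon usage: count × family size / family total."""

    values: dict[str, float | None]
    family: dict[str, tuple[str, ...]]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name="RSCU")


def rscu(inventory: CodonInventory | Mapping[str, int],
         include_stops: bool = False) -> RSCUTable:
    """RSCU per codon.

    Within a family with nonzero total the values average to exactly 1; codons
    of an entirely unused family are ``None`` (0/0 is not a preference).  Stop
    codons are excluded unless ``include_stops`` (they are not synonymous
    choices of an amino acid, but their raw usage is sometimes reported).
    """
    counts = inventory.counts if isinstance(inventory, CodonInventory) else Counter(inventory)
    families = dict(SYNONYMOUS_FAMILIES)
    if include_stops:
        families["*"] = tuple(sorted(STOP_CODONS))
    values: dict[str, float | None] = {}
    for codons in families.values():
        total = sum(counts.get(c, 0) for c in codons)
        size = len(codons)
        for c in codons:
            values[c] = None if total == 0 else counts.get(c, 0) * size / total
    return RSCUTable(values=values, family=families)


@dataclass
class StartStopCensus:
    """Start/stop codon usage per gene and overall, across genomes."""

    starts: pd.DataFrame  # genes × codon → count
    stops: pd.DataFrame
    start_pct: pd.Series  # overall percentage per codon
    stop_pct: pd.Series


def start_stop_census(records: Sequence[MitogenomeRecord]) -> StartStopCensus:
    """Tabulate start/stop codons of every PCG across genomes (pie-chart shape)."""
    start_rows: dict[str, Counter] = {}
    stop_rows: dict[str, Counter] = {}
    for rec in records:
        if rec.sequence is None:
            raise ValueError(f"record {rec.id} lacks a sequence")
        for f in rec.features_of_type("PCG"):
            inv = split_codons(extract_feature_sequence(rec, f))
            start, stop = classify_start_stop(inv)
            gene = f.name.split("#")[0]
            start_rows.setdefault(gene, Counter())[start] += 1
            stop_rows.setdefault(gene, Counter())[stop] += 1
    starts = pd.DataFrame(start_rows).T.fillna(0).astype(int)
    stops = pd.DataFrame(stop_rows).T.fillna(0).astype(int)
    start_tot = starts.sum(axis=0)
    stop_tot = stops.sum(axis=0)
    return StartStopCensus(
        starts=starts.sort_index(),
        stops=stops.sort_index(),
        start_pct=100 * start_tot / start_tot.sum(),
        stop_pct=100 * stop_tot / stop_tot.sum(),
    )


def composition_table(rec: MitogenomeRecord) -> pd.DataFrame:
    """Per-class composition rows (PCGs, tRNA, rRNA, CR, Genome).

    Requires a sequence; per-class rows concatenate the class's feature
    sequences in reading orientation.
    """
    if rec.sequence is None:
        raise ValueError("composition_table requires a sequence")
    rows = {}
    for label, ftype in (("PCGs", "PCG"), ("tRNA", "tRNA"),
                         ("rRNA", "rRNA"), ("CR", "CR")):
        feats = rec.features_of_type(ftype)
        if not feats:
            continue
        seq = "".join(extract_feature_sequence(rec, f) for f in feats)
        rows[label] = composition(seq)
    rows["Genome"] = composition(rec.sequence)
    return pd.DataFrame(
        {
            label: {
                "Length": c.length,
                "T%": c.pct_T, "C%": c.pct_C, "A%": c.pct_A, "G%": c.pct_G,
                "AT%": c.pct_AT, "AT-skew": c.at_skew, "GC-skew": c.gc_skew,
            }
            for label, c in rows.items()
        }
    ).T


__all__ = [
    "CompositionStats", "CodonInventory", "RSCUTable", "StartStopCensus",
    "CODON_TO_AA", "STOP_CODONS", "SENSE_CODONS", "SYNONYMOUS_FAMILIES",
    "composition", "split_codons", "total_codons", "classify_start_stop",
    "amino_acid_distribution", "rscu", "start_stop_census", "composition_table",
]
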