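"""Data model and I/O for mitogenomes and their feature tables.

Coordinates are 1-based and inclusive at every external interface, matching the
conventions of published mitogenome feature tables.  A feature table is a TSV
with columns ``Gene, Strand, Location, Size, Anticodon, StartCodon, StopCodon,
Intergenics``; ``Location`` is ``start–end`` (en-dash or hyphen, thousands
separators tolerated).  The ``Size`` and ``Intergenics`` columns are advisory:
coordinates are authoritative, and mismatches raise :class:`FeatureTableWarning`
rather than errors, because published tables are not always internally
consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "CR", "OL", "NC")

#: Incomplete stop-codon tokens (completed by post-transcriptional polyadenylation).
INCOMPLETE_STOPS = ("TA-", "T--", "AG-")


class FeatureTableWarning(UserWarning):
    """A feature table's advisory columns disagree with its coordinates."""


@dataclass(frozen=True)
class Feature:
    """One annotated element of a mitogenome (gene, rRNA, tRNA or noncoding)."""

    name: str
    ftype: str
    strand: str
    start: int
    end: int
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"1-based start must be >= 1, got {self.start}")
        if self.end < self.start and not self.wraps_origin:
            raise ValueError(
                f"feature {self.name}: end {self.end} < start {self.start} "
                "without wraps_origin"
            )


@dataclass
class MitogenomeRecord:
    """A mitogenome: optional H-strand sequence plus an ordered feature list."""

    id: str
    sequence: str | None = None
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            n = len(self.sequence)
            for f in self.features:
                if f.start > n or f.end > n:
                    raise ValueError(
                        f"feature {f.name} exceeds sequence length {n}"
                    )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    @property
    def length(self) -> int:
        """Genome length: sequence length, else the maximum end coordinate."""
        if self.sequence is not None:
            return len(self.sequence)
        if not self.features:
            raise ValueError("record has neither sequence nor features")
        return max(f.end for f in self.features)

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    def get_feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# feature-table TSV

_DASHES = "–—−"  # en dash, em dash, minus sign


def _clean_int(token: str) -> int:
    token = token.strip().replace(",", "").replace(" ", "").replace(" ", "")
    for d in _DASHES:
        token = token.replace(d, "-")
    return int(token)


def _parse_location(token: str) -> tuple[int, int]:
    t = token.strip().replace(",", "").replace(" ", "")
    for d in _DASHES:
        t = t.replace(d, "-")
    parts = [p for p in t.split("-") if p != ""]
    if len(parts) != 2:
        raise ValueError(f"malformed Location {token!r}")
    return int(parts[0]), int(parts[1])


def infer_feature_type(name: str) -> str:
    low = name.strip().lower()
    if low.startswith("trna") or low.startswith("trn"):
        return "tRNA"
    if "rrna" in low or low in ("12s", "16s"):
        return "rRNA"
    if low.startswith("control") or low in ("cr", "d-loop", "dloop"):
        return "CR"
    if low == "ol" or low.startswith("ol"):
        return "OL"
    if low == "nc" or low.startswith("nc"):
        return "NC"
    return "PCG"


def read_feature_table(path: str | Path) -> MitogenomeRecord:
    """Read a Table-1-dialect feature TSV into a :class:`MitogenomeRecord`.

    Advisory-column checks: ``Size`` is compared with ``end - start + 1`` and
    ``Intergenics`` with the computed gap to the next row; any mismatch emits a
    :class:`FeatureTableWarning` and the coordinate-derived value wins.
    Duplicate gene names are disambiguated with ``#2``-style suffixes.
    """
    path = Path(path)
    rows: list[dict[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        cols = [c.strip().lower() for c in header]
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            vals = line.rstrip("\r\n").split("\t")
            row = {cols[i]: vals[i].strip() if i < len(vals) else ""
                   for i in range(len(cols))}
            row["__line"] = str(lineno)
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty feature table")

    features: list[Feature] = []
    printed_gaps: list[int | None] = []
    seen: dict[str, int] = {}
    for row in rows:
        name = row.get("gene", "")
        if not name:
            raise ValueError(f"{path} line {row['__line']}: missing gene name")
        strand = row.get("strand", "+")
        for d in _DASHES:
            strand = strand.replace(d, "-")
        if strand not in ("+", "-"):
            raise ValueError(f"{path} line {row['__line']}: bad strand {strand!r}")
        start, end = _parse_location(row.get("location", ""))
        if name in seen:
            seen[name] += 1
            warnings.warn(
                f"duplicate gene name {name!r}; renamed {name}#{seen[name]}",
                FeatureTableWarning,
                stacklevel=2,
            )
            name = f"{name}#{seen[name]}"
        else:
            seen[name] = 1
        size_tok = row.get("size", "")
        if size_tok:
            printed = _clean_int(size_tok)
            computed = end - start + 1
            if printed != computed:
                warnings.warn(
                    f"{name}: printed Size {printed} != end-start+1 = {computed}; "
                    "coordinates win",
                    FeatureTableWarning,
                    stacklevel=2,
                )
        gap_tok = row.get("intergenics", row.get("intergenicslength", ""))
        printed_gaps.append(_clean_int(gap_tok) if gap_tok not in ("", "-", "–") else None)
        ftype = infer_feature_type(name)
        features.append(
            Feature(
                name=name,
                ftype=ftype,
                strand=strand,
                start=start,
                end=end,
                anticodon=row.get("anticodon") or None,
                start_codon=row.get("startcodon") or None,
                stop_codon=row.get("stopcodon") or None,
            )
        )

    for i in range(len(features) - 1):
        printed = printed_gaps[i]
        if printed is None:
            continue
        computed = intergenic_gap(features[i], features[i + 1])
        if printed != computed:
            warnings.warn(
                f"{features[i].name}→{features[i + 1].name}: printed Intergenics "
                f"{printed} != computed {computed}; computed value kept",
                FeatureTableWarning,
                stacklevel=2,
            )

    return MitogenomeRecord(id=path.stem, sequence=None, features=features)


def load_reference_feature_table() -> MitogenomeRecord:
    """The packaged *Suruga fundicola* PV067722 feature table."""
    ref = resources.files("mitocr") / "data" / "sfundicola_pv067722_features.tsv"
    with resources.as_file(ref) as p:
        rec = read_feature_table(p)
    rec.id = "PV067722"
    return rec


# ---------------------------------------------------------------------------
# coordinate arithmetic

def feature_length(f: Feature, genome_length: int | None = None) -> int:
    """Length in bp; origin-wrapping features need ``genome_length``."""
    if f.wraps_origin:
        if genome_length is None:
            raise ValueError(f"{f.name} wraps the origin; genome_length required")
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


def intergenic_gap(prev: Feature, nxt: Feature) -> int:
    """Gap in bp between consecutive features; negative means overlap."""
    return nxt.start - prev.end - 1


def extract_feature_sequence(rec: MitogenomeRecord, f: Feature) -> str:
    """Feature sequence in reading orientation (minus strand reverse-complemented)."""
    if rec.sequence is None:
        raise ValueError(f"record {rec.id} has no sequence")
    n = len(rec.sequence)
    if f.wraps_origin or f.end < f.start:
        if not rec.circular:
            raise ValueError(f"{f.name} wraps origin of a non-circular record")
        sub = rec.sequence[f.start - 1:] + rec.sequence[: f.end]
    else:
        if f.end > n:
            raise ValueError(f"{f.name} exceeds sequence length {n}")
        sub = rec.sequence[f.start - 1: f.end]
    if f.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def partition_totals(rec: MitogenomeRecord) -> dict[str, int]:
    """Per-class bp totals plus ``genome``.

    Overlapping features are counted per-feature (not deduplicated), matching
    how published per-class totals are tallied from table columns.
    """
    if not rec.features:
        raise ValueError("empty feature list")
    totals: dict[str, int] = {t: 0 for t in FEATURE_TYPES}
    glen = rec.length
    for f in rec.features:
        totals[f.ftype] += feature_length(f, genome_length=glen)
    totals["genome"] = glen
    return totals


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-FASTA → ordered mapping id → uppercase sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path, wrap: int = 70) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    seqrecs = [SeqRecord(Seq(s), id=i, description="") for i, s in items]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(seqrecs)


__all__ = [
    "Feature",
    "MitogenomeRecord",
    "FeatureTableWarning",
    "INCOMPLETE_STOPS",
    "read_feature_table",
    "load_reference_feature_table",
    "infer_feature_type",
    "feature_length",
    "intergenic_gap",
    "extract_feature_sequence",
    "partition_totals",
    "read_fasta",
    "write_fasta",
    "replace",
]
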