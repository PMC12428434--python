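"""Tandem-repeat arrays in the control region: detection, unit typing, array
patterns, and the cohort-level recombination-evidence rule.

The 3' variable region (VR3) of the control region carries long tandem repeats
(~107 bp units in the motivating system).  Distinct unit sequences within a
cohort are *types* (T1, T2, ...; T1 is the modal unit), and each individual's
array is summarised as a run-length *pattern* over type labels (P1, P2, ...).
An array made of a single type is *pure* — compatible with slipped-strand
mispairing, the default mechanism for homogeneous repeat expansion.  A
heterogeneous array whose constituent types each also occur somewhere in the
cohort as a pure array is flagged *recombination-supported*: producing such a
mixed array by slippage alone would require both donor haplotypes in the same
molecule, so insertion via recombination between coexisting haplotypes is the
more plausible origin.  Heterogeneous arrays without that support stay
"slippage-or-unknown".

Detection is deliberately simple and fully deterministic: exact k-mer
recurrences seed candidate periods, arrays grow unit-by-unit while each unit
stays above an identity floor against the running majority-rule consensus, and
overlapping candidates are resolved by longest array, then smallest unit, then
leftmost start.  Unit typing is by exact sequence identity — no clustering
threshold — because the types of interest differ at a handful of fixed sites.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from itertools import groupby
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class PartialCopy:
    """A flanking imperfect copy of the repeat unit (not a full copy).

    ``side`` is where the copy sits relative to the array: ``"3'"`` means it
    follows the array and matches a *prefix* of the unit (the common case: a
    truncated terminal copy), ``"5'"`` that it precedes the array and matches a
    unit *suffix*.
    """

    side: str  # "5'" or "3'"
    sequence: str
    matched_len: int


@dataclass(frozen=True)
class RepeatArray:
    """A decomposed tandem array (1-based inclusive coordinates in source)."""

    source_id: str
    start: int
    end: int
    unit_length: int
    units: tuple[str, ...]
    consensus: str
    partial_copy: PartialCopy | None = None

    def __post_init__(self) -> None:
        if any(len(u) != self.unit_length for u in self.units):
            raise ValueError("all units must have length unit_length")
        if len(self.units) < 2:
            raise ValueError("an array needs at least 2 units")

    @property
    def copy_number(self) -> int:
        """Number of complete units (the partial copy is excluded)."""
        return len(self.units)

    def reconstruct(self) -> str:
        """Concatenation of units plus the partial copy at its side."""
        core = "".join(self.units)
        if self.partial_copy is None:
            return core
        if self.partial_copy.side == "5'":
            return self.partial_copy.sequence + core
        return core + self.partial_copy.sequence


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _consensus(units: Sequence[str]) -> str:
    """Per-column majority; ties broken by the earliest unit's base."""
    if len(units) == 1:
        return units[0]
    out = []
    for col in zip(*units):
        counts = Counter(col)
        best = max(counts.values())
        for base in col:  # earliest-unit order
            if counts[base] == best:
                out.append(base)
                break
    return "".join(out)


_BASE_LUT = np.full(256, 4, dtype=np.intp)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i


def _consensus_mismatches(sa: np.ndarray, start0: int, count: int, d: int) -> int:
    """Total mismatches of an array's units against its majority consensus
    (ties to the earliest unit's base, as in :func:`_consensus`)."""
    idx = _BASE_LUT[sa[start0: start0 + count * d]].reshape(count, d)
    cols = np.arange(d)
    cnt = np.zeros((5, d), dtype=np.int32)
    for b in range(5):
        cnt[b] = (idx == b).sum(axis=0)
    maxc = cnt.max(axis=0)
    at_max = cnt[idx, cols[None, :]] == maxc[None, :]
    first = np.argmax(at_max, axis=0)  # earliest unit holding a modal base
    cons = idx[first, cols]
    return int((idx != cons[None, :]).sum())


def _grow_arr(sa: np.ndarray, pos0: int, d: int,
              min_identity: float) -> tuple[int, int]:
    """Grow an array of period d around the unit at 0-based pos0.

    ``sa`` is the sequence as a uint8 array.  The running consensus is
    maintained incrementally (per-column base counts; a column changes only
    when a base strictly outvotes the current consensus base, so ties keep
    the earliest unit's base).  Returns (start, unit count).
    """
    cons = sa[pos0: pos0 + d].copy()
    counts = np.zeros((d, 5), dtype=np.int32)
    rows = np.arange(d)
    counts[rows, _BASE_LUT[cons]] = 1
    floor = min_identity * d

    def absorb(seg: np.ndarray) -> None:
        idx = _BASE_LUT[seg]
        counts[rows, idx] += 1
        better = counts[rows, idx] > counts[rows, _BASE_LUT[cons]]
        cons[better] = seg[better]

    start, count = pos0, 1
    n = len(sa)
    while True:  # right
        a = start + count * d
        if a + d > n:
            break
        seg = sa[a: a + d]
        if int((seg == cons).sum()) < floor:
            break
        count += 1
        absorb(seg)
    while start - d >= 0:  # left
        seg = sa[start - d: start]
        if int((seg == cons).sum()) < floor:
            break
        count += 1
        start -= d
        absorb(seg)
    return start, count


def _grow(seq: str, pos0: int, d: int, min_identity: float) -> tuple[int, list[str]]:
    """String-level wrapper over :func:`_grow_arr`."""
    sa = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    start, count = _grow_arr(sa, pos0, d, min_identity)
    return start, [seq[start + i * d: start + (i + 1) * d] for i in range(count)]


def _try_reduce(
    s: str,
    sa: np.ndarray,
    start0: int,
    n_units: int,
    d: int,
    min_unit: int,
    min_copies: int,
    min_identity: float,
) -> tuple[int, int, int] | None:
    """Re-grow an array at the smallest admissible divisor of its period.

    The array is re-cut at each candidate sub-period; if some sub-unit is
    clean (meets the identity floor against the sub-consensus), the array is
    re-grown from it at that period.  Arrays that are not truly periodic at
    the sub-period fail the re-grow and stay as they are.  Returns
    (start, unit count, period) or None.
    """
    span = s[start0: start0 + n_units * d]
    for p in range(min_unit, d):
        if d % p:
            continue
        subs = [span[i * p: (i + 1) * p] for i in range(len(span) // p)]
        cons = _consensus(subs)
        idents = [_identity(u, cons) for u in subs]
        k = max(range(len(subs)), key=lambda i: idents[i])
        if idents[k] < min_identity:
            continue
        ns, ncount = _grow_arr(sa, start0 + k * p, p, min_identity)
        if ncount >= min_copies:
            return ns, ncount, p
    return None


def detect_tandem_repeats(
    seq: str,
    source_id: str = "seq",
    min_unit: int = 10,
    max_unit: int = 500,
    min_copies: int = 2,
    min_identity: float = 0.85,
    seed_k: int = 10,
) -> list[RepeatArray]:
    """Find tandem arrays by exact k-mer seeding and consensus extension.

    Candidate periods are distances d in [min_unit, max_unit] between exact
    occurrences of the same k-mer; each candidate grows in both directions
    while every added unit keeps >= ``min_identity`` to the running consensus.
    Overlapping arrays are resolved by longest span, then smallest unit, then
    leftmost start.
    """
    s = seq.upper()
    n = len(s)
    if n < 2 * min_unit:
        return []
    sa = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - seed_k + 1):
        positions[s[i: i + seed_k]].append(i)
    # candidate periods: distances between *consecutive* occurrences of a
    # k-mer (non-consecutive pairs only add harmonics of these)
    candidates: set[tuple[int, int]] = set()
    for plist in positions.values():
        for a, b in zip(plist, plist[1:]):
            if min_unit <= b - a <= max_unit:
                candidates.add((a, b - a))

    built: list[tuple[int, int, int, list[str]]] = []  # (start0, end0, d, units)
    for pos, d in sorted(candidates):
        skip = False
        for bs, be, bd, _ in built:
            if bs <= pos and pos + seed_k <= be and d % bd == 0 and (
                    bd < d or (pos - bs) % d == 0):
                # inside an already-built array: re-growing at the same
                # period and phase is a no-op, and growing at a multiple of
                # the built period only yields a harmonic of it
                skip = True
                break
        if skip:
            continue
        start0, count = _grow_arr(sa, pos, d, min_identity)
        if count < min_copies:
            continue
        # period reduction: an array grown at a multiple of a smaller
        # admissible period, and genuinely periodic at that smaller period,
        # is re-grown there — harmonic periods otherwise absorb noise at the
        # edges because most of their positions match by construction
        reduced = _try_reduce(s, sa, start0, count, d, min_unit, min_copies,
                              min_identity)
        if reduced is not None:
            start0, count, d = reduced
        mism = _consensus_mismatches(sa, start0, count, d)
        span = (start0, start0 + count * d, d, mism)
        if span not in built:
            built.append(span)

    # resolve overlaps: longest span, then smallest unit, then fewest
    # mismatches to the array consensus, then leftmost
    built.sort(key=lambda t: (-(t[1] - t[0]), t[2], t[3], t[0]))
    chosen: list[tuple[int, int, int, int]] = []
    for cand in built:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda t: t[0])
    out = []
    for s0, e0, d, _ in chosen:
        units = [s[s0 + i * d: s0 + (i + 1) * d] for i in range((e0 - s0) // d)]
        out.append(RepeatArray(
            source_id=source_id,
            start=s0 + 1,
            end=e0,
            unit_length=d,
            units=tuple(units),
            consensus=_consensus(units),
        ))
    return out


def detect_partial_copy(
    seq: str,
    array: RepeatArray,
    min_len: int = 20,
    min_identity: float = 0.90,
) -> RepeatArray:
    """Attach a flanking imperfect unit copy to a detected array, if present.

    The 3' flank is compared against unit prefixes, the 5' flank against unit
    suffixes; the longest flank segment of length >= ``min_len`` (and < one
    unit) at >= ``min_identity`` is attached.  The partial copy never counts
    toward the copy number.
    """
    s = seq.upper()
    d = array.unit_length
    best: PartialCopy | None = None
    # 3' side: segment after the array vs consensus prefix
    tail = s[array.end: array.end + d - 1]
    for L in range(len(tail), min_len - 1, -1):
        if _identity(tail[:L], array.consensus[:L]) >= min_identity:
            best = PartialCopy(side="3'", sequence=tail[:L], matched_len=L)
            break
    if best is None:
        head = s[max(0, array.start - d): array.start - 1]
        for L in range(len(head), min_len - 1, -1):
            if _identity(head[-L:], array.consensus[-L:]) >= min_identity:
                best = PartialCopy(side="5'", sequence=head[-L:], matched_len=L)
                break
    if best is None:
        return array
    return replace(array, partial_copy=best)


@dataclass(frozen=True)
class UnitType:
    """A distinct unit sequence, labelled by cohort frequency (T1 = modal)."""

    label: str
    sequence: str
    n_diffs: int
    diff_sites: tuple[tuple[int, str], ...]  # (1-based position, base)


def _rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


def type_units(
    arrays: Sequence[RepeatArray],
    reference_unit: str | None = None,
) -> list[UnitType]:
    """Assign T-labels to the distinct unit sequences of a cohort.

    All arrays must share one unit length.  Unit phase is aligned by the best
    circular rotation of each array against the cohort's modal unit (ties by
    lexicographically smallest rotated consensus, then smallest offset); in
    phase-consistent cohorts this is the identity.  T1 is the modal unit
    (overridable via ``reference_unit``); remaining labels go by descending
    frequency, ties by first occurrence.
    """
    if not arrays:
        raise ValueError("no arrays to type")
    lengths = {a.unit_length for a in arrays}
    if len(lengths) != 1:
        bad = max(arrays, key=lambda a: a.unit_length)
        raise ValueError(
            f"unit length disagreement: array in {bad.source_id} has "
            f"unit_length {bad.unit_length}, cohort has {sorted(lengths)}"
        )
    d = lengths.pop()

    all_units: list[str] = [u for a in arrays for u in a.units]
    counts0 = Counter(all_units)
    best_count = max(counts0.values())
    anchor = next(u for u in all_units if counts0[u] == best_count)

    aligned_units: list[str] = []
    for a in arrays:
        scored = [
            (-sum(x == y for x, y in zip(rot, anchor)), rot, r)
            for r, rot in enumerate(_rotations(a.consensus))
        ]
        _, _, r = min(scored)
        if r == 0:
            aligned_units.extend(a.units)
        else:
            cyc = "".join(a.units)
            aligned_units.extend(
                (cyc + cyc)[i * d + r: (i + 1) * d + r] for i in range(len(a.units))
            )

    freq = Counter(aligned_units)
    order: list[str] = []
    for u in aligned_units:
        if u not in order:
            order.append(u)
    ranked = sorted(order, key=lambda u: (-freq[u], order.index(u)))

    t1 = reference_unit if reference_unit is not None else ranked[0]
    if t1 not in ranked:
        ranked.insert(0, t1)
    else:
        ranked.remove(t1)
        ranked.insert(0, t1)

    types = []
    for i, u in enumerate(ranked, start=1):
        diffs = tuple(
            (pos + 1, b) for pos, (a_, b) in enumerate(zip(t1, u)) if a_ != b
        )
        types.append(UnitType(label=f"T{i}", sequence=u, n_diffs=len(diffs),
                              diff_sites=diffs))
    return types


@dataclass(frozen=True)
class ArrayPattern:
    """Run-length encoding of an array over type labels, e.g. T1*2,T3*2."""

    runs: tuple[tuple[str, int], ...]
    copy_number: int
    is_pure: bool
    label: str | None = None

    def __str__(self) -> str:
        return ",".join(f"{t}*{c}" for t, c in self.runs)


def pattern_of(array: RepeatArray, types: Sequence[UnitType]) -> ArrayPattern:
    """Encode an array as runs of type labels; every unit must match a type."""
    by_seq = {t.sequence: t.label for t in types}
    labels = []
    for u in array.units:
        if u not in by_seq:
            raise ValueError(
                f"unit in {array.source_id} matches no type "
                "(was typing done on a different cohort?)"
            )
        labels.append(by_seq[u])
    runs = tuple((lab, len(list(g))) for lab, g in groupby(labels))
    return ArrayPattern(
        runs=runs,
        copy_number=len(labels),
        is_pure=len({lab for lab, _ in runs}) == 1,
    )


MECHANISM_PURE = "slippage-consistent"
MECHANISM_RECOMBINATION = "recombination-supported"
MECHANISM_UNKNOWN = "slippage-or-unknown"


@dataclass
class CohortSummary:
    """Cohort-level pattern census and mechanism calls."""

    patterns: dict[str, ArrayPattern]  # individual id → labelled pattern
    pattern_census: dict[str, int]  # P-label → count
    copy_number_census: dict[int, int]
    heterogeneous: set[str]  # P-labels
    recombination_supported: set[str]  # P-labels
    mechanism: dict[str, str]  # P-label → mechanism annotation

    @property
    def n_pure_individuals(self) -> int:
        return sum(1 for p in self.patterns.values() if p.is_pure)

    @property
    def n_heterogeneous_individuals(self) -> int:
        return sum(1 for p in self.patterns.values() if not p.is_pure)


def cohort_summary(
    patterns: Mapping[str, ArrayPattern] | Iterable[tuple[str, ArrayPattern]],
) -> CohortSummary:
    """Label patterns P1, P2, ... by first occurrence and apply the
    recombination-evidence rule.

    A heterogeneous pattern is recombination-supported iff every one of its
    constituent types also occurs as a *pure* pattern in at least one other
    individual of the cohort.
    """
    items = list(patterns.items()) if isinstance(patterns, Mapping) else list(patterns)
    if not items:
        raise ValueError("empty cohort")
    label_of: dict[tuple, str] = {}
    labelled: dict[str, ArrayPattern] = {}
    for ind, pat in items:
        key = pat.runs
        if key not in label_of:
            label_of[key] = f"P{len(label_of) + 1}"
        labelled[ind] = replace(pat, label=label_of[key])

    census = Counter(p.label for p in labelled.values())
    cn_census = Counter(p.copy_number for p in labelled.values())

    pure_types = {
        p.runs[0][0] for p in labelled.values() if p.is_pure
    }
    het = {p.label for p in labelled.values() if not p.is_pure}
    supported = set()
    mechanism: dict[str, str] = {}
    for key, lab in label_of.items():
        pat = next(p for p in labelled.values() if p.label == lab)
        if pat.is_pure:
            mechanism[lab] = MECHANISM_PURE
        elif all(t in pure_types for t, _ in pat.runs):
            supported.add(lab)
            mechanism[lab] = MECHANISM_RECOMBINATION
        else:
            mechanism[lab] = MECHANISM_UNKNOWN

    return CohortSummary(
        patterns=labelled,
        pattern_census=dict(census),
        copy_number_census=dict(cn_census),
        heterogeneous=het,
        recombination_supported=supported,
        mechanism=mechanism,
    )


def analyze_cohort(
    sequences: Mapping[str, str],
    min_unit: int = 10,
    max_unit: int = 500,
    min_identity: float = 0.85,
    reference_unit: str | None = None,
) -> tuple[list[UnitType], CohortSummary, dict[str, RepeatArray]]:
    """End-to-end VR3 cohort analysis: detect, attach partials, type, summarise.

    Per individual, the single best (longest) array is used; individuals with
    no detectable array raise, since the cohort question presumes arrays.
    """
    arrays: dict[str, RepeatArray] = {}
    for ind, seq in sequences.items():
        found = detect_tandem_repeats(
            seq, source_id=ind, min_unit=min_unit, max_unit=max_unit,
            min_identity=min_identity,
        )
        if not found:
            raise ValueError(f"no tandem array detected in {ind}")
        arr = max(found, key=lambda a: (a.end - a.start, -a.unit_length))
        arrays[ind] = detect_partial_copy(seq, arr)
    types = type_units(list(arrays.values()), reference_unit=reference_unit)
    pats = {ind: pattern_of(arr, types) for ind, arr in arrays.items()}
    summary = cohort_summary(pats)
    summary.patterns = {
        ind: summary.patterns[ind] for ind in sequences
    }
    return types, summary, arrays


__all__ = [
    "PartialCopy", "RepeatArray", "UnitType", "ArrayPattern", "CohortSummary",
    "MECHANISM_PURE", "MECHANISM_RECOMBINATION", "MECHANISM_UNKNOWN",
    "detect_tandem_repeats", "detect_partial_copy", "type_units", "pattern_of",
    "cohort_summary", "analyze_cohort",
]
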