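"""Seeded generators for synthetic inputs with machine-readable ground truth.

Every generator returns a :class:`TruthBundle` whose ``records`` are the
sequences (FASTA-ready) and whose ``truth`` tables index exactly into them;
regenerating with the same seed is byte-identical.  The generators emulate the
statistical structure the analyses assume:

- control regions: i.i.d. AT-rich background (default base frequencies from a
  teleost control region: A 37.7%, T 28.8%, C 19.3%, G 14.2%) with planted
  TAS/CSB/T-homopolymer instances, and the background *rejection-sampled* so
  that no unplanted motif instance survives — clean negative controls;
- repeat cohorts: 19 individuals by default, ~107 bp units, 8 unit types at
  1–3 substitutions from the base unit, 10 array patterns (5 pure, 5
  two-type heterogeneous), copy numbers 3/4/5/6 distributed 1/12/5/1, a 256 bp
  pre-repeat flank and a 3'-terminal imperfect copy (unit prefix: the 52 bp
  upstream part plus 5 bases of the downstream part);
- gene orders: canonical vertebrate order with planted cluster swaps,
  long-range moves, tRNA duplications, strand flips and OL loss;
- codon sequences: a stationary ancestor and a descendant mutated under an
  accept/reject scheme with nonsynonymous acceptance probability omega and
  transition:transversion weight kappa, run to a target synonymous divergence.

What these do *not* emulate: real phylogenetic correlation structure,
alignment gaps/errors, within-individual heteroplasmy mixtures, or
compositional heterogeneity along the molecule — passing recovery tests here
shows the algorithms are correct on their stated model, not that real data
meet that model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from . import cr_annotation as cra
from .cr_annotation import Alternation, Gap, Literal, MotifPattern
from .evolution import TRANSITIONS, _codon_sites
from .gene_order import CANONICAL_ORDER, GeneOrderSignature, _normalize
from .seq_stats import CODON_TO_AA, SENSE_CODONS, STOP_CODONS

_BASES = "ACGT"

#: Default background base frequencies (A, C, G, T) of a control region.
CR_BACKGROUND = {"A": 0.377, "C": 0.193, "G": 0.142, "T": 0.288}


@dataclass
class TruthBundle:
    """Generated records plus the planted ground truth and provenance."""

    records: dict[str, str]
    truth: dict[str, Any]
    seed: int
    params: dict[str, Any] = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _draw(rng: np.random.Generator, n: int,
          freqs: Mapping[str, float] | None = None) -> str:
    if freqs is None:
        return "".join(rng.choice(list(_BASES), size=n))
    bases = sorted(freqs)
    p = np.array([freqs[b] for b in bases])
    return "".join(rng.choice(bases, size=n, p=p / p.sum()))


# ---------------------------------------------------------------------------
# control regions with planted landmarks

def _instantiate_motif(rng: np.random.Generator, pattern: MotifPattern,
                       freqs: Mapping[str, float]) -> tuple[str, list[bool]]:
    """One concrete instance of a pattern plus a literal-position mask."""
    parts: list[str] = []
    mask: list[bool] = []
    for e in pattern.elements:
        if isinstance(e, Literal):
            parts.append(e.seq)
            mask.extend([True] * len(e.seq))
        elif isinstance(e, Alternation):
            opt = e.options[int(rng.integers(len(e.options)))]
            parts.append(opt)
            mask.extend([True] * len(opt))
        elif isinstance(e, Gap):
            glen = int(rng.integers(e.min_len, e.max_len + 1))
            parts.append(_draw(rng, glen, freqs))
            mask.extend([False] * glen)
    return "".join(parts), mask


def _valid_instance(instance: str, own: MotifPattern,
                    patterns: Sequence[MotifPattern]) -> bool:
    for p in patterns:
        hits = cra.scan(instance, p)
        want = [(1, len(instance))] if p.name == own.name else []
        if [(h.start, h.end) for h in hits] != want:
            return False
    return True


def make_cr(
    seed: int,
    length: int = 1495,
    elements_spec: Mapping[str, int] | None = None,
    t_run_len: int = 8,
    background: Mapping[str, float] | None = None,
    max_rejections: int = 2000,
) -> TruthBundle:
    """A control-region-like sequence with planted landmarks.

    ``elements_spec`` maps built-in pattern names (plus ``"T-homopolymer"``)
    to instance counts; the default mirrors a teleost CR: 3 TAS, 1 CSB-II,
    1 CSB-III, 1 T-homopolymer (and no CSB-D).  The background is re-drawn
    locally until the only motif instances in the sequence are the planted
    ones, so annotation recovers the truth exactly.
    """
    if elements_spec is None:
        elements_spec = {"TAS": 3, "CSB-II": 1, "CSB-III": 1, "T-homopolymer": 1}
    freqs = dict(background or CR_BACKGROUND)
    rng = _rng(seed)
    patterns = {p.name: p for p in cra.builtin_patterns()}
    for name in elements_spec:
        if name != "T-homopolymer" and name not in patterns:
            raise ValueError(f"unknown element {name!r}")

    # build instances
    instances: list[tuple[str, str, list[bool]]] = []  # (name, seq, literal mask)
    for name, count in elements_spec.items():
        for _ in range(int(count)):
            if name == "T-homopolymer":
                instances.append((name, "T" * t_run_len, [True] * t_run_len))
                continue
            pat = patterns[name]
            for _attempt in range(200):
                inst, mask = _instantiate_motif(rng, pat, freqs)
                if _valid_instance(inst, pat, list(patterns.values())):
                    break
            else:
                raise RuntimeError(f"could not instantiate {name}")
            instances.append((name, inst, mask))

    margin = 2
    need = sum(len(i[1]) + margin for i in instances) + margin
    if need > length:
        raise ValueError(f"elements ({need} bp with margins) overflow length {length}")

    # place without overlap (1 bp guard on each side for T-run boundary bases)
    placed: list[tuple[str, int, str, list[bool]]] = []
    occupied: list[tuple[int, int]] = []
    for name, inst, mask in instances:
        for _attempt in range(5000):
            start0 = int(rng.integers(1, length - len(inst) - 1))
            span = (start0 - margin, start0 + len(inst) + margin)
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                occupied.append(span)
                placed.append((name, start0, inst, mask))
                break
        else:
            raise ValueError("could not place elements without overlap")

    seq = list(_draw(rng, length, freqs))
    protected = [False] * length
    for name, start0, inst, mask in placed:
        seq[start0:start0 + len(inst)] = list(inst)
        for k, lit in enumerate(mask):
            if lit:
                protected[start0 + k] = True
        if name == "T-homopolymer":  # keep the run maximal at its coordinates
            for g in (start0 - 1, start0 + len(inst)):
                if 0 <= g < length:
                    seq[g] = "A"
                    protected[g] = True

    planted_hits = {
        name: sorted(
            (s0 + 1, s0 + len(inst))
            for n2, s0, inst, _ in placed if n2 == name
        )
        for name in patterns
    }
    planted_runs = sorted(
        (s0 + 1, len(inst)) for n2, s0, inst, _ in placed
        if n2 == "T-homopolymer"
    )

    # scrub unplanted instances (and repair grazed planted ones) by
    # re-drawing unprotected bases in the offending span
    for _iteration in range(max_rejections):
        s = "".join(seq)
        redo: list[tuple[int, int]] = []
        for name, pat in patterns.items():
            want = planted_hits[name]
            got = [(h.start, h.end) for h in cra.scan(s, pat)]
            redo.extend(h for h in got if h not in want)
            redo.extend(w for w in want if w not in got)
        got_runs = cra.find_t_homopolymer(s, min_len=6)
        redo.extend(
            (st, st + ln - 1) for st, ln in got_runs if (st, ln) not in planted_runs
        )
        if not redo:
            break
        for st, en in redo:
            free = [k for k in range(st - 1, en) if not protected[k]]
            if not free:
                raise RuntimeError("unfixable motif collision with planted elements")
            for k in free:
                seq[k] = _draw(rng, 1, freqs)
    else:
        raise RuntimeError("rejection cap reached; spec may be infeasible")

    truth = {
        "hits": planted_hits,
        "t_runs": planted_runs,
        "elements_spec": dict(elements_spec),
    }
    return TruthBundle(
        records={"cr_synthetic": "".join(seq)},
        truth=truth,
        seed=seed,
        params={"length": length, "t_run_len": t_run_len, "background": freqs},
    )


# ---------------------------------------------------------------------------
# repeat cohorts

#: Default type construction: substitutions from the base unit (T1).
DEFAULT_TYPE_DIFFS = {
    "T1": 0, "T2": 1, "T3": 1, "T4": 3, "T5": 1, "T6": 2, "T7": 1, "T8": 1,
}

#: Default cohort: 19 individuals, 10 patterns (5 pure / 5 heterogeneous),
#: copy numbers 3x1, 4x12, 5x5, 6x1.  The two heterogeneous patterns mixing
#: T1 and T3 are recombination-supported (pure T1 and pure T3 arrays exist
#: elsewhere in the cohort); the other three mix a type never seen pure.
DEFAULT_PATTERN_SPEC: tuple[tuple[str, tuple[tuple[str, int], ...]], ...] = (
    ("S01", (("T1", 2), ("T3", 2))),            # P1, het, supported
    ("S02", (("T1", 4),)),                      # P2, pure T1
    ("S03", (("T1", 5),)),                      # P3, pure T1 (copy 5)
    ("S04", (("T2", 4),)),                      # P4, pure T2
    ("S05", (("T1", 3), ("T4", 1))),            # P5, het, T4 never pure
    ("S06", (("T5", 1), ("T1", 3))),            # P6, het, T5 never pure
    ("S07", (("T3", 4),)),                      # P7, pure T3
    ("S08", (("T6", 6),)),                      # P8, pure T6 (copy 6)
    ("S09", (("T3", 1), ("T1", 3), ("T3", 1))), # P9, het, supported
    ("S10", (("T7", 2), ("T8", 1))),            # P10, het, copy 3
    ("S11", (("T1", 4),)),
    ("S12", (("T1", 4),)),
    ("S13", (("T1", 4),)),
    ("S14", (("T1", 4),)),
    ("S15", (("T1", 4),)),
    ("S16", (("T1", 5),)),
    ("S17", (("T1", 5),)),
    ("S18", (("T1", 5),)),
    ("S19", (("T2", 4),)),
)


def make_repeat_cohort(
    seed: int,
    n: int = 19,
    unit_length: int = 107,
    n_types: int = 8,
    max_diffs: int = 3,
    pattern_spec: Sequence[tuple[str, Sequence[tuple[str, int]]]] | None = None,
    type_diffs: Mapping[str, int] | None = None,
    flank_len: int = 256,
    partial_copy: bool = True,
    upstream_len: int = 52,
    partial_extra: int = 5,
) -> TruthBundle:
    """A VR3-like cohort: flank + tandem units (+ 3' imperfect terminal copy).

    The default spec plants 8 unit types (1–3 substitutions from the base
    unit), 10 array patterns over 19 individuals, and copy numbers 3–6; see
    :data:`DEFAULT_PATTERN_SPEC`.  Truth records type sequences, per-individual
    run lists, copy numbers and array coordinates.
    """
    rng = _rng(seed)
    spec = list(pattern_spec if pattern_spec is not None else DEFAULT_PATTERN_SPEC[:n])
    diffs = dict(type_diffs or DEFAULT_TYPE_DIFFS)
    if max(diffs.values()) > max_diffs:
        raise ValueError("type_diffs exceeds max_diffs")
    used_types = {t for _, runs in spec for t, _ in runs}
    undefined = used_types - set(diffs)
    if undefined:
        raise ValueError(f"pattern uses undefined types {sorted(undefined)}")
    for _, runs in spec:
        if sum(c for _, c in runs) < 2:
            raise ValueError("each individual needs copy number >= 2")

    base = _draw(rng, unit_length)
    # Variant sites go in the central window of the unit, clear of both
    # edges: a difference within the leading (partial-copy-length) bases or
    # the trailing (identity-slack) bases could be rotated out of the array
    # by a phase-shifted but equally good decomposition, making the planted
    # phase non-identifiable.  Central sites keep the truth unique.
    site_lo = (upstream_len + partial_extra) if partial_copy else 2
    site_hi = unit_length - int(round(0.15 * unit_length)) - 2
    if site_hi - site_lo + 1 < 2 * max(diffs.values(), default=1):
        raise ValueError("unit too short for a central variant-site window")
    window = np.arange(site_lo, site_hi + 1)
    type_seqs: dict[str, str] = {}
    taken: set[tuple[int, str]] = set()
    for label in sorted(diffs, key=lambda t: int(t[1:])):
        k = diffs[label]
        if k == 0:
            type_seqs[label] = base
            continue
        for _attempt in range(1000):
            sites = sorted(rng.choice(window, size=k, replace=False).tolist())
            subs = []
            for s in sites:
                alt = _BASES[int(rng.integers(4))]
                while alt == base[s]:
                    alt = _BASES[int(rng.integers(4))]
                subs.append((s, alt))
            if k == 1 and tuple(subs[0]) in taken:
                continue
            variant = list(base)
            for s, alt in subs:
                variant[s] = alt
            vs = "".join(variant)
            if vs not in type_seqs.values():
                break
        else:
            raise ValueError("could not derive distinct type sequences")
        if k == 1:
            taken.add(tuple(subs[0]))
        type_seqs[label] = vs
    if len(set(type_seqs.values())) != len(type_seqs):
        raise ValueError("duplicate type sequences requested")

    records: dict[str, str] = {}
    individuals = {}
    for ind, runs in spec:
        units = [type_seqs[t] for t, c in runs for _ in range(int(c))]
        first, last = units[0], units[-1]
        partial = last[: upstream_len + partial_extra] if partial_copy else ""
        core = "".join(units) + partial
        core_kmers = {core[i:i + 10] for i in range(len(core) - 9)}
        # flank constraints for a clean plant: no duplicated seed 10-mer
        # within itself, no 10-mer shared with the repeat region (either
        # could seed a spurious or harmonically-inflated array), and a final
        # base differing from the unit's final base so the detected array
        # cannot slip one position to the left
        while True:
            flank = _draw(rng, flank_len)
            if flank[-1] == first[-1]:
                continue
            kmers: dict[str, int] = {}
            bad = False
            for i in range(flank_len - 9):
                km = flank[i:i + 10]
                if km in core_kmers or (km in kmers and i - kmers[km] >= 10):
                    bad = True
                    break
                kmers.setdefault(km, i)
            if not bad:
                break
        seq = flank + core
        records[ind] = seq
        individuals[ind] = {
            "runs": [(t, int(c)) for t, c in runs],
            "copy_number": len(units),
            "is_pure": len({t for t, _ in runs}) == 1,
            "array_start": flank_len + 1,
            "array_end": flank_len + len(units) * unit_length,
            "partial_len": len(partial),
        }

    truth = {
        "base_unit": base,
        "type_sequences": type_seqs,
        "type_diffs": diffs,
        "individuals": individuals,
        "n_patterns": len({tuple(runs) for _, runs in spec}),
        "recombination_supported_runs": _supported_runs(spec),
    }
    return TruthBundle(records=records, truth=truth, seed=seed,
                       params={"unit_length": unit_length,
                               "flank_len": flank_len,
                               "partial_copy": partial_copy})


def _supported_runs(spec) -> list[tuple[tuple[str, int], ...]]:
    pure_types = {runs[0][0] for _, runs in spec if len({t for t, _ in runs}) == 1}
    out = []
    for _, runs in spec:
        types = {t for t, _ in runs}
        if len(types) > 1 and types <= pure_types:
            key = tuple((t, int(c)) for t, c in runs)
            if key not in out:
                out.append(key)
    return out


def random_sequence_without_repeats(
    seed: int,
    length: int = 1000,
    min_unit: int = 10,
    max_unit: int = 500,
    seed_k: int = 10,
    max_rejections: int = 10000,
) -> str:
    """Uniform random sequence screened to contain no duplicated k-mer at a
    tandem-admissible distance — a guaranteed negative control for repeat
    detection."""
    rng = _rng(seed)
    for _ in range(max_rejections):
        s = _draw(rng, length)
        pos: dict[str, list[int]] = {}
        ok = True
        for i in range(length - seed_k + 1):
            km = s[i:i + seed_k]
            for j in pos.get(km, ()):
                if min_unit <= i - j <= max_unit:
                    ok = False
                    break
            if not ok:
                break
            pos.setdefault(km, []).append(i)
        if ok:
            return s
    raise RuntimeError("rejection cap reached")


# ---------------------------------------------------------------------------
# gene orders

#: Default 10-genome fixture: canonical x3 plus the classic single events.
DEFAULT_ORDER_EVENTS: tuple[tuple[tuple, ...], ...] = (
    (),
    (),
    (),
    (("swap", "I", "Q"),),
    (("swap", "I", "Q"),),
    (("dup", "F", "CR"),),
    (("move", "H", "L2"),),   # His-Ser-Leu cluster -> Ser-Leu-His
    (("loss", "OL"),),
    (("flip", "ND6"),),
    (("move", "D", "CYTB"),),  # long-range translocation
)


def make_gene_orders(
    seed: int,
    events_spec: Sequence[Sequence[tuple]] | None = None,
) -> TruthBundle:
    """Gene-order signatures derived from the canonical order by planted
    events.

    Events: ``("swap", g1, g2)`` adjacent swap, ``("move", g, after)`` move g
    to just after ``after``, ``("dup", g, after)`` insert a copy of g after
    ``after``, ``("flip", g)`` strand switch, ``("loss", g)`` removal.
    """
    spec = list(events_spec if events_spec is not None else DEFAULT_ORDER_EVENTS)
    sigs: list[GeneOrderSignature] = []
    truth_events = []
    for gi, events in enumerate(spec):
        touched: set[str] = set()
        pairs = list(CANONICAL_ORDER)
        for ev in events:
            kind, g = ev[0], ev[1]
            if g in touched:
                raise ValueError(f"contradictory events on {g}")
            touched.add(g)
            idx = [k for k, (s, _) in enumerate(pairs) if s == g]
            if kind != "dup" and not idx:
                raise ValueError(f"gene {g} not present for event {kind}")
            if kind == "swap":
                h = ev[2]
                jdx = [k for k, (s, _) in enumerate(pairs) if s == h]
                i, j = idx[0], jdx[0]
                pairs[i], pairs[j] = pairs[j], pairs[i]
                touched.add(h)
            elif kind == "move":
                after = ev[2]
                item = pairs.pop(idx[0])
                dest = [k for k, (s, _) in enumerate(pairs) if s == after][0]
                pairs.insert(dest + 1, item)
            elif kind == "dup":
                after = ev[2] if len(ev) > 2 else g
                src = idx[0] if idx else None
                item = pairs[src]
                dest = [k for k, (s, _) in enumerate(pairs) if s == after][0]
                pairs.insert(dest + 1, item)
            elif kind == "flip":
                i = idx[0]
                pairs[i] = (pairs[i][0], "-" if pairs[i][1] == "+" else "+")
            elif kind == "loss":
                pairs.pop(idx[0])
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        sigs.append(_normalize(pairs))
        expected = {"swap": "reshuffling", "move": None, "dup": "duplication",
                    "flip": "inversion", "loss": "loss"}
        truth_events.append([
            {"event": list(ev),
             "expected_kind": expected[ev[0]]}
            for ev in events
        ])

    truth = {
        "signatures": [str(s) for s in sigs],
        "events": truth_events,
        "n_distinct": len({str(s) for s in sigs}),
    }
    bundle = TruthBundle(records={}, truth=truth, seed=seed,
                         params={"n_genomes": len(spec)})
    bundle.truth["signature_objects"] = sigs
    return bundle


def random_single_edit(seed: int) -> tuple[tuple, str]:
    """One random single rearrangement event and its expected classification.

    Cluster swaps are adjacent-gene swaps inside the IQM / WANCY /
    His-Ser-Leu tRNA clusters (reshuffling); moves relocate a tRNA far away
    (translocation); duplications, strand flips and OL loss map to their own
    kinds.
    """
    rng = _rng(seed)
    clusters = [("I", "Q"), ("Q", "M"), ("A", "N"), ("C", "Y"),
                ("H", "S1"), ("S1", "L2")]
    kind = ["swap", "move", "dup", "flip", "loss"][int(rng.integers(5))]
    if kind == "swap":
        g1, g2 = clusters[int(rng.integers(len(clusters)))]
        return ("swap", g1, g2), "reshuffling"
    if kind == "move":
        # displace a tRNA by well over the reshuffle window
        moves = [("D", "CYTB"), ("K", "T"), ("G", "ND1"), ("W", "ND5")]
        g, after = moves[int(rng.integers(len(moves)))]
        return ("move", g, after), "translocation"
    if kind == "dup":
        g = ["F", "T", "P"][int(rng.integers(3))]
        return ("dup", g, "CR"), "duplication"
    if kind == "flip":
        g = ["ND6", "W", "G"][int(rng.integers(3))]
        return ("flip", g), "inversion"
    return ("loss", "OL"), "loss"


# ---------------------------------------------------------------------------
# codon evolution

def evolve_cds(
    seed: int,
    n_codons: int = 5000,
    omega: float = 0.2,
    kappa: float = 2.0,
    target_ks: float = 0.3,
) -> TruthBundle:
    """An ancestor/descendant CDS pair evolved at a planted omega.

    Mutations are proposed one base at a time (transition weight ``kappa``
    against 1 per transversion), stops are rejected, synonymous changes are
    always accepted and nonsynonymous ones with probability ``omega``, until
    the accepted synonymous substitutions reach ``target_ks`` x the ancestor's
    synonymous site count.  Truth records the realised substitution counts.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if target_ks <= 0 or target_ks >= 0.7:
        raise ValueError("target_ks must be in (0, 0.7): higher saturates the "
                         "proportion correction")
    rng = _rng(seed)
    sense = list(SENSE_CODONS)
    ancestor = [sense[i] for i in rng.integers(len(sense), size=n_codons)]
    S_sites = sum(_codon_sites(c)[0] for c in ancestor)
    target_syn = target_ks * S_sites

    descendant = list(ancestor)
    syn_subs = nonsyn_subs = 0
    max_proposals = 500 * max(1, int(target_syn))
    proposals = 0
    while syn_subs < target_syn:
        proposals += 1
        if proposals > max_proposals:
            raise RuntimeError("saturation guard: target_ks unattainable")
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = descendant[ci]
        old = codon[pos]
        alts = [b for b in _BASES if b != old]
        w = np.array([kappa if (old, b) in TRANSITIONS else 1.0 for b in alts])
        new = alts[int(rng.choice(3, p=w / w.sum()))]
        cand = codon[:pos] + new + codon[pos + 1:]
        if cand in STOP_CODONS:
            continue
        if CODON_TO_AA[cand] == CODON_TO_AA[codon]:
            descendant[ci] = cand
            syn_subs += 1
        elif rng.random() < omega:
            descendant[ci] = cand
            nonsyn_subs += 1

    truth = {
        "omega": omega,
        "kappa": kappa,
        "target_ks": target_ks,
        "syn_substitutions": syn_subs,
        "nonsyn_substitutions": nonsyn_subs,
        "S_sites_ancestor": S_sites,
        "proposals": proposals,
    }
    return TruthBundle(
        records={"ancestor": "".join(ancestor),
                 "descendant": "".join(descendant)},
        truth=truth,
        seed=seed,
        params={"n_codons": n_codons, "omega": omega, "kappa": kappa,
                "target_ks": target_ks},
    )


__all__ = [
    "TruthBundle", "CR_BACKGROUND", "DEFAULT_TYPE_DIFFS",
    "DEFAULT_PATTERN_SPEC", "DEFAULT_ORDER_EVENTS",
    "make_cr", "make_repeat_cohort", "random_sequence_without_repeats",
    "make_gene_orders", "random_single_edit", "evolve_cds",
]
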