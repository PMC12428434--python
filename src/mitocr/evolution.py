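"""Pairwise evolutionary statistics: Kimura 2-parameter distances,
neighbor-joining trees, and Nei–Gojobori (1986-style) Ka/Ks.

K2P separates transition (A<->G, C<->T) and transversion proportions P and Q
over pairwise-deletion-comparable sites and corrects them as
``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))``; the distance is undefined
(flagged, never silently NaN) once either log argument is non-positive
(saturation).

NJ is the Saitou–Nei agglomeration with the rate-corrected criterion
``Q_ij = (n-2) d_ij - r_i - r_j``, deterministic tie-breaking by the smallest
index pair, and the closed-form final three-taxon join.  Negative branch
lengths are retained as computed (and flagged) unless clamping is requested.

The Ka/Ks estimator is the unweighted pathway-counting method: per-codon
synonymous/nonsynonymous site fractions (mutations to stop codons excluded
from the per-position denominator, so S + N = 3 x codons holds exactly),
multi-difference codons averaged over all substitution orderings that avoid
stop codons (all orderings if every one passes through a stop), and
Jukes–Cantor correction ``-(3/4) ln(1 - (4/3) p)`` of both proportions.  The
vertebrate mitochondrial code is used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

import pandas as pd

from .seq_stats import CODON_TO_AA, STOP_CODONS

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})
_ACGT = "ACGT"


# ---------------------------------------------------------------------------
# Kimura 2-parameter

@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    n_sites: int
    d: float | None
    undefined_reason: str | None = None


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance with pairwise deletion of non-ACGT sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _ACGT or y not in _ACGT:
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P, Q, n, None, "saturated (log argument <= 0)")
    return K2PResult(P, Q, n, -0.5 * math.log(w1 * math.sqrt(w2)))


def k2p_matrix(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric K2P distance matrix over aligned sequences."""
    labels = list(seqs)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, x in enumerate(labels):
        for y in labels[i + 1:]:
            r = k2p_distance(seqs[x], seqs[y])
            if r.d is None:
                raise ValueError(f"K2P undefined for pair ({x},{y}): "
                                 f"{r.undefined_reason}")
            mat.loc[x, y] = mat.loc[y, x] = r.d
    return mat


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """An unrooted tree (represented with an arbitrary internal root node)."""

    root: TreeNode
    has_negative_branches: bool = False

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(n: TreeNode) -> None:
            if n.is_leaf():
                out.append(n.label or "")
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return out

    def clamp_negative_branches(self) -> "PhyloTree":
        def walk(n: TreeNode) -> TreeNode:
            return TreeNode(
                label=n.label,
                children=[(walk(c), max(0.0, bl)) for c, bl in n.children],
            )

        return PhyloTree(root=walk(self.root), has_negative_branches=False)


def nj_tree(
    dist: pd.DataFrame | Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    clamp: bool = False,
) -> PhyloTree:
    """Saitou–Nei neighbor joining of a symmetric distance matrix.

    Ties in the joining criterion break on the smallest (i, j) index pair, so
    the output is deterministic.  Two taxa yield a single-edge tree as a
    convenience.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        D = [[float(dist.iloc[i, j]) for j in range(len(labels))]
             for i in range(len(labels))]
    else:
        D = [[float(v) for v in row] for row in dist]
        labels = list(labels) if labels is not None else [
            f"t{i + 1}" for i in range(len(D))
        ]
    n = len(D)
    if n != len(labels) or any(len(row) != n for row in D):
        raise ValueError("distance matrix must be square and match labels")
    for i in range(n):
        for j in range(n):
            v = D[i][j]
            if not math.isfinite(v):
                raise ValueError("distance matrix has undefined entries")
            if abs(v - D[j][i]) > 1e-9:
                raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in labels]
    negative = False

    if n == 2:
        root = TreeNode(children=[(nodes[0], D[0][1] / 2), (nodes[1], D[0][1] / 2)])
        return PhyloTree(root, has_negative_branches=D[0][1] < 0)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m - 1):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = D[i][j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i][j] - vi
        negative = negative or vi < 0 or vj < 0
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        for row in D:
            row.append(0.0)
        D.append([0.0] * (len(D) + 1))
        u = len(D) - 1
        for k in active:
            if k in (i, j):
                continue
            duk = (D[i][k] + D[j][k] - D[i][j]) / 2
            D[u][k] = D[k][u] = duk
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    va = (D[a][b] + D[a][c] - D[b][c]) / 2
    vb = (D[a][b] + D[b][c] - D[a][c]) / 2
    vc = (D[a][c] + D[b][c] - D[a][b]) / 2
    negative = negative or min(va, vb, vc) < 0
    root = TreeNode(children=[(nodes[a], va), (nodes[b], vb), (nodes[c], vc)])
    tree = PhyloTree(root, has_negative_branches=negative)
    return tree.clamp_negative_branches() if clamp else tree


_NEWICK_UNSAFE = set(" ()[]':;,")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree) -> str:
    """Render a tree as a newick string with branch lengths."""

    def render(n: TreeNode) -> str:
        if n.is_leaf():
            return _quote(n.label or "")
        inner = ",".join(f"{render(c)}:{bl:.10g}" for c, bl in n.children)
        return f"({inner})"

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# NG86 Ka/Ks

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the fraction of the non-stop single-base changes that are
    synonymous; positions whose every change hits a stop count as fully
    nonsynonymous, keeping s + n = 3 exactly.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _ACGT:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over stop-free substitution pathways (all pathways if none is
    stop-free)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            paths.append((syn, non))
    if not paths:  # every ordering passes through a stop: fall back to all
        for order in permutations(diff_pos):
            cur = c1
            syn = non = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            paths.append((syn, non))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    n_codons: int
    n_excluded_codons: int
    undefined_reason: str | None = None


def ng86_kaks(cds_a: str, cds_b: str,
              zero_over_zero: float | None = None) -> KaKsResult:
    """Pairwise Ka/Ks by pathway counting under the vertebrate mito code.

    Codon pairs containing non-ACGT bases or aligned to a stop in either
    sequence are excluded.  ``ratio`` is ``Ka/Ks`` when ``Ks > 0``, else
    ``zero_over_zero`` (default ``None``).
    """
    a = cds_a.upper()
    b = cds_b.upper()
    if len(a) != len(b):
        raise ValueError("CDS must be aligned to equal length")
    trimmed = len(a) - len(a) % 3
    a, b = a[:trimmed], b[:trimmed]
    S = N = Sd = Nd = 0.0
    used = excluded = 0
    for i in range(0, trimmed, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in _ACGT for ch in ca + cb) or \
                ca in STOP_CODONS or cb in STOP_CODONS:
            excluded += 1
            continue
        used += 1
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = _codon_diffs(ca, cb)
        Sd += ds
        Nd += dn
    if used == 0:
        raise ValueError("no comparable codons")
    pS, pN = Sd / S if S else 0.0, Nd / N if N else 0.0
    Ks, Ka = _jc(pS), _jc(pN)
    reason = None
    if Ks is None or Ka is None:
        reason = "proportion >= 0.75: Jukes-Cantor correction undefined"
    ratio: float | None
    if Ka is None or Ks is None:
        ratio = None
    elif Ks > 0:
        ratio = Ka / Ks
    else:
        ratio = zero_over_zero
    return KaKsResult(
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        Ks=Ks, Ka=Ka, ratio=ratio, n_codons=used,
        n_excluded_codons=excluded, undefined_reason=reason,
    )


def kaks_profile(
    gene_sets: Mapping[str, Mapping[str, str]],
    focal: str,
) -> pd.DataFrame:
    """Per-gene and concatenated Ka/Ks of the focal species against each
    background species.

    ``gene_sets`` maps species id → {gene name → aligned CDS}.  The
    concatenated row pools site and difference counts over genes (not the mean
    of per-gene ratios).  Missing genes yield null cells with a warning.
    """
    if focal not in gene_sets:
        raise KeyError(f"focal species {focal!r} not in gene_sets")
    if len(gene_sets) < 2:
        raise ValueError("need at least two species")
    focal_genes = gene_sets[focal]
    rows = []
    for other in gene_sets:
        if other == focal:
            continue
        pooled = {"S": 0.0, "N": 0.0, "Sd": 0.0, "Nd": 0.0}
        for gene in focal_genes:
            if gene not in gene_sets[other]:
                warnings.warn(f"gene {gene} missing in {other}; cell left null")
                rows.append({"gene": gene, "species": other,
                             "Ka": None, "Ks": None, "ratio": None})
                continue
            r = ng86_kaks(focal_genes[gene], gene_sets[other][gene])
            pooled["S"] += r.S_sites
            pooled["N"] += r.N_sites
            pooled["Sd"] += r.Sd
            pooled["Nd"] += r.Nd
            rows.append({"gene": gene, "species": other,
                         "Ka": r.Ka, "Ks": r.Ks, "ratio": r.ratio})
        Ks = _jc(pooled["Sd"] / pooled["S"]) if pooled["S"] else None
        Ka = _jc(pooled["Nd"] / pooled["N"]) if pooled["N"] else None
        ratio = (Ka / Ks) if (Ka is not None and Ks not in (None, 0.0)) else None
        rows.append({"gene": "concatenated", "species": other,
                     "Ka": Ka, "Ks": Ks, "ratio": ratio})
    return pd.DataFrame(rows, columns=["gene", "species", "Ka", "Ks", "ratio"])


__all__ = [
    "TRANSITIONS", "K2PResult", "PhyloTree", "TreeNode", "KaKsResult",
    "k2p_distance", "k2p_matrix", "nj_tree", "write_newick",
    "ng86_kaks", "kaks_profile",
]
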