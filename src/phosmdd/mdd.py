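"""Maximal dependence decomposition (MDD) of aligned peptide fragments.

The twenty amino acids are collapsed into five biochemical groups
(neutral, acid, basic, aromatic, imino).  For every ordered pair of flank
positions a 5x5 contingency table of group co-occurrence is built and
tested for independence with Pearson's chi-square statistic on 16 degrees
of freedom; a value above the default cutoff 34.3 (upper 0.005 quantile)
flags a strong positional dependence.  The fragment set is then split
recursively on the position with the largest aggregate dependence,
partitioning by presence/absence of the modal group at that position,
until subgroups fall below a minimum cluster size.  Each resulting leaf
is a candidate kinase substrate motif.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA20, AA_INDEX
from .fragments import PeptideFragment

logger = logging.getLogger(__name__)

GROUP_ORDER = ("neutral", "acid", "basic", "aromatic", "imino")
N_GROUPS = len(GROUP_ORDER)
UNMAPPED = N_GROUPS  # sentinel code for pads / non-standard letters

DEFAULT_CHI2_CUTOFF = 34.3
CHI2_DF = (N_GROUPS - 1) ** 2  # 16 for the 5x5 table


@dataclass(frozen=True)
class GroupScheme:
    """Partition of the 20 amino acids into five biochemical property groups."""

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if tuple(self.groups) != GROUP_ORDER:
            raise ValueError(f"groups must be exactly {GROUP_ORDER} in order")
        covered = sorted("".join("".join(sorted(g)) for g in self.groups.values()))
        if "".join(covered) != "".join(sorted(AA20)):
            raise ValueError("groups must partition the 20 standard amino acids")

    @property
    def residue_to_group(self) -> dict[str, int]:
        return {aa: gi for gi, name in enumerate(GROUP_ORDER) for aa in self.groups[name]}

    def group_name(self, index: int) -> str:
        return GROUP_ORDER[index]


#: Default scheme: acid = D/E, basic = K/R/H, aromatic = F/W/Y, imino = P,
#: everything else neutral.  Override via config for alternative chemistries.
DEFAULT_SCHEME = GroupScheme(
    groups={
        "neutral": frozenset("GAVLIMCSTNQ"),
        "acid": frozenset("DE"),
        "basic": frozenset("KRH"),
        "aromatic": frozenset("FWY"),
        "imino": frozenset("P"),
    }
)


def map_group(residue: str, scheme: GroupScheme = DEFAULT_SCHEME) -> str:
    """Name of the property group of ``residue``; ``"unmapped"`` for pads etc."""
    idx = scheme.residue_to_group.get(residue)
    return "unmapped" if idx is None else GROUP_ORDER[idx]


def flank_positions(w: int) -> list[int]:
    """Flank coordinates -w..+w excluding the centre 0."""
    return [p for p in range(-w, w + 1) if p != 0]


def _window_index(p: int, w: int) -> int:
    if p == 0 or not -w <= p <= w:
        raise ValueError(f"flank position must be in -{w}..+{w} and nonzero, got {p}")
    return p + w


def encode_group_codes(
    fragments: Sequence[PeptideFragment], scheme: GroupScheme = DEFAULT_SCHEME
) -> tuple[np.ndarray, int]:
    """Encode fragments as an (n, 2w+1) int8 matrix of group codes.

    Pads and non-standard letters get the UNMAPPED sentinel and are
    excluded from all contingency counts.
    """
    if not fragments:
        raise ValueError("no fragments to encode")
    L = len(fragments[0].window)
    if L % 2 != 1:
        raise ValueError("window length must be odd")
    w = L // 2
    lut = np.full(128, UNMAPPED, dtype=np.int8)
    for aa, gi in scheme.residue_to_group.items():
        lut[ord(aa)] = gi
    raw = np.frombuffer(
        "".join(f.window for f in fragments).encode("ascii"), dtype=np.uint8
    ).reshape(len(fragments), L)
    return lut[raw], w


@dataclass
class ContingencyTable:
    """5x5 group co-occurrence counts for one ordered position pair."""

    counts: np.ndarray  # (5, 5) int
    position_i: int
    position_j: int

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency(
    fragments: Sequence[PeptideFragment],
    i: int,
    j: int,
    scheme: GroupScheme = DEFAULT_SCHEME,
) -> ContingencyTable:
    """Cross-tabulate group occurrence at flank positions ``i`` and ``j``.

    A fragment contributes only if both positions carry a mapped standard
    residue (no pad).
    """
    codes, w = encode_group_codes(fragments, scheme)
    return _contingency_from_codes(codes, _window_index(i, w), _window_index(j, w), i, j)


def _contingency_from_codes(
    codes: np.ndarray, ci: int, cj: int, pos_i: int, pos_j: int
) -> ContingencyTable:
    if ci == cj:
        raise ValueError("positions must differ")
    a, b = codes[:, ci], codes[:, cj]
    valid = (a != UNMAPPED) & (b != UNMAPPED)
    flat = np.bincount(
        a[valid].astype(np.int64) * N_GROUPS + b[valid], minlength=N_GROUPS * N_GROUPS
    )
    return ContingencyTable(
        counts=flat.reshape(N_GROUPS, N_GROUPS), position_i=pos_i, position_j=pos_j
    )


def chi_square(table: ContingencyTable) -> float:
    """Pearson chi-square statistic of the table.

    Expected counts are ``row * col / total``; cells whose expected count
    is zero (an empty row or column margin) contribute nothing, keeping
    the statistic defined on sparse tables.  An empty table returns 0
    with a warning.
    """
    X = table.total
    if X == 0:
        warnings.warn("chi_square on an empty contingency table; returning 0", stacklevel=2)
        return 0.0
    expected = np.outer(table.row_sums, table.col_sums) / X
    mask = expected > 0
    observed = table.counts
    return float((((observed - expected) ** 2)[mask] / expected[mask]).sum())


@dataclass
class DependenceMatrix:
    """Pairwise chi-square values over all flank position pairs."""

    positions: list[int]
    chi2: np.ndarray  # symmetric (P, P), zero diagonal
    cutoff: float = DEFAULT_CHI2_CUTOFF
    df: int = CHI2_DF

    def value(self, i: int, j: int) -> float:
        return float(self.chi2[self.positions.index(i), self.positions.index(j)])


def dependence_matrix(
    fragments: Sequence[PeptideFragment],
    scheme: GroupScheme = DEFAULT_SCHEME,
    cutoff: float = DEFAULT_CHI2_CUTOFF,
) -> DependenceMatrix:
    """Chi-square dependence between every pair of flank positions."""
    codes, w = encode_group_codes(fragments, scheme)
    positions = flank_positions(w)
    P = len(positions)
    mat = np.zeros((P, P))
    for ii in range(P):
        for jj in range(ii + 1, P):
            t = _contingency_from_codes(
                codes,
                _window_index(positions[ii], w),
                _window_index(positions[jj], w),
                positions[ii],
                positions[jj],
            )
            v = chi_square(t) if t.total else 0.0
            mat[ii, jj] = mat[jj, ii] = v
    return DependenceMatrix(positions=positions, chi2=mat, cutoff=cutoff)


def _position_sort_key(p: int) -> tuple[int, int]:
    # smaller magnitude first; negative before positive at equal magnitude
    return (abs(p), 0 if p < 0 else 1)


def choose_split(
    fragments: Sequence[PeptideFragment],
    scheme: GroupScheme = DEFAULT_SCHEME,
    cutoff: float = DEFAULT_CHI2_CUTOFF,
) -> tuple[int, str] | None:
    """Pick the split position and group with maximal aggregate dependence.

    For each position the chi-square values of its strongly dependent
    pairs (those above ``cutoff``) are summed; the position with the
    largest sum wins (ties towards the centre, negative flank first).
    The split group is the group whose rows contribute most chi-square
    mass across that position's significant pairs — the group actually
    driving the dependence (ties by group order).  Returns ``None`` when
    no pair exceeds the cutoff.
    """
    if len(fragments) < 2:
        return None
    dep = dependence_matrix(fragments, scheme, cutoff)
    sig = np.where(dep.chi2 > cutoff, dep.chi2, 0.0)
    scores = sig.sum(axis=1)
    if not scores.any():
        return None
    best = max(
        range(len(dep.positions)),
        key=lambda k: (scores[k], [-v for v in _position_sort_key(dep.positions[k])]),
    )
    position = dep.positions[best]

    codes, w = encode_group_codes(fragments, scheme)
    ci = _window_index(position, w)
    contrib = np.zeros(N_GROUPS)
    for kk, pj in enumerate(dep.positions):
        if sig[best, kk] <= 0:
            continue
        table = _contingency_from_codes(codes, ci, _window_index(pj, w), position, pj)
        X = table.total
        if X == 0:
            continue
        expected = np.outer(table.row_sums, table.col_sums) / X
        mask = expected > 0
        cell = np.zeros_like(expected)
        cell[mask] = (table.counts - expected)[mask] ** 2 / expected[mask]
        contrib += cell.sum(axis=1)
    group = GROUP_ORDER[int(np.argmax(contrib))]  # argmax ties -> first in group order
    return position, group


@dataclass
class MDDNode:
    """A node of the recursive decomposition tree."""

    members: list[PeptideFragment]
    depth: int = 0
    split_position: int | None = None
    split_group: str | None = None
    present_child: "MDDNode | None" = None
    absent_child: "MDDNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.present_child is None

    def leaves(self) -> list["MDDNode"]:
        if self.is_leaf:
            return [self]
        return self.present_child.leaves() + self.absent_child.leaves()


def mdd_cluster(
    fragments: Sequence[PeptideFragment],
    scheme: GroupScheme = DEFAULT_SCHEME,
    cutoff: float = DEFAULT_CHI2_CUTOFF,
    min_cluster_size: int = 200,
) -> MDDNode:
    """Build the MDD tree by recursive presence/absence splitting.

    A node splits only while it has at least ``min_cluster_size`` members,
    a strong dependence exists, and both children are non-empty; every
    split strictly shrinks both children, so recursion terminates.
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")

    def build(members: list[PeptideFragment], depth: int) -> MDDNode:
        node = MDDNode(members=members, depth=depth)
        if len(members) < min_cluster_size:
            return node
        split = choose_split(members, scheme, cutoff)
        if split is None:
            return node
        position, group = split
        group_set = scheme.groups[group]
        _, w = encode_group_codes(members[:1], scheme)
        idx = _window_index(position, w)
        present = [f for f in members if f.window[idx] in group_set]
        absent = [f for f in members if f.window[idx] not in group_set]
        if not present or not absent:
            return node
        node.split_position = position
        node.split_group = group
        node.present_child = build(present, depth + 1)
        node.absent_child = build(absent, depth + 1)
        return node

    return build(list(fragments), 0)


@dataclass
class MotifCluster:
    """A subgroup of fragments sharing a substrate motif."""

    id: str
    members: list[PeptideFragment]
    group_freqs: np.ndarray = field(default=None, repr=False)  # (2w+1, 5)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("motif cluster must be non-empty")
        if self.group_freqs is None:
            self.group_freqs = group_frequencies(self.members)


def group_frequencies(
    members: Sequence[PeptideFragment], scheme: GroupScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Per-position distribution over the five groups; uniform where all pads."""
    codes, w = encode_group_codes(members, scheme)
    L = 2 * w + 1
    freqs = np.full((L, N_GROUPS), 1.0 / N_GROUPS)
    for c in range(L):
        col = codes[:, c]
        counts = np.bincount(col[col != UNMAPPED], minlength=N_GROUPS).astype(float)
        if counts.sum() > 0:
            freqs[c] = counts / counts.sum()
    return freqs


def tree_clusters(
    root: MDDNode, prefix: str = "S", scheme: GroupScheme = DEFAULT_SCHEME
) -> list[MotifCluster]:
    """Number the tree's leaves depth-first (present branch first) as motif clusters."""
    return [
        MotifCluster(id=f"{prefix}{k + 1}", members=leaf.members,
                     group_freqs=group_frequencies(leaf.members, scheme))
        for k, leaf in enumerate(root.leaves())
    ]


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits between two discrete distributions."""
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def motif_distance(a: MotifCluster, b: MotifCluster) -> float:
    """Mean flank-position JS divergence between group-frequency profiles.

    The centre position is excluded: it is fixed by the residue class and
    would only dilute the distance.
    """
    if a.group_freqs.shape != b.group_freqs.shape:
        raise ValueError("clusters must share window length")
    w = a.group_freqs.shape[0] // 2
    return float(
        np.mean([
            _js_divergence(p, q)
            for c, (p, q) in enumerate(zip(a.group_freqs, b.group_freqs))
            if c != w
        ])
    )


def merge_similar(
    leaves: Sequence[MotifCluster],
    distance_threshold: float = 0.0,
    scheme: GroupScheme = DEFAULT_SCHEME,
) -> list[MotifCluster]:
    """Single-linkage agglomeration of near-identical motif clusters.

    Merging repeats while the closest pair is below the threshold; the
    merged cluster recomputes its frequencies from the member union.  A
    threshold of 0 disables merging and returns the input unchanged.
    """
    if distance_threshold <= 0 or len(leaves) < 2:
        return list(leaves)
    clusters = list(leaves)
    while len(clusters) > 1:
        best_pair, best_d = None, np.inf
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = motif_distance(clusters[x], clusters[y])
                if d < best_d:
                    best_pair, best_d = (x, y), d
        if best_d >= distance_threshold:
            break
        x, y = best_pair
        merged_members = clusters[x].members + clusters[y].members
        merged = MotifCluster(
            id=f"{clusters[x].id}+{clusters[y].id}",
            members=merged_members,
            group_freqs=group_frequencies(merged_members, scheme),
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    # renumber sequentially, keeping the shared prefix
    prefix = "".join(ch for ch in clusters[0].id if not ch.isdigit() and ch != "+")[:1] or "C"
    return [
        MotifCluster(id=f"{prefix}{k + 1}", members=c.members, group_freqs=c.group_freqs)
        for k, c in enumerate(clusters)
    ]


def motif_summary(cluster: MotifCluster) -> "pd.DataFrame":
    """Per-position residue frequencies and information content in bits.

    Information content at a position is ``log2(20) - H`` where H is the
    Shannon entropy of the residue distribution there, pads excluded.  A
    position where every member is padded reports 0 bits and is flagged.
    """
    import pandas as pd

    L = len(cluster.members[0].window)
    w = L // 2
    raw = np.frombuffer(
        "".join(f.window for f in cluster.members).encode("ascii"), dtype=np.uint8
    ).reshape(len(cluster.members), L)
    lut = np.full(128, -1, dtype=np.int8)
    for aa, k in AA_INDEX.items():
        lut[ord(aa)] = k
    coded = lut[raw]
    rows = []
    for c in range(L):
        col = coded[:, c]
        counts = np.bincount(col[col >= 0], minlength=20).astype(float)
        n = counts.sum()
        if n == 0:
            freqs = np.zeros(20)
            info = 0.0
            all_pad = True
        else:
            freqs = counts / n
            nz = freqs[freqs > 0]
            info = np.log2(20) + float((nz * np.log2(nz)).sum())
            all_pad = False
        rows.append(
            {"position": c - w, **{aa: freqs[k] for aa, k in AA_INDEX.items()},
             "info_bits": info, "n": int(n), "all_pad": all_pad}
        )
    return pd.DataFrame(rows)


def tree_to_json(root: MDDNode, path: str | Path | None = None) -> dict:
    """Serialise the decomposition tree (splits + member fragment keys)."""

    def node_dict(node: MDDNode) -> dict:
        d: dict = {
            "n_members": len(node.members),
            "depth": node.depth,
            "split_position": node.split_position,
            "split_group": node.split_group,
        }
        if node.is_leaf:
            d["member_keys"] = [[f.protein_id, f.site_position] for f in node.members]
        else:
            d["present_child"] = node_dict(node.present_child)
            d["absent_child"] = node_dict(node.absent_child)
        return d

    out = node_dict(root)
    if path is not None:
        Path(path).write_text(json.dumps(out, indent=1))
    return out
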