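"""Size-matched negative selection by medoid clustering on Hamming distance.

Random down-sampling of the (much larger) negative set risks an
unrepresentative draw.  Instead the negatives are clustered into K groups
— K being the positive count — and each cluster contributes its medoid,
the member with minimal total Hamming distance to the rest of its
cluster.  The selected representatives are therefore real sequences, not
averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fragments import PeptideFragment

_MAX_ITER = 100


@dataclass
class BalanceResult:
    """Outcome of representative selection: K medoid fragments plus the assignment."""

    selected: list[PeptideFragment]
    cluster_assignment: dict[tuple[str, int], int] = field(repr=False)
    seed: int = 0


def encode_windows(windows: Sequence[str]) -> np.ndarray:
    """Encode equal-length windows as an (n, L) uint8 matrix of character codes."""
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"all windows must have equal length, got lengths {sorted(lengths)}")
    return np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(
        len(windows), lengths.pop()
    )


def hamming(a: str, b: str) -> int:
    """Character Hamming distance; the pad X matches X and mismatches any letter."""
    if len(a) != len(b):
        raise ValueError("windows must have equal length")
    return sum(x != y for x, y in zip(a, b))


def _distances_to(codes: np.ndarray, medoid_codes: np.ndarray) -> np.ndarray:
    # (n, K) pairwise Hamming distances via broadcasting
    return (codes[:, None, :] != medoid_codes[None, :, :]).sum(axis=2)


def _cluster_medoid(codes: np.ndarray, member_idx: np.ndarray) -> int:
    """Index (into codes) of the member minimising total intra-cluster distance.

    Ties break towards the earliest input position.
    """
    sub = codes[member_idx]
    totals = (sub[:, None, :] != sub[None, :, :]).sum(axis=2).sum(axis=1)
    return int(member_idx[int(np.argmin(totals))])


def select_representatives(
    negatives: Sequence[PeptideFragment], K: int, seed: int = 0
) -> BalanceResult:
    """Pick K representative fragments by Lloyd-style k-medoids on Hamming distance.

    Initialisation is k-means++-like (distance-squared weighted) from
    ``seed``; assignment goes to the nearest medoid, medoids update to the
    member with minimal total within-cluster distance, empty clusters are
    reseeded with the point farthest from its medoid.  Deterministic for a
    fixed seed and input order.
    """
    n = len(negatives)
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K:
        raise ValueError(f"cannot select {K} representatives from {n} fragments")
    codes = encode_windows([f.window for f in negatives])
    if n == K:
        assignment = {f.key: i for i, f in enumerate(negatives)}
        return BalanceResult(selected=list(negatives), cluster_assignment=assignment, seed=seed)

    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    d_near = _distances_to(codes, codes[medoids]).min(axis=1).astype(float)
    while len(medoids) < K:
        weights = d_near**2
        total = weights.sum()
        if total == 0:
            # all remaining points coincide with a medoid; fill by input order
            chosen = set(medoids)
            for i in range(n):
                if i not in chosen:
                    medoids.append(i)
                    chosen.add(i)
                    if len(medoids) == K:
                        break
            break
        nxt = int(rng.choice(n, p=weights / total))
        medoids.append(nxt)
        d_near = np.minimum(d_near, _distances_to(codes, codes[[nxt]])[:, 0])

    medoids_arr = np.array(sorted(set(medoids))[:K], dtype=int)
    # rare duplicate picks: top up deterministically
    if len(medoids_arr) < K:
        extra = [i for i in range(n) if i not in set(medoids_arr.tolist())]
        medoids_arr = np.array(sorted(medoids_arr.tolist() + extra[: K - len(medoids_arr)]))

    assign = np.empty(n, dtype=int)
    for _ in range(_MAX_ITER):
        dist = _distances_to(codes, codes[medoids_arr])
        assign = dist.argmin(axis=1)
        point_d = dist[np.arange(n), assign]
        new_medoids = medoids_arr.copy()
        for c in range(K):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                far = int(np.argmax(point_d))
                new_medoids[c] = far
                point_d[far] = -1
            else:
                new_medoids[c] = _cluster_medoid(codes, members)
        if np.array_equal(new_medoids, medoids_arr):
            break
        medoids_arr = new_medoids

    dist = _distances_to(codes, codes[medoids_arr])
    assign = dist.argmin(axis=1)
    selected = [negatives[int(i)] for i in medoids_arr]
    assignment = {f.key: int(assign[i]) for i, f in enumerate(negatives)}
    return BalanceResult(selected=selected, cluster_assignment=assignment, seed=seed)
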