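"""Position-specific log-odds models for MDD subgroups.

Because the training fragments are gap-free fixed-length windows, a full
match/insert/delete profile architecture degenerates to an ungapped
positional model: one emission distribution per flank position, scored
against a background (null) distribution.  The score of a query window
is the base-2 log-likelihood ratio in bits,

    score = sum_p log2( e_p(a_p) / b(a_p) )

over flank positions p carrying a mapped residue a_p; pads contribute
nothing.  Each model carries an integer bit-score threshold calibrated by
cross-validation: a window scoring above the threshold is a positive hit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA20, AA_INDEX
from .fragments import PeptideFragment
from .mdd import MotifCluster

FORMAT_TAG = "phosmdd-bundle-v1"


def _residue_lut() -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int8)
    for aa, k in AA_INDEX.items():
        lut[ord(aa)] = k
    return lut


_LUT = _residue_lut()


@dataclass
class ProfileModel:
    """Ungapped positional emission model with a calibrated bit-score threshold.

    ``emissions`` has one row per window position (length ``2w+1``); the
    centre row is unused (the centre residue is fixed by the class) and
    kept only so row index ``p + w`` addresses flank coordinate ``p``.
    """

    cluster_id: str
    residue_class: str
    w: int
    emissions: np.ndarray = field(repr=False)  # (2w+1, 20)
    background: np.ndarray = field(repr=False)  # (20,)
    pseudocount: float = 1.0
    threshold_bits: int = 0
    training_size: int = 0

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.emissions.shape != (2 * self.w + 1, 20):
            raise ValueError("emissions must be (2w+1, 20)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def log_odds(self) -> np.ndarray:
        """(2w+1, 20) matrix of per-position log2 odds; centre row zeroed."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.emissions) - np.log2(self.background)[None, :]
        lo[self.w, :] = 0.0
        return lo


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def pooled_background(fragments: Iterable[PeptideFragment]) -> np.ndarray:
    """Residue frequencies pooled over the flank positions of all fragments.

    The centre column is excluded (it is fixed to the site class and would
    bias the null); pads and non-standard letters are ignored.  Zero-count
    residues receive a single pseudo-observation so the null assigns every
    residue positive mass.
    """
    counts = np.zeros(20)
    for f in fragments:
        w = len(f.window) // 2
        for i, ch in enumerate(f.window):
            if i == w:
                continue
            k = AA_INDEX.get(ch)
            if k is not None:
                counts[k] += 1
    if counts.sum() == 0:
        return uniform_background()
    counts[counts == 0] = 1.0
    return counts / counts.sum()


def train_profile(
    cluster: MotifCluster | Sequence[PeptideFragment],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    cluster_id: str | None = None,
) -> ProfileModel:
    """Estimate per-position emission distributions from a subgroup's positives.

    emission(p, a) = (count of a at p + pseudocount) / (mapped count at p
    + 20 * pseudocount); pads are excluded from the counts.  Only positive
    instances are used — the model describes the motif, not its complement.
    """
    if isinstance(cluster, MotifCluster):
        members = cluster.members
        cid = cluster_id or cluster.id
    else:
        members = list(cluster)
        cid = cluster_id or "C1"
    if not members:
        raise ValueError("cannot train a profile on an empty cluster")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    L = len(members[0].window)
    w = L // 2
    raw = np.frombuffer(
        "".join(f.window for f in members).encode("ascii"), dtype=np.uint8
    ).reshape(len(members), L)
    coded = _LUT[raw]
    emissions = np.full((L, 20), 1.0 / 20)
    for c in range(L):
        col = coded[:, c]
        counts = np.bincount(col[col >= 0], minlength=20).astype(float)
        denom = counts.sum() + 20 * pseudocount
        if denom > 0:
            emissions[c] = (counts + pseudocount) / denom
    bg = uniform_background() if background is None else np.asarray(background, float)
    return ProfileModel(
        cluster_id=cid,
        residue_class=members[0].center_residue,
        w=w,
        emissions=emissions,
        background=bg,
        pseudocount=pseudocount,
        training_size=len(members),
    )


def bit_score(model: ProfileModel, window: str) -> float:
    """Log-odds score of one window in bits; pad positions contribute 0."""
    L = 2 * model.w + 1
    if len(window) != L:
        raise ValueError(f"window length {len(window)} != model length {L}")
    lo = model.log_odds
    score = 0.0
    for i, ch in enumerate(window):
        if i == model.w:
            continue
        k = AA_INDEX.get(ch)
        if k is not None:
            score += lo[i, k]
    return score


def score_windows(model: ProfileModel, windows: Sequence[str]) -> np.ndarray:
    """Vectorised :func:`bit_score` over many equal-length windows."""
    if not windows:
        return np.zeros(0)
    L = 2 * model.w + 1
    raw = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(
        len(windows), L
    )
    coded = _LUT[raw]
    lo = np.hstack([model.log_odds, np.zeros((L, 1))])  # extra column: unmapped -> 0
    idx = np.where(coded >= 0, coded, 20)
    pos = np.arange(L)
    return lo[pos[None, :], idx].sum(axis=1)


def save_bundle(
    models: Sequence[ProfileModel], path: str | Path, metadata: dict | None = None
) -> None:
    """Write a model bundle as versioned JSON."""
    if not models:
        raise ValueError("no models to save")
    payload = {
        "format": FORMAT_TAG,
        "residue_class": models[0].residue_class,
        "w": models[0].w,
        "alphabet": AA20,
        "background": models[0].background.tolist(),
        "metadata": metadata or {},
        "clusters": [
            {
                "id": m.cluster_id,
                "threshold_bits": m.threshold_bits,
                "training_size": m.training_size,
                "pseudocount": m.pseudocount,
                "emissions": m.emissions.tolist(),
            }
            for m in models
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_bundle(path: str | Path) -> list[ProfileModel]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != FORMAT_TAG:
        raise ValueError(f"unrecognised bundle format {payload.get('format')!r}")
    bg = np.array(payload["background"])
    return [
        ProfileModel(
            cluster_id=c["id"],
            residue_class=payload["residue_class"],
            w=payload["w"],
            emissions=np.array(c["emissions"]),
            background=bg,
            pseudocount=c["pseudocount"],
            threshold_bits=c["threshold_bits"],
            training_size=c["training_size"],
        )
        for c in payload["clusters"]
    ]
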