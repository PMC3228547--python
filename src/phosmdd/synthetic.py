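"""Synthetic labelled fragment datasets with planted positional dependencies.

Real substrate subgroups differ by which flank positions carry a
conserved biochemical signal — a proline just downstream of the site, an
acidic patch at +3, basic residues upstream.  The generator emulates
that structure: positives are drawn from a mixture of motif
specifications over a residue background, each motif planting symbols at
chosen flank positions with a stated probability (optionally coupling
two positions so their symbols co-occur); negatives are pure background.
The true motif identity of every positive is recorded separately from
the fragments so that tests can score clustering purity without the
training path ever seeing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .alphabet import AA20, PHOSPHO_RESIDUES
from .fragments import (
    NEGATIVE,
    POSITIVE,
    PeptideFragment,
    write_fragments_tsv,
)
from .mdd import DEFAULT_SCHEME, GROUP_ORDER, GroupScheme


@dataclass(frozen=True)
class MotifSpec:
    """One planted motif: flank position -> (symbol, probability).

    A symbol is either a single residue letter (planted verbatim) or a
    group name from the five-group alphabet (a uniform draw within the
    group).  ``coupling`` names two planted positions whose symbols are
    planted jointly — both or neither per fragment, driven by one
    Bernoulli draw at the probability of the first coupled position.
    """

    name: str
    plants: Mapping[int, tuple[str, float]]
    coupling: tuple[int, int] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        for pos, (_symbol, prob) in self.plants.items():
            if pos == 0:
                raise ValueError("cannot plant at the centre position 0")
            if not 0 < prob <= 1:
                raise ValueError(f"plant probability must be in (0, 1], got {prob}")
        if self.coupling is not None:
            a, b = self.coupling
            if a not in self.plants or b not in self.plants:
                raise ValueError("coupled positions must both be planted")


@dataclass
class DatasetSpec:
    """Recipe for one synthetic dataset of a single residue class."""

    n_pos: int
    n_neg: int
    w: int = 10
    residue_class: str = "S"
    motifs: Sequence[MotifSpec] = field(default_factory=list)
    background: np.ndarray | None = None  # (20,) over AA20; uniform if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        if self.residue_class not in PHOSPHO_RESIDUES:
            raise ValueError("residue_class must be S, T or Y")
        if self.motifs:
            total = sum(m.weight for m in self.motifs)
            if not np.isclose(total, 1.0):
                raise ValueError(f"motif weights must sum to 1, got {total}")


@dataclass
class SyntheticDataset:
    positives: list[PeptideFragment]
    negatives: list[PeptideFragment]
    motif_of: dict[str, str]  # protein_id -> true motif name (generator truth)
    spec: DatasetSpec


def _draw_windows(
    rng: np.random.Generator, n: int, w: int, residue_class: str,
    background: np.ndarray | None,
) -> list[list[str]]:
    L = 2 * w + 1
    p = np.full(20, 1 / 20) if background is None else np.asarray(background, float)
    p = p / p.sum()
    letters = np.array(list(AA20))
    draws = rng.choice(20, size=(n, L), p=p)
    windows = letters[draws]
    windows[:, w] = residue_class
    return [list(row) for row in windows]


def _symbol_residue(
    rng: np.random.Generator, symbol: str, scheme: GroupScheme
) -> str:
    if symbol in GROUP_ORDER:
        members = sorted(scheme.groups[symbol])
        return members[int(rng.integers(len(members)))]
    if len(symbol) == 1 and symbol in AA20:
        return symbol
    raise ValueError(f"unknown plant symbol {symbol!r}")


def plant_motif(
    fragments: Sequence[PeptideFragment],
    spec: MotifSpec,
    seed: int = 0,
    scheme: GroupScheme = DEFAULT_SCHEME,
) -> list[PeptideFragment]:
    """Plant one motif into existing fragments, returning modified copies."""
    rng = np.random.default_rng(seed)
    out = []
    for frag in fragments:
        chars = list(frag.window)
        w = len(chars) // 2
        _plant_into(rng, chars, w, spec, scheme)
        out.append(
            PeptideFragment(frag.protein_id, frag.site_position,
                            frag.center_residue, "".join(chars), frag.label)
        )
    return out


def _plant_into(
    rng: np.random.Generator, chars: list[str], w: int,
    spec: MotifSpec, scheme: GroupScheme,
) -> bool:
    """Plant the motif's symbols in place; True if at least one symbol landed."""
    planted = False
    coupled = set(spec.coupling) if spec.coupling else set()
    if coupled:
        first = spec.coupling[0]
        prob = spec.plants[first][1]
        if rng.random() < prob:
            for pos in spec.coupling:
                chars[pos + w] = _symbol_residue(rng, spec.plants[pos][0], scheme)
            planted = True
    for pos, (symbol, prob) in spec.plants.items():
        if pos in coupled:
            continue
        if not -w <= pos <= w:
            raise ValueError(f"planted position {pos} outside the window")
        if rng.random() < prob:
            chars[pos + w] = _symbol_residue(rng, symbol, scheme)
            planted = True
    return planted


def generate_dataset(
    spec: DatasetSpec, scheme: GroupScheme = DEFAULT_SCHEME
) -> SyntheticDataset:
    """Draw the dataset: positives from the motif mixture, negatives background.

    Fully deterministic for a fixed spec and seed.  Each fragment poses
    as its own short protein (the window itself) so the full pipeline —
    FASTA in, predictions out — can run on simulated data.
    """
    rng = np.random.default_rng(spec.seed)
    positives: list[PeptideFragment] = []
    motif_of: dict[str, str] = {}
    pos_windows = _draw_windows(rng, spec.n_pos, spec.w, spec.residue_class, spec.background)
    if spec.motifs:
        weights = np.array([m.weight for m in spec.motifs])
        choices = rng.choice(len(spec.motifs), size=spec.n_pos, p=weights / weights.sum())
    else:
        choices = np.full(spec.n_pos, -1)
    for i, chars in enumerate(pos_windows):
        pid = f"pos{i:05d}"
        if choices[i] >= 0:
            motif = spec.motifs[int(choices[i])]
            planted = _plant_into(rng, chars, spec.w, motif, scheme)
            # truth records the realised state: a fragment whose plant
            # draws all missed is indistinguishable from background
            motif_of[pid] = motif.name if planted else "background"
        else:
            motif_of[pid] = "background"
        positives.append(
            PeptideFragment(pid, spec.w + 1, spec.residue_class, "".join(chars), POSITIVE)
        )
    negatives = [
        PeptideFragment(f"neg{i:05d}", spec.w + 1, spec.residue_class,
                        "".join(chars), NEGATIVE)
        for i, chars in enumerate(
            _draw_windows(rng, spec.n_neg, spec.w, spec.residue_class, spec.background)
        )
    ]
    return SyntheticDataset(positives=positives, negatives=negatives,
                            motif_of=motif_of, spec=spec)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Emit FASTA + sites TSV + fragment TSVs consumable by the training CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fa:
        for frag in ds.positives + ds.negatives:
            fa.write(f">{frag.protein_id}\n{frag.window}\n")
    with open(outdir / "sites.tsv", "w") as ts:
        ts.write("protein_id\tposition\tresidue\n")
        for frag in ds.positives:
            ts.write(f"{frag.protein_id}\t{frag.site_position}\t{frag.center_residue}\n")
    write_fragments_tsv(ds.positives, outdir / "positives.tsv")
    write_fragments_tsv(ds.negatives, outdir / "negatives.tsv")
    with open(outdir / "truth.tsv", "w") as th:
        th.write("protein_id\tmotif\n")
        for pid, name in ds.motif_of.items():
            th.write(f"{pid}\t{name}\n")


def spec_from_yaml(path: str | Path, seed: int | None = None) -> DatasetSpec:
    """Load a DatasetSpec from YAML; an explicit seed argument wins."""
    raw = yaml.safe_load(Path(path).read_text())
    motifs = [
        MotifSpec(
            name=m["name"],
            plants={int(p): (str(v[0]), float(v[1])) for p, v in m["plants"].items()},
            coupling=tuple(m["coupling"]) if m.get("coupling") else None,
            weight=float(m.get("weight", 1.0)),
        )
        for m in raw.get("motifs", [])
    ]
    background = raw.get("background")
    return DatasetSpec(
        n_pos=int(raw["n_pos"]),
        n_neg=int(raw["n_neg"]),
        w=int(raw.get("w", 10)),
        residue_class=str(raw.get("residue_class", "S")),
        motifs=motifs,
        background=None if background is None else np.asarray(background, float),
        seed=int(seed if seed is not None else raw.get("seed", 0)),
    )
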