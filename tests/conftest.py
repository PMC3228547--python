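import numpy as np
import pytest

from phosmdd.fragments import NEGATIVE, POSITIVE, PeptideFragment
from phosmdd.synthetic import DatasetSpec, MotifSpec, generate_dataset


def make_fragment(window: str, label: str = POSITIVE, pid: str = "P1", pos: int = 11):
    return PeptideFragment(
        protein_id=pid,
        site_position=pos,
        center_residue=window[len(window) // 2],
        window=window,
        label=label,
    )


def random_fragments(n: int, w: int = 10, seed: int = 0, center: str = "S"):
    """Uniform-background fragments with no planted structure."""
    spec = DatasetSpec(n_pos=n, n_neg=0, w=w, residue_class=center, seed=seed)
    return generate_dataset(spec).positives


@pytest.fixture
def toy_fasta(tmp_path):
    path = tmp_path / "proteins.fasta"
    path.write_text(">P1\nMKSAPLESD\n>P2\nTTYSPKRDE\n")
    return path


@pytest.fixture
def toy_sites(tmp_path):
    path = tmp_path / "sites.tsv"
    path.write_text("protein_id\tposition\tresidue\nP1\t3\tS\nP2\t3\tY\n")
    return path


@pytest.fixture
def coupled_dataset():
    """1000 positives, half carrying a planted imino(+1)/acid(+3) coupling."""
    spec = DatasetSpec(
        n_pos=1000,
        n_neg=500,
        seed=7,
        motifs=[MotifSpec("coupled", {1: ("P", 0.5), 3: ("acid", 0.5)}, coupling=(1, 3))],
    )
    return generate_dataset(spec)


@pytest.fixture
def strong_three_motif_dataset():
    """Three disjoint strong motifs, each with three positions at 0.9 consensus."""
    return generate_dataset(strong_three_motif_spec())


def strong_three_motif_spec(n_pos: int = 600, n_neg: int = 600, seed: int = 42):
    return DatasetSpec(
        n_pos=n_pos,
        n_neg=n_neg,
        seed=seed,
        motifs=[
            MotifSpec("proline", {1: ("P", 0.9), 2: ("P", 0.9), 3: ("P", 0.9)},
                      weight=1 / 3),
            MotifSpec("acidic", {4: ("D", 0.9), 5: ("E", 0.9), 6: ("D", 0.9)},
                      weight=1 / 3),
            MotifSpec("basic", {-3: ("K", 0.9), -4: ("R", 0.9), -5: ("K", 0.9)},
                      weight=1 / 3),
        ],
    )


def weighted_purity(clusters, truth: dict) -> float:
    """Fraction of fragments in their leaf's majority truth label."""
    total = sum(len(c.members) for c in clusters)
    correct = 0
    for c in clusters:
        labels = [truth[f.protein_id] for f in c.members]
        correct += max(labels.count(l) for l in set(labels))
    return correct / total
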