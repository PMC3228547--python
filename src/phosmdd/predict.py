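"""Scanning query proteins with the trained model ensemble.

Every S/T/Y residue of the requested class yields a window scored
against all models of that class.  A window is called a phosphosite when
at least one model scores it above that model's calibrated threshold; if
several models fire, the best-scoring one names the matched substrate
motif.  When no model fires the site is a non-site.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .fragments import PeptideFragment, ProteinRecord, window_at
from .profiles import ProfileModel, score_windows


@dataclass(frozen=True)
class PredictionRecord:
    protein_id: str
    position: int
    residue: str
    window: str
    best_cluster: str | None
    best_score: float
    decision: str  # "phosphosite" | "non-site"


def ensemble_scores(models: Sequence[ProfileModel], windows: Sequence[str]) -> np.ndarray:
    """(n_windows, n_models) bit-score matrix."""
    if not models:
        raise ValueError("model ensemble must be non-empty")
    return np.column_stack([score_windows(m, windows) for m in models])


def classify_window(
    models: Sequence[ProfileModel], window: str
) -> tuple[bool, str | None, float]:
    """Apply the at-least-one-model rule to a single window.

    Returns (is_phosphosite, best_cluster_id or None, best_score).  The
    best cluster is the highest-scoring model among those exceeding their
    thresholds, ties broken by cluster id order; when no model fires the
    best score is still reported (the overall maximum) with no cluster.
    """
    scores = ensemble_scores(models, [window])[0]
    return _decide(models, scores)


def _decide(
    models: Sequence[ProfileModel], scores: np.ndarray
) -> tuple[bool, str | None, float]:
    hits = [k for k, m in enumerate(models) if scores[k] > m.threshold_bits]
    if hits:
        top = max(scores[k] for k in hits)
        # score ties break by cluster id order
        best = min((k for k in hits if scores[k] == top),
                   key=lambda k: models[k].cluster_id)
        return True, models[best].cluster_id, float(scores[best])
    return False, None, float(scores.max())


def scan_protein(
    models: Sequence[ProfileModel],
    protein: ProteinRecord,
    residue_class: str | None = None,
    all_sites: bool = False,
) -> list[PredictionRecord]:
    """Score every residue of the class in one protein.

    Windows are extracted and X-padded exactly as during training.  By
    default only predicted phosphosites are reported; ``all_sites=True``
    reports every scanned residue with its decision.
    """
    if not models:
        raise ValueError("model ensemble must be non-empty")
    classes = {m.residue_class for m in models}
    if len(classes) != 1:
        raise ValueError(f"models span multiple residue classes: {sorted(classes)}")
    model_class = next(iter(classes))
    if residue_class is not None and residue_class != model_class:
        raise ValueError(f"models are for class {model_class}, not {residue_class}")
    cls = model_class
    w = models[0].w
    positions = [i + 1 for i, aa in enumerate(protein.sequence) if aa == cls]
    if not positions:
        return []
    windows = [window_at(protein.sequence, p, w) for p in positions]
    score_matrix = ensemble_scores(models, windows)
    records = []
    for p, win, scores in zip(positions, windows, score_matrix):
        is_site, cluster, score = _decide(models, scores)
        if is_site or all_sites:
            records.append(
                PredictionRecord(
                    protein_id=protein.id, position=p, residue=cls, window=win,
                    best_cluster=cluster, best_score=score,
                    decision="phosphosite" if is_site else "non-site",
                )
            )
    return records


def scan_proteins(
    models: Sequence[ProfileModel],
    proteins: Iterable[ProteinRecord],
    residue_class: str | None = None,
    all_sites: bool = False,
) -> list[PredictionRecord]:
    out: list[PredictionRecord] = []
    for protein in proteins:
        out.extend(scan_protein(models, protein, residue_class, all_sites))
    return out


def write_predictions_tsv(records: Iterable[PredictionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["protein_id", "position", "residue", "window",
             "best_cluster", "best_score", "decision"]
        )
        for r in records:
            writer.writerow(
                [r.protein_id, r.position, r.residue, r.window,
                 r.best_cluster or ".", f"{r.best_score:.4f}", r.decision]
            )
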