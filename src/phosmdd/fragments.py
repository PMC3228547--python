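"""Peptide-window extraction around annotated phosphorylation sites.

Proteins arrive as FASTA, experimentally verified sites as a three-column
TSV (protein id, 1-based position, residue).  Every S/T/Y residue of the
chosen class yields one fixed-width window centred on the site; annotated
residues become positives, all remaining residues of the class negatives.
Windows overhanging a protein terminus are padded with ``X`` so that all
fragments stay positionally aligned.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alphabet import PAD, PHOSPHO_RESIDUES

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class SiteAnnotation:
    """An experimentally verified phosphosite: protein, 1-based position, residue."""

    protein_id: str
    position: int
    residue: str


@dataclass(frozen=True)
class PeptideFragment:
    """A fixed-width window centred on an S/T/Y residue.

    ``site_position`` is the 1-based index of the centre residue in the
    source protein; ``window`` has length ``2w + 1`` with the centre at
    index ``w`` and ``X`` pads only at the extremities.
    """

    protein_id: str
    site_position: int
    center_residue: str
    window: str
    label: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.site_position)


class InputValidationError(ValueError):
    """Raised when a site annotation contradicts its protein sequence."""


def load_inputs(
    fasta_path: str | Path, sites_path: str | Path
) -> tuple[list[ProteinRecord], list[SiteAnnotation]]:
    """Read proteins (FASTA) and site annotations (TSV) and cross-validate them.

    Annotations referencing unknown proteins are dropped with a logged
    count; an annotation whose residue does not match the protein at the
    stated position raises :class:`InputValidationError`.  Duplicate
    annotations (same protein and position) collapse to one with a
    warning.
    """
    proteins: list[ProteinRecord] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen_ids:
            raise InputValidationError(f"duplicate protein id {rec.id!r} in {fasta_path}")
        seen_ids.add(rec.id)
        proteins.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not proteins:
        raise InputValidationError(f"no FASTA records found in {fasta_path}")

    by_id = {p.id: p for p in proteins}
    annotations: list[SiteAnnotation] = []
    seen_sites: set[tuple[str, int]] = set()
    dropped_orphans = 0
    with open(sites_path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in {"protein_id", "protein", "id"}:
                continue
            if len(row) < 3:
                raise InputValidationError(
                    f"{sites_path} line {lineno}: expected 3 columns, got {len(row)}"
                )
            pid, pos_str, residue = row[0].strip(), row[1].strip(), row[2].strip().upper()
            try:
                position = int(pos_str)
            except ValueError as exc:
                raise InputValidationError(
                    f"{sites_path} line {lineno}: position {pos_str!r} is not an integer"
                ) from exc
            if residue not in PHOSPHO_RESIDUES:
                raise InputValidationError(
                    f"{sites_path} line {lineno}: residue {residue!r} is not one of S/T/Y"
                )
            protein = by_id.get(pid)
            if protein is None:
                dropped_orphans += 1
                continue
            if not 1 <= position <= len(protein.sequence):
                raise InputValidationError(
                    f"annotation {pid}:{position} outside protein of length "
                    f"{len(protein.sequence)}"
                )
            actual = protein.sequence[position - 1]
            if actual != residue:
                raise InputValidationError(
                    f"annotation {pid}:{position} expects {residue} but protein has {actual}"
                )
            if (pid, position) in seen_sites:
                logger.warning("duplicate annotation %s:%d collapsed", pid, position)
                continue
            seen_sites.add((pid, position))
            annotations.append(SiteAnnotation(pid, position, residue))
    if dropped_orphans:
        logger.info("dropped %d annotation rows referencing unknown proteins", dropped_orphans)
    return proteins, annotations


def window_at(sequence: str, position: int, w: int) -> str:
    """Extract the ``2w+1`` window centred on 1-based ``position``, X-padded."""
    i = position - 1
    left = sequence[max(0, i - w) : i]
    right = sequence[i + 1 : i + 1 + w]
    return PAD * (w - len(left)) + left + sequence[i] + right + PAD * (w - len(right))


def extract_fragments(
    proteins: Iterable[ProteinRecord],
    sites: Iterable[SiteAnnotation],
    w: int = 10,
    residue_class: str = "S",
) -> tuple[list[PeptideFragment], list[PeptideFragment]]:
    """Extract labelled windows for one residue class.

    Returns one positive fragment per annotated site of the class and one
    negative fragment per unannotated residue of the class, in protein
    order then position order.
    """
    if w < 1:
        raise ValueError("half-window w must be >= 1")
    if residue_class not in PHOSPHO_RESIDUES:
        raise ValueError(f"residue_class must be one of S/T/Y, got {residue_class!r}")
    annotated = {
        (s.protein_id, s.position) for s in sites if s.residue == residue_class
    }
    positives: list[PeptideFragment] = []
    negatives: list[PeptideFragment] = []
    for protein in proteins:
        for i, aa in enumerate(protein.sequence):
            if aa != residue_class:
                continue
            position = i + 1
            label = POSITIVE if (protein.id, position) in annotated else NEGATIVE
            frag = PeptideFragment(
                protein_id=protein.id,
                site_position=position,
                center_residue=residue_class,
                window=window_at(protein.sequence, position, w),
                label=label,
            )
            (positives if label == POSITIVE else negatives).append(frag)
    return positives, negatives


def deduplicate(
    positives: Sequence[PeptideFragment], negatives: Sequence[PeptideFragment]
) -> tuple[list[PeptideFragment], list[PeptideFragment]]:
    """Remove fragments with identical window strings.

    Within each set the first occurrence is retained; a window present in
    both sets survives only in the positives, so the two outputs are
    disjoint as window strings.
    """
    pos_out: list[PeptideFragment] = []
    pos_windows: set[str] = set()
    for frag in positives:
        if frag.window not in pos_windows:
            pos_windows.add(frag.window)
            pos_out.append(frag)
    neg_out: list[PeptideFragment] = []
    neg_windows: set[str] = set()
    removed = 0
    for frag in negatives:
        if frag.window in pos_windows:
            removed += 1
            continue
        if frag.window not in neg_windows:
            neg_windows.add(frag.window)
            neg_out.append(frag)
    if removed:
        logger.info("removed %d negative fragments whose window also occurs in positives", removed)
    return pos_out, neg_out


def write_fragments_tsv(fragments: Iterable[PeptideFragment], path: str | Path) -> None:
    """Write the fragment exchange TSV: id, position, residue, window, label."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "position", "residue", "window", "label"])
        for f in fragments:
            writer.writerow([f.protein_id, f.site_position, f.center_residue, f.window, f.label])


def read_fragments_tsv(path: str | Path) -> list[PeptideFragment]:
    fragments: list[PeptideFragment] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            fragments.append(
                PeptideFragment(
                    protein_id=row[0],
                    site_position=int(row[1]),
                    center_residue=row[2],
                    window=row[3],
                    label=row[4],
                )
            )
    return fragments
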