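"""Residue importance scores (RIS) and interface evaluation.

A reconstructed peptide profile p* assigns a value to every gapped 5-mer
template.  After standardizing p* column-wise across a cohort of
reconstructions (e.g. leave-one-out RNA queries), each residue of an RBR is
scored by summing, over every template occurrence covering it, the template's
standardized value divided by the template's occurrence count in the RBR.
Residues covered by no 5-mer window keep score 0.  Against externally
supplied contact labels (residues within 5 A of RNA in a co-complex
structure) the score track is evaluated with AUROC and AUPR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from jple.featurize import PEPTIDE_K, RBR, WILDCARD, _window_templates
from jple.io import KmerMatrix


@dataclass
class ReconstructionSet:
    """A cohort of reconstructed peptide profiles (rows)."""

    matrix: KmerMatrix
    standardized: bool = False


def standardize_reconstructions(recon: ReconstructionSet) -> ReconstructionSet:
    """Column-wise z-scores (population sd); constant columns become 0."""
    values = np.asarray(recon.matrix.values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError(
            "cannot standardize a single reconstruction; pass the row "
            "unstandardized explicitly if that is intended"
        )
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant columns set to zero")
    z = np.where(constant, 0.0, (values - mu) / np.where(constant, 1.0, sd))
    out = KmerMatrix(list(recon.matrix.row_ids), list(recon.matrix.col_ids), z)
    return ReconstructionSet(out, standardized=True)


@dataclass
class ResidueImportance:
    """A per-residue score track over an RBR's concatenated segments."""

    rbr_sequence: str
    scores: np.ndarray
    occurrence_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.rbr_sequence),):
            raise ValueError("score track length does not match the sequence")


def residue_importance(
    p_star: Mapping[str, float] | Sequence[float],
    rbr: RBR,
    kmer_ids: Sequence[str] | None = None,
) -> ResidueImportance:
    """Distribute template values of p* onto the residues of an RBR.

    For each template with occurrence count c > 0 in the RBR, every
    occurrence adds p*_template / c to all five covered residue positions
    (the wildcard position included).  ``p_star`` is either a template ->
    value mapping or a vector aligned to ``kmer_ids``.
    """
    if len(rbr) == 0:
        raise ValueError("empty RBR")
    if not isinstance(p_star, Mapping):
        if kmer_ids is None:
            raise ValueError("a p* vector needs kmer_ids")
        if len(p_star) != len(kmer_ids):
            raise ValueError("p* length does not match kmer_ids")
        p_star = dict(zip(kmer_ids, np.asarray(p_star, dtype=float)))

    # occurrences[t] = list of (segment index, window start) covering t
    occurrences: dict[str, list[tuple[int, int]]] = {}
    for si, (seq, _) in enumerate(rbr.segments):
        for i in range(len(seq) - PEPTIDE_K + 1):
            window = seq[i : i + PEPTIDE_K]
            if WILDCARD in window:
                continue
            for t in _window_templates(window):
                occurrences.setdefault(t, []).append((si, i))

    seg_offsets = np.cumsum([0] + [len(seq) for seq, _ in rbr.segments[:-1]])
    scores = np.zeros(len(rbr))
    for t, occ in occurrences.items():
        value = p_star.get(t)
        if value is None or value == 0:
            continue
        per_occurrence = float(value) / len(occ)
        for si, i in occ:
            start = seg_offsets[si] + i
            scores[start : start + PEPTIDE_K] += per_occurrence
    counts = {t: len(occ) for t, occ in occurrences.items()}
    return ResidueImportance(rbr.sequence, scores, counts)


def interface_metrics(
    scores: ResidueImportance | Sequence[float],
    contact_labels: Sequence[int],
) -> tuple[float, float]:
    """(AUROC, AUPR) of a residue score track against binary contact labels.

    AUROC is rank-based with ties averaged; AUPR is average precision.
    Both classes must be present.
    """
    track = scores.scores if isinstance(scores, ResidueImportance) else scores
    track = np.asarray(track, dtype=float)
    labels = np.asarray(contact_labels)
    if track.shape != labels.shape:
        raise ValueError("labels and scores have different lengths")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    if len(np.unique(labels)) < 2:
        raise ValueError("both contact classes must be present")
    return (
        float(roc_auc_score(labels, track)),
        float(average_precision_score(labels, track)),
    )
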