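"""Motif utilities: specifically-bound 7-mer calls, the top-10 7-mer position
frequency matrix, PSAM conversion, and PSAM scanning of RNA sequences.

A 7-mer is called specifically bound when its Z-score's upper-tail normal
p-value survives a Bonferroni correction at the requested family-wise error
rate (default 1%).  The PFM is built by greedily stacking the top-n 7-mers
without gaps: each next 7-mer is placed at the ungapped offset maximizing
identity to the running consensus.  PSAMs rescale each PFM column to a
maximum of 1, so a sequence window's score is a product of per-position
affinities with maximum possible score 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from jple.featurize import RNA_BASES, RNABindingProfile

_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}


@dataclass
class PFM:
    """A position frequency matrix over ACGU; ``columns`` is width x 4 and
    each column sums to 1; ``support`` counts the 7-mers covering each
    column."""

    columns: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("PFM columns must be width x 4")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PFM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RNA_BASES[int(j)] for j in self.columns.argmax(axis=1))


@dataclass
class PSAM:
    """A position-specific affinity matrix: every column's maximum is 1."""

    columns: np.ndarray

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("PSAM columns must be width x 4")
        if not np.allclose(self.columns.max(axis=1), 1.0):
            raise ValueError("PSAM columns must have maximum 1")

    @property
    def width(self) -> int:
        return self.columns.shape[0]


def specific_7mers(profile: RNABindingProfile, fwer: float = 0.01) -> set[str]:
    """7-mers whose upper-tail Z-test p-value is <= fwer / vocabulary size."""
    if not (0 < fwer < 1):
        raise ValueError("fwer must be in (0, 1)")
    cutoff = norm.isf(fwer / len(profile.kmer_ids))
    return {k for k, z in zip(profile.kmer_ids, profile.z) if z >= cutoff}


def top_kmers(profile: RNABindingProfile, n: int) -> list[str]:
    """The n highest-Z 7-mers, ties broken lexicographically."""
    order = sorted(
        range(len(profile.kmer_ids)),
        key=lambda i: (-profile.z[i], profile.kmer_ids[i]),
    )
    return [profile.kmer_ids[i] for i in order[:n]]


def pfm_from_top_kmers(profile: RNABindingProfile, top_n: int = 10) -> PFM:
    """Ungapped greedy alignment of the top-n 7-mers into a PFM.

    The rank-1 7-mer seeds the alignment; every further 7-mer, in rank
    order, is placed at the offset (within +/-6 of the seed) maximizing
    identity to the running consensus, ties to the smaller absolute offset
    and then to the negative offset.  Columns are normalized by their
    coverage (number of placed 7-mers overlapping the column).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    kmers = top_kmers(profile, top_n)
    k = len(kmers[0])
    span = 3 * k - 2  # offsets -(k-1) .. +(k-1) relative to the seed
    counts = np.zeros((span, 4))
    coverage = np.zeros(span, dtype=int)
    origin = k - 1  # seed start within the working frame

    def place(kmer: str, offset: int) -> None:
        for i, b in enumerate(kmer):
            counts[origin + offset + i, _BASE_INDEX[b]] += 1
            coverage[origin + offset + i] += 1

    place(kmers[0], 0)
    for kmer in kmers[1:]:
        best: tuple[int, int, int] | None = None  # (-identity, |off|, off)
        for off in range(-(k - 1), k):
            identity = 0
            for i, b in enumerate(kmer):
                col = origin + off + i
                if coverage[col] == 0:
                    continue
                consensus = int(counts[col].argmax())
                if _BASE_INDEX[b] == consensus:
                    identity += 1
            key = (-identity, abs(off), off)
            if best is None or key < best:
                best = key
        place(kmer, best[2])
    occupied = coverage > 0
    freqs = counts[occupied] / coverage[occupied, None]
    return PFM(freqs, coverage[occupied])


def psam_from_pfm(pfm: PFM) -> PSAM:
    """Divide each PFM column by its maximum entry."""
    maxima = pfm.columns.max(axis=1)
    if np.any(maxima == 0):
        raise ValueError("PFM has an all-zero column")
    return PSAM(pfm.columns / maxima[:, None])


def scan_binding_score(
    psam: PSAM, sequence: str, threshold_frac: float = 0.1
) -> float:
    """Sum of sliding-window PSAM scores exceeding ``threshold_frac`` of the
    maximum possible window score (which is 1 for a max-normalized PSAM).

    A sequence shorter than the motif scores 0 with a warning.  Windows with
    characters outside ACGU (after T->U) score 0.
    """
    seq = sequence.upper().replace("T", "U")
    w = psam.width
    if len(seq) < w:
        warnings.warn("sequence shorter than the motif; binding score 0")
        return 0.0
    total = 0.0
    for i in range(len(seq) - w + 1):
        score = 1.0
        for j in range(w):
            base = _BASE_INDEX.get(seq[i + j])
            if base is None:
                score = 0.0
                break
            score *= psam.columns[j, base]
        if score > threshold_frac:
            total += score
    return total
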