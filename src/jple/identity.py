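"""Amino-acid sequence identity: global affine-gap alignment, domain-aware
RBR identity, the 70% homology-transfer rule, and MSA-based identities.

Pairwise identity uses Needleman-Wunsch global alignment with BLOSUM62 and
affine gap penalties (open 11, extend 1; a gap of length L costs
11 + (L - 1)).  Because co-optimal alignments can disagree on identity, the
optimization is fully tie-broken: maximize score, then match count, then
prefer fewer alignment columns.  Identity is exact matches divided by the
alignment length (default) or by the shorter sequence length.

RBR-level identity aligns each RNA-binding domain (with flanks) of one
protein to the corresponding domain of the other.  With equal domain counts
the per-pair identities are averaged; with unequal counts every contiguous
placement of the shorter protein's domains onto the longer's is scored and
the maximum mean identity is returned (adjacent domains stay adjacent,
accounting for domain gain/loss during evolution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from jple.featurize import RBR
from jple.io import DomainAnnotation, ProteinRecord

GAP_OPEN = 11
GAP_EXTEND = 1

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID = set("ACDEFGHIKLMNPQRSTVWYX")

# Lexicographic objective (score, matches, -columns) packed into one integer;
# per-step contributions are additive, so Bellman recursion applies.  Field
# widths: columns and matches < 1024 each; a unit score difference (2^20)
# dominates any match/column difference.
_MATCH_UNIT = 1 << 10
_SCORE_UNIT = 1 << 20
_MAX_LEN = 1000


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with gap characters, its score, and identity."""

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    matches: int

    def __post_init__(self) -> None:
        if self.aligned_a.replace("-", "") == "" or len(self.aligned_a) != len(
            self.aligned_b
        ):
            raise ValueError("malformed alignment")


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name}: invalid residues {sorted(bad)}")


def nw_identity(
    a: str,
    b: str,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> AlignmentResult:
    """Global BLOSUM62 alignment (gap open 11, extend 1) of two sequences.

    Gotoh's three-state dynamic program; end gaps are penalized (true global
    alignment).  See the module docstring for the tie-breaking rules that
    make the reported identity deterministic.
    """
    a, b = a.upper(), b.upper()
    _check_sequence(a, "a")
    _check_sequence(b, "b")
    if len(a) >= _MAX_LEN or len(b) >= _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} not supported")
    n, m = len(a), len(b)
    NEG = -(1 << 50)

    def step(score: int, match: int) -> int:
        # packed contribution of one alignment column
        return score * _SCORE_UNIT + match * _MATCH_UNIT - 1

    OPEN = step(-GAP_OPEN, 0)
    EXT = step(-GAP_EXTEND, 0)
    sub = [[int(_BLOSUM62[ca][cb]) for cb in b] for ca in a]
    eq = [[ca == cb for cb in b] for ca in a]

    # States: M diag (a[i-1] with b[j-1]); X gap in b (consumes a);
    # Y gap in a (consumes b).  bt_* record the predecessor state (0/1/2
    # for M/X/Y) with tie priority M > X > Y; value ties are harmless
    # because the packed objective already fixes score, matches, columns.
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    bt_M = [[0] * (m + 1) for _ in range(n + 1)]
    bt_X = [[0] * (m + 1) for _ in range(n + 1)]
    bt_Y = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = (M[0][0] + OPEN) if i == 1 else (X[i - 1][0] + EXT)
        bt_X[i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0][j] = (M[0][0] + OPEN) if j == 1 else (Y[0][j - 1] + EXT)
        bt_Y[0][j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        bMi, bXi, bYi = bt_M[i], bt_X[i], bt_Y[i]
        subi, eqi = sub[i - 1], eq[i - 1]
        for j in range(1, m + 1):
            cands = (Mp[j - 1], Xp[j - 1], Yp[j - 1])
            best = max(cands)
            if best > NEG:
                Mi[j] = best + step(subi[j - 1], 1 if eqi[j - 1] else 0)
                bMi[j] = cands.index(best)

            cands = (Mp[j] + OPEN, Xp[j] + EXT, Yp[j] + OPEN)
            best = max(cands)
            Xi[j] = best
            bXi[j] = cands.index(best)

            cands = (Mi[j - 1] + OPEN, Xi[j - 1] + OPEN, Yi[j - 1] + EXT)
            best = max(cands)
            Yi[j] = best
            bYi[j] = cands.index(best)

    finals = (M[n][m], X[n][m], Y[n][m])
    packed = max(finals)
    state = finals.index(packed)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = bt_M[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = bt_X[i][j]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = bt_Y[i][j]
            j -= 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    cols = len(aligned_a)
    v = (packed + cols) // _MATCH_UNIT  # = score * 2^10 + matches
    matches = int(v % (_SCORE_UNIT // _MATCH_UNIT))
    score = (v - matches) // (_SCORE_UNIT // _MATCH_UNIT)
    denom = cols if denominator == "alignment" else min(n, m)
    return AlignmentResult(
        aligned_a, aligned_b, float(score), matches / denom, matches
    )


def domain_units(
    protein: ProteinRecord,
    domains: Sequence[DomainAnnotation],
    flank: int = 15,
) -> list[tuple[str, str]]:
    """Per-domain (class, flank-extended subsequence) units, unmerged and in
    domain order — the inputs to domain-aware RBR identity."""
    mine = sorted(
        (d for d in domains if d.protein_id == protein.id),
        key=lambda d: (d.start, d.end),
    )
    if not mine:
        raise ValueError(f"no RBDs for protein {protein.id!r}")
    n = len(protein.sequence)
    out = []
    for d in mine:
        a = max(0, d.start - 1 - flank)
        b = min(n, d.end + flank)
        out.append((d.domain_class, protein.sequence[a:b]))
    return out


def rbr_sid(
    units_a: Sequence[tuple[str, str]],
    units_b: Sequence[tuple[str, str]],
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> float:
    """Domain-aware amino-acid sequence identity between two RBRs.

    ``units_*`` are (domain class, sequence) lists from :func:`domain_units`.
    Equal domain counts: mean per-pair identity.  Unequal: maximum over
    contiguous placements of the shorter list onto the longer.  Domain
    classes must match at every aligned pair of a placement.
    """
    if not units_a or not units_b:
        raise ValueError("both RBRs need at least one domain")
    short, long_ = (units_a, units_b) if len(units_a) <= len(units_b) else (
        units_b, units_a
    )
    best = None
    for offset in range(len(long_) - len(short) + 1):
        pairs = list(zip(short, long_[offset : offset + len(short)]))
        if any(ca != cb for (ca, _), (cb, _) in pairs):
            continue
        mean_sid = float(
            np.mean(
                [nw_identity(sa, sb, denominator).identity
                 for (_, sa), (_, sb) in pairs]
            )
        )
        if best is None or mean_sid > best:
            best = mean_sid
    if best is None:
        raise ValueError("incompatible domain classes at every placement")
    return best


def infer_by_sid(
    query_units: Sequence[tuple[str, str]],
    reference_set: Sequence[tuple[Sequence[tuple[str, str]], object]],
    min_sid: float = 0.70,
    denominator: Literal["alignment", "shorter"] = "alignment",
) -> tuple[object, float, bool]:
    """Motif transfer from the highest-identity reference RBP (the 70% rule).

    ``reference_set`` holds (domain units, RNA-binding profile) pairs.
    Returns (profile of the best reference, its SID, SID >= min_sid).
    Exact SID ties go to the earlier reference, with a warning.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    sids = [rbr_sid(query_units, units, denominator) for units, _ in reference_set]
    best = int(np.argmax(sids))
    if sids.count(sids[best]) > 1:
        warnings.warn("SID tie between references; keeping the first")
    return reference_set[best][1], sids[best], sids[best] >= min_sid


def msa_sid(msa: Sequence[str]) -> np.ndarray:
    """Pairwise identity matrix from an MSA block.

    Identity of a pair is the number of columns where both rows have the
    same non-gap residue, divided by the alignment length.  The diagonal is
    1 by convention.
    """
    if not msa:
        raise ValueError("empty MSA")
    lengths = {len(row) for row in msa}
    if len(lengths) > 1:
        raise ValueError("ragged MSA rows")
    L = lengths.pop()
    if L == 0:
        raise ValueError("zero-length MSA")
    arr = np.frombuffer("".join(msa).encode(), dtype=np.uint8).reshape(len(msa), L)
    gap = ord("-")
    n = len(msa)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != gap) & (arr[j] != gap)
            matches = int(np.count_nonzero(both & (arr[i] == arr[j])))
            out[i, j] = out[j, i] = matches / L
    return out
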