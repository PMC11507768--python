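"""The joint protein-ligand embedding model.

The model is a linear auto-encoder over joint vectors that concatenate a
peptide profile block P and an RNA-binding profile block R.  After dropping
zero-variance columns, centring each column and scaling it to unit Euclidean
norm, the SVD of the concatenation [P R] = U S V^T is computed and components
are ranked by their contribution to the variance of the RNA block,

    s_i = sigma_i^2 * ||v_{R,i}||^2,    sum_i s_i = tr(R R^T),

rather than to the joint variance as in ordinary PCA.  The top-d components
by this score form the retained basis (V'_P stacked over V'_R), and the rows
of W = U' S' are the training embeddings.

Queries project a preprocessed peptide (or RNA) profile onto the retained
basis by least squares, measure the cosine distance in embedding space to
every training embedding (the e-dist), and reconstruct the missing block
either globally (linear decode, V'_block w + column rescaling + mean) or
locally (RBF-kernel weighted average of the raw training profiles of the
embedding neighborhood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.linalg

from jple.featurize import (
    RBR,
    PeptideProfile,
    RNABindingProfile,
    count_templates,
    _window_templates,
    PEPTIDE_K,
    WILDCARD,
)
from jple.io import KmerMatrix

DEFAULT_GAMMA = 25.0
DEFAULT_NBH_THRESHOLD = 0.01
DEFAULT_CONF_CUTOFF = 0.127
DEFAULT_PCC_MIN = 0.95


@dataclass
class TrainingMatrices:
    """Preprocessed training blocks plus the statistics to reuse at query
    time.  Kept columns have mean 0 and unit norm; ``mu_*`` store the raw
    means of *all* raw columns (dropped columns decode to their mean)."""

    P: np.ndarray
    R: np.ndarray
    kept_P: np.ndarray
    kept_R: np.ndarray
    mu_P: np.ndarray
    mu_R: np.ndarray
    norm_P: np.ndarray
    norm_R: np.ndarray
    row_ids: list[str]
    col_ids_P: list[str]
    col_ids_R: list[str]


def _preprocess_block(raw: np.ndarray):
    kept = np.ptp(raw, axis=0) > 0
    mu = raw.mean(axis=0)
    centered = raw[:, kept] - mu[kept]
    norms = np.linalg.norm(centered, axis=0)
    return centered / norms, kept, mu, norms


def preprocess(P_raw: KmerMatrix, R_raw: KmerMatrix) -> TrainingMatrices:
    """Drop zero-variance columns, centre, and scale columns to unit norm."""
    if P_raw.row_ids != R_raw.row_ids:
        raise ValueError("P and R must have identical row ids in order")
    if len(P_raw.row_ids) < 2:
        raise ValueError("need at least 2 training rows")
    P, kept_P, mu_P, norm_P = _preprocess_block(P_raw.values)
    R, kept_R, mu_R, norm_R = _preprocess_block(R_raw.values)
    if P.shape[1] == 0 or R.shape[1] == 0:
        raise ValueError("all columns of a block have zero variance")
    return TrainingMatrices(
        P, R, kept_P, kept_R, mu_P, mu_R, norm_P, norm_R,
        list(P_raw.row_ids), list(P_raw.col_ids), list(R_raw.col_ids),
    )


def _row_pcc(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = np.linalg.norm(Ac, axis=1) * np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def select_dimension(R: np.ndarray, pcc_min: float = DEFAULT_PCC_MIN) -> int:
    """Smallest rank d whose SVD reconstruction of R gives every training row
    a Pearson correlation >= ``pcc_min`` with its original; rank(R) with a
    warning if the target is never reached."""
    if not (0 < pcc_min <= 1):
        raise ValueError("pcc_min must be in (0, 1]")
    U, S, Vt = np.linalg.svd(np.asarray(R, dtype=float), full_matrices=False)
    tol = S[0] * max(R.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    recon = np.zeros_like(np.asarray(R, dtype=float))
    for d in range(1, rank + 1):
        recon += S[d - 1] * np.outer(U[:, d - 1], Vt[d - 1])
        if _row_pcc(R, recon).min() >= pcc_min:
            return d
    warnings.warn(
        f"minimum per-row PCC {pcc_min} not reached; returning rank {rank}"
    )
    return rank


@dataclass
class JointModel:
    """A fitted model: retained singular system, training embeddings, and the
    preprocessing statistics needed to transform and decode queries."""

    Vp: np.ndarray          # kept-P columns x d
    Vr: np.ndarray          # kept-R columns x d
    S: np.ndarray           # d retained singular values
    W: np.ndarray           # n x d training embeddings (U' S')
    d: int
    scores: np.ndarray      # variance-of-R contribution of every component
    gamma: float
    nbh_threshold: float
    conf_cutoff: float
    row_ids: list[str]
    col_ids_P: list[str]
    col_ids_R: list[str]
    kept_P: np.ndarray
    kept_R: np.ndarray
    mu_P: np.ndarray
    mu_R: np.ndarray
    norm_P: np.ndarray
    norm_R: np.ndarray
    R_raw: np.ndarray | None = None  # raw training RNA profiles (local decoder)

    def equals(self, other: "JointModel") -> bool:
        """Field-by-field equality with bit-exact array comparison."""
        def eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(np.asarray(a), np.asarray(b))

        return (
            self.d == other.d
            and self.gamma == other.gamma
            and self.nbh_threshold == other.nbh_threshold
            and self.conf_cutoff == other.conf_cutoff
            and list(self.row_ids) == list(other.row_ids)
            and list(self.col_ids_P) == list(other.col_ids_P)
            and list(self.col_ids_R) == list(other.col_ids_R)
            and all(
                eq(getattr(self, f), getattr(other, f))
                for f in ("Vp", "Vr", "S", "W", "scores", "kept_P", "kept_R",
                          "mu_P", "mu_R", "norm_P", "norm_R", "R_raw")
            )
        )


@dataclass
class Embedding:
    """A point in the retained latent space."""

    w: np.ndarray
    source: Literal["protein", "rna", "joint"]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite embedding")


@dataclass
class QueryResult:
    embedding: Embedding
    edists: np.ndarray
    esims: np.ndarray
    neighborhood: list[str]
    reconstruction: np.ndarray
    reconstruction_cols: list[str]
    min_edist: float
    confident: bool


def fit_joint(tm: TrainingMatrices, d: int) -> JointModel:
    """SVD of [P R]; retain the top-d components by RNA-variance score.

    Ties in the score are broken by original singular-value order, and each
    retained component's sign is fixed so the largest-magnitude entry of its
    right singular vector is positive (deterministic output).
    """
    P, R = tm.P, tm.R
    p = P.shape[1]
    J = np.concatenate([P, R], axis=1)
    U, S, Vt = np.linalg.svd(J, full_matrices=False)
    tol = S[0] * max(J.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if not (1 <= d <= rank):
        raise ValueError(f"d={d} outside [1, rank={rank}]")
    scores = S**2 * np.linalg.norm(Vt[:, p:], axis=1) ** 2
    order = np.argsort(-scores[:rank], kind="stable")
    sel = order[:d]
    V_sel = Vt[sel].T.copy()          # (p+r) x d
    U_sel = U[:, sel].copy()
    for j in range(d):
        i_max = int(np.argmax(np.abs(V_sel[:, j])))
        if V_sel[i_max, j] < 0:
            V_sel[:, j] *= -1
            U_sel[:, j] *= -1
    S_sel = S[sel]
    return JointModel(
        Vp=V_sel[:p],
        Vr=V_sel[p:],
        S=S_sel,
        W=U_sel * S_sel,
        d=d,
        scores=scores,
        gamma=DEFAULT_GAMMA,
        nbh_threshold=DEFAULT_NBH_THRESHOLD,
        conf_cutoff=DEFAULT_CONF_CUTOFF,
        row_ids=list(tm.row_ids),
        col_ids_P=list(tm.col_ids_P),
        col_ids_R=list(tm.col_ids_R),
        kept_P=tm.kept_P,
        kept_R=tm.kept_R,
        mu_P=tm.mu_P,
        mu_R=tm.mu_R,
        norm_P=tm.norm_P,
        norm_R=tm.norm_R,
    )


def fit(
    P_raw: KmerMatrix,
    R_raw: KmerMatrix,
    d: int | None = None,
    pcc_min: float = DEFAULT_PCC_MIN,
    gamma: float = DEFAULT_GAMMA,
    nbh_threshold: float = DEFAULT_NBH_THRESHOLD,
    conf_cutoff: float = DEFAULT_CONF_CUTOFF,
) -> JointModel:
    """Preprocess, pick the dimension from the RNA block (unless given), fit
    the joint SVD, and attach the raw RNA profiles for local decoding."""
    tm = preprocess(P_raw, R_raw)
    if d is None:
        d = select_dimension(tm.R, pcc_min=pcc_min)
    model = fit_joint(tm, d)
    model.gamma = gamma
    model.nbh_threshold = nbh_threshold
    model.conf_cutoff = conf_cutoff
    model.R_raw = np.array(R_raw.values, dtype=float)
    return model


# ---------------------------------------------------------------------------
# Encoders


def _query_vector(
    raw: Mapping[str, float] | np.ndarray,
    col_ids: Sequence[str],
    kept: np.ndarray,
    mu: np.ndarray,
    norm: np.ndarray,
    what: str,
) -> np.ndarray:
    """Align a raw query onto the training vocabulary and apply the stored
    mask -> centre -> scale transform."""
    if isinstance(raw, Mapping):
        index = {c: j for j, c in enumerate(col_ids)}
        x = np.zeros(len(col_ids))
        unseen = []
        hit = False
        for key, val in raw.items():
            j = index.get(key)
            if j is None:
                unseen.append(key)
            else:
                x[j] = val
                hit = True
        if unseen:
            warnings.warn(
                f"{len(unseen)} {what} features outside the training "
                f"vocabulary ignored"
            )
        if not hit:
            raise ValueError(
                f"empty {what} profile after masking to the training vocabulary"
            )
    else:
        x = np.asarray(raw, dtype=float)
        if x.shape != (len(col_ids),):
            raise ValueError(
                f"{what} vector length {x.shape} does not match vocabulary "
                f"({len(col_ids)})"
            )
    return (x[kept] - mu[kept]) / norm


def embed_protein(
    p_raw: PeptideProfile | Mapping[str, float] | np.ndarray, model: JointModel
) -> Embedding:
    """Least-squares projection of a preprocessed peptide profile onto V'_P.

    Uses a minimum-norm solve, so rank-deficient normal equations (possible
    on small training sets) are handled without forming an inverse.
    """
    if isinstance(p_raw, PeptideProfile):
        p_raw = p_raw.as_dict()
    x = _query_vector(
        p_raw, model.col_ids_P, model.kept_P, model.mu_P, model.norm_P, "peptide"
    )
    w, *_ = scipy.linalg.lstsq(model.Vp, x)
    return Embedding(w, "protein")


def embed_rna(
    r_raw: RNABindingProfile | Mapping[str, float] | np.ndarray, model: JointModel
) -> Embedding:
    """Least-squares projection of a preprocessed RNA profile onto V'_R."""
    if isinstance(r_raw, RNABindingProfile):
        r_raw = dict(zip(r_raw.kmer_ids, r_raw.z))
    x = _query_vector(
        r_raw, model.col_ids_R, model.kept_R, model.mu_R, model.norm_R, "RNA"
    )
    w, *_ = scipy.linalg.lstsq(model.Vr, x)
    return Embedding(w, "rna")


# ---------------------------------------------------------------------------
# Distances and decoders


def e_dist(w1: Embedding | np.ndarray, w2: Embedding | np.ndarray) -> float:
    """Cosine distance between embeddings, in [0, 2].  A zero vector has
    distance 1 to everything (neutral, never confident), with a warning."""
    a = w1.w if isinstance(w1, Embedding) else np.asarray(w1, dtype=float)
    b = w2.w if isinstance(w2, Embedding) else np.asarray(w2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"embedding dimensions differ: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine distance to a zero embedding defined as 1")
        return 1.0
    return float(1.0 - a @ b / (na * nb))


def _edists_to_training(w: np.ndarray, W: np.ndarray) -> np.ndarray:
    nw = np.linalg.norm(w)
    nW = np.linalg.norm(W, axis=1)
    if nw == 0:
        warnings.warn("cosine distance to a zero embedding defined as 1")
        return np.ones(W.shape[0])
    zero = nW == 0
    if zero.any():
        warnings.warn("cosine distance to a zero embedding defined as 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - (W @ w) / (nW * nw)
    return np.where(zero, 1.0, d)


def decode_global(
    w: Embedding | np.ndarray,
    model: JointModel,
    block: Literal["rna", "peptide"] = "rna",
) -> np.ndarray:
    """Linear decode V'_block w on the raw column scale.

    The centred/unit-norm decode is multiplied by the stored column norms and
    the column means are added back; dropped (zero-variance) columns decode
    to their training mean.
    """
    wv = w.w if isinstance(w, Embedding) else np.asarray(w, dtype=float)
    if block == "rna":
        V, kept, mu, norm, cols = (
            model.Vr, model.kept_R, model.mu_R, model.norm_R, model.col_ids_R
        )
    elif block == "peptide":
        V, kept, mu, norm, cols = (
            model.Vp, model.kept_P, model.mu_P, model.norm_P, model.col_ids_P
        )
    else:
        raise ValueError("block must be 'rna' or 'peptide'")
    out = np.array(mu, dtype=float)
    out[kept] = (V @ wv) * norm + mu[kept]
    return out


def decode_local(
    w: Embedding | np.ndarray,
    model: JointModel,
    R_train_raw: KmerMatrix | np.ndarray | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """RBF-kernel weighted average of raw training RNA profiles.

    e-sim = exp(-gamma e-dist^2); the neighborhood is every training protein
    with e-sim >= the threshold; weights are normalized e-sims.  An empty
    neighborhood decodes to the zero vector (flagged by the caller).

    Returns (reconstruction, neighborhood ids, edists, esims).
    """
    wv = w.w if isinstance(w, Embedding) else np.asarray(w, dtype=float)
    if R_train_raw is None:
        if model.R_raw is None:
            raise ValueError("local decoding needs the raw training RNA profiles")
        R = model.R_raw
    elif isinstance(R_train_raw, KmerMatrix):
        if R_train_raw.row_ids != model.row_ids:
            raise ValueError("R_train_raw rows do not match the model")
        R = R_train_raw.values
    else:
        R = np.asarray(R_train_raw, dtype=float)
    edists = _edists_to_training(wv, model.W)
    esims = np.exp(-model.gamma * edists**2)
    in_nbh = esims >= model.nbh_threshold
    if not in_nbh.any():
        return np.zeros(R.shape[1]), [], edists, esims
    wts = esims[in_nbh] / esims[in_nbh].sum()
    recon = wts @ R[in_nbh]
    ids = [model.row_ids[i] for i in np.flatnonzero(in_nbh)]
    return recon, ids, edists, esims


# ---------------------------------------------------------------------------
# Queries


def protein_query(
    p_raw: PeptideProfile | Mapping[str, float] | np.ndarray,
    model: JointModel,
    decoder: Literal["local", "global"] = "local",
) -> QueryResult:
    """Embed a peptide profile and reconstruct its RNA-binding profile.

    The result is confident when the minimum e-dist to a training embedding
    is below the model's confidence cutoff.
    """
    emb = embed_protein(p_raw, model)
    if decoder == "local":
        recon, nbh, edists, esims = decode_local(emb, model)
    elif decoder == "global":
        edists = _edists_to_training(emb.w, model.W)
        esims = np.exp(-model.gamma * edists**2)
        nbh = [model.row_ids[i]
               for i in np.flatnonzero(esims >= model.nbh_threshold)]
        recon = decode_global(emb, model, "rna")
    else:
        raise ValueError("decoder must be 'local' or 'global'")
    min_edist = float(edists.min())
    return QueryResult(
        embedding=emb,
        edists=edists,
        esims=esims,
        neighborhood=nbh,
        reconstruction=recon,
        reconstruction_cols=list(model.col_ids_R),
        min_edist=min_edist,
        confident=bool(min_edist < model.conf_cutoff and len(nbh) > 0),
    )


def rna_query(
    r_raw: RNABindingProfile | Mapping[str, float] | np.ndarray,
    model: JointModel,
) -> QueryResult:
    """Embed an RNA-binding profile and globally decode the peptide block,
    giving the reconstructed peptide profile p* on the raw count scale."""
    emb = embed_rna(r_raw, model)
    edists = _edists_to_training(emb.w, model.W)
    esims = np.exp(-model.gamma * edists**2)
    nbh = [model.row_ids[i] for i in np.flatnonzero(esims >= model.nbh_threshold)]
    recon = decode_global(emb, model, "peptide")
    min_edist = float(edists.min())
    return QueryResult(
        embedding=emb,
        edists=edists,
        esims=esims,
        neighborhood=nbh,
        reconstruction=recon,
        reconstruction_cols=list(model.col_ids_P),
        min_edist=min_edist,
        confident=bool(min_edist < model.conf_cutoff),
    )


# ---------------------------------------------------------------------------
# Homolog-augmented peptide representations


def augmented_template_counts(alignment: Sequence[str]) -> dict[str, float]:
    """Gapped 5-mer template weights from an aligned homolog block.

    All rows must have equal length (gapped, aligned against one training
    RBR).  At each alignment window start, windows containing a gap or an
    unknown residue are skipped; each *distinct* remaining 5-mer contributes
    weight 1 / (number of distinct 5-mers at that position) to its five
    wildcard templates, so a position's total weight is 1 and duplicated
    homologs do not inflate the profile.
    """
    lengths = {len(row) for row in alignment}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    counts: dict[str, float] = {}
    if not alignment:
        return counts
    L = lengths.pop()
    for j in range(L - PEPTIDE_K + 1):
        windows = []
        for row in alignment:
            win = row[j : j + PEPTIDE_K]
            if "-" in win or WILDCARD in win:
                continue
            windows.append(win)
        distinct = sorted(set(windows))
        if not distinct:
            continue
        weight = 1.0 / len(distinct)
        for win in distinct:
            for t in _window_templates(win):
                counts[t] = counts.get(t, 0.0) + weight
    return counts


@dataclass
class AugmentationEntry:
    """Homolog alignment blocks for one training construct.

    ``blocks`` is a list of gapped alignment blocks (one per RBR segment, or
    a single block against the concatenated RBR); the caller enforces the
    homolog identity band (50-99% by default in the published pipeline).
    ``rbr`` is the fallback when no homolog is available.
    """

    row_id: str
    blocks: list[list[str]]
    rbr: RBR | None = None


def build_augmented_profiles(entries: Sequence[AugmentationEntry]) -> KmerMatrix:
    """Stack homolog-augmented peptide representations P+ for a training set."""
    per_row: list[dict[str, float]] = []
    for entry in entries:
        counts: dict[str, float] = {}
        n_rows = sum(len(b) for b in entry.blocks)
        if n_rows == 0:
            if entry.rbr is None:
                raise ValueError(
                    f"{entry.row_id}: no homologs and no fallback RBR"
                )
            warnings.warn(
                f"{entry.row_id}: no homologs; using its own peptide profile"
            )
            counts = count_templates(entry.rbr)
        else:
            for block in entry.blocks:
                for t, c in augmented_template_counts(block).items():
                    counts[t] = counts.get(t, 0.0) + c
        per_row.append(counts)
    vocab = sorted(set().union(*[set(c) for c in per_row]) if per_row else set())
    values = np.zeros((len(entries), len(vocab)))
    index = {t: j for j, t in enumerate(vocab)}
    for i, counts in enumerate(per_row):
        for t, c in counts.items():
            values[i, index[t]] = c
    return KmerMatrix([e.row_id for e in entries], vocab, values)


# ---------------------------------------------------------------------------
# Cross-validation driver


def loocv_rna_queries(
    P_raw: KmerMatrix,
    R_raw: KmerMatrix,
    d: int | None = None,
    pcc_min: float = DEFAULT_PCC_MIN,
) -> KmerMatrix:
    """Reconstructed peptide profiles p* for every training row by
    leave-one-out RNA queries (the cohort used to standardize residue
    importance scores)."""
    n = len(P_raw.row_ids)
    rows = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        P_i = KmerMatrix(
            [P_raw.row_ids[j] for j in keep], P_raw.col_ids, P_raw.values[keep]
        )
        R_i = KmerMatrix(
            [R_raw.row_ids[j] for j in keep], R_raw.col_ids, R_raw.values[keep]
        )
        model = fit(P_i, R_i, d=d, pcc_min=pcc_min)
        res = rna_query(dict(zip(R_raw.col_ids, R_raw.values[i])), model)
        full = dict(zip(res.reconstruction_cols, res.reconstruction))
        rows.append([full.get(c, 0.0) for c in P_raw.col_ids])
    return KmerMatrix(list(P_raw.row_ids), list(P_raw.col_ids), np.asarray(rows))
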