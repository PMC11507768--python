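"""Featurization: RNA-binding regions, gapped peptide profiles, the RNA 7-mer
vocabulary, and quantification of probe arrays into 7-mer Z-score profiles.

An RNA-binding region (RBR) is the protein subsequence spanning all annotated
RNA-binding domains, each extended by a short flank (default 15 residues);
overlapping or adjacent extended intervals are merged.  The peptide profile of
an RBR counts gapped 5-mer templates: every 5-residue window contributes the
five templates obtained by placing a wildcard 'X' at each of its positions
("AXAAA" and "AAXAA" are distinct templates).  Windows never span merged
segment boundaries, and windows containing an unknown residue 'X' are skipped.

Probe-array quantification mirrors the standard assay pipeline: intensities
are centred and variance-normalized per sample column and then per probe row,
each 7-mer is scored by the trimmed mean (inner 95%) of the normalized
intensities of probes containing it, and the 7-mer scores are Z-transformed
to mean 0, standard deviation 1 (population denominator).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from jple.io import DomainAnnotation, KmerMatrix, ProteinRecord

RNA_BASES = "ACGU"
WILDCARD = "X"
PEPTIDE_K = 5
RNA_K = 7

#: The excluded restriction-site 7-mers, as printed in the assay's DNA
#: alphabet; transliterated T->U before use.
RESTRICTION_SITES_DNA = ("GCTCTTC", "CGAGAAG")


def enumerate_7mers(exclude_restriction: bool = True) -> list[str]:
    """All RNA 7-mers in lexicographic order over {A, C, G, U}.

    With ``exclude_restriction`` the two restriction-site 7-mers are removed,
    leaving the standard 16,382-entry vocabulary.
    """
    kmers = ["".join(p) for p in itertools.product(RNA_BASES, repeat=RNA_K)]
    if exclude_restriction:
        excluded = {s.replace("T", "U") for s in RESTRICTION_SITES_DNA}
        kmers = [k for k in kmers if k not in excluded]
    return kmers


@dataclass
class RBR:
    """An RNA-binding region: ordered, merged segments of one protein.

    ``segments`` holds ``(subsequence, start)`` pairs with 0-based start
    offsets into the protein sequence; ``domain_classes`` lists the class of
    each annotated domain, in order.
    """

    protein_id: str
    segments: list[tuple[str, int]]
    domain_classes: list[str]

    @property
    def sequence(self) -> str:
        """Concatenation of the segments (windows never cross the joins)."""
        return "".join(seq for seq, _ in self.segments)

    def __len__(self) -> int:
        return sum(len(seq) for seq, _ in self.segments)


def build_rbr(
    protein: ProteinRecord,
    domains: Sequence[DomainAnnotation],
    flank: int = 15,
) -> RBR:
    """Extend each domain by ``flank`` residues per side, clip to the
    sequence, and merge overlapping or adjacent intervals into segments."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    mine = [d for d in domains if d.protein_id == protein.id]
    if not mine:
        raise ValueError(f"no RBDs for protein {protein.id!r}")
    n = len(protein.sequence)
    for d in mine:
        if d.end > n:
            raise ValueError(
                f"domain [{d.start}, {d.end}] exceeds length {n} of "
                f"protein {protein.id!r}"
            )
    mine = sorted(mine, key=lambda d: (d.start, d.end))
    # 1-based inclusive file coordinates -> 0-based half-open, once.
    intervals = [(max(0, d.start - 1 - flank), min(n, d.end + flank)) for d in mine]
    merged: list[list[int]] = []
    for a, b in intervals:
        if merged and a <= merged[-1][1]:  # overlap or adjacency
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    segments = [(protein.sequence[a:b], a) for a, b in merged]
    return RBR(protein.id, segments, [d.domain_class for d in mine])


@dataclass
class PeptideProfile:
    """Counts of gapped 5-mer templates (4 residues + 1 wildcard)."""

    vocabulary: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.vocabulary),):
            raise ValueError("counts length does not match vocabulary")
        if np.any(self.counts < 0):
            raise ValueError("negative template counts")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.vocabulary, self.counts))


def _window_templates(window: str) -> list[str]:
    return [window[:i] + WILDCARD + window[i + 1 :] for i in range(PEPTIDE_K)]


def count_templates(rbr: RBR) -> dict[str, float]:
    """Template -> count over all 5-residue windows of the RBR segments."""
    counts: dict[str, float] = {}
    for seq, _ in rbr.segments:
        for i in range(len(seq) - PEPTIDE_K + 1):
            window = seq[i : i + PEPTIDE_K]
            if WILDCARD in window:
                continue
            for t in _window_templates(window):
                counts[t] = counts.get(t, 0.0) + 1.0
    return counts


def peptide_profile(
    rbr: RBR, vocabulary: Sequence[str] | None = None
) -> PeptideProfile:
    """Gapped 5-mer template counts for one RBR.

    With an explicit ``vocabulary`` the counts are aligned to it (templates
    outside the vocabulary are dropped); otherwise the vocabulary is the
    sorted set of observed templates.  An empty profile is allowed but
    flagged with a warning.
    """
    counts = count_templates(rbr)
    if not counts:
        warnings.warn(f"empty peptide profile for {rbr.protein_id!r}")
    if vocabulary is None:
        vocabulary = sorted(counts)
    vec = np.array([counts.get(t, 0.0) for t in vocabulary], dtype=float)
    return PeptideProfile(list(vocabulary), vec)


def peptide_count_matrix(rbrs: Sequence[RBR]) -> KmerMatrix:
    """Stack peptide profiles for a training cohort on their union vocabulary."""
    per_rbr = [count_templates(r) for r in rbrs]
    vocab = sorted(set().union(*[set(c) for c in per_rbr]) if per_rbr else set())
    values = np.zeros((len(rbrs), len(vocab)))
    index = {t: j for j, t in enumerate(vocab)}
    for i, counts in enumerate(per_rbr):
        for t, c in counts.items():
            values[i, index[t]] = c
    return KmerMatrix([r.protein_id for r in rbrs], vocab, values)


@dataclass
class RNABindingProfile:
    """Z-scores over an ordered RNA 7-mer vocabulary (the motif)."""

    kmer_ids: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.kmer_ids),):
            raise ValueError("z length does not match kmer_ids")


@dataclass
class ProbeArray:
    """A designed probe array: sequences plus a probes x samples intensity
    matrix."""

    probe_ids: list[str]
    probe_sequences: list[str]
    intensities: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, s = self.intensities.shape
        if n != len(self.probe_ids) or n != len(self.probe_sequences):
            raise ValueError("intensity rows do not match probes")
        if s != len(self.sample_ids):
            raise ValueError("intensity columns do not match samples")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite probe intensities")
        short = [s_ for s_ in self.probe_sequences if len(s_) < RNA_K]
        if short:
            raise ValueError("probe sequences shorter than 7 nt")


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(RNA_BASES):
    _BASE_CODE[ord(_b)] = _i
_BASE_CODE[ord("T")] = _BASE_CODE[ord("U")]  # accept DNA-alphabet probes


def _probe_kmer_pairs(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Unique (probe index, 7-mer code) membership pairs over all probes."""
    probe_idx: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    lengths = {len(s) for s in sequences}
    if len(lengths) == 1:
        length = lengths.pop()
        flat = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
        enc = _BASE_CODE[flat].reshape(len(sequences), length)
        valid_base = enc >= 0
        windows = length - RNA_K + 1
        code = np.zeros((len(sequences), windows), dtype=np.int64)
        ok = np.ones((len(sequences), windows), dtype=bool)
        for j in range(RNA_K):
            block = enc[:, j : j + windows]
            code = code * 4 + np.where(block > 0, block, 0)
            ok &= valid_base[:, j : j + windows]
        pid = np.repeat(np.arange(len(sequences)), windows)
        mask = ok.ravel()
        probe_idx.append(pid[mask])
        codes.append(code.ravel()[mask])
    else:
        for i, seq in enumerate(sequences):
            enc = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            w = len(seq) - RNA_K + 1
            c = np.zeros(w, dtype=np.int64)
            ok = np.ones(w, dtype=bool)
            for j in range(RNA_K):
                block = enc[j : j + w]
                c = c * 4 + np.where(block > 0, block, 0)
                ok &= block >= 0
            probe_idx.append(np.full(int(ok.sum()), i, dtype=np.int64))
            codes.append(c[ok])
    pid = np.concatenate(probe_idx)
    code = np.concatenate(codes)
    # containment is a set property: deduplicate (probe, 7-mer) pairs
    key = np.unique(pid * (4**RNA_K) + code)
    return key // (4**RNA_K), key % (4**RNA_K)


def normalize_intensities(array: ProbeArray) -> np.ndarray:
    """Centre and variance-normalize intensities per sample column, then per
    probe row.  Row normalization needs >= 2 samples and is skipped with a
    warning otherwise."""
    x = np.array(array.intensities, dtype=float)
    col_sd = x.std(axis=0)
    if np.any(col_sd == 0):
        raise ValueError("degenerate probe array: zero-variance sample column")
    x = (x - x.mean(axis=0)) / col_sd
    if x.shape[1] >= 2:
        row_sd = x.std(axis=1, keepdims=True)
        zero = (row_sd == 0).ravel()
        if zero.any():
            warnings.warn(f"{int(zero.sum())} constant probe rows set to zero")
        x = np.where(zero[:, None], 0.0, (x - x.mean(axis=1, keepdims=True))
                     / np.where(row_sd == 0, 1.0, row_sd))
    else:
        warnings.warn(
            "single-sample array: per-probe normalization skipped "
            "(a length-1 row cannot be centred)"
        )
    return x


def quantify_rnacompete(
    array: ProbeArray, sample: str, kmers: Sequence[str] | None = None
) -> RNABindingProfile:
    """Quantify one sample of a probe array into a 7-mer Z-score profile.

    For each 7-mer in ``kmers`` (default: the standard 16,382 vocabulary) the
    score is the mean normalized intensity of the inner 95% of probes
    containing it (drop ``ceil(0.025 n)`` from each tail, values tie-broken by
    probe order); the scores are then Z-transformed.  7-mers contained in no
    probe get the minimum Z with a warning.
    """
    if kmers is None:
        kmers = enumerate_7mers(exclude_restriction=True)
    if sample not in array.sample_ids:
        raise KeyError(f"sample {sample!r} not in array")
    x = normalize_intensities(array)
    v = x[:, array.sample_ids.index(sample)]

    pid, code = _probe_kmer_pairs(array.probe_sequences)
    kmer_codes = np.array(
        [int("".join(str(RNA_BASES.index(b)) for b in k), 4) for k in kmers],
        dtype=np.int64,
    )
    col_of_code = np.full(4**RNA_K, -1, dtype=np.int64)
    col_of_code[kmer_codes] = np.arange(len(kmers))
    kcol = col_of_code[code]
    keep = kcol >= 0
    kcol, pid = kcol[keep], pid[keep]

    vals = v[pid]
    order = np.lexsort((pid, vals, kcol))  # by 7-mer, then value, then probe
    kcol_s, vals_s = kcol[order], vals[order]
    bounds = np.searchsorted(kcol_s, np.arange(len(kmers) + 1))
    cs = np.concatenate([[0.0], np.cumsum(vals_s)])

    counts = bounds[1:] - bounds[:-1]
    trim = np.ceil(0.025 * counts).astype(np.int64)
    trim = np.where(counts - 2 * trim >= 1, trim, 0)  # keep >= 1 value
    lo = bounds[:-1] + trim
    hi = bounds[1:] - trim
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, (cs[hi] - cs[lo]) / (hi - lo), np.nan)

    covered = ~np.isnan(means)
    if not covered.any():
        raise ValueError("no 7-mer is contained in any probe")
    mu = means[covered].mean()
    sd = means[covered].std()
    if sd == 0:
        raise ValueError("degenerate quantification: all 7-mer scores equal")
    z = (means - mu) / sd
    if not covered.all():
        missing = [kmers[j] for j in np.flatnonzero(~covered)]
        warnings.warn(
            f"{len(missing)} 7-mers contained in no probe set to minimum Z: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
        z[~covered] = z[covered].min()
    return RNABindingProfile(list(kmers), z)


def read_probe_array(path: str) -> ProbeArray:
    """Read a probe array TSV (probe_id, sequence, one column per sample)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "sequence": str})
    if "probe_id" not in df.columns or "sequence" not in df.columns:
        raise ValueError(f"{path}: expected probe_id and sequence columns")
    samples = [c for c in df.columns if c not in ("probe_id", "sequence")]
    if not samples:
        raise ValueError(f"{path}: no sample columns")
    return ProbeArray(
        list(df["probe_id"]),
        list(df["sequence"]),
        df[samples].to_numpy(dtype=float),
        samples,
    )


def write_probe_array(array: ProbeArray, path: str) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {"probe_id": array.probe_ids, "sequence": array.probe_sequences}
    )
    for j, s in enumerate(array.sample_ids):
        df[s] = array.intensities[:, j]
    df.to_csv(path, sep="\t", index=False)
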