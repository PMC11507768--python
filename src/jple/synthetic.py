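"""Synthetic proteomes with planted peptide -> RNA-specificity structure.

The generator emulates the structure of the training data the embedding
method is designed for, without imitating any real proteome:

* Families.  Every protein is 150 aa with one 50-aa "domain" at positions
  [51, 100] (1-based) and, inside it, a 20-aa specificity block at
  [71, 90].  All founders descend from a single fixture-wide scaffold
  (each founder substitutes ~15% of scaffold positions), as unrelated RRMs
  share most of their fold; only the specificity block is family-private
  random sequence.  Without this shared scaffold every flank peptide would
  be family-private and as predictive of the family's motif as the true
  determinants, and no method could (or should) tell them apart.  Members
  are derived from their founder by seeded point substitutions targeting
  declared amino-acid identity bands over the RNA-binding region (domain
  plus 15-aa flanks); for bands >= 0.5 the substitutions avoid the
  conserved block (the family keeps its specificity determinants, with one
  block substitution allowed in the 0.5-0.8 mid range), below that they
  hit it freely (the motif diverges along with the sequence).

* Planted specificity.  Every family's informative templates are the gapped
  5-mers of its founder's conserved block.  Template effects over the 7-mer
  vocabulary are linear combinations of a small number of family-private
  latent factors.  Each factor is a motif-like energy field: the log total
  Boltzmann weight of a random short position-weight core scored over a
  random sequence context containing the 7-mer.  Such fields are smooth
  across overlapping/shifted 7-mers, as real motif-driven binding is — and
  as probe-array quantification requires, since a probe's intensity always
  sums contributions of overlapping windows.  The RNA-profile matrix has
  low rank per family and profiles of unrelated families are uncorrelated.  A protein's true
  profile is the sum of the effects of the informative templates its own
  sequence still contains, scaled to unit spread, plus Gaussian noise, then
  Z-transformed.  Effects are additive, matching the linearity of the
  embedding model, so recovery failures indicate bugs rather than model
  mismatch.

* Probe arrays.  Designed-length probes with intensities that sum
  softmax-scaled 7-mer affinities over the probe's windows plus an additive
  lognormal probe effect and Gaussian noise at a declared signal-to-noise
  ratio.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from jple.featurize import (
    RNA_BASES,
    RNA_K,
    ProbeArray,
    RNABindingProfile,
    RBR,
    build_rbr,
    count_templates,
    enumerate_7mers,
    peptide_count_matrix,
)
from jple.io import DomainAnnotation, KmerMatrix, ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

PROTEIN_LENGTH = 150
DOMAIN_START, DOMAIN_END = 51, 100          # 1-based inclusive
BLOCK_START, BLOCK_END = 71, 90             # conserved specificity block
DEFAULT_BANDS = (0.95, 0.9, 0.65, 0.45, 0.25)
FLANK = 15
SCAFFOLD_DIVERGENCE = 0.15
GLOBAL_RANK = 6
BACKGROUND_AMPLITUDE = 0.2


@dataclass
class FamilyFixture:
    """A synthetic cohort of protein families."""

    proteins: list[ProteinRecord]
    domains: list[DomainAnnotation]
    family_of: dict[str, int]
    band_of: dict[str, float]          # founders carry band 1.0
    founder_ids: list[str]
    block_span: tuple[int, int] = (BLOCK_START, BLOCK_END)
    flank: int = FLANK

    def rbrs(self) -> list[RBR]:
        return [build_rbr(p, self.domains, self.flank) for p in self.proteins]

    def peptide_matrix(self) -> KmerMatrix:
        return peptide_count_matrix(self.rbrs())


def gen_families(
    n_families: int,
    members: int,
    seed: int,
    bands: Sequence[float] = DEFAULT_BANDS,
) -> FamilyFixture:
    """Generate ``n_families`` families of ``members`` proteins each
    (founder included); members cycle through the identity ``bands``."""
    if n_families < 1 or members < 1:
        raise ValueError("n_families and members must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA20))
    proteins: list[ProteinRecord] = []
    domains: list[DomainAnnotation] = []
    family_of: dict[str, int] = {}
    band_of: dict[str, float] = {}
    founder_ids: list[str] = []

    rbr_lo = DOMAIN_START - 1 - FLANK          # 0-based RBR span
    rbr_hi = DOMAIN_END + FLANK                # exclusive
    rbr_positions = np.arange(rbr_lo, rbr_hi)
    block = set(range(BLOCK_START - 1, BLOCK_END))

    # One fixture-wide scaffold: unrelated families share their fold.
    # Founders differ *inside* the RBR only by their specificity block —
    # family-wide drift elsewhere in the RBR would be inherited by every
    # member and become statistically indistinguishable from the block.
    # Between-family drift is placed outside the RBR.
    scaffold = rng.choice(aa, size=PROTEIN_LENGTH)
    outside_rbr = np.array(
        [p for p in range(PROTEIN_LENGTH) if not (rbr_lo <= p < rbr_hi)]
    )

    for f in range(n_families):
        seq0 = scaffold.copy()
        # family-private specificity block
        for p in sorted(block):
            seq0[p] = aa[rng.integers(len(aa))]
        # scaffold drift between families, outside the RBR
        n_div = round(SCAFFOLD_DIVERGENCE * len(outside_rbr))
        for p in rng.choice(outside_rbr, size=n_div, replace=False):
            choices = [c for c in AA20 if c != seq0[p]]
            seq0[p] = choices[rng.integers(len(choices))]
        founder = "".join(seq0)
        fid = f"F{f:02d}_founder"
        proteins.append(ProteinRecord(fid, founder))
        domains.append(DomainAnnotation(fid, "RRM", DOMAIN_START, DOMAIN_END))
        family_of[fid] = f
        band_of[fid] = 1.0
        founder_ids.append(fid)
        for k in range(members - 1):
            band = bands[k % len(bands)]
            # specificity drifts gradually with sequence divergence: the
            # conserved block takes 0 hits at high identity, a single hit in
            # the 0.5-0.8 mid range, a handful below 0.5, and is
            # unprotected below 0.3
            if band >= 0.8:
                block_hits = 0
            elif band >= 0.5:
                block_hits = 1
            elif band >= 0.3:
                block_hits = 4
            else:
                block_hits = None  # unrestricted
            n_mut = round((1.0 - band) * len(rbr_positions))
            if block_hits is None:
                pool = rbr_positions
                sites = rng.choice(pool, size=min(n_mut, len(pool)),
                                   replace=False)
            else:
                outside = np.array([p for p in rbr_positions if p not in block])
                block_hits = min(block_hits, n_mut)
                n_out = min(n_mut - block_hits, len(outside))
                sites = np.concatenate([
                    rng.choice(sorted(block), size=block_hits, replace=False),
                    rng.choice(outside, size=n_out, replace=False),
                ])
            seq = list(founder)
            for p in sites:
                choices = [c for c in AA20 if c != seq[p]]
                seq[p] = choices[rng.integers(len(choices))]
            mid = f"F{f:02d}_m{k}_b{int(round(band * 100)):02d}"
            proteins.append(ProteinRecord(mid, "".join(seq)))
            domains.append(
                DomainAnnotation(mid, "RRM", DOMAIN_START, DOMAIN_END)
            )
            family_of[mid] = f
            band_of[mid] = band
    return FamilyFixture(
        proteins, domains, family_of, band_of, founder_ids
    )


def _kmer_encoding(kmers: Sequence[str]) -> np.ndarray:
    return np.array([[RNA_BASES.index(b) for b in k] for k in kmers])


def _core_energy_field(
    rng: np.random.Generator,
    enc: np.ndarray,
    core_width: int = 4,
    scale: float = 1.0,
) -> np.ndarray:
    """A motif-like affinity field over the 7-mer vocabulary.

    A random position-weight core of ``core_width`` is scored at every
    offset of a random context containing the 7-mer (positions outside the
    7-mer average over bases); the field is the log of the summed Boltzmann
    weights, standardized.  Fields built this way are smooth across
    single-shift 7-mer neighbors, like motif-driven binding.
    """
    k = enc.shape[1]
    W = rng.standard_normal((core_width, 4)) * scale
    Wbar = W.mean(axis=1)
    total = np.zeros(enc.shape[0])
    for o in range(-(core_width - 1), k):
        s = np.zeros(enc.shape[0])
        for j in range(core_width):
            p = o + j
            if 0 <= p < k:
                s += W[j, enc[:, p]]
            else:
                s += Wbar[j]
        total += np.exp(s)
    f = np.log(total)
    return (f - f.mean()) / f.std()


@dataclass
class PlantedModel:
    """The planted peptide -> specificity map: per-family latent factors and
    template loadings.  ``informative_templates`` maps each gapped 5-mer to
    its family; ``effect(t)`` materializes its effect over the 7-mers."""

    kmer_ids: list[str]
    informative_templates: dict[str, int]
    loadings: dict[str, np.ndarray]
    factors: list[np.ndarray]          # per family: latent_rank x n_kmers
    family_scale: list[float]          # sd of each family's full template sum
    global_factors: np.ndarray         # weak background basis over 7-mers
    bg_sd: float                       # per-template background loading sd
    latent_rank: int
    noise_sd: float
    seed: int

    def effect(self, template: str) -> np.ndarray:
        """Effect vector, scaled so a family's full template set sums to a
        unit-sd signal."""
        f = self.informative_templates[template]
        return (self.loadings[template] @ self.factors[f]) / self.family_scale[f]

    def background_loading(self, template: str) -> np.ndarray:
        """Deterministic weak background loading of any template (keyed by a
        template checksum, so it needs no stored table)."""
        key = zlib.crc32(template.encode())
        rng = np.random.default_rng([self.seed & 0x7FFFFFFF, key])
        return self.bg_sd * rng.standard_normal(self.global_factors.shape[0])


def gen_planted_model(
    fixture: FamilyFixture,
    latent_rank: int = 2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> PlantedModel:
    """Plant informative templates (the founders' conserved-block 5-mers)
    with low-rank, family-private effect vectors."""
    if latent_rank < 1:
        raise ValueError("latent_rank must be >= 1")
    rng = np.random.default_rng(seed)
    kmers = enumerate_7mers(exclude_restriction=True)
    informative: dict[str, int] = {}
    loadings: dict[str, np.ndarray] = {}
    factors: list[np.ndarray] = []
    by_id = {p.id: p for p in fixture.proteins}
    b0, b1 = fixture.block_span
    enc = _kmer_encoding(kmers)
    drawn: list[np.ndarray] = []

    def next_factor() -> np.ndarray:
        # Orthogonalize against all previous factors: motif-like fields share
        # low-dimensional (base-composition) structure, and unrelated
        # families must have uncorrelated profiles.
        f = _core_energy_field(rng, enc)
        f = f - f.mean()
        for g in drawn:
            f -= (f @ g) / (g @ g) * g
        f /= f.std()
        drawn.append(f)
        return f

    family_scale: list[float] = []
    for f, fid in enumerate(fixture.founder_ids):
        factors.append(np.vstack([next_factor() for _ in range(latent_rank)]))
        blockseq = by_id[fid].sequence[b0 - 1 : b1]
        block_rbr = RBR(fid, [(blockseq, b0 - 1)], ["RRM"])
        fam_templates = []
        for t in count_templates(block_rbr):
            if t in informative:   # cross-family collision: keep the first
                continue
            informative[t] = f
            # dominant shared component plus weaker template-specific
            # modulation: partial template subsets (degraded homologs) keep
            # a signal positively correlated with the family's, as shared
            # motif cores do
            c = 0.35 * rng.standard_normal(latent_rank)
            c[0] += 1.0
            loadings[t] = c
            fam_templates.append(t)
        full = np.zeros(len(kmers))
        for t in fam_templates:
            full += loadings[t] @ factors[f]
        family_scale.append(float(full.std()) if full.std() > 0 else 1.0)

    # Weak background: every RBR peptide modulates specificity slightly
    # through a shared low-rank basis, as flanking residues modulate real
    # binding affinity.  Calibrated so a typical full RBR (~380 templates)
    # contributes background of sd BACKGROUND_AMPLITUDE.
    global_factors = np.vstack([next_factor() for _ in range(GLOBAL_RANK)])
    bg_sd = BACKGROUND_AMPLITUDE / np.sqrt(380.0 * GLOBAL_RANK)
    return PlantedModel(
        kmers, informative, loadings, factors, family_scale, global_factors,
        bg_sd, latent_rank, noise_sd, seed,
    )


def gen_profiles(fixture: FamilyFixture, model: PlantedModel) -> KmerMatrix:
    """True RNA-binding profiles: per protein, the sum of the effects of the
    informative templates its RBR contains, plus Gaussian noise of sd
    ``model.noise_sd``, Z-transformed row-wise.

    Effects are pre-scaled so a full, intact template set yields a unit-sd
    signal; a protein that has lost part of its specificity block therefore
    has a proportionally weaker signal against the fixed noise floor, and an
    isolated cross-family template coincidence stays within the noise.
    """
    rng = np.random.default_rng(model.seed + 1)
    rows = []
    for rbr in fixture.rbrs():
        present = count_templates(rbr)
        signal = np.zeros(len(model.kmer_ids))
        bg = np.zeros(model.global_factors.shape[0])
        for t in present:
            if t in model.informative_templates:
                signal += model.effect(t)
            bg += model.background_loading(t)
        signal += bg @ model.global_factors
        noisy = signal + rng.normal(0.0, model.noise_sd, size=signal.shape)
        spread = noisy.std()
        if spread == 0:  # no informative template and no noise
            rows.append(np.zeros_like(noisy))
        else:
            rows.append((noisy - noisy.mean()) / spread)
    return KmerMatrix(
        [p.id for p in fixture.proteins], list(model.kmer_ids), np.asarray(rows)
    )


def member_cv_folds(
    fixture: FamilyFixture,
    row_ids: Sequence[str],
    n_folds: int,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Cross-validation folds over family members, stratified by identity
    band; founders stay in every training split.

    Founders act as each family's canonical training anchor: the benchmark
    queries emulate uncharacterized homologs at graded divergence from a
    characterized relative.  (Querying a family's centroid while training on
    its satellites inverts the usual accuracy-vs-distance relation and tests
    a different, rarer scenario.)
    """
    by_band: dict[float, list[int]] = {}
    for i, r in enumerate(row_ids):
        band = fixture.band_of[r]
        if band < 1.0:
            by_band.setdefault(band, []).append(i)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for _, members in sorted(by_band.items()):
        members = list(rng.permutation(members))
        for j, i in enumerate(members):
            folds[j % n_folds].append(int(i))
    return [sorted(f) for f in folds]


def stratified_holdout(
    fixture: FamilyFixture,
    row_ids: Sequence[str],
    frac: float,
    rng: np.random.Generator,
) -> list[int]:
    """Row indices of a held-out fraction stratified by identity band, so
    every divergence level is represented in a benchmark split."""
    by_band: dict[float, list[int]] = {}
    for i, r in enumerate(row_ids):
        by_band.setdefault(fixture.band_of[r], []).append(i)
    held: list[int] = []
    for _, members in sorted(by_band.items()):
        k = max(1, round(frac * len(members)))
        held.extend(int(j) for j in rng.choice(members, size=k, replace=False))
    return sorted(held)


def gen_motif_profile(seed: int, core_width: int = 4) -> RNABindingProfile:
    """A single planted motif-like binding profile over the standard 7-mer
    vocabulary — the natural input for probe-array simulation, mirroring one
    RBP's specificity rather than a family mixture."""
    rng = np.random.default_rng(seed)
    kmers = enumerate_7mers(exclude_restriction=True)
    z = _core_energy_field(rng, _kmer_encoding(kmers), core_width=core_width)
    return RNABindingProfile(kmers, z)


def softmax_affinities(z: np.ndarray, temperature: float = 2.0) -> np.ndarray:
    """Relative affinities exp(z / T), shifted so the maximum affinity is 1."""
    z = np.asarray(z, dtype=float)
    return np.exp((z - z.max()) / temperature)


def gen_probe_array(
    profile: RNABindingProfile,
    n_probes: int,
    probe_len: int = 40,
    seed: int = 0,
    snr: float = 3.0,
    probe_effect_sd: float = 0.1,
    temperature: float = 2.0,
    sample_id: str = "sample",
) -> ProbeArray:
    """Simulate a designed probe array for one binding profile.

    Probe intensity = sum over the probe's 7-mer windows of softmax-scaled
    affinities, plus an additive lognormal probe effect, plus Gaussian noise
    with sd = sd(signal) / ``snr``.
    """
    if n_probes < 1000:
        raise ValueError("n_probes must be >= 1000")
    rng = np.random.default_rng(seed)
    enc = rng.integers(0, 4, size=(n_probes, probe_len), dtype=np.int64)

    aff_by_code = np.zeros(4**RNA_K)
    affinities = softmax_affinities(profile.z, temperature)
    codes = np.array(
        [int("".join(str(RNA_BASES.index(b)) for b in k), 4)
         for k in profile.kmer_ids],
        dtype=np.int64,
    )
    aff_by_code[codes] = affinities

    windows = probe_len - RNA_K + 1
    code = np.zeros((n_probes, windows), dtype=np.int64)
    for j in range(RNA_K):
        code = code * 4 + enc[:, j : j + windows]
    signal = aff_by_code[code].sum(axis=1)

    noise_sd = signal.std() / snr if signal.std() > 0 else 1.0
    intensity = (
        signal
        + rng.lognormal(0.0, probe_effect_sd, size=n_probes)
        + rng.normal(0.0, noise_sd, size=n_probes)
    )
    base_arr = np.array(list(RNA_BASES))
    seqs = ["".join(row) for row in base_arr[enc]]
    return ProbeArray(
        [f"probe{i:06d}" for i in range(n_probes)],
        seqs,
        intensity[:, None],
        [sample_id],
    )
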