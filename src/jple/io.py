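"""Readers and writers for sequences, annotation tables, k-mer matrices,
MEME motifs, and the serialized model container.

Conventions
-----------
All files use 1-based inclusive coordinates; internal code uses 0-based
half-open intervals.  The conversion happens exactly once, at this I/O
boundary (``read_domain_table`` keeps the file convention inside
:class:`DomainAnnotation`; :func:`jple.featurize.build_rbr` converts).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from jple.core import JointModel
    from jple.motifs import PFM

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DOMAIN_CLASSES = ("RRM", "KH", "other")

MODEL_FORMAT_VERSION = "jple-model-1"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; 20 canonical amino acids plus 'X' (unknown)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """An RNA-binding domain interval, 1-based inclusive (file convention)."""

    protein_id: str
    domain_class: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise FormatError(
                f"domain class {self.domain_class!r} not in {DOMAIN_CLASSES}"
            )
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"{self.protein_id}: invalid interval [{self.start}, {self.end}]"
            )


@dataclass
class KmerMatrix:
    """A dense real matrix with ordered row identifiers and k-mer columns."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != len(self.row_ids) or m != len(self.col_ids):
            raise ValueError("matrix shape does not match row/column ids")
        if len(set(self.row_ids)) != n:
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != m:
            raise ValueError("duplicate column ids")

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    Sequences are upper-cased and '*' stop characters stripped.  Duplicate
    ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("*", "")
        out.append(ProteinRecord(rec.id, seq))
    return out


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a tab-separated domain table (protein_id, domain_class, start, end).

    Coordinates are kept 1-based inclusive.  Unknown domain classes are
    demoted to "other" with a warning; start > end is an error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_class": str})
    required = ["protein_id", "domain_class", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        cls = row.domain_class
        if cls not in DOMAIN_CLASSES:
            warnings.warn(
                f"{path} line {i}: unknown domain class {cls!r}, using 'other'"
            )
            cls = "other"
        start, end = int(row.start), int(row.end)
        if start > end:
            raise FormatError(f"{path} line {i}: start {start} > end {end}")
        out.append(DomainAnnotation(str(row.protein_id), cls, start, end))
    return out


def write_domain_table(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_class\tstart\tend\n")
        for d in domains:
            fh.write(f"{d.protein_id}\t{d.domain_class}\t{d.start}\t{d.end}\n")


def read_kmer_matrix(path: str | Path) -> KmerMatrix:
    """Read a TSV k-mer matrix (first column row id, k-mer-labelled columns)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")[1:]
        if len(set(cols)) != len(cols):
            dups = sorted({c for c in cols if cols.count(c) > 1})
            raise FormatError(f"{path}: duplicate k-mer columns {dups}")
        row_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols) + 1:
                raise FormatError(
                    f"{path} line {lineno}: expected {len(cols) + 1} fields, "
                    f"got {len(fields)}"
                )
            row_ids.append(fields[0])
            try:
                rows.append(np.asarray(fields[1:], dtype=float))
            except ValueError:
                for j, cell in enumerate(fields[1:]):
                    try:
                        float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path} line {lineno}: non-numeric value {cell!r} "
                            f"in row {fields[0]!r}, column {cols[j]!r}"
                        ) from None
                raise
    if not rows:
        raise FormatError(f"{path}: no data rows")
    if len(set(row_ids)) != len(row_ids):
        dups = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise FormatError(f"{path}: duplicate row ids {dups}")
    return KmerMatrix(row_ids, cols, np.vstack(rows))


def write_kmer_matrix(matrix: KmerMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(matrix.col_ids) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_meme_pfm(pfm: "PFM", path: str | Path, name: str = "motif") -> None:
    """Write a position frequency matrix in MEME minimal motif format (ACGU).

    Columns must sum to 1 within 1e-6.
    """
    freqs = np.asarray(pfm.columns, dtype=float)  # width x 4
    sums = freqs.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > 1e-6):
        j = int(np.argmax(off))
        raise ValueError(
            f"PFM column {j} sums to {sums[j]:.8f}, expected 1 within 1e-6"
        )
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGU\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 U 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {freqs.shape[0]} "
            f"nsites= {max(1, int(max(pfm.support)))} E= 0\n"
        )
        for col in freqs:
            fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")


# ---------------------------------------------------------------------------
# Model container


def save_model(model: "JointModel", path: str | Path) -> None:
    """Serialize a fitted model to a keyed-array bundle (.npz + JSON metadata).

    The round trip ``load_model(save_model(m))`` reproduces every array
    bit-exactly.
    """
    from jple.core import JointModel  # local import to avoid cycle

    if not isinstance(model, JointModel):
        raise TypeError("save_model expects a fitted JointModel")
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "d": int(model.d),
        "gamma": float(model.gamma),
        "nbh_threshold": float(model.nbh_threshold),
        "conf_cutoff": float(model.conf_cutoff),
        "has_R_raw": model.R_raw is not None,
    }
    arrays = {
        "Vp": model.Vp,
        "Vr": model.Vr,
        "S": model.S,
        "W": model.W,
        "scores": model.scores,
        "row_ids": np.asarray(model.row_ids, dtype="U"),
        "col_ids_P": np.asarray(model.col_ids_P, dtype="U"),
        "col_ids_R": np.asarray(model.col_ids_R, dtype="U"),
        "kept_P": model.kept_P,
        "kept_R": model.kept_R,
        "mu_P": model.mu_P,
        "mu_R": model.mu_R,
        "norm_P": model.norm_P,
        "norm_R": model.norm_R,
        "meta_json": np.asarray(json.dumps(meta)),
    }
    if model.R_raw is not None:
        arrays["R_raw"] = model.R_raw
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> "JointModel":
    """Load a model bundle written by :func:`save_model`."""
    from jple.core import JointModel

    try:
        with np.load(path, allow_pickle=False) as data:
            if "meta_json" not in data:
                raise FormatError(f"{path}: not a jple model bundle")
            meta = json.loads(str(data["meta_json"]))
            version = meta.get("format_version")
            if version != MODEL_FORMAT_VERSION:
                raise FormatError(
                    f"{path}: model format version {version!r} not supported "
                    f"(expected {MODEL_FORMAT_VERSION!r})"
                )
            return JointModel(
                Vp=data["Vp"],
                Vr=data["Vr"],
                S=data["S"],
                W=data["W"],
                d=int(meta["d"]),
                scores=data["scores"],
                gamma=float(meta["gamma"]),
                nbh_threshold=float(meta["nbh_threshold"]),
                conf_cutoff=float(meta["conf_cutoff"]),
                row_ids=list(data["row_ids"]),
                col_ids_P=list(data["col_ids_P"]),
                col_ids_R=list(data["col_ids_R"]),
                kept_P=data["kept_P"],
                kept_R=data["kept_R"],
                mu_P=data["mu_P"],
                mu_R=data["mu_R"],
                norm_P=data["norm_P"],
                norm_R=data["norm_R"],
                R_raw=data["R_raw"] if meta.get("has_R_raw") else None,
            )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot read model bundle ({exc})") from exc
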