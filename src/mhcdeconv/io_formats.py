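"""File I/O: FASTA proteomes, peptide-list TSVs, variant tables, result tables.

All tabular formats are tab-delimited UTF-8 with a header row. Peptide
sequences are sanitized to uppercase and validated against the 20-letter
canonical alphabet before they enter the pipeline.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import is_valid_sequence

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LENGTH = 7
MAX_PEPTIDE_LENGTH = 30


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class PeptideRecord:
    """A detected peptide, optionally tied to a sample and an intensity."""

    sequence: str
    sample_id: str = ""
    intensity: float | None = None
    source_proteins: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.sequence):
            raise ValidationError(f"peptide {self.sequence!r} contains non-canonical residues")
        if not (MIN_PEPTIDE_LENGTH <= len(self.sequence) <= MAX_PEPTIDE_LENGTH):
            raise ValidationError(
                f"peptide {self.sequence!r} has length {len(self.sequence)}, outside "
                f"[{MIN_PEPTIDE_LENGTH}, {MAX_PEPTIDE_LENGTH}]"
            )
        if self.intensity is not None and self.intensity < 0:
            raise ValidationError(f"negative intensity for {self.sequence!r}")


@dataclass(frozen=True)
class ProteinVariant:
    """A single-residue protein variant at a 1-based position."""

    gene: str
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    disease_label: str = ""

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"variant {self.gene}:{self.position} has ref_aa == alt_aa ({self.ref_aa})"
            )
        if self.position < 1:
            raise ValidationError(f"variant {self.gene} position {self.position} is not 1-based")
        for aa in (self.ref_aa, self.alt_aa):
            if not is_valid_sequence(aa) or len(aa) != 1:
                raise ValidationError(f"variant {self.gene}: {aa!r} is not a canonical residue")


@dataclass(frozen=True)
class EpitopeTableRow:
    """One row of the packaged ADRD epitope table."""

    gene: str
    disorder: str
    peptide: str
    allele: str
    el_rank_percent: float
    allele_normalized: str = ""

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValidationError("empty peptide in epitope table row")
        if not (0 < self.el_rank_percent <= 100):
            raise ValidationError(
                f"el_rank_percent {self.el_rank_percent} outside (0, 100] for {self.peptide}"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(protein_id, sequence), ...]`` in file order.

    Sequences are uppercased and trailing ``*`` stop characters stripped.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not rec.id:
            raise FormatError(f"{path}: FASTA record #{len(records) + 1} has an empty header")
        if not seq:
            raise FormatError(f"{path}: FASTA record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Peptide lists

def read_peptide_list(path: str | Path, drop_invalid: bool = False) -> list[PeptideRecord]:
    """Read a peptide TSV (columns: sequence, optionally sample_id/intensity/source_proteins).

    Rows whose sequence violates the canonical alphabet or the length bounds
    are dropped with a logged count when ``drop_invalid`` is set, otherwise a
    :class:`ValidationError` is raised on the first offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sequence" not in df.columns:
        raise FormatError(f"{path}: missing required 'sequence' column")
    records: list[PeptideRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        seq = str(row["sequence"]).strip().upper()
        sample = str(row.get("sample_id", "") or "")
        raw_int = str(row.get("intensity", "") or "").strip()
        sources = tuple(s for s in str(row.get("source_proteins", "") or "").split(";") if s)
        try:
            intensity = float(raw_int) if raw_int else None
            records.append(
                PeptideRecord(sequence=seq, sample_id=sample, intensity=intensity,
                              source_proteins=sources)
            )
        except (ValidationError, ValueError):
            if drop_invalid:
                n_dropped += 1
            else:
                raise
    if n_dropped:
        logger.info("read_peptide_list(%s): dropped %d invalid rows", path, n_dropped)
    return records


def write_peptide_list(path: str | Path, records: Iterable[PeptideRecord]) -> None:
    rows = [
        {
            "sequence": r.sequence,
            "sample_id": r.sample_id,
            "intensity": "" if r.intensity is None else repr(r.intensity),
            "source_proteins": ";".join(r.source_proteins),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["sequence", "sample_id", "intensity", "source_proteins"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Variant tables

_VARIANT_COLUMNS = ["gene", "protein_id", "position", "ref_aa", "alt_aa", "disease_label"]


def read_variant_table(path: str | Path) -> list[ProteinVariant]:
    """Read a variant TSV with columns gene/protein_id/position/ref_aa/alt_aa."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _VARIANT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing variant columns {missing}")
    variants = []
    for _, row in df.iterrows():
        raw_pos = str(row["position"]).strip()
        try:
            position = int(raw_pos)
        except ValueError:
            raise FormatError(f"{path}: non-integer position {raw_pos!r} for gene {row['gene']}")
        variants.append(
            ProteinVariant(
                gene=str(row["gene"]),
                protein_id=str(row["protein_id"]),
                position=position,
                ref_aa=str(row["ref_aa"]).strip().upper(),
                alt_aa=str(row["alt_aa"]).strip().upper(),
                disease_label=str(row.get("disease_label", "") or ""),
            )
        )
    return variants


def write_variant_table(path: str | Path, variants: Iterable[ProteinVariant]) -> None:
    rows = [
        {
            "gene": v.gene, "protein_id": v.protein_id, "position": v.position,
            "ref_aa": v.ref_aa, "alt_aa": v.alt_aa, "disease_label": v.disease_label,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged epitope table

_TOP_RANK_RE = re.compile(r"^\s*top\s*([0-9]*\.?[0-9]+)\s*%\s*$", re.IGNORECASE)


def parse_top_rank(text: str) -> float:
    """Parse a 'TOP x%' EL-rank string to a percent value (case-insensitive)."""
    m = _TOP_RANK_RE.match(text)
    if not m:
        raise FormatError(f"cannot parse EL rank {text!r} (expected 'TOP x%')")
    return float(m.group(1))


def load_reported_epitope_table() -> list[EpitopeTableRow]:
    """Load the packaged ADRD epitope table (gene, disorder, peptide, allele, EL rank).

    The fixture stores both the printed allele form and a normalized
    star-separated form; EL ranks are parsed from the 'TOP x%' notation.
    """
    ref = resources.files("mhcdeconv").joinpath("data/adrd_epitopes.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    expected = {"gene", "disorder", "peptide", "allele", "allele_normalized", "el_rank"}
    if set(df.columns) != expected:
        raise FormatError(f"epitope fixture corrupted: columns {sorted(df.columns)}")
    rows = []
    for _, row in df.iterrows():
        try:
            rows.append(
                EpitopeTableRow(
                    gene=row["gene"],
                    disorder=row["disorder"],
                    peptide=row["peptide"],
                    allele=row["allele"],
                    allele_normalized=row["allele_normalized"],
                    el_rank_percent=parse_top_rank(row["el_rank"]),
                )
            )
        except (ValidationError, FormatError) as exc:
            raise FormatError(f"epitope fixture corrupted at gene {row['gene']}: {exc}") from exc
    if not rows:
        raise FormatError("epitope fixture corrupted: no rows")
    return rows
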