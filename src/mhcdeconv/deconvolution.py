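"""Allele deconvolution of detected peptides and summary statistics.

Each peptide is assigned to the allele giving the minimum percentile rank;
class-specific cutoffs decide retention (default < 2% class I, < 5% class II)
and binder classes (strong < 0.5% / weak < 2% for class I, strong < 1% /
weak < 5% for class II).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .binding_model import AlleleMotifModel, RankCalibration, percent_ranks, score_peptides
from .io_formats import EpitopeTableRow, PeptideRecord, ValidationError
from .synthetic_data import CLASS_WINDOWS

logger = logging.getLogger(__name__)

DEFAULT_RANK_CUTOFFS: dict[str, float] = {"I": 2.0, "II": 5.0}
STRONG_BINDER_BOUNDS: dict[str, float] = {"I": 0.5, "II": 1.0}


@dataclass
class PeptideAssignment:
    """A peptide with its best allele, rank, and binder class."""

    peptide: str
    hla_class: str
    best_allele: str
    best_rank: float
    per_allele_ranks: dict[str, float]
    binder_class: str
    retained: bool


@dataclass
class DeconvolutionSummary:
    retained_per_allele: dict[str, int]
    length_histogram: dict[int, int]
    top_epitopes: dict[str, list[tuple[str, float]]]
    n_input: int
    n_scored: int
    n_retained: int
    n_skipped: int


def classify_binder(rank: float, hla_class: str) -> str:
    """Binder class from a percentile rank: strong / weak / non."""
    strong = STRONG_BINDER_BOUNDS[hla_class]
    weak = DEFAULT_RANK_CUTOFFS[hla_class]
    if rank < strong:
        return "strong"
    if rank < weak:
        return "weak"
    return "non"


def deconvolute(
    peptides: list[PeptideRecord],
    models: dict[str, AlleleMotifModel],
    calibrations: dict[str, RankCalibration],
    hla_class: str,
    rank_cutoff: float | None = None,
) -> list[PeptideAssignment]:
    """Assign each distinct peptide sequence to its minimum-rank allele.

    Peptides outside the class length window are skipped (logged). Ties in
    rank go to the lexicographically smallest allele name. Duplicate
    sequences across samples collapse to one assignment.
    """
    if not models:
        raise ValidationError("empty allele set")
    for name, model in models.items():
        if model.hla_class != hla_class:
            raise ValidationError(f"allele {name} is class {model.hla_class}, expected {hla_class}")
        if name not in calibrations:
            raise ValidationError(f"no calibration for allele {name}")
    cutoff = DEFAULT_RANK_CUTOFFS[hla_class] if rank_cutoff is None else float(rank_cutoff)
    lo, hi = CLASS_WINDOWS[hla_class]

    seen: set[str] = set()
    sequences: list[str] = []
    n_skipped = 0
    for rec in peptides:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        if lo <= len(rec.sequence) <= hi:
            sequences.append(rec.sequence)
        else:
            n_skipped += 1
    if n_skipped:
        logger.info("deconvolute: skipped %d peptides outside the class %s window",
                    n_skipped, hla_class)
    if not sequences:
        return []

    allele_names = sorted(models)
    rank_matrix = np.empty((len(sequences), len(allele_names)), dtype=float)
    by_length: dict[int, list[int]] = {}
    for i, seq in enumerate(sequences):
        by_length.setdefault(len(seq), []).append(i)
    for j, name in enumerate(allele_names):
        scores = score_peptides(models[name], sequences)
        for length, idxs in by_length.items():
            rank_matrix[idxs, j] = percent_ranks(calibrations[name], scores[idxs], length)

    assignments = []
    best_j = np.argmin(rank_matrix, axis=1)  # first minimum = lexicographically smallest
    for i, seq in enumerate(sequences):
        j = int(best_j[i])
        best_rank = float(rank_matrix[i, j])
        assignments.append(
            PeptideAssignment(
                peptide=seq,
                hla_class=hla_class,
                best_allele=allele_names[j],
                best_rank=best_rank,
                per_allele_ranks={a: float(rank_matrix[i, k]) for k, a in enumerate(allele_names)},
                binder_class=classify_binder(best_rank, hla_class),
                retained=best_rank < cutoff,
            )
        )
    return assignments


def length_distribution(
    assignments: list[PeptideAssignment], retained_only: bool = True
) -> dict[int, int]:
    """Histogram of peptide lengths over (retained) assignments."""
    counts = Counter(
        len(a.peptide) for a in assignments if a.retained or not retained_only
    )
    return dict(sorted(counts.items()))


def top_epitopes_per_allele(
    assignments: list[PeptideAssignment], n: int
) -> dict[str, list[PeptideAssignment]]:
    """Per allele, the n lowest-rank retained peptides (rank, then lexicographic)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    grouped: dict[str, list[PeptideAssignment]] = {}
    for a in assignments:
        if a.retained:
            grouped.setdefault(a.best_allele, []).append(a)
    return {
        allele: sorted(items, key=lambda a: (a.best_rank, a.peptide))[:n]
        for allele, items in sorted(grouped.items())
    }


def summarize(assignments: list[PeptideAssignment], n_top: int = 3,
              n_input: int | None = None, n_skipped: int = 0) -> DeconvolutionSummary:
    retained = [a for a in assignments if a.retained]
    per_allele = Counter(a.best_allele for a in retained)
    tops = top_epitopes_per_allele(assignments, n_top) if retained else {}
    return DeconvolutionSummary(
        retained_per_allele=dict(sorted(per_allele.items())),
        length_histogram=length_distribution(assignments, retained_only=True),
        top_epitopes={a: [(x.peptide, x.best_rank) for x in items] for a, items in tops.items()},
        n_input=len(assignments) if n_input is None else n_input,
        n_scored=len(assignments),
        n_retained=len(retained),
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# Set-overlap summaries

@dataclass(frozen=True)
class OverlapSummary:
    shared: int
    unique_a: int
    unique_b: int
    shared_pct: int
    unique_a_pct: int
    unique_b_pct: int


def _pct_half_up(count: int, total: int) -> int:
    if total == 0:
        return 0
    share = Decimal(100 * count) / Decimal(total)
    return int(share.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def overlap_summary_from_counts(shared: int, unique_a: int, unique_b: int) -> OverlapSummary:
    """Overlap percentages (of the union, rounded half-up) from raw Venn counts."""
    union = shared + unique_a + unique_b
    return OverlapSummary(
        shared=shared,
        unique_a=unique_a,
        unique_b=unique_b,
        shared_pct=_pct_half_up(shared, union),
        unique_a_pct=_pct_half_up(unique_a, union),
        unique_b_pct=_pct_half_up(unique_b, union),
    )


def overlap_summary(set_a: set, set_b: set) -> OverlapSummary:
    """Shared/unique counts of two identifier sets with whole-percent shares of the union."""
    shared = len(set_a & set_b)
    return overlap_summary_from_counts(shared, len(set_a) - shared, len(set_b) - shared)


# ---------------------------------------------------------------------------
# Reported-table filtering

def filter_epitope_table(
    rows: list[EpitopeTableRow], rank_cutoff: float
) -> tuple[list[EpitopeTableRow], int, int]:
    """Retain rows with EL rank <= cutoff; report row count and distinct genes.

    Inclusive comparison: table rows carry reported (rounded) ranks, so
    boundary values are retained.
    """
    retained = [r for r in rows if r.el_rank_percent <= rank_cutoff]
    genes = {r.gene for r in retained}
    return retained, len(retained), len(genes)
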