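"""Wildtype-vs-mutant epitope scan around protein point variants.

For every peptide window covering a variant position, the wildtype and mutant
windows are scored against every allele; mutant candidates are kept when they
bind at least as strongly as wildtype (rank <=, configurable to strict <) and
clear the class strong-binder bound.
"""

from __future__ import annotations

from dataclasses import dataclass

from .binding_model import AlleleMotifModel, RankCalibration, percent_rank, score_peptide
from .deconvolution import STRONG_BINDER_BOUNDS
from .io_formats import ProteinVariant, ValidationError
from .synthetic_data import CLASS_WINDOWS

DEFAULT_SCAN_LENGTHS: dict[str, tuple[int, ...]] = {
    "I": tuple(range(8, 15)),
    "II": (15,),
}


class ReferenceMismatchError(ValidationError):
    """The variant's reference residue does not match the protein sequence."""


@dataclass
class VariantEpitopeCandidate:
    """One WT/mutant window pair scored against one allele."""

    gene: str
    variant: ProteinVariant
    allele: str
    length: int
    start: int  # 1-based window start in the protein
    wt_peptide: str
    mut_peptide: str
    wt_rank: float
    mut_rank: float
    kept: bool


def enumerate_variant_windows(
    sequence: str, variant: ProteinVariant, lengths: set[int] | tuple[int, ...]
) -> list[tuple[int, int, str, str]]:
    """All (start, length, wt, mut) windows containing the variant position.

    Windows are emitted in (length ascending, start ascending) order; starts
    are 1-based. Raises if the variant position is out of bounds or the
    reference residue disagrees with the sequence.
    """
    pos = variant.position
    if not 1 <= pos <= len(sequence):
        raise ValidationError(
            f"variant {variant.gene}:{pos} outside protein of length {len(sequence)}"
        )
    if sequence[pos - 1] != variant.ref_aa:
        raise ReferenceMismatchError(
            f"variant {variant.gene}:{pos} expects {variant.ref_aa}, "
            f"sequence has {sequence[pos - 1]}"
        )
    mutated = sequence[: pos - 1] + variant.alt_aa + sequence[pos:]
    windows = []
    for length in sorted(lengths):
        first = max(1, pos - length + 1)
        last = min(pos, len(sequence) - length + 1)
        for start in range(first, last + 1):
            wt = sequence[start - 1 : start - 1 + length]
            mut = mutated[start - 1 : start - 1 + length]
            windows.append((start, length, wt, mut))
    return windows


def scan_variant(
    sequence: str,
    variant: ProteinVariant,
    models: dict[str, AlleleMotifModel],
    calibrations: dict[str, RankCalibration],
    lengths_by_class: dict[str, tuple[int, ...]] | None = None,
    strong_bounds: dict[str, float] | None = None,
    strict: bool = False,
) -> list[VariantEpitopeCandidate]:
    """Score every variant window against every allele; flag kept candidates.

    kept iff mut_rank <= wt_rank (or < when ``strict``) and mut_rank is below
    the class strong-binder bound. All candidates are returned so the filter
    is auditable.
    """
    lengths_by_class = lengths_by_class or DEFAULT_SCAN_LENGTHS
    strong_bounds = strong_bounds or STRONG_BINDER_BOUNDS
    candidates: list[VariantEpitopeCandidate] = []
    for name in sorted(models):
        model = models[name]
        cal = calibrations[name]
        bound = strong_bounds[model.hla_class]
        lo, hi = CLASS_WINDOWS[model.hla_class]
        lengths = [
            L for L in lengths_by_class[model.hla_class] if lo <= L <= hi
        ]
        for start, length, wt, mut in enumerate_variant_windows(sequence, variant, lengths):
            wt_rank = percent_rank(cal, score_peptide(model, wt), length)
            mut_rank = percent_rank(cal, score_peptide(model, mut), length)
            stronger = mut_rank < wt_rank if strict else mut_rank <= wt_rank
            candidates.append(
                VariantEpitopeCandidate(
                    gene=variant.gene,
                    variant=variant,
                    allele=name,
                    length=length,
                    start=start,
                    wt_peptide=wt,
                    mut_peptide=mut,
                    wt_rank=wt_rank,
                    mut_rank=mut_rank,
                    kept=stronger and mut_rank < bound,
                )
            )
    return candidates


def summarize_scan(
    candidates: list[VariantEpitopeCandidate],
) -> dict[tuple[str, str], list[VariantEpitopeCandidate]]:
    """Kept candidates grouped by (gene, allele), deduplicated by mutant peptide.

    The same mutant peptide under the same allele counts once, keeping its
    lowest mut_rank; groups are internally sorted by ascending mut_rank.
    """
    best: dict[tuple[str, str, str], VariantEpitopeCandidate] = {}
    for c in candidates:
        if not c.kept:
            continue
        key = (c.gene, c.allele, c.mut_peptide)
        if key not in best or c.mut_rank < best[key].mut_rank:
            best[key] = c
    grouped: dict[tuple[str, str], list[VariantEpitopeCandidate]] = {}
    for (gene, allele, _), c in best.items():
        grouped.setdefault((gene, allele), []).append(c)
    return {
        key: sorted(items, key=lambda c: (c.mut_rank, c.mut_peptide))
        for key, items in sorted(grouped.items())
    }
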