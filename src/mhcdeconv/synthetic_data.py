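"""Synthetic ligandome generation: allele motifs, ligands, decoys, proteomes, variants.

Every generator is driven by named child RNG streams derived from one integer
seed, so outputs are bitwise reproducible and adding an allele never perturbs
another allele's samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import AA_ALPHABET, AA_INDEX, BACKGROUND, N_AA
from .io_formats import PeptideRecord, ProteinVariant, ValidationError

CLASS_WINDOWS: dict[str, tuple[int, int]] = {"I": (8, 14), "II": (11, 20)}

#: Default per-class length sampling weights (class I mode 9, class II mode 15).
DEFAULT_LENGTH_WEIGHTS: dict[str, dict[int, float]] = {
    "I": {8: 0.15, 9: 0.40, 10: 0.18, 11: 0.12, 12: 0.08, 13: 0.04, 14: 0.03},
    "II": {11: 0.04, 12: 0.07, 13: 0.10, 14: 0.15, 15: 0.25,
           16: 0.15, 17: 0.10, 18: 0.07, 19: 0.04, 20: 0.03},
}

CORE_LENGTH = 9
DECOY_LABEL = "decoy"


def _token_seed(token: str) -> int:
    """Stable 64-bit integer derived from a string token."""
    return int.from_bytes(hashlib.sha256(token.encode()).digest()[:8], "little")


def child_rng(seed: int, *tokens: str) -> np.random.Generator:
    """A named child stream: deterministic in (seed, tokens), independent across names."""
    return np.random.default_rng([int(seed)] + [_token_seed(t) for t in tokens])


@dataclass
class SyntheticLigandomeSpec:
    """Parameters of a synthetic ligandome draw.

    alleles: (name, class) pairs with class in {"I", "II"}.
    anchor_positions: per allele, 0-based positions within the 9-residue core
        that carry a concentrated residue preference.
    anchor_residues: optional fixed preferred residues per allele/position;
        positions left unspecified get a deterministic seeded choice.
    motif_sharpness: probability mass on the preferred residue at an anchor.
    """

    alleles: list[tuple[str, str]]
    anchor_positions: dict[str, tuple[int, ...]]
    motif_sharpness: float = 0.8
    length_weights: dict[str, dict[int, float]] = field(
        default_factory=lambda: {c: dict(w) for c, w in DEFAULT_LENGTH_WEIGHTS.items()}
    )
    n_ligands_per_allele: int = 1000
    decoy_fraction: float = 0.0
    seed: int = 0
    anchor_residues: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValidationError("allele list is empty")
        for name, cls in self.alleles:
            if cls not in CLASS_WINDOWS:
                raise ValidationError(f"allele {name}: unknown class {cls!r}")
            if name not in self.anchor_positions:
                raise ValidationError(f"allele {name}: no anchor positions given")
            for pos in self.anchor_positions[name]:
                if not 0 <= pos < CORE_LENGTH:
                    raise ValidationError(f"allele {name}: anchor position {pos} outside core")
        if not (0 < self.motif_sharpness <= 1):
            raise ValidationError("motif_sharpness must be in (0, 1]")
        if not (0 <= self.decoy_fraction < 1):
            raise ValidationError("decoy_fraction must be in [0, 1)")
        if self.n_ligands_per_allele < 1:
            raise ValidationError("n_ligands_per_allele must be positive")
        for cls in {c for _, c in self.alleles}:
            weights = self.length_weights.get(cls, {})
            lo, hi = CLASS_WINDOWS[cls]
            if any(not lo <= length <= hi for length in weights):
                raise ValidationError(f"class {cls} length weights outside [{lo}, {hi}]")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValidationError(f"class {cls} length weights do not sum to 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Mapping peptide sequence -> generating allele name or the decoy label."""

    labels: dict[str, str]

    def label(self, peptide: str) -> str:
        return self.labels[peptide]


def make_allele_motifs(spec: SyntheticLigandomeSpec) -> dict[str, np.ndarray]:
    """Build one (core_length x 20) position-probability matrix per allele.

    Anchor columns put ``motif_sharpness`` mass on the preferred residue and
    spread the remainder over the other 19 residues in proportion to
    background; non-anchor columns are a mild Dirichlet perturbation of the
    background. Deterministic given the spec seed.
    """
    motifs: dict[str, np.ndarray] = {}
    for name, _cls in spec.alleles:
        rng = child_rng(spec.seed, "motif", name)
        mat = np.empty((CORE_LENGTH, N_AA), dtype=float)
        fixed = spec.anchor_residues.get(name, {})
        for pos in range(CORE_LENGTH):
            if pos in spec.anchor_positions[name]:
                if pos in fixed:
                    aa_idx = AA_INDEX[fixed[pos]]
                    rng.integers(N_AA)  # burn a draw so fixed/sampled streams align
                else:
                    aa_idx = int(rng.integers(N_AA))
                if spec.motif_sharpness <= BACKGROUND[aa_idx]:
                    raise ValidationError(
                        f"allele {name}: sharpness {spec.motif_sharpness} does not exceed "
                        f"background frequency of {AA_ALPHABET[aa_idx]}"
                    )
                col = np.zeros(N_AA)
                others = np.arange(N_AA) != aa_idx
                rest = 1.0 - spec.motif_sharpness
                if rest > 0:
                    col[others] = rest * BACKGROUND[others] / BACKGROUND[others].sum()
                col[aa_idx] = spec.motif_sharpness
            else:
                col = rng.dirichlet(BACKGROUND * 200.0)
            mat[pos] = col
        motifs[name] = mat
    return motifs


def _sample_from_columns(rng: np.random.Generator, matrix: np.ndarray, n: int) -> np.ndarray:
    """Draw n core sequences (n x core_length int array) column by column."""
    cores = np.empty((n, matrix.shape[0]), dtype=np.int64)
    for pos in range(matrix.shape[0]):
        cores[:, pos] = rng.choice(N_AA, size=n, p=matrix[pos])
    return cores


def _assemble_class1(rng: np.random.Generator, core: np.ndarray, length: int) -> np.ndarray:
    """Embed a 9-residue core into a class-I peptide of the requested length.

    Inverse of the core mapping used at scoring time: extra residues for
    L > 9 are background insertions after core position 5; an 8-mer drops
    the central core residue.
    """
    if length == CORE_LENGTH:
        return core
    if length == CORE_LENGTH - 1:
        return np.delete(core, 4)
    extra = rng.choice(N_AA, size=length - CORE_LENGTH, p=BACKGROUND)
    return np.concatenate([core[:5], extra, core[5:]])


def _assemble_class2(rng: np.random.Generator, core: np.ndarray, length: int) -> np.ndarray:
    """Pad a 9-residue core with background flanks up to the requested length."""
    flank = length - CORE_LENGTH
    left = int(rng.integers(0, flank + 1)) if flank > 0 else 0
    lflank = rng.choice(N_AA, size=left, p=BACKGROUND)
    rflank = rng.choice(N_AA, size=flank - left, p=BACKGROUND)
    return np.concatenate([lflank, core, rflank])


def _indices_to_seq(idx: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in idx)


def sample_ligandome(
    spec: SyntheticLigandomeSpec, motifs: dict[str, np.ndarray]
) -> tuple[list[PeptideRecord], SyntheticTruth]:
    """Sample ligands per allele plus background decoys, with truth labels.

    Decoy count per class is ``decoy_fraction / (1 - decoy_fraction)`` times
    the class's ligand count, so decoys make up ``decoy_fraction`` of the
    emitted class total.
    """
    if not spec.alleles:
        raise ValidationError("allele list is empty")
    records: list[PeptideRecord] = []
    labels: dict[str, str] = {}

    def _emit(seq: str, label: str) -> None:
        records.append(PeptideRecord(sequence=seq, sample_id="synthetic"))
        labels.setdefault(seq, label)

    class_ligand_counts: dict[str, int] = {}
    for name, cls in spec.alleles:
        rng = child_rng(spec.seed, "ligand", name)
        n = spec.n_ligands_per_allele
        lengths_avail = sorted(spec.length_weights[cls])
        probs = np.array([spec.length_weights[cls][L] for L in lengths_avail])
        drawn = rng.choice(lengths_avail, size=n, p=probs)
        cores = _sample_from_columns(rng, motifs[name], n)
        assemble = _assemble_class1 if cls == "I" else _assemble_class2
        for i in range(n):
            _emit(_indices_to_seq(assemble(rng, cores[i], int(drawn[i]))), name)
        class_ligand_counts[cls] = class_ligand_counts.get(cls, 0) + n

    if spec.decoy_fraction > 0:
        for cls, n_lig in sorted(class_ligand_counts.items()):
            rng = child_rng(spec.seed, "decoy", cls)
            n_decoys = round(spec.decoy_fraction / (1.0 - spec.decoy_fraction) * n_lig)
            lo, hi = CLASS_WINDOWS[cls]
            lengths = rng.integers(lo, hi + 1, size=n_decoys)
            for L in lengths:
                _emit(_indices_to_seq(rng.choice(N_AA, size=int(L), p=BACKGROUND)), DECOY_LABEL)

    return records, SyntheticTruth(labels=labels)


def sample_background_proteome(
    n_proteins: int, mean_length: int, seed: int
) -> list[tuple[str, str]]:
    """Random proteins drawn from the built-in background residue frequencies."""
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    if mean_length < 1:
        raise ValidationError("mean_length must be >= 1")
    rng = child_rng(seed, "proteome")
    proteome = []
    for i in range(n_proteins):
        length = max(20, int(rng.poisson(mean_length)))
        seq = _indices_to_seq(rng.choice(N_AA, size=length, p=BACKGROUND))
        proteome.append((f"SYN{i:05d}", seq))
    return proteome


def make_variant_fixture(
    proteome: list[tuple[str, str]],
    n_variants: int,
    seed: int,
    motifs: dict[str, np.ndarray] | None = None,
    anchor_positions: dict[str, tuple[int, ...]] | None = None,
) -> list[ProteinVariant]:
    """Random point variants over a proteome; ref always matches the sequence.

    When ``motifs`` (and their anchor positions) are supplied, every other
    variant is anchor-improving: its position sits at an anchor offset of a
    9-residue window and the alternate residue is that allele's preferred
    anchor residue, so the mutant window outscores the wildtype window under
    the generating motif.
    """
    if not proteome:
        raise ValidationError("proteome is empty")
    rng = child_rng(seed, "variants")
    allele_names = sorted(motifs) if motifs else []
    variants: list[ProteinVariant] = []
    attempts = 0
    while len(variants) < n_variants and attempts < 100 * n_variants:
        attempts += 1
        pid, seq = proteome[int(rng.integers(len(proteome)))]
        planted = bool(allele_names) and len(variants) % 2 == 0
        if planted and len(seq) >= CORE_LENGTH:
            allele = allele_names[int(rng.integers(len(allele_names)))]
            anchors = (anchor_positions or {}).get(allele)
            if not anchors:
                continue
            start = int(rng.integers(len(seq) - CORE_LENGTH + 1))  # 0-based window start
            offset = int(rng.choice(np.asarray(anchors)))
            position = start + offset + 1
            alt = AA_ALPHABET[int(np.argmax(motifs[allele][offset]))]
            label = f"planted:{allele}"
        else:
            position = int(rng.integers(len(seq))) + 1
            alt = AA_ALPHABET[int(rng.integers(N_AA))]
            label = "random"
        ref = seq[position - 1]
        if ref == alt:
            continue
        variants.append(
            ProteinVariant(gene=pid, protein_id=pid, position=position,
                           ref_aa=ref, alt_aa=alt, disease_label=label)
        )
    if len(variants) < n_variants:
        raise ValidationError("could not place the requested number of variants")
    return variants
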