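"""Amino-acid alphabet, background frequencies, and BLOSUM62 conditionals.

Shared numeric conventions for the whole package: residues are encoded as
integers 0..19 in the fixed order of :data:`AA_ALPHABET`; index 20 is the
neutral placeholder used when an 8-mer is mapped onto a 9-position core.
"""

from __future__ import annotations

import functools

import numpy as np
from Bio.Align import substitution_matrices

AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA: int = 20

#: Index of the neutral gap/placeholder symbol (scores exactly 0 bits).
PLACEHOLDER_INDEX: int = 20
PLACEHOLDER_CHAR: str = "-"

# Average Swiss-Prot residue composition, renormalised to sum to 1.
_RAW_BACKGROUND = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0473,
    "S": 0.0664, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


def background_frequencies() -> np.ndarray:
    """Built-in background residue frequencies, ordered by AA_ALPHABET."""
    v = np.array([_RAW_BACKGROUND[aa] for aa in AA_ALPHABET], dtype=float)
    return v / v.sum()


BACKGROUND: np.ndarray = background_frequencies()


def is_valid_sequence(seq: str) -> bool:
    """True iff ``seq`` is non-empty and uses only the 20 canonical residues."""
    return bool(seq) and all(c in AA_INDEX for c in seq)


def encode(seq: str) -> np.ndarray:
    """Encode a peptide as an int array; placeholder chars map to index 20."""
    try:
        return np.array(
            [PLACEHOLDER_INDEX if c == PLACEHOLDER_CHAR else AA_INDEX[c] for c in seq],
            dtype=np.int64,
        )
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} in {seq!r} is outside the canonical alphabet") from None


def decode(indices: np.ndarray) -> str:
    return "".join(
        PLACEHOLDER_CHAR if i == PLACEHOLDER_INDEX else AA_ALPHABET[i] for i in indices
    )


@functools.lru_cache(maxsize=1)
def blosum62_conditionals() -> np.ndarray:
    """BLOSUM62-derived conditional substitution frequencies.

    Returns a (20, 20) matrix ``C`` with ``C[a, b] = P(a | b)``, obtained by
    exponentiating the half-bit BLOSUM62 log-odds scores against the built-in
    background and renormalising each conditioning column. Columns sum to 1.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    scores = np.empty((N_AA, N_AA), dtype=float)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            scores[i, j] = blosum[a, b]
    # BLOSUM62 scores are log2-odds in half-bit units: q_ab/(p_a p_b) ~ 2^(s/2)
    cond = BACKGROUND[:, None] * np.exp2(scores / 2.0)
    return cond / cond.sum(axis=0, keepdims=True)
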