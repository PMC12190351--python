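"""Per-allele PSSM training, peptide scoring, and percentile-rank calibration.

A transparent substitute for black-box binding predictors: position-specific
log2-odds matrices with BLOSUM62-conditional pseudocounts, scored directly
against a 9-residue core (class I, with length normalisation) or by the best
sliding 9-mer core (class II), then converted to eluted-ligand-style
percentile ranks against an empirical background score distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._alphabet import (
    AA_ALPHABET,
    BACKGROUND,
    N_AA,
    PLACEHOLDER_CHAR,
    blosum62_conditionals,
    encode,
    is_valid_sequence,
)
from .io_formats import ValidationError
from .synthetic_data import CLASS_WINDOWS

DEFAULT_CORE_LENGTH = 9
DEFAULT_BETA = 50.0

#: Class II ranks are always computed against this background window length.
CLASS2_CALIBRATION_LENGTH = 15


class ScoringError(ValueError):
    """A peptide cannot be scored by the requested model."""


# ---------------------------------------------------------------------------
# Core mapping (class I length normalisation)

def _core_index_map(length: int, core_length: int) -> np.ndarray:
    """Peptide index per core position; -1 marks the neutral placeholder.

    length == core: identity. length > core: the central (length - core)
    residues are deleted, keeping ceil(core/2) from the N-side. length ==
    core - 1: a placeholder is inserted at the central core position.
    """
    if length < core_length - 1:
        raise ScoringError(f"length {length} cannot be mapped onto a {core_length}-core")
    if length == core_length:
        return np.arange(core_length)
    n_front = -(-core_length // 2)  # ceil
    if length == core_length - 1:
        idx = np.empty(core_length, dtype=np.int64)
        idx[: n_front - 1] = np.arange(n_front - 1)
        idx[n_front - 1] = -1
        idx[n_front:] = np.arange(n_front - 1, length)
        return idx
    n_back = core_length - n_front
    return np.concatenate([np.arange(n_front), np.arange(length - n_back, length)])


def map_to_core(peptide: str, core_length: int = DEFAULT_CORE_LENGTH) -> str:
    """Map a peptide onto a fixed-length core; placeholder char scores 0 bits."""
    idx = _core_index_map(len(peptide), core_length)
    return "".join(PLACEHOLDER_CHAR if i < 0 else peptide[i] for i in idx)


# ---------------------------------------------------------------------------
# Model

@dataclass
class AlleleMotifModel:
    """Position-specific log2-odds matrix for one allele."""

    allele: str
    hla_class: str
    core_length: int
    log_odds: np.ndarray  # (core_length, 20), bits vs background
    beta: float
    background_freqs: np.ndarray  # (20,)
    n_training_ligands: int

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.hla_class not in CLASS_WINDOWS:
            raise ValidationError(f"unknown HLA class {self.hla_class!r}")
        if self.core_length < 1 or self.log_odds.shape != (self.core_length, N_AA):
            raise ValidationError("log_odds shape does not match core_length x 20")

    @property
    def extended_log_odds(self) -> np.ndarray:
        """log_odds with a 21st zero column for the neutral placeholder."""
        return np.hstack([self.log_odds, np.zeros((self.core_length, 1))])

    @property
    def probabilities(self) -> np.ndarray:
        """Per-position residue probabilities implied by the log-odds."""
        return np.exp2(self.log_odds) * self.background_freqs[None, :]

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in np.argmax(self.log_odds, axis=1))

    def to_dict(self) -> dict:
        return {
            "allele": self.allele,
            "hla_class": self.hla_class,
            "core_length": self.core_length,
            "log_odds": self.log_odds.tolist(),
            "beta": self.beta,
            "background_freqs": self.background_freqs.tolist(),
            "n_training_ligands": self.n_training_ligands,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlleleMotifModel":
        return cls(
            allele=d["allele"],
            hla_class=d["hla_class"],
            core_length=int(d["core_length"]),
            log_odds=np.array(d["log_odds"], dtype=float),
            beta=float(d["beta"]),
            background_freqs=np.array(d["background_freqs"], dtype=float),
            n_training_ligands=int(d["n_training_ligands"]),
        )


def _frequency_matrix(cores: list[str], core_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-position frequencies over cores; placeholders excluded.

    Returns (freqs (core x 20), n_observed (core,)).
    """
    counts = np.zeros((core_length, N_AA), dtype=float)
    n_obs = np.zeros(core_length, dtype=float)
    for core in cores:
        idx = encode(core)
        for pos in range(core_length):
            if idx[pos] < N_AA:
                counts[pos, idx[pos]] += 1.0
                n_obs[pos] += 1.0
    freqs = np.divide(counts, n_obs[:, None], out=np.zeros_like(counts), where=n_obs[:, None] > 0)
    return freqs, n_obs


def _blend_log_odds(
    freqs: np.ndarray, n_obs: np.ndarray, beta: float, background: np.ndarray
) -> np.ndarray:
    """p = (n f + beta g) / (n + beta) with g the BLOSUM62-conditional prior."""
    g = freqs @ blosum62_conditionals().T  # g[pos, a] = sum_b C[a, b] f[pos, b]
    denom = n_obs[:, None] + beta
    p = (n_obs[:, None] * freqs + beta * g) / denom
    with np.errstate(divide="ignore"):
        return np.log2(p / background[None, :])


def build_motif_model(
    ligands: list[str],
    allele: str,
    hla_class: str = "I",
    core_length: int = DEFAULT_CORE_LENGTH,
    beta: float = DEFAULT_BETA,
    background_freqs: np.ndarray | None = None,
    max_refinement_iter: int = 20,
) -> AlleleMotifModel:
    """Train a per-allele PSSM from eluted ligands.

    Class I ligands are mapped to fixed cores; class II ligands are
    core-aligned by iterative best-core refinement starting from the
    N-terminal 9-mer (ties toward the smaller offset, at most
    ``max_refinement_iter`` rounds).
    """
    if not ligands:
        raise ValidationError(f"allele {allele}: no training ligands")
    background = BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    for lig in ligands:
        if not is_valid_sequence(lig):
            raise ScoringError(f"training ligand {lig!r} has non-canonical residues")
        if len(lig) < core_length - (1 if hla_class == "I" else 0):
            raise ScoringError(f"training ligand {lig!r} is shorter than the {core_length}-core")

    if hla_class == "I":
        cores = [map_to_core(lig, core_length) for lig in ligands]
        freqs, n_obs = _frequency_matrix(cores, core_length)
        log_odds = _blend_log_odds(freqs, n_obs, beta, background)
    else:
        encoded = [encode(lig) for lig in ligands]
        offsets = np.zeros(len(ligands), dtype=np.int64)
        log_odds = None
        for _ in range(max_refinement_iter):
            cores = [lig[off : off + core_length] for lig, off in zip(ligands, offsets)]
            freqs, n_obs = _frequency_matrix(cores, core_length)
            log_odds = _blend_log_odds(freqs, n_obs, beta, background)
            new_offsets = offsets.copy()
            for i, idx in enumerate(encoded):
                n_win = len(idx) - core_length + 1
                win_scores = np.array(
                    [log_odds[np.arange(core_length), idx[o : o + core_length]].sum()
                     for o in range(n_win)]
                )
                new_offsets[i] = int(np.argmax(win_scores))  # first max = smallest offset
            if np.array_equal(new_offsets, offsets):
                break
            offsets = new_offsets

    return AlleleMotifModel(
        allele=allele,
        hla_class=hla_class,
        core_length=core_length,
        log_odds=log_odds,
        beta=beta,
        background_freqs=background,
        n_training_ligands=len(ligands),
    )


# ---------------------------------------------------------------------------
# Scoring

def _check_window(model: AlleleMotifModel, length: int) -> None:
    lo, hi = CLASS_WINDOWS[model.hla_class]
    if not lo <= length <= hi:
        raise ScoringError(
            f"length {length} outside the class {model.hla_class} window [{lo}, {hi}]"
        )


def score_peptide(model: AlleleMotifModel, peptide: str) -> float:
    """Score one peptide in bits (class I: mapped core; class II: best core)."""
    if not is_valid_sequence(peptide):
        raise ScoringError(f"peptide {peptide!r} has non-canonical residues")
    _check_window(model, len(peptide))
    return float(score_peptides(model, [peptide])[0])


def score_peptides(model: AlleleMotifModel, peptides: list[str]) -> np.ndarray:
    """Vectorised scoring of a peptide list (mixed lengths allowed)."""
    scores = np.empty(len(peptides), dtype=float)
    by_length: dict[int, list[int]] = {}
    for i, pep in enumerate(peptides):
        by_length.setdefault(len(pep), []).append(i)
    ext = model.extended_log_odds
    core = model.core_length
    pos_idx = np.arange(core)
    for length, idxs in by_length.items():
        _check_window(model, length)
        mat = np.stack([encode(peptides[i]) for i in idxs])  # (n, L)
        if model.hla_class == "I":
            cmap = _core_index_map(length, core)
            cores = np.where(cmap[None, :] < 0, N_AA, mat[:, np.clip(cmap, 0, None)])
            scores[idxs] = ext[pos_idx[None, :], cores].sum(axis=1)
        else:
            wins = np.lib.stride_tricks.sliding_window_view(mat, core, axis=1)  # (n, W, core)
            win_scores = ext[pos_idx[None, None, :], wins].sum(axis=-1)
            scores[idxs] = win_scores.max(axis=1)
    return scores


# ---------------------------------------------------------------------------
# Rank calibration

@dataclass
class RankCalibration:
    """Per-length sorted background score distributions for one allele."""

    allele: str
    hla_class: str
    background_scores: dict[int, np.ndarray]  # length -> sorted ascending
    seed: int
    source: str = ""

    def __post_init__(self) -> None:
        for length, arr in self.background_scores.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1 or arr.size < 1:
                raise ValidationError(f"empty calibration array for length {length}")
            self.background_scores[length] = np.sort(arr)

    @property
    def m_per_length(self) -> dict[int, int]:
        return {length: int(arr.size) for length, arr in self.background_scores.items()}

    def query_length(self, peptide_length: int) -> int:
        """Calibration length used for a query peptide of the given length."""
        if self.hla_class == "II":
            return CLASS2_CALIBRATION_LENGTH
        return peptide_length

    def to_dict(self) -> dict:
        return {
            "allele": self.allele,
            "hla_class": self.hla_class,
            "seed": self.seed,
            "source": self.source,
            "background_scores": {str(k): v.tolist() for k, v in self.background_scores.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RankCalibration":
        return cls(
            allele=d["allele"],
            hla_class=d["hla_class"],
            background_scores={int(k): np.array(v, float) for k, v in d["background_scores"].items()},
            seed=int(d["seed"]),
            source=d.get("source", ""),
        )


def calibrate_ranks(
    model: AlleleMotifModel,
    background_proteome: list[tuple[str, str]],
    lengths: list[int] | None = None,
    m_per_length: int = 10_000,
    seed: int = 0,
) -> RankCalibration:
    """Empirical background score distribution from random proteome windows.

    For each length, ``m_per_length`` windows are sampled uniformly (with
    replacement) over all valid windows of all proteins, scored, and sorted.
    Class II calibrates 15-mer windows only, used for every query length.
    """
    if lengths is None:
        if model.hla_class == "I":
            lo, hi = CLASS_WINDOWS["I"]
            lengths = list(range(lo, hi + 1))
        else:
            lengths = [CLASS2_CALIBRATION_LENGTH]
    rng = np.random.default_rng([int(seed)] + [hash_allele(model.allele)])
    sequences = [seq for _, seq in background_proteome]
    calib: dict[int, np.ndarray] = {}
    for length in lengths:
        counts = np.array([max(0, len(s) - length + 1) for s in sequences], dtype=np.int64)
        total = int(counts.sum())
        if total < m_per_length:
            raise ValidationError(
                f"background proteome provides {total} windows of length {length}, "
                f"fewer than the requested {m_per_length}"
            )
        cum = np.cumsum(counts)
        draws = rng.integers(0, total, size=m_per_length)
        prot = np.searchsorted(cum, draws, side="right")
        start = draws - (cum[prot] - counts[prot])
        peptides = [sequences[p][s : s + length] for p, s in zip(prot, start)]
        calib[length] = np.sort(score_peptides(model, peptides))
    return RankCalibration(
        allele=model.allele,
        hla_class=model.hla_class,
        background_scores=calib,
        seed=int(seed),
        source=f"{len(background_proteome)} background proteins",
    )


def hash_allele(name: str) -> int:
    """Stable non-negative integer from an allele name (seeds calibration draws)."""
    import hashlib

    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "little")


def percent_rank(calibration: RankCalibration, score: float, length: int) -> float:
    """Percentile rank in (0, 100]: 100 * (1 + #{bg >= score}) / (M + 1)."""
    return float(percent_ranks(calibration, np.array([score]), length)[0])


def percent_ranks(calibration: RankCalibration, scores: np.ndarray, length: int) -> np.ndarray:
    length = calibration.query_length(length)
    if length not in calibration.background_scores:
        raise ScoringError(
            f"no calibration for length {length} (allele {calibration.allele})"
        )
    arr = calibration.background_scores[length]
    m = arr.size
    count_ge = m - np.searchsorted(arr, np.asarray(scores, dtype=float), side="left")
    return 100.0 * (1.0 + count_ge) / (m + 1.0)


# ---------------------------------------------------------------------------
# Serialization

def save_models(path: str | Path, models: dict[str, AlleleMotifModel]) -> None:
    payload = {name: m.to_dict() for name, m in sorted(models.items())}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path: str | Path) -> dict[str, AlleleMotifModel]:
    payload = json.loads(Path(path).read_text())
    return {name: AlleleMotifModel.from_dict(d) for name, d in payload.items()}


def save_calibrations(path: str | Path, calibrations: dict[str, RankCalibration]) -> None:
    payload = {name: c.to_dict() for name, c in sorted(calibrations.items())}
    Path(path).write_text(json.dumps(payload))


def load_calibrations(path: str | Path) -> dict[str, RankCalibration]:
    payload = json.loads(Path(path).read_text())
    return {name: RankCalibration.from_dict(d) for name, d in payload.items()}
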