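import numpy as np
import pytest

from mhcdeconv.binding_model import build_motif_model, calibrate_ranks
from mhcdeconv.synthetic_data import (
    SyntheticLigandomeSpec,
    make_allele_motifs,
    sample_background_proteome,
    sample_ligandome,
)


@pytest.fixture(scope="session")
def background_proteome():
    return sample_background_proteome(n_proteins=150, mean_length=500, seed=99)


@pytest.fixture(scope="session")
def two_allele_spec():
    """Fixed-seed two-allele class-I ligandome with disjoint anchor residues."""
    return SyntheticLigandomeSpec(
        alleles=[("SYN-A", "I"), ("SYN-B", "I")],
        anchor_positions={"SYN-A": (1, 8), "SYN-B": (1, 8)},
        anchor_residues={"SYN-A": {1: "L", 8: "V"}, "SYN-B": {1: "K", 8: "R"}},
        motif_sharpness=0.9,
        n_ligands_per_allele=500,
        decoy_fraction=0.2,
        seed=1234,
    )


@pytest.fixture(scope="session")
def two_allele_ligandome(two_allele_spec):
    motifs = make_allele_motifs(two_allele_spec)
    records, truth = sample_ligandome(two_allele_spec, motifs)
    return motifs, records, truth


@pytest.fixture(scope="session")
def two_allele_models(two_allele_spec, two_allele_ligandome):
    _, records, truth = two_allele_ligandome
    by_allele = {}
    for rec in records:
        by_allele.setdefault(truth.labels[rec.sequence], []).append(rec.sequence)
    return {
        name: build_motif_model(by_allele[name], allele=name, hla_class="I")
        for name, _ in two_allele_spec.alleles
    }


@pytest.fixture(scope="session")
def two_allele_calibrations(two_allele_models, background_proteome):
    return {
        name: calibrate_ranks(model, background_proteome, m_per_length=5000, seed=5)
        for name, model in two_allele_models.items()
    }


@pytest.fixture(scope="session")
def single_allele_model(background_proteome):
    """One class-I allele trained on its own synthetic ligands, plus calibration."""
    spec = SyntheticLigandomeSpec(
        alleles=[("SOLO", "I")],
        anchor_positions={"SOLO": (1, 8)},
        anchor_residues={"SOLO": {1: "Y", 8: "K"}},
        motif_sharpness=0.85,
        n_ligands_per_allele=400,
        seed=77,
    )
    motifs = make_allele_motifs(spec)
    records, truth = sample_ligandome(spec, motifs)
    model = build_motif_model([r.sequence for r in records], allele="SOLO", hla_class="I")
    calibration = calibrate_ranks(model, background_proteome, m_per_length=10_000, seed=6)
    return spec, motifs, model, calibration


def rng_background_peptides(seed: int, n: int, length: int) -> list[str]:
    """Fresh background peptides, independent of any package sampling path."""
    from mhcdeconv._alphabet import AA_ALPHABET, BACKGROUND

    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n, length), p=BACKGROUND)
    return ["".join(AA_ALPHABET[i] for i in row) for row in draws]
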