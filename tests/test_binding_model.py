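import itertools

import numpy as np
import pytest
from scipy import stats

from mhcdeconv._alphabet import (
    AA_ALPHABET,
    AA_INDEX,
    BACKGROUND,
    blosum62_conditionals,
)
from mhcdeconv.binding_model import (
    AlleleMotifModel,
    RankCalibration,
    ScoringError,
    build_motif_model,
    calibrate_ranks,
    load_calibrations,
    load_models,
    map_to_core,
    percent_rank,
    percent_ranks,
    save_calibrations,
    save_models,
    score_peptide,
    score_peptides,
)
from mhcdeconv.io_formats import ValidationError

from conftest import rng_background_peptides


def point_mass_model(consensus: str = "YLKAFWHVK") -> AlleleMotifModel:
    """Model whose per-position probability is 1 on the consensus residue,
    against a uniform background of 1/20."""
    uniform = np.full(20, 0.05)
    log_odds = np.full((9, 20), -np.inf)
    for i, aa in enumerate(consensus):
        log_odds[i, AA_INDEX[aa]] = np.log2(1.0 / 0.05)
    return AlleleMotifModel(
        allele="PM", hla_class="I", core_length=9, log_odds=log_odds,
        beta=0.0, background_freqs=uniform, n_training_ligands=1,
    )


def null_model(hla_class: str = "I") -> AlleleMotifModel:
    return AlleleMotifModel(
        allele="NULL", hla_class=hla_class, core_length=9,
        log_odds=np.zeros((9, 20)), beta=0.0,
        background_freqs=BACKGROUND, n_training_ligands=0,
    )


class TestMapToCore:
    def test_identity_for_core_length(self):
        assert map_to_core("ACDEFGHIK", 9) == "ACDEFGHIK"

    def test_ten_mer_deletes_one_central_residue(self):
        # keep ceil(9/2)=5 from the N side, then the last 4 residues
        assert map_to_core("ACDEFGHIKL", 9) == "ACDEF" + "HIKL"

    def test_fourteen_mer(self):
        pep = "ACDEFGHIKLMNPQ"
        assert map_to_core(pep, 9) == pep[:5] + pep[-4:]

    def test_eight_mer_placeholder_central(self):
        core = map_to_core("ACDEFGHI", 9)
        assert len(core) == 9
        assert core == "ACDE-FGHI"

    def test_too_short_errors(self):
        with pytest.raises(ScoringError):
            map_to_core("ACDEFGH", 9)


class TestBuildMotifModel:
    def test_single_ligand_no_pseudocounts(self):
        model = build_motif_model(["AAAAAAAAA"], "X", beta=0.0)
        probs = model.probabilities
        np.testing.assert_allclose(probs[:, AA_INDEX["A"]], 1.0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_blosum_blending_single_ligand(self):
        # n=1, beta=1: p = (f + g)/2 with g the BLOSUM62-conditional prior of f
        model = build_motif_model(["AAAAAAAAA"], "X", beta=1.0)
        g_a = blosum62_conditionals()[AA_INDEX["A"], AA_INDEX["A"]]
        expected = (1.0 + g_a) / 2.0
        np.testing.assert_allclose(model.probabilities[:, AA_INDEX["A"]], expected, rtol=1e-9)

    def test_shared_anchor_argmax_recovered(self):
        rng = np.random.default_rng(0)
        ligands = []
        for _ in range(100):
            pep = [AA_ALPHABET[i] for i in rng.integers(0, 20, size=9)]
            pep[8] = "K"
            ligands.append("".join(pep))
        model = build_motif_model(ligands, "X", beta=0.0)
        assert AA_ALPHABET[np.argmax(model.log_odds[8])] == "K"

    def test_probability_rows_sum_to_one(self, two_allele_models):
        for model in two_allele_models.values():
            np.testing.assert_allclose(model.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_ligands_rejected(self):
        with pytest.raises(ValidationError):
            build_motif_model([], "X")

    def test_short_ligand_named_in_error(self):
        with pytest.raises(ScoringError, match="ACDEFGH"):
            build_motif_model(["ACDEFGH"], "X")

    def test_anchor_recovery_from_synthetic_ligands(self, two_allele_spec,
                                                    two_allele_ligandome, two_allele_models):
        # training on >=200 ligands at sharpness 0.9 recovers every anchor argmax
        motifs, _, _ = two_allele_ligandome
        for name, model in two_allele_models.items():
            for pos in two_allele_spec.anchor_positions[name]:
                assert np.argmax(model.log_odds[pos]) == np.argmax(motifs[name][pos])

    def test_class2_refinement_recovers_core_register(self):
        # refinement must place every ligand's best core at a register offset
        # consistent (up to one global shift) with the embedded true core
        rng = np.random.default_rng(5)
        core_consensus = "YFWKDERHM"
        ligands, lefts = [], []
        for _ in range(150):
            flank = lambda n: "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=n))
            left = int(rng.integers(0, 7))
            ligands.append(flank(left) + core_consensus + flank(6 - left))
            lefts.append(left)
        model = build_motif_model(ligands, "X", hla_class="II", beta=5.0)
        shifts = []
        for lig, left in zip(ligands, lefts):
            win_scores = [
                model.log_odds[np.arange(9), [AA_INDEX[c] for c in lig[o : o + 9]]].sum()
                for o in range(len(lig) - 8)
            ]
            shifts.append(int(np.argmax(win_scores)) - left)
        values, counts = np.unique(shifts, return_counts=True)
        dominant = int(values[np.argmax(counts)])
        assert abs(dominant) <= 1
        # ligands whose flank is too short to realize the dominant shift clip
        # to the nearest feasible offset
        n_consistent = sum(
            shift == dominant or left + shift == np.clip(left + dominant, 0, len(lig) - 9)
            for shift, left, lig in zip(shifts, lefts, ligands)
        )
        assert n_consistent >= 0.95 * len(ligands)
        # and the learned consensus reproduces the true core at that register
        learned = model.consensus()
        if dominant == 0:
            assert learned == core_consensus
        elif dominant < 0:
            assert learned[-dominant:] == core_consensus[:dominant]
        else:
            assert learned[:-dominant] == core_consensus[dominant:]


class TestScorePeptide:
    def test_point_mass_consensus_score(self):
        model = point_mass_model("YLKAFWHVK")
        assert score_peptide(model, "YLKAFWHVK") == pytest.approx(9 * np.log2(20))

    def test_class2_embedded_core_attains_max(self):
        consensus = "YFWKDERHM"
        model = build_motif_model([consensus], "X", hla_class="II", beta=0.0)
        embedded = "AAA" + consensus + "AAA"
        core_score = model.log_odds[
            np.arange(9), [AA_INDEX[c] for c in consensus]
        ].sum()
        assert score_peptide(model, embedded) == pytest.approx(core_score)

    def test_null_model_scores_zero(self):
        model = null_model()
        for pep in ("ACDEFGHIK", "ACDEFGHIKLMNPQ", "ACDEFGHI"):
            assert score_peptide(model, pep) == 0.0

    def test_eight_mer_scores_real_positions_only(self):
        model = null_model()
        rng_lo = np.random.default_rng(1).normal(size=(9, 20))
        model.log_odds = rng_lo
        pep = "ACDEFGHI"
        core = map_to_core(pep, 9)
        expected = sum(
            rng_lo[i, AA_INDEX[c]] for i, c in enumerate(core) if c != "-"
        )
        assert score_peptide(model, pep) == pytest.approx(expected)

    def test_window_violation_errors(self):
        with pytest.raises(ScoringError):
            score_peptide(null_model("I"), "A" * 16)
        with pytest.raises(ScoringError):
            score_peptide(null_model("II"), "A" * 9)

    def test_non_canonical_residue_errors(self):
        with pytest.raises(ScoringError):
            score_peptide(null_model(), "ACDEFGHIX")

    def test_vectorized_matches_scalar(self, two_allele_models):
        model = next(iter(two_allele_models.values()))
        peps = rng_background_peptides(3, 50, 9) + rng_background_peptides(4, 50, 12)
        np.testing.assert_allclose(
            score_peptides(model, peps), [score_peptide(model, p) for p in peps]
        )


class TestCalibration:
    def test_determinism(self, single_allele_model, background_proteome):
        _, _, model, _ = single_allele_model
        c1 = calibrate_ranks(model, background_proteome, lengths=[9], m_per_length=1000, seed=3)
        c2 = calibrate_ranks(model, background_proteome, lengths=[9], m_per_length=1000, seed=3)
        np.testing.assert_array_equal(c1.background_scores[9], c2.background_scores[9])

    def test_arrays_ascending(self, single_allele_model):
        _, _, _, calibration = single_allele_model
        for arr in calibration.background_scores.values():
            assert np.all(np.diff(arr) >= 0)

    def test_proteome_too_short_errors(self, single_allele_model):
        _, _, model, _ = single_allele_model
        with pytest.raises(ValidationError):
            calibrate_ranks(model, [("P1", "ACDEFGHIKL")], lengths=[9], m_per_length=100)

    def test_self_calibration_uniform(self, single_allele_model):
        # fresh background 9-mers ranked against the calibration: uniform on (0,100]
        _, _, model, calibration = single_allele_model
        peps = rng_background_peptides(123, 10_000, 9)
        ranks = percent_ranks(calibration, score_peptides(model, peps), 9)
        ks = stats.kstest(ranks / 100.0, "uniform").statistic
        assert ks < 0.05

    def test_roundtrip_serialization(self, single_allele_model, tmp_path):
        _, _, model, calibration = single_allele_model
        save_models(tmp_path / "m.json", {"SOLO": model})
        save_calibrations(tmp_path / "c.json", {"SOLO": calibration})
        m2 = load_models(tmp_path / "m.json")["SOLO"]
        c2 = load_calibrations(tmp_path / "c.json")["SOLO"]
        np.testing.assert_array_equal(m2.log_odds, model.log_odds)
        for length in calibration.background_scores:
            np.testing.assert_array_equal(
                c2.background_scores[length], calibration.background_scores[length]
            )
        peps = rng_background_peptides(9, 20, 9)
        np.testing.assert_allclose(score_peptides(m2, peps), score_peptides(model, peps))


class TestPercentRank:
    def make_calibration(self, scores):
        return RankCalibration(
            allele="X", hla_class="I",
            background_scores={9: np.asarray(scores, dtype=float)}, seed=0,
        )

    def test_top_rank_plus_one_smoothing(self):
        cal = self.make_calibration(np.arange(9999))
        assert percent_rank(cal, 1e9, 9) == pytest.approx(100.0 / 10_000)

    def test_bottom_rank_is_100(self):
        cal = self.make_calibration(np.arange(9999))
        assert percent_rank(cal, -1e9, 9) == pytest.approx(100.0)

    def test_median_rank_about_50(self):
        m = 9999
        rng = np.random.default_rng(2)
        scores = rng.normal(size=m)
        cal = self.make_calibration(scores)
        median = float(np.median(scores))
        # brute-force tie counting oracle
        count_ge = int(np.sum(scores >= median))
        expected = 100.0 * (1 + count_ge) / (m + 1)
        assert percent_rank(cal, median, 9) == pytest.approx(expected)
        assert abs(percent_rank(cal, median, 9) - 50.0) <= 100.0 / (m + 1) + 1e-9

    def test_missing_length_errors(self):
        cal = self.make_calibration([0.0, 1.0])
        with pytest.raises(ScoringError):
            percent_rank(cal, 0.5, 10)

    def test_monotone_in_score(self):
        cal = self.make_calibration(np.random.default_rng(0).normal(size=500))
        scores = np.linspace(-3, 3, 101)
        ranks = percent_ranks(cal, scores, 9)
        assert np.all(np.diff(ranks) <= 0)

    def test_class2_uses_single_calibration_length(self):
        cal = RankCalibration(
            allele="X", hla_class="II",
            background_scores={15: np.arange(100, dtype=float)}, seed=0,
        )
        for length in (11, 15, 20):
            assert percent_rank(cal, 50.0, length) == percent_rank(cal, 50.0, 15)


class TestConsensusDominance:
    def test_exhaustive_four_letter_alphabet(self):
        # consensus attains the max score over every 9-mer on {A,K,W,E}
        letters = "AKWE"
        rng = np.random.default_rng(7)
        log_odds = rng.normal(size=(9, 20))
        model = AlleleMotifModel(
            allele="X", hla_class="I", core_length=9, log_odds=log_odds,
            beta=0.0, background_freqs=BACKGROUND, n_training_ligands=0,
        )
        sub = [AA_INDEX[c] for c in letters]
        consensus = "".join(
            letters[int(np.argmax(log_odds[i, sub]))] for i in range(9)
        )
        best = score_peptide(model, consensus)
        # brute-force oracle: direct matrix sums over all 4^9 index tuples
        combos = np.array(list(itertools.product(sub, repeat=9)), dtype=np.int64)
        all_scores = log_odds[np.arange(9)[None, :], combos].sum(axis=1)
        assert best == pytest.approx(all_scores.max())
        # and therefore the minimum rank among same-length peptides
        cal = RankCalibration(
            allele="X", hla_class="I",
            background_scores={9: np.sort(all_scores)}, seed=0,
        )
        ranks = percent_ranks(cal, all_scores, 9)
        assert percent_rank(cal, best, 9) == pytest.approx(ranks.min())
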