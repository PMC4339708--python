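"""Profile-HMM build, Viterbi search, and E-value calibration."""

import json

import numpy as np
import pytest

from bhlhkit.hmm import (
    AMINO_ACIDS,
    AA_INDEX,
    AlphabetError,
    CalibrationError,
    GumbelCalibration,
    MotifAlignment,
    ProfileHMM,
    build_profile,
    calibrate_evalues,
    enumerate_paths_score,
    scan_motifs,
    viterbi_search,
)

MOTIF40 = "GLCLVPVSCTQQVGSENGADYWAPAYGGG"


def random_model(rng, max_L=4, max_cols_extra=2):
    """A small random model (or None if no column passes the threshold)."""
    L = int(rng.integers(1, max_L + 1))
    ncols = int(rng.integers(L, L + max_cols_extra + 1))
    nrows = int(rng.integers(1, 5))
    rows = [(f"r{r}", "".join(rng.choice(list(AMINO_ACIDS + "--"), size=ncols)))
            for r in range(nrows)]
    try:
        return build_profile(MotifAlignment("m", rows))
    except ValueError:
        return None


class TestBuildProfile:
    def test_single_sequence_degenerate_alignment(self):
        hmm = build_profile(MotifAlignment("toy", [("s1", "ACD")]))
        assert hmm.L == 3
        modal = [AMINO_ACIDS[int(np.argmax(hmm.match_emissions[i]))] for i in range(3)]
        assert modal == ["A", "C", "D"]

    def test_mostly_gap_column_becomes_insert_state(self):
        aln = MotifAlignment("g", [("a", "AAA"), ("b", "A-A"), ("c", "A-A"), ("d", "A-A")])
        hmm = build_profile(aln, match_threshold=0.5)
        assert hmm.L == aln.n_columns - 1
        assert hmm.build_metadata["match_columns"] == [0, 2]

    def test_laplace_pseudocounts(self):
        hmm = build_profile(MotifAlignment("col", [("a", "A"), ("b", "A"), ("c", "C")]))
        assert hmm.match_emissions[0, AA_INDEX["A"]] == pytest.approx(3 / 23)
        assert hmm.match_emissions[0, AA_INDEX["C"]] == pytest.approx(2 / 23)
        assert hmm.match_emissions[0, AA_INDEX["W"]] == pytest.approx(1 / 23)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MotifAlignment("e", [])

    def test_illegal_symbol_reported_with_location(self):
        with pytest.raises(AlphabetError, match="row 'b', column 2"):
            MotifAlignment("bad", [("a", "AC"), ("b", "AZ")])

    def test_normalization_holds_for_random_alignments(self):
        rng = np.random.default_rng(42)
        built = 0
        for _ in range(50):
            hmm = random_model(rng, max_L=6, max_cols_extra=3)
            if hmm is None:
                continue
            hmm.validate()  # raises on any normalization violation
            built += 1
        assert built >= 30

    def test_json_round_trip(self):
        hmm = build_profile(MotifAlignment("rt", [("a", "ACDEF"), ("b", "ACD-F")]))
        clone = ProfileHMM.from_json(hmm.to_json())
        assert clone.L == hmm.L
        np.testing.assert_allclose(clone.match_emissions, hmm.match_emissions)
        np.testing.assert_allclose(clone.transitions, hmm.transitions)
        assert clone.build_metadata["match_columns"] == hmm.build_metadata["match_columns"]


class TestViterbi:
    def test_unique_high_scoring_placement(self):
        hmm = build_profile(MotifAlignment("hlh", [(f"s{i}", "HLH") for i in range(5)]))
        hit = viterbi_search(hmm, "AAHLHAA", "t")
        assert (hit.model_start, hit.model_end) == (1, 3)
        assert (hit.env_start, hit.env_end) == (2, 5)
        assert hit.bit_score > 0

    def test_score_equals_exhaustive_enumeration(self):
        """Dynamic programming agrees with brute-force path enumeration."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            hmm = random_model(rng)
            if hmm is None:
                continue
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 7))))
            v = viterbi_search(hmm, seq).bit_score
            o = enumerate_paths_score(hmm, seq)
            assert v == pytest.approx(o, abs=1e-6)
            checked += 1

    def test_training_rows_score_positive(self):
        rows = [("a", "WNDYKT"), ("b", "WNDYKT"), ("c", "WNDYKT"), ("d", "WNDFKT")]
        hmm = build_profile(MotifAlignment("t", rows))
        for _, seq in rows:
            assert viterbi_search(hmm, seq.replace("-", "")).bit_score > 0

    def test_background_padding_cannot_decrease_score(self):
        rng = np.random.default_rng(11)
        hmm = build_profile(MotifAlignment("p", [("a", "WNDYK"), ("b", "WNDYK")]))
        core = "WNDYK"
        base = viterbi_search(hmm, core).bit_score
        for _ in range(10):
            pad_l = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 20))))
            pad_r = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 20))))
            padded = viterbi_search(hmm, pad_l + core + pad_r).bit_score
            assert padded >= base - 1e-9

    def test_x_scores_as_background_and_other_codes_rejected(self):
        hmm = build_profile(MotifAlignment("x", [("a", "WND"), ("b", "WND")]))
        hit = viterbi_search(hmm, "WXD")
        assert hit is not None
        with pytest.raises(AlphabetError):
            viterbi_search(hmm, "WBD")

    def test_deletion_path_reported(self):
        # one training row skips column 3, so the delete transition is
        # affordable and the optimal path for the 4-mer uses it
        rows = [(f"s{i}", "WNDYK") for i in range(4)] + [("gap", "WN-YK")]
        hmm = build_profile(MotifAlignment("d", rows))
        hit = viterbi_search(hmm, "WNYK")
        kinds = [(k, m) for k, m, _ in hit.state_path]
        assert ("D", 3) in kinds
        assert (hit.model_start, hit.model_end) == (1, 5)


@pytest.fixture(scope="module")
def model():
    rows = [(f"s{i}", MOTIF40) for i in range(3)]
    return build_profile(MotifAlignment("Motif40", rows))


@pytest.fixture(scope="module")
def calibration(model):
    return calibrate_evalues(model, length=300, n_shuffles=100, seed=3)


@pytest.fixture(scope="module")
def motif_setup():
    rng = np.random.default_rng(5)
    rows = [("cons", MOTIF40)]
    for r in range(2):
        var = list(MOTIF40)
        for i in rng.choice(len(var), size=2, replace=False):
            var[i] = str(rng.choice([a for a in AMINO_ACIDS if a != var[i]]))
        rows.append((f"v{r}", "".join(var)))
    m = build_profile(MotifAlignment("Motif40", rows))
    cal = calibrate_evalues(m, length=400, n_shuffles=100, seed=9)
    return m, cal


class TestCalibration:
    def test_same_seed_bit_identical(self, model, calibration):
        again = calibrate_evalues(model, length=300, n_shuffles=100, seed=3)
        assert (again.mu, again.lam) == (calibration.mu, calibration.lam)

    def test_evalue_strictly_decreasing_in_score(self, calibration):
        # strictly decreasing through the tail; saturated at 1 far below it
        scores = np.linspace(calibration.mu, calibration.mu + 40, 60)
        evs = [calibration.evalue(s) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))
        assert calibration.evalue(calibration.mu - 100) == 1.0

    def test_median_shuffled_score_has_half_database_evalue(self, model, calibration):
        rng = np.random.default_rng(3)
        aas = np.array(list(AMINO_ACIDS))
        scores = [viterbi_search(model, "".join(rng.choice(aas, size=300))).bit_score
                  for _ in range(calibration.n_shuffles)]
        median = float(np.median(scores))
        e_at_median = calibration.evalue(median, n_targets=calibration.n_shuffles)
        assert e_at_median == pytest.approx(calibration.n_shuffles / 2, rel=0.2)

    def test_degenerate_scores_raise(self):
        # a model whose every shuffle scores identically cannot be fitted
        hmm = build_profile(MotifAlignment("one", [("a", "A")]))
        uniform = type(hmm)(
            name="flat", L=1,
            match_emissions=np.full((1, 20), 1 / 20),
            insert_emissions=np.full((2, 20), 1 / 20),
            transitions=hmm.transitions.copy(),
            background=np.full(20, 1 / 20))
        with pytest.raises(CalibrationError):
            calibrate_evalues(uniform, length=5, n_shuffles=100, seed=0)

    def test_minimum_shuffles_enforced(self, model):
        with pytest.raises(ValueError):
            calibrate_evalues(model, n_shuffles=50, seed=0)
        with pytest.raises(ValueError):
            GumbelCalibration(mu=0.0, lam=-1.0, n_shuffles=100, length=10, seed=0)


class TestScanMotifs:
    def test_planted_consensus_found_below_1e_7(self, motif_setup):
        model, cal = motif_setup
        rng = np.random.default_rng(1)
        aas = np.array(list(AMINO_ACIDS))
        flank = lambda n: "".join(rng.choice(aas, size=n))
        protein = flank(140) + MOTIF40 + flank(140)
        hits = scan_motifs(protein, [model], {"Motif40": cal}, "p1")
        assert len(hits) == 1
        assert hits[0].evalue < 1e-7
        # the envelope covers the strongly conserved core of the motif
        core_start = 140 + MOTIF40.index("NGADYWAP")
        assert hits[0].env_start <= core_start
        assert hits[0].env_end >= core_start + len("NGADYWAP")

    def test_empty_model_list(self):
        assert scan_motifs("ACDEF", [], {}) == []

    def test_null_sequences_rarely_reach_1e_4(self, motif_setup):
        model, cal = motif_setup
        rng = np.random.default_rng(123)
        aas = np.array(list(AMINO_ACIDS))
        false_hits = 0
        for _ in range(100):
            protein = "".join(rng.choice(aas, size=300))
            hits = scan_motifs(protein, [model], {"Motif40": cal}, "null",
                               max_evalue=1e-4)
            false_hits += bool(hits)
        assert false_hits <= 5

    def test_ambiguity_codes_other_than_x_rejected(self, motif_setup):
        model, _ = motif_setup
        with pytest.raises(AlphabetError):
            scan_motifs("ACDB", [model], {})
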