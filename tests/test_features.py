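"""Feature layout, PSSM parsing, fragment feature and window extraction."""

import numpy as np
import pytest

from torsionnet.features import (LAYOUT_V1, ErrorDistributionTable,
                                 FeatureMatrix, PSSMFormatError, WindowConfig,
                                 ZERO_SET, build_residue_features,
                                 estimate_error_distribution, extract_windows,
                                 fragment_feature, fragment_mean_angles,
                                 normalize_pssm, parse_pssm)
from torsionnet.physchem import AMINO_ACIDS, PHYSCHEM_SCALED

# a tiny hand-written PSI-BLAST style PSSM: header in non-canonical column
# order, three residues, footer statistics
_PSSM_TEXT = """
Last position-specific scoring matrix computed, weight ratio ...

           R  A  C  D  E  F  G  H  I  K  L  M  N  P  Q  S  T  V  W  Y
    1 M   -2  0  1 -3 -2  0 -3 -2  1 -1  2  6 -2 -2  0 -1 -1  1 -1 -1
    2 A   -1  4 -1 -2 -1 -2  0 -2 -1 -1 -1 -1 -2 -1 -1  1  0  0 -3 -2
    3 G    0 -1 -2 -1 -2 -3  6 -2 -4 -1 -4 -3  0 -2 -2  0 -2 -3 -2 -3

                      K         Lambda
Standard Ungapped    0.1347     0.3023
"""


class TestLayout:
    def test_widths_sum_to_56(self):
        assert LAYOUT_V1.width == 56
        assert sum(w for _, w in LAYOUT_V1.blocks) == 56

    @pytest.mark.parametrize("w", [1, 3, 5, 7, 9, 11, 13, 15, 17])
    def test_window_row_lengths(self, w):
        # 56 * w reproduces the windowed input widths 56 .. 952
        m = FeatureMatrix("p", np.random.default_rng(0).random((20, 56)))
        out = extract_windows(m, WindowConfig(w))
        assert out.shape == (20, 56 * w)

    def test_window_halfwidth(self):
        assert WindowConfig(15).k == 7
        assert WindowConfig(1).k == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(4)

    def test_subset_preserves_order(self):
        sub = LAYOUT_V1.subset(["ss8", "pssm"])
        assert sub.names == ("pssm", "ss8")
        assert sub.width == 28


class TestNormalizePSSM:
    def test_logistic_values(self):
        assert normalize_pssm(0) == pytest.approx(0.5)
        assert normalize_pssm(20) > 0.999
        assert normalize_pssm(2) == pytest.approx(0.88080, abs=1e-5)

    def test_monotone(self):
        x = np.arange(-16, 17)
        y = normalize_pssm(x)
        assert np.all(np.diff(y) > 0)
        assert y.min() > 0 and y.max() < 1


class TestParsePSSM:
    def test_fixture_roundtrip(self):
        raw, seq = parse_pssm(_PSSM_TEXT)
        assert seq == "MAG"
        assert raw.shape == (3, 20)
        # columns remapped to canonical order: M row has score 6 at 'M'
        assert raw[0, AMINO_ACIDS.index("M")] == 6
        assert raw[1, AMINO_ACIDS.index("A")] == 4
        assert raw[2, AMINO_ACIDS.index("G")] == 6
        assert raw[0, AMINO_ACIDS.index("R")] == -2

    def test_row_count_equals_sequence_length(self):
        raw, seq = parse_pssm(_PSSM_TEXT)
        assert raw.shape[0] == len(seq)

    def test_truncated_row_names_line(self):
        bad = _PSSM_TEXT.replace(
            "    2 A   -1  4 -1 -2 -1 -2  0 -2 -1 -1 -1 -1 -2 -1 -1  1  0  0 -3 -2",
            "    2 A   -1  4")
        with pytest.raises(PSSMFormatError, match="line"):
            parse_pssm(bad)

    def test_missing_header(self):
        with pytest.raises(PSSMFormatError):
            parse_pssm("no header here\n1 M 2 3\n")


class TestErrorDistribution:
    def test_perfect_predictions_give_zero(self):
        angles = [10.0, -50.0, 120.0]
        types = ["A", "L", "Q"]
        t = estimate_error_distribution(angles, angles, angles, angles, types)
        assert np.all(t.avg_phi == 0) and np.all(t.std_phi == 0)

    def test_zero_set_forced_to_zero(self):
        # glycine errors are ignored by construction
        t = estimate_error_distribution([100.0] * 5, [0.0] * 5,
                                        [50.0] * 5, [0.0] * 5, ["G"] * 5)
        gi = AMINO_ACIDS.index("G")
        assert t.avg_phi[gi] == 0 and t.std_phi[gi] == 0 and t.zero_set[gi]
        assert ZERO_SET == frozenset("CDGHNST")

    def test_monte_carlo_recovery(self, rng):
        n = 10000
        errs = rng.normal(10, 20, n)
        truth = rng.uniform(-90, 90, n)
        pred = truth + errs
        t = estimate_error_distribution(pred, truth, pred, truth, ["A"] * n)
        ai = AMINO_ACIDS.index("A")
        assert t.avg_phi[ai] == pytest.approx(10, abs=1)
        assert t.std_phi[ai] == pytest.approx(20, abs=1)

    def test_unobserved_type_warns_and_zeroes(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="torsionnet.features"):
            t = estimate_error_distribution([5.0], [0.0], [5.0], [0.0], ["A"])
        li = AMINO_ACIDS.index("L")
        assert t.avg_phi[li] == 0 and t.std_phi[li] == 0
        assert any("no fragment-error observations" in r.message for r in caplog.records)

    def test_tsv_roundtrip(self, tmp_path):
        t = estimate_error_distribution([12.0, 14.0], [0.0, 0.0],
                                        [-8.0, -6.0], [0.0, 0.0], ["A", "A"])
        t.to_tsv(tmp_path / "tab.tsv")
        back = ErrorDistributionTable.from_tsv(tmp_path / "tab.tsv")
        assert np.allclose(back.avg_phi, t.avg_phi)
        assert np.array_equal(back.zero_set, t.zero_set)


class TestFragmentFeature:
    def test_circular_mean_of_fragments(self):
        assert fragment_mean_angles([[37.0] * 200])[0] == pytest.approx(37.0)
        assert fragment_mean_angles([[179.0, -179.0]])[0] == pytest.approx(180.0)
        assert fragment_mean_angles([[0.0, 90.0]])[0] == pytest.approx(45.0)
        with pytest.raises(ValueError):
            fragment_mean_angles([[]])

    def _table(self, avg_phi=0.0):
        t = estimate_error_distribution([0.0], [0.0], [0.0], [0.0], ["A"])
        t.avg_phi[AMINO_ACIDS.index("A")] = avg_phi
        return t

    def test_zero_set_alpha_is_raw_angle(self):
        t = self._table()
        f = fragment_feature(30.0, 0.0, "G", t)  # zero-set: avg = 0
        assert f[0] == pytest.approx((np.sin(np.deg2rad(30)) + 1) / 2)

    def test_known_alpha_values(self):
        t = self._table(avg_phi=10.0)
        f = fragment_feature(30.0, 0.0, "A", t)  # alpha_phi = 20
        assert f[0] == pytest.approx(0.67101, abs=1e-5)
        assert f[1] == pytest.approx(0.96985, abs=1e-5)

    def test_alpha_wraps(self):
        t = self._table(avg_phi=170.0)
        f = fragment_feature(-170.0, 0.0, "A", t)  # alpha = 20, not -340
        assert f[0] == pytest.approx(0.67101, abs=1e-5)

    def test_invariant_under_plus_360(self):
        t = self._table(avg_phi=10.0)
        assert np.allclose(fragment_feature(30.0, 0.0, "A", t),
                           fragment_feature(390.0, 0.0, "A", t))

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            fragment_feature(0.0, 0.0, "Z", self._table())


class TestBuildResidueFeatures:
    def _blocks(self, rng):
        return {name: rng.random(w) for name, w in LAYOUT_V1.blocks}

    def test_length_and_range(self, rng):
        v = build_residue_features(self._blocks(rng))
        assert v.shape == (56,)
        assert v.min() >= 0 and v.max() <= 1

    def test_wrong_width_names_block(self, rng):
        blocks = self._blocks(rng)
        blocks["ss8"] = np.zeros(7)
        with pytest.raises(ValueError, match="ss8"):
            build_residue_features(blocks)

    def test_deterministic_regardless_of_dict_order(self, rng):
        blocks = self._blocks(rng)
        reordered = dict(reversed(list(blocks.items())))
        assert np.array_equal(build_residue_features(blocks),
                              build_residue_features(reordered))


class TestExtractWindows:
    def test_identity_window(self, rng):
        m = FeatureMatrix("p", rng.random((9, 56)))
        assert np.array_equal(extract_windows(m, WindowConfig(1)), m.values)

    def test_zero_padding_at_termini(self, rng):
        m = FeatureMatrix("p", rng.random((5, 56)) * 0.5 + 0.25)
        out = extract_windows(m, WindowConfig(3))
        assert np.all(out[0, :56] == 0)        # position i-1 of residue 1
        assert np.all(out[-1, -56:] == 0)      # position i+1 of residue L
        assert np.array_equal(out[0, 56:112], m.values[0])

    def test_center_slice_is_own_features(self, rng):
        m = FeatureMatrix("p", rng.random((12, 56)))
        out = extract_windows(m, WindowConfig(7))
        k = 3
        assert np.array_equal(out[:, k * 56:(k + 1) * 56], m.values)


class TestFeatureMatrix:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            FeatureMatrix("p", np.full((3, 56), 1.5))

    def test_rejects_wrong_width(self):
        with pytest.raises(ValueError):
            FeatureMatrix("p", np.zeros((3, 55)))


def test_physchem_table_scaled():
    assert PHYSCHEM_SCALED.shape == (20, 7)
    assert PHYSCHEM_SCALED.min() == 0.0 and PHYSCHEM_SCALED.max() == 1.0
    assert np.all(PHYSCHEM_SCALED.min(axis=0) == 0)
    assert np.all(PHYSCHEM_SCALED.max(axis=0) == 1)
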