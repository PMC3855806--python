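import math

import numpy as np
import pytest

from salivapred import descriptors as D
from salivapred.scales import (
    AA_ALPHABET,
    DEFAULT_GROUPINGS,
    DEFAULT_SCALES,
    GroupingScheme,
    PropertyScale,
)
from salivapred.seqio import ProteinRecord

KD = DEFAULT_SCALES[0]


def autocorr_oracle(seq: str, scale: PropertyScale, method: str, lag: int) -> float:
    """Direct-summation reference, coded independently of the vectorized path."""
    p = [scale.standardized[c] for c in seq]
    L = len(p)
    if method == "moreau_broto":
        return sum(p[i] * p[i + lag] for i in range(L - lag)) / (L - lag)
    pbar = sum(p) / L
    if method == "moran":
        denom = sum((x - pbar) ** 2 for x in p) / L
        if denom == 0:
            return 0.0
        num = sum((p[i] - pbar) * (p[i + lag] - pbar) for i in range(L - lag)) / (L - lag)
        return num / denom
    denom = sum((x - pbar) ** 2 for x in p) / (L - 1)
    if denom == 0:
        return 0.0
    num = sum((p[i] - p[i + lag]) ** 2 for i in range(L - lag)) / (2 * (L - lag))
    return num / denom


class TestScales:
    def test_standardized_mean_zero_sd_one(self):
        for sc in DEFAULT_SCALES:
            vals = sc.values(standardized=True)
            assert abs(vals.mean()) < 1e-12
            assert abs(vals.std() - 1) < 1e-12

    def test_groupings_partition_alphabet(self):
        for g in DEFAULT_GROUPINGS:
            assert sorted("".join(g.groups)) == sorted(AA_ALPHABET)


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", {"A": 1.0}),
            (AA_ALPHABET, {a: 0.05 for a in AA_ALPHABET}),
            ("AAC", {"A": 2 / 3, "C": 1 / 3}),
        ],
    )
    def test_aa_composition(self, seq, expected):
        v = D.aa_composition(seq)
        for i, a in enumerate(AA_ALPHABET):
            assert v[i] == pytest.approx(expected.get(a, 0.0))
        assert v.sum() == pytest.approx(1.0)

    def test_dipeptide_values(self):
        v = D.dipeptide_composition("AA")
        assert v[0] == 1.0 and v.sum() == 1.0
        v = D.dipeptide_composition("ACA")
        names = [a + b for a in AA_ALPHABET for b in AA_ALPHABET]
        d = dict(zip(names, v))
        assert d["AC"] == pytest.approx(0.5)
        assert d["CA"] == pytest.approx(0.5)

    def test_dipeptide_too_short(self):
        with pytest.raises(ValueError):
            D.dipeptide_composition("A")

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            D.aa_composition("")


class TestAutocorrelation:
    def test_two_residue_identities(self):
        # any two distinct property values force moran = -1, geary = 1
        assert D.autocorrelation("AC", KD, "moran", 1) == pytest.approx(-1.0)
        assert D.autocorrelation("AC", KD, "geary", 1) == pytest.approx(1.0)

    def test_homopolymer_degenerate_rule(self):
        assert D.autocorrelation("AAAA", KD, "moran", 1) == 0.0
        assert D.autocorrelation("AAAA", KD, "geary", 1) == 0.0

    def test_lag_out_of_range(self):
        with pytest.raises(ValueError):
            D.autocorrelation("ACDE", KD, "moran", 4)
        with pytest.raises(ValueError):
            D.autocorrelation("ACDE", KD, "moran", 0)

    def test_matches_direct_summation_oracle(self, rng, random_sequences):
        for seq in random_sequences:
            scale = DEFAULT_SCALES[int(rng.integers(len(DEFAULT_SCALES)))]
            for method in D.AUTOCORR_METHODS:
                for lag in range(1, 6):
                    got = D.autocorrelation(seq, scale, method, lag)
                    want = autocorr_oracle(seq, scale, method, lag)
                    assert got == pytest.approx(want, abs=1e-12)


class TestCTD:
    grouping = GroupingScheme("toy", ("ACDEFG", "HIKLMN", "PQRSTVWY"))

    def test_single_class_sequence(self):
        # all residues in class 1, L=4
        v = D.ctd("ACDF", self.grouping)
        assert v[:3] == pytest.approx([1, 0, 0])
        assert v[3:6] == pytest.approx([0, 0, 0])
        assert v[6:11] == pytest.approx([0.25, 0.25, 0.5, 0.75, 1.0])
        assert v[11:] == pytest.approx(np.zeros(10))

    def test_alternating_transition(self):
        # classes 1,2,1,2 -> all 3 adjacent pairs are (1,2)
        v = D.ctd("AHAH", self.grouping)
        assert v[3] == pytest.approx(1.0)  # trans(1,2)
        assert v[4] == v[5] == 0.0

    def test_single_residue(self):
        v = D.ctd("P", self.grouping)
        assert v[:3] == pytest.approx([0, 0, 1])
        assert v[3:6] == pytest.approx([0, 0, 0])

    def test_composition_sums_to_one(self, random_sequences):
        for seq in random_sequences[:20]:
            for g in DEFAULT_GROUPINGS:
                v = D.ctd(seq, g)
                assert v[:3].sum() == pytest.approx(1.0)


class TestPhysicoAndStructure:
    @pytest.mark.parametrize("seq,charge", [("K", 1.0), ("DE", -2.0), ("KRH", 2.1)])
    def test_net_charge(self, seq, charge):
        assert D.physico_summary(seq)[1] == pytest.approx(charge)

    def test_homopolymer_mean_hydrophobicity(self):
        assert D.physico_summary("G" * 10)[0] == pytest.approx(-0.4)

    def test_disorder_extremes(self):
        _, frac_i = D.disorder_profile("I" * 50)
        _, frac_e = D.disorder_profile("E" * 50)
        assert frac_i == 0.0
        assert frac_e == 1.0

    def test_disorder_fraction_in_unit_interval(self, random_sequences):
        for seq in random_sequences[:20]:
            _, frac = D.disorder_profile(seq)
            assert 0.0 <= frac <= 1.0

    def test_ss_fractions_sum_to_one(self, random_sequences):
        for seq in random_sequences[:20]:
            assert D.ss_composition(seq).sum() == pytest.approx(1.0, abs=1e-12)

    def test_ss_polyalanine_is_all_helix(self):
        assert D.ss_composition("A" * 12) == pytest.approx([1.0, 0.0, 0.0])

    def test_radius_formula_and_monotonicity(self):
        assert D.radius_estimate(1) == pytest.approx(2.2)
        assert D.radius_estimate(100) == pytest.approx(2.2 * 100**0.38)
        lengths = [1, 10, 100, 1000]
        radii = [D.radius_estimate(L) for L in lengths]
        assert radii == sorted(radii)

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("MSRRGFLKAAA", True),
            ("MKVLLLAAAAA", False),
            ("A" * 40 + "SRRGFLK", False),  # motif outside the N-terminal window
            ("A" * 30 + "SRRGFLK", True),
        ],
    )
    def test_tat_motif_window(self, seq, expected):
        assert D.tat_motif(seq) is expected


class TestFeaturize:
    def test_default_dimension_is_documented_constant(self):
        cfg = D.DescriptorConfig()
        assert cfg.dimension == 1302
        assert len(cfg.column_names()) == len(set(cfg.column_names()))

    def test_deterministic_and_row_order(self, make_sequence):
        recs = [ProteinRecord(f"P{i}", make_sequence(60)) for i in range(5)]
        X1 = D.featurize(recs)
        X2 = D.featurize(recs)
        assert X1.equals(X2)
        assert list(X1.index) == [r.id for r in recs]

    def test_single_record_and_finiteness(self, make_sequence):
        rec = ProteinRecord("P0", make_sequence(45))
        X = D.featurize([rec])
        assert X.shape == (1, 1302)
        assert np.isfinite(X.to_numpy()).all()

    def test_short_sequence_pads_infeasible_lags_with_zeros(self):
        rec = ProteinRecord("S", "ACDEFGHIKL")  # length 10 < d_max 30
        X = D.featurize([rec])
        assert np.isfinite(X.to_numpy()).all()
        assert X.iloc[0]["moran.kd_hydrophobicity.lag25"] == 0.0

    def test_failure_names_offending_record(self):
        good = ProteinRecord("GOOD", "ACDEFGHIKL")
        bad = ProteinRecord("GOOD2", "ACDEFGHIKL")
        bad.sequence = "A"  # too short for dipeptides, mutated post-validation
        with pytest.raises(ValueError, match="GOOD2"):
            D.featurize([good, bad])

    def test_composition_blocks_sum_to_one(self, make_sequence):
        recs = [ProteinRecord(f"P{i}", make_sequence(80)) for i in range(3)]
        X = D.featurize(recs)
        aac = X[[c for c in X.columns if c.startswith("aac.")]]
        dpc = X[[c for c in X.columns if c.startswith("dpc.")]]
        assert aac.sum(axis=1).to_numpy() == pytest.approx(np.ones(3))
        assert dpc.sum(axis=1).to_numpy() == pytest.approx(np.ones(3))
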