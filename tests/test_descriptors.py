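"""Descriptor tests against independent brute-force oracles.

The oracles below recompute each descriptor with straight-line loops and
explicit formulas, independently of the package implementation.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transpred.descriptors import (
    AAC_COMPONENTS,
    HOPP_WOODS_HYDROPHILICITY,
    PAAC_COMPONENTS,
    SIDE_CHAIN_MASS,
    TANFORD_HYDROPHOBICITY,
    DescriptorError,
    PropertyTable,
    PseAACParams,
    compute_aac,
    compute_paac,
    compute_pseaac,
    default_property_tables,
    pseaac_components,
    standardize_property,
    theta_factors,
)
from transpred.seqio import AMINO_ACIDS, ProteinSequence

sequences_st = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120).map(
    lambda s: ProteinSequence("h", s)
)


# ---------------------------------------------------------------- oracles
def oracle_aac(residues):
    return np.array([residues.count(aa) / len(residues) for aa in AMINO_ACIDS])


def oracle_paac(residues):
    counts = {p: 0 for p in itertools.product(AMINO_ACIDS, repeat=2)}
    for a, b in zip(residues, residues[1:]):
        counts[(a, b)] += 1
    return np.array(
        [counts[p] / (len(residues) - 1)
         for p in itertools.product(AMINO_ACIDS, repeat=2)]
    )


def oracle_standardize(raw: dict):
    vals = [raw[aa] for aa in AMINO_ACIDS]
    mean = sum(vals) / 20
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20)
    return {aa: (raw[aa] - mean) / sd for aa in AMINO_ACIDS}


def oracle_theta(residues, lam):
    h1 = oracle_standardize(TANFORD_HYDROPHOBICITY)
    h2 = oracle_standardize(HOPP_WOODS_HYDROPHILICITY)
    m = oracle_standardize(SIDE_CHAIN_MASS)

    def corr(a, b):
        return ((h1[b] - h1[a]) ** 2 + (h2[b] - h2[a]) ** 2 + (m[b] - m[a]) ** 2) / 3

    L = len(residues)
    thetas = []
    for j in range(1, lam + 1):
        s = sum(corr(residues[i], residues[i + j]) for i in range(L - j))
        thetas.append(s / (L - j))
    return np.array(thetas)


def oracle_pseaac(residues, lam, omega):
    freqs = oracle_aac(residues)
    thetas = oracle_theta(residues, lam)
    denom = freqs.sum() + omega * thetas.sum()
    return np.concatenate([freqs / denom, omega * thetas / denom])


# -------------------------------------------------------------------- AAC
class TestAAC:
    def test_homopolymer(self):
        vec = compute_aac(ProteinSequence("h", "AAAAA"))
        assert vec.values[0] == 1.0
        assert vec.values[1:].sum() == 0.0

    def test_symmetry(self):
        vec = compute_aac(ProteinSequence("h", "ACAC"))
        lookup = dict(zip(vec.components, vec.values))
        assert lookup["AAC_A"] == 0.5
        assert lookup["AAC_C"] == 0.5

    def test_seeded_200mer_oracle(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 200)
        np.testing.assert_allclose(compute_aac(seq).values, oracle_aac(seq.residues),
                                   atol=1e-15)

    def test_component_order(self):
        assert AAC_COMPONENTS[0] == "AAC_A"
        assert AAC_COMPONENTS[-1] == "AAC_Y"

    @given(sequences_st)
    @settings(max_examples=30, deadline=None)
    def test_sums_to_one_and_nonnegative(self, seq):
        vec = compute_aac(seq)
        assert abs(vec.sum() - 1.0) < 1e-9
        assert (vec.values >= 0).all()

    def test_permutation_invariance(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 100)
        shuffled = "".join(rng.permutation(list(seq.residues)))
        np.testing.assert_allclose(
            compute_aac(seq).values,
            compute_aac(ProteinSequence("p", shuffled)).values,
            atol=1e-15,
        )


# ------------------------------------------------------------------- PAAC
class TestPAAC:
    def test_homopolymer(self):
        vec = compute_paac(ProteinSequence("h", "AAA"))
        assert vec.values[0] == 1.0  # (A,A) pair
        assert vec.sum() == 1.0

    def test_alternating(self):
        vec = compute_paac(ProteinSequence("h", "ACA"))
        lookup = dict(zip(vec.components, vec.values))
        assert lookup["PAAC_AC"] == 0.5
        assert lookup["PAAC_CA"] == 0.5

    def test_single_residue_errors(self):
        with pytest.raises(DescriptorError):
            compute_paac(ProteinSequence("h", "A"))

    def test_seeded_300mer_oracle(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 300)
        np.testing.assert_allclose(compute_paac(seq).values, oracle_paac(seq.residues),
                                   atol=1e-15)

    def test_not_permutation_invariant_counterexample(self):
        a = compute_paac(ProteinSequence("h", "AACC"))
        b = compute_paac(ProteinSequence("h", "ACAC"))
        assert not np.allclose(a.values, b.values)

    @given(st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=120))
    @settings(max_examples=30, deadline=None)
    def test_sums_to_one(self, residues):
        assert abs(compute_paac(ProteinSequence("h", residues)).sum() - 1.0) < 1e-9

    def test_component_order(self):
        assert PAAC_COMPONENTS[0] == "PAAC_AA"
        assert PAAC_COMPONENTS[1] == "PAAC_AC"
        assert PAAC_COMPONENTS[-1] == "PAAC_YY"


# --------------------------------------------------- property standardization
class TestStandardizeProperty:
    @pytest.mark.parametrize("raw", [
        TANFORD_HYDROPHOBICITY, HOPP_WOODS_HYDROPHILICITY, SIDE_CHAIN_MASS,
    ], ids=["hydrophobicity", "hydrophilicity", "mass"])
    def test_mean_zero_population_variance_one(self, raw):
        table = standardize_property(PropertyTable("p", raw))
        vals = table.as_array()
        assert abs(vals.mean()) < 1e-9
        assert abs(np.mean(vals**2) - 1.0) < 1e-9

    def test_constant_table_errors(self):
        const = PropertyTable("c", {aa: 3.0 for aa in AMINO_ACIDS})
        with pytest.raises(DescriptorError, match="constant"):
            standardize_property(const)

    def test_tanford_componentwise_oracle(self):
        table = standardize_property(PropertyTable("h1", TANFORD_HYDROPHOBICITY))
        expected = oracle_standardize(TANFORD_HYDROPHOBICITY)
        for aa in AMINO_ACIDS:
            assert table[aa] == pytest.approx(expected[aa], abs=1e-12)

    def test_wrong_size_rejected(self):
        with pytest.raises(DescriptorError):
            PropertyTable("bad", {"A": 1.0})


# ------------------------------------------------------------ theta factors
class TestThetaFactors:
    def test_homopolymer_zero(self):
        props = default_property_tables()
        thetas = theta_factors(ProteinSequence("h", "AAAAAA"), props, 3)
        np.testing.assert_allclose(thetas, np.zeros(3))

    def test_pair_hand_evaluation(self):
        props = default_property_tables()
        h1, h2, m = props
        expected = (
            (h1["C"] - h1["A"]) ** 2
            + (h2["C"] - h2["A"]) ** 2
            + (m["C"] - m["A"]) ** 2
        ) / 3
        thetas = theta_factors(ProteinSequence("h", "AC"), props, 1)
        assert thetas[0] == pytest.approx(expected, abs=1e-12)

    def test_seeded_100mer_oracle(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 100)
        thetas = theta_factors(seq, default_property_tables(), 5)
        np.testing.assert_allclose(thetas, oracle_theta(seq.residues, 5), atol=1e-12)

    def test_lambda_too_large_errors(self):
        with pytest.raises(DescriptorError):
            theta_factors(ProteinSequence("h", "ACDE"), default_property_tables(), 4)

    def test_nonnegative(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 60)
        assert (theta_factors(seq, default_property_tables(), 10) >= 0).all()


# ---------------------------------------------------------------- PseAAC
class TestPseAAC:
    def test_sums_to_one(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 120)
        vec = compute_pseaac(seq, PseAACParams(lam=8, omega=0.3))
        assert abs(vec.sum() - 1.0) < 1e-9
        assert len(vec) == 28

    def test_homopolymer_equals_aac_with_zero_tail(self):
        seq = ProteinSequence("h", "A" * 50)
        vec = compute_pseaac(seq, PseAACParams(lam=5))
        np.testing.assert_allclose(vec.values[:20], compute_aac(seq).values)
        np.testing.assert_allclose(vec.values[20:], np.zeros(5))

    def test_seeded_80mer_oracle(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 80)
        vec = compute_pseaac(seq, PseAACParams(lam=2, omega=0.05))
        np.testing.assert_allclose(
            vec.values, oracle_pseaac(seq.residues, 2, 0.05), atol=1e-12
        )

    def test_omega_to_zero_limit_is_aac(self, rng, random_protein_factory):
        # renormalizing the first 20 components recovers the AAC exactly,
        # so as omega -> 0 (tail mass -> 0) PseAAC tends to AAC + zero tail
        seq = random_protein_factory(rng, 90)
        vec = compute_pseaac(seq, PseAACParams(lam=3, omega=0.05))
        aac = compute_aac(seq).values
        head = vec.values[:20]
        np.testing.assert_allclose(head / head.sum(), aac, atol=1e-12)
        thetas = vec.values[20:]
        # tail mass equals omega*sum(theta)/(1 + omega*sum(theta)): -> 0 with omega
        tail = thetas.sum()
        assert 0 < tail < 0.05 * 3 * 10  # bounded by omega * lam * max-theta scale

    def test_lambda_ge_length_errors(self):
        with pytest.raises(DescriptorError):
            compute_pseaac(ProteinSequence("h", "ACDE"), PseAACParams(lam=10))

    def test_clamp_mode_pads_to_declared_length(self):
        seq = ProteinSequence("h", "ACDEFGHIKL")
        vec = compute_pseaac(seq, PseAACParams(lam=30, clamp=True))
        assert len(vec) == 50
        assert abs(vec.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(vec.values[20 + 9:], np.zeros(30 - 9))

    def test_invalid_params(self):
        with pytest.raises(DescriptorError):
            PseAACParams(lam=0)
        with pytest.raises(DescriptorError):
            PseAACParams(omega=0.9)

    def test_components(self):
        comps = pseaac_components(2)
        assert comps[0] == "PseAAC_A"
        assert comps[-1] == "PseAAC_theta2"

    def test_deterministic(self, rng, random_protein_factory):
        seq = random_protein_factory(rng, 70)
        a = compute_pseaac(seq, PseAACParams(lam=4))
        b = compute_pseaac(seq, PseAACParams(lam=4))
        np.testing.assert_array_equal(a.values, b.values)
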