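"""Descriptor families versus independent brute-force reimplementations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protlife import tables
from protlife.descriptors import (
    DescriptorConfig,
    DescriptorGroup,
    cksaap,
    ctd,
    dde,
    descriptor_groups,
    descriptor_names,
    encode_physchem,
    moran,
    socn,
)
from protlife.tables import AA, CODON_COUNTS

sequences = st.text(alphabet=AA, min_size=50, max_size=200)


# --- brute-force oracles (plain loops, no numpy vectorisation) -----------

def cksaap_oracle(seq, max_gap):
    out = []
    L = len(seq)
    for g in range(max_gap + 1):
        for a in AA:
            for b in AA:
                count = sum(
                    1
                    for i in range(L - g - 1)
                    if seq[i] == a and seq[i + g + 1] == b
                )
                out.append(count / (L - g - 1))
    return np.array(out)


def dde_oracle(seq):
    L = len(seq)
    out = []
    for a in AA:
        for b in AA:
            dc = sum(
                1 for i in range(L - 1) if seq[i] == a and seq[i + 1] == b
            ) / (L - 1)
            tm = (CODON_COUNTS[a] / 61) * (CODON_COUNTS[b] / 61)
            tv = tm * (1 - tm) / (L - 1)
            out.append((dc - tm) / math.sqrt(tv))
    return np.array(out)


def ctd_oracle(seq):
    L = len(seq)
    out = []
    for attr, groups in tables.CTD_ATTRIBUTES.items():
        cls = [next(k for k, g in enumerate(groups) if c in g) for c in seq]
        for k in range(3):
            out.append(cls.count(k) / L)
        for c1, c2 in ((0, 1), (0, 2), (1, 2)):
            n = sum(
                1
                for i in range(L - 1)
                if {cls[i], cls[i + 1]} == {c1, c2}
            )
            out.append(n / (L - 1))
        for k in range(3):
            pos = [i + 1 for i, c in enumerate(cls) if c == k]
            if not pos:
                out.extend([0.0] * 5)
                continue
            n = len(pos)
            for p in (0.0, 0.25, 0.5, 0.75, 1.0):
                out.append(100.0 * pos[max(1, math.ceil(p * n)) - 1] / L)
    return np.array(out)


def moran_oracle(seq, n_lag):
    out = []
    L = len(seq)
    for _, scale in tables.MORAN_PROPERTIES:
        vals = np.array([scale[a] for a in AA])
        vals = (vals - vals.mean()) / vals.std()
        prop = {a: v for a, v in zip(AA, vals)}
        x = [prop[c] for c in seq]
        xbar = sum(x) / L
        denom = sum((xi - xbar) ** 2 for xi in x) / L
        for d in range(1, n_lag + 1):
            if denom == 0:
                out.append(0.0)
                continue
            num = sum((x[i] - xbar) * (x[i + d] - xbar) for i in range(L - d)) / (L - d)
            out.append(num / denom)
    return np.array(out)


def socn_oracle(seq, n_lag):
    D = tables.physicochemical_distance_matrix()
    idx = {a: i for i, a in enumerate(AA)}
    out = []
    for d in range(1, n_lag + 1):
        out.append(
            sum(D[idx[seq[i]], idx[seq[i + d]]] ** 2 for i in range(len(seq) - d))
        )
    return np.array(out)


ORACLES = {
    "cksaap": (lambda s: cksaap(s, 3), lambda s: cksaap_oracle(s, 3)),
    "dde": (dde, dde_oracle),
    "ctd": (ctd, ctd_oracle),
    "moran": (lambda s: moran(s, 10), lambda s: moran_oracle(s, 10)),
    "socn": (lambda s: socn(s, 10), lambda s: socn_oracle(s, 10)),
}


@pytest.mark.parametrize("family", ORACLES)
def test_family_matches_bruteforce_oracle(family, rng):
    impl, oracle = ORACLES[family]
    for _ in range(5):
        seq = "".join(rng.choice(list(AA), size=int(rng.integers(50, 200))))
        np.testing.assert_allclose(impl(seq), oracle(seq), atol=1e-9)


class TestCksaap:
    def test_homopolymer_single_feature(self):
        v = cksaap("AAAA", max_gap=0)
        names = descriptor_names(DescriptorConfig(cksaap_max_gap=0))
        assert v[names.index("CKSAAP.g0.AA")] == 1.0
        assert v.sum() == 1.0

    def test_hand_enumerated_gapped_pairs(self):
        # "ACAC", gap 1: spaced pairs are (A,A) and (C,C)
        v = cksaap("ACAC", max_gap=1)[400:]
        names = [f"{a}{b}" for a in AA for b in AA]
        assert v[names.index("AA")] == pytest.approx(0.5)
        assert v[names.index("CC")] == pytest.approx(0.5)
        assert v.sum() == pytest.approx(1.0)

    @given(sequences)
    def test_each_gap_block_sums_to_one(self, seq):
        v = cksaap(seq, max_gap=5)
        for g in range(6):
            assert v[g * 400 : (g + 1) * 400].sum() == pytest.approx(1.0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cksaap("ACD", max_gap=3)


class TestDde:
    def test_absent_dipeptide_value(self):
        seq = "ACDEF" * 20  # no WW anywhere
        L = len(seq)
        tm = (CODON_COUNTS["W"] / 61) ** 2
        tv = tm * (1 - tm) / (L - 1)
        expected = -tm / math.sqrt(tv)
        names = [f"{a}{b}" for a in AA for b in AA]
        assert dde(seq)[names.index("WW")] == pytest.approx(expected)

    @given(sequences)
    def test_observed_fractions_form_a_distribution(self, seq):
        L = len(seq)
        tm = np.outer(
            np.array([CODON_COUNTS[a] for a in AA]) / 61,
            np.array([CODON_COUNTS[a] for a in AA]) / 61,
        ).ravel()
        tv = tm * (1 - tm) / (L - 1)
        dc = dde(seq) * np.sqrt(tv) + tm
        assert np.all(dc >= -1e-12) and np.all(dc <= 1 + 1e-12)
        assert dc.sum() == pytest.approx(1.0)


class TestCtd:
    def test_homopolymer_composition_and_transitions(self):
        v = ctd("A" * 60)
        names = [n[4:] for n in descriptor_names(DescriptorConfig()) if n.startswith("CTD.")]
        # A is in hydrophobicity class 2 (neutral, 'GASTPHY')
        assert v[names.index("hydrophobicity.C2")] == 1.0
        assert all(v[names.index(f"hydrophobicity.T{t}")] == 0 for t in ("12", "13", "23"))

    @given(sequences)
    def test_composition_triplets_sum_to_one(self, seq):
        v = ctd(seq)
        for attr_idx in range(7):
            triplet = v[attr_idx * 21 : attr_idx * 21 + 3]
            assert triplet.sum() == pytest.approx(1.0)


class TestMoran:
    def test_homopolymer_degenerate_denominator_is_zero(self):
        assert np.all(moran("W" * 80, 10) == 0.0)

    def test_alternating_sequence_lag1_is_minus_one(self):
        # strictly alternating profile: deviations are +/-c, so I(1) = -1
        v = moran("AI" * 100, 1)
        assert v[0] == pytest.approx(-1.0, abs=1e-9)  # hydropathy block, lag 1

    def test_lag_bound_enforced(self):
        with pytest.raises(ValueError):
            moran("ACDEF", 5)


class TestSocn:
    def test_homopolymer_is_zero(self):
        assert np.all(socn("K" * 60, 10) == 0.0)

    @given(sequences)
    def test_nonnegative(self, seq):
        assert np.all(socn(seq, 10) >= 0)


class TestEncodePhyschem:
    def test_group_partition_covers_all_features(self):
        cfg = DescriptorConfig()
        groups = descriptor_groups(cfg)
        assert len(groups) == len(descriptor_names(cfg))
        assert {g for g in groups} == set(DescriptorGroup)

    def test_vector_length_is_documented_sum(self):
        # 400*(5+1) CKSAAP + 400 DDE + 147 CTD + 8*30 Moran + 30 SOCN
        vec = encode_physchem("ACDEFGHIKLMNPQRSTVWY" * 3)
        assert len(vec.values) == 2400 + 400 + 147 + 240 + 30 == 3217

    def test_deterministic(self):
        seq = "MKWLV" * 12
        a, b = encode_physchem(seq), encode_physchem(seq)
        np.testing.assert_array_equal(a.values, b.values)

    @given(sequences)
    def test_always_finite(self, seq):
        assert np.all(np.isfinite(encode_physchem(seq).values))

    def test_shuffle_preserves_g0_marginals(self, rng):
        # single-residue marginals of the gap-0 block are composition-only
        seq = "".join(rng.choice(list(AA), size=120))
        shuffled = "".join(rng.permutation(list(seq)))
        a = cksaap(seq, 0).reshape(20, 20)
        b = cksaap(shuffled, 0).reshape(20, 20)
        # the first L-1 positions define the marginals, so moving the last
        # residue can shift two rows by 1/(L-1) but no more
        np.testing.assert_allclose(
            a.sum(axis=1), b.sum(axis=1), atol=1.5 / (len(seq) - 1)
        )
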