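"""Normalized moment-of-inertia descriptors: oracle equivalence and invariances."""

import math

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from spiraldna import (
    FermatSpiralDescriptor,
    NucleotideSequence,
    RepresentationParams,
    center_of_mass,
    descriptor,
    descriptor_table,
    moment_of_inertia,
)
from spiraldna.descriptor import Centroid, massed_points
from spiraldna.spiral import SpiralPoint

_MASS = {
    "0100": 1 / 6, "0101": 2 / 6, "1100": 3 / 6, "0110": 3 / 6,
    "1101": 4 / 6, "1110": 5 / 6, "0111": 5 / 6, "1111": 1.0,
}


def oracle_descriptor(residues, L, epsilon=0.0375, restraint="exp-decay", com="as-printed"):
    """From-scratch single-function recomputation of the whole pipeline:
    partition, spiral embedding, context masses, restraint, centroid, moment.
    Shares no code with the implementation."""
    n = len(residues)
    out = []
    for base in "ACGT":
        pts = []
        for p in (i + 1 for i, c in enumerate(residues) if c == base):
            th = 2 * math.pi * (p - 1) / (L - 1)
            rh = math.sqrt(th)
            x, y = rh * math.cos(th), rh * math.sin(th)
            pat = "".join(
                "1" if 0 <= j < n and residues[j] == base else "0"
                for j in (p - 2, p - 1, p, p + 1)
            )
            m = _MASS[pat]
            if p > L and epsilon > 0:
                if restraint == "exp-decay":
                    m *= math.exp(-epsilon * (p - L))
                elif restraint == "linear-floor":
                    m = max(m * (1 - epsilon * (p - L)), 1e-6)
            pts.append((x, y, m))
        if not pts:
            out.append(0.0)
            continue
        total = sum(m for _, _, m in pts)
        denom = len(pts) if com == "as-printed" else total
        cx = sum(m * x for x, _, m in pts) / denom
        cy = sum(m * y for _, y, m in pts) / denom
        M = sum(m * ((x - cx) ** 2 + (y - cy) ** 2) for x, y, m in pts)
        out.append(math.sqrt(M / total))
    return np.array(out)


def _points(coords_masses):
    return [
        SpiralPoint(base="A", position=i + 1, theta=0, rho=0, x=x, y=y, mass=m)
        for i, (x, y, m) in enumerate(coords_masses)
    ]


class TestCenterOfMass:
    def test_unit_masses_make_variants_coincide(self):
        pts = _points([(0, 0, 1.0), (2, 4, 1.0), (1, -1, 1.0)])
        a = center_of_mass(pts, "as-printed")
        b = center_of_mass(pts, "true-com")
        assert (a.x, a.y) == pytest.approx((1.0, 1.0))
        assert (b.x, b.y) == pytest.approx((1.0, 1.0))

    def test_single_point_true_com_is_itself(self):
        (c,) = [center_of_mass(_points([(3.0, -2.0, 0.5)]), "true-com")]
        assert (c.x, c.y) == pytest.approx((3.0, -2.0))

    def test_single_point_as_printed_scales_by_mass(self):
        # the as-printed convention divides by N, not total mass: a lone
        # half-mass point gets centroid (x/2, y/2)
        c = center_of_mass(_points([(3.0, -2.0, 0.5)]), "as-printed")
        assert (c.x, c.y) == pytest.approx((1.5, -1.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass([], "true-com")


class TestMomentOfInertia:
    def test_single_point_about_itself_is_zero(self):
        pts = _points([(3.0, -2.0, 0.5)])
        s = moment_of_inertia(pts, center_of_mass(pts, "true-com"))
        assert (s.M, s.r) == (0.0, 0.0)
        assert s.total_mass == 0.5

    def test_symmetric_dumbbell(self):
        pts = _points([(0, 0, 1.0), (2, 0, 1.0)])
        s = moment_of_inertia(pts, Centroid(1.0, 0.0))
        assert (s.M, s.total_mass, s.r) == (2.0, 2.0, 1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        coords = [(rng.normal(), rng.normal(), rng.uniform(0.1, 1)) for _ in range(10)]
        pts = _points(coords)
        c = center_of_mass(pts, "true-com")
        s = moment_of_inertia(pts, c)
        M = sum(m * ((x - c.x) ** 2 + (y - c.y) ** 2) for x, y, m in coords)
        total = sum(m for *_, m in coords)
        assert s.M == pytest.approx(M, abs=1e-12)
        assert s.r == pytest.approx(math.sqrt(M / total), abs=1e-12)


class TestDescriptor:
    @pytest.mark.parametrize("com", ["as-printed", "true-com"])
    def test_cacag_matches_oracle(self, com):
        params = RepresentationParams(L=5, epsilon=0.0, com_variant=com)
        d = descriptor(NucleotideSequence("x", "CACAG"), params)
        np.testing.assert_allclose(
            d.as_array(), oracle_descriptor("CACAG", 5, 0.0, com=com), atol=1e-12
        )

    def test_identical_sequences_identical_vectors(self, default_params):
        a = descriptor(NucleotideSequence("a", "ACGTTGCA"), default_params)
        b = descriptor(NucleotideSequence("b", "ACGTTGCA"), default_params)
        assert np.array_equal(a.as_array(), b.as_array())

    def test_absent_base_component_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            d = descriptor(NucleotideSequence("x", "ACAC"), RepresentationParams(L=4))
        assert d.r_G == 0.0 and d.r_T == 0.0
        assert "never occurs" in caplog.text

    @pytest.mark.parametrize("com", ["as-printed", "true-com"])
    @pytest.mark.parametrize("restraint", ["exp-decay", "linear-floor", "none"])
    def test_oracle_equivalence_random_sequences(self, com, restraint):
        """200 random sequences of length <= 30, restraint engaged (L=10):
        the pipeline equals the from-scratch oracle to 1e-12."""
        rng = np.random.default_rng(42)
        params = RepresentationParams(
            L=10, epsilon=0.0375, restraint_variant=restraint, com_variant=com
        )
        n_checked = 200 if (com, restraint) == ("as-printed", "exp-decay") else 30
        for _ in range(n_checked):
            residues = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 31)))
            d = descriptor(NucleotideSequence("x", residues), params)
            np.testing.assert_allclose(
                d.as_array(),
                oracle_descriptor(residues, 10, 0.0375, restraint, com),
                atol=1e-12,
            )


class TestInvariances:
    def _random_massed(self, seed=9, n=160):
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list("ACGT"), size=n))
        seq = NucleotideSequence("x", residues)
        return massed_points(seq, RepresentationParams(L=86, com_variant="true-com"))

    def test_uniform_mass_scaling_leaves_r_unchanged(self):
        """In the true-com convention the mass scale cancels between the
        centroid, the moment and the normalization."""
        for pts in self._random_massed().values():
            r0 = moment_of_inertia(pts, center_of_mass(pts, "true-com")).r
            for c in (0.1, 3.7):
                scaled = [p.with_mass(p.mass * c) for p in pts]
                r = moment_of_inertia(scaled, center_of_mass(scaled, "true-com")).r
                assert r == pytest.approx(r0, abs=1e-12)

    def test_rigid_rotation_leaves_r_unchanged(self):
        import dataclasses

        rng = np.random.default_rng(13)
        for pts in self._random_massed().values():
            r0 = moment_of_inertia(pts, center_of_mass(pts, "true-com")).r
            for _ in range(3):
                a = rng.uniform(0, 2 * math.pi)
                ca, sa = math.cos(a), math.sin(a)
                rot = [
                    dataclasses.replace(p, x=ca * p.x - sa * p.y, y=sa * p.x + ca * p.y)
                    for p in pts
                ]
                r = moment_of_inertia(rot, center_of_mass(rot, "true-com")).r
                assert r == pytest.approx(r0, abs=1e-10)

    def test_point_order_permutation_stable(self):
        rng = np.random.default_rng(17)
        for pts in self._random_massed().values():
            r0 = moment_of_inertia(pts, center_of_mass(pts, "as-printed")).r
            shuffled = list(pts)
            rng.shuffle(shuffled)
            r = moment_of_inertia(shuffled, center_of_mass(shuffled, "as-printed")).r
            assert abs(r - r0) < 1e-10

    def test_large_epsilon_converges_to_truncated_curve(self):
        """As epsilon grows, post-L masses vanish and the descriptor tends to
        that of the curve cut at position L with unrestrained masses (checked
        at epsilon = 50, true-com). The leading 'ACGT' guarantees every base
        has in-range points, so the limit is nondegenerate."""
        rng = np.random.default_rng(21)
        residues = "ACGT" + "".join(rng.choice(list("ACGT"), size=116))
        seq = NucleotideSequence("x", residues)
        L = 80
        strong = RepresentationParams(L=L, epsilon=50.0, com_variant="true-com")
        d = descriptor(seq, strong).as_array()
        free = massed_points(
            seq, RepresentationParams(L=L, epsilon=0.0, com_variant="true-com")
        )
        truncated = []
        for base in "ACGT":
            pts = [p for p in free[base] if p.position <= L]
            truncated.append(
                moment_of_inertia(pts, center_of_mass(pts, "true-com")).r
            )
        np.testing.assert_allclose(d, truncated, atol=1e-6)


class TestEstimator:
    def test_fit_resolves_reference_length(self):
        est = FermatSpiralDescriptor().fit(["ACGTACGT", "ACGTAC"])
        assert est.L_ == 6
        assert est.params_.epsilon == 0.0375

    def test_fixed_L_and_transform_matches_descriptor(self):
        est = FermatSpiralDescriptor(L=86, epsilon=0.0).fit(["ACGT"])
        got = est.transform(["CACAG"])
        want = descriptor(
            NucleotideSequence("seq0", "CACAG"), RepresentationParams(L=86, epsilon=0.0)
        ).as_array()
        np.testing.assert_allclose(got[0], want)

    def test_sklearn_protocol(self):
        est = FermatSpiralDescriptor(epsilon=0.1)
        cloned = clone(est)
        assert cloned.get_params()["epsilon"] == 0.1
        cloned.set_params(com_variant="true-com", L=20)
        X = ["ACGTACGTAACCGGTT", "TTGGCCAATGCATGCA"]
        out = Pipeline([("desc", cloned)]).fit_transform(X)
        assert out.shape == (2, 4)
        assert list(cloned.get_feature_names_out()) == ["r_A", "r_C", "r_G", "r_T"]

    def test_transform_before_fit_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            FermatSpiralDescriptor().transform(["ACGT"])


def test_descriptor_table_layout(default_params):
    seqs = [NucleotideSequence("a", "ACGTAC"), NucleotideSequence("b", "TTGGCA")]
    table = descriptor_table(seqs, default_params)
    assert list(table.columns) == [
        "id", "r_A", "r_C", "r_G", "r_T", "L", "epsilon",
        "restraint_variant", "com_variant",
    ]
    assert list(table["id"]) == ["a", "b"]
    assert (table["L"] == 86).all()
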