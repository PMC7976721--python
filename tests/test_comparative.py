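import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from bseeker import comparative as comp


class TestBinomialCoincidence:
    def test_fifteen_coincidences_out_of_100(self):
        t = comp.binom_coincidence(100, 15, 1 / 25)
        assert f"{t.pmf:.3g}" == "8.47e-06"

    @pytest.mark.parametrize(
        "k,printed", [(19, "5.3e-25"), (14, "2.3e-15"), (11, "9.8e-11")]
    )
    def test_shared_gene_counts_out_of_21(self, k, printed):
        t = comp.binom_coincidence(21, k, 0.04)
        assert f"{t.pmf:.2g}" == printed

    def test_percent_rescaling_matches_direct_percent_computation(self):
        t = comp.binom_coincidence(227, 34, 1 / 25)
        assert t.pmf_percent_scale == pytest.approx(
            comp.binom_pmf(100, 15, 1 / 25), rel=1e-12
        )

    def test_certain_outcome_probability_one(self):
        assert comp.binom_coincidence(50, 0, 1e-12).pmf == pytest.approx(1.0)

    def test_agrees_with_scipy_binom(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 300))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.001, 0.999))
            assert comp.binom_pmf(n, k, p) == pytest.approx(
                stats.binom.pmf(k, n, p), rel=1e-9
            )

    def test_normalizes_at_n_227_without_overflow(self):
        total = sum(comp.binom_pmf(227, k, 1 / 25) for k in range(228))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n,k,p", [(10, 11, 0.5), (10, -1, 0.5), (10, 5, 0.0)])
    def test_invalid_arguments_rejected(self, n, k, p):
        with pytest.raises(ValueError):
            comp.binom_coincidence(n, k, p)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0.0), ("ACGT", "ACGA", 0.25), ("AC-T", "ACGT", 0.0)]
    )
    def test_examples(self, a, b, d):
        assert comp.p_distance(a, b) == pytest.approx(d)

    def test_ambiguity_codes_pairwise_deleted(self):
        assert comp.p_distance("ANGT", "ACGA") == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            comp.p_distance("ACG", "ACGT")

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            comp.p_distance("--", "AC")


class TestGeneContentDistances:
    def test_identical_and_four_gene_difference(self):
        m = pd.DataFrame(
            {"sp1": [1, 1, 0, 0, 1], "sp2": [1, 1, 0, 0, 1], "sp3": [0, 0, 1, 1, 1]}
        )
        d = comp.gene_content_distances(m)
        assert d["sp1", "sp2"] == 0.0
        assert d["sp1", "sp3"] == pytest.approx(2.0)  # sqrt(4)

    def test_matches_column_pair_loop_oracle(self, rng):
        m = pd.DataFrame(
            rng.integers(0, 2, size=(30, 4)), columns=list("abcd")
        )
        d = comp.gene_content_distances(m)
        for s, t in itertools.combinations(m.columns, 2):
            diff = sum(
                1 for g in range(len(m)) if m.loc[g, s] != m.loc[g, t]
            )  # brute-force oracle
            assert d[s, t] == pytest.approx(math.sqrt(diff))

    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError):
            comp.gene_content_distances(pd.DataFrame({"a": [0, 2], "b": [1, 0]}))


def _random_dm(rng, n, labels=None):
    pts = rng.normal(size=(n, 3))
    m = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix(m, ids=labels or [f"s{i}" for i in range(n)])


class TestMantel:
    def test_self_comparison_r_one(self, rng):
        d = _random_dm(rng, 5)
        res = comp.mantel_test(d, d, n_perm=200, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_positive_affine_transform_r_one(self, rng):
        d1 = _random_dm(rng, 5)
        m2 = 2.5 * d1.data + 0.7
        np.fill_diagonal(m2, 0.0)
        res = comp.mantel_test(d1, DistanceMatrix(m2, ids=d1.ids), n_perm=200, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_four_labels(self, rng):
        d1 = _random_dm(rng, 4)
        d2 = _random_dm(rng, 4)
        iu = np.triu_indices(4, k=1)
        x = d1.data[iu]
        r_obs = np.corrcoef(x, d2.data[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            y = d2.data[np.ix_(perm, perm)][iu]
            r = np.corrcoef(x, y)[0, 1]
            if r >= r_obs - 1e-12:
                count += 1
        exact_p = count / 24
        res = comp.mantel_test(d1, d2, n_perm=10000, seed=1)
        assert res.p_value == pytest.approx(exact_p, abs=0.02)

    def test_agrees_with_skbio_mantel(self, rng):
        d1 = _random_dm(rng, 6)
        d2 = _random_dm(rng, 6)
        res = comp.mantel_test(d1, d2, n_perm=2000, seed=0)
        r_skbio, p_skbio, _ = skbio_mantel(
            d1, d2, method="pearson", permutations=2000, alternative="greater"
        )
        assert res.r == pytest.approx(float(r_skbio), abs=1e-9)
        assert res.p_value == pytest.approx(float(p_skbio), abs=0.03)

    def test_mismatched_labels_rejected(self, rng):
        d1 = _random_dm(rng, 4)
        d2 = _random_dm(rng, 4, labels=list("wxyz"))
        with pytest.raises(ValueError):
            comp.mantel_test(d1, d2)

    def test_too_small_rejected(self, rng):
        d = _random_dm(rng, 2)
        with pytest.raises(ValueError):
            comp.mantel_test(d, d)

    def test_null_p_values_calibrated(self):
        """Rejection rate at alpha 0.05 in [0.03, 0.07] over 500 null pairs."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 500
        for i in range(n_sim):
            d1 = _random_dm(rng, 6)
            d2 = _random_dm(rng, 6)
            res = comp.mantel_test(d1, d2, n_perm=199, seed=i)
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestSpearman:
    def test_monotone_relations(self, rng):
        x = rng.normal(size=20)
        rho, t = comp.spearman_rho(x, np.exp(x))
        assert rho == pytest.approx(1.0) and math.isinf(t)
        rho, _ = comp.spearman_rho(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            rho, t = comp.spearman_rho(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rho_oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(rho_oracle, abs=1e-12)
            assert t == pytest.approx(rho * math.sqrt(13 / (1 - rho**2)))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            comp.spearman_rho([1, 1, 1], [1, 2, 3])


def test_p_distance_matrix_symmetry(rng):
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT-"), size=60)) for i in range(4)
    }
    d = comp.p_distance_matrix(seqs)
    m = d.data
    assert np.allclose(m, m.T) and np.all(np.diag(m) == 0)
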