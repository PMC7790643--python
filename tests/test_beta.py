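"""Hellinger machinery, ordination, permutation tests and partitions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from resurvey import beta
from resurvey.survey import ValidationError


def random_matrix(rng, n_cells=6, n_species=5):
    m = rng.gamma(1.0, 1.0, size=(n_cells, n_species))
    m[rng.random(m.shape) < 0.3] = 0.0
    m[m.sum(axis=1) == 0, 0] = 1.0  # no empty cells
    return pd.DataFrame(m, index=[f"c{i}" for i in range(n_cells)],
                        columns=[f"s{j}" for j in range(n_species)])


class TestHellinger:
    def test_known_rows(self):
        df = pd.DataFrame([[4.0, 0.0, 0.0], [1.0, 1.0, 2.0]],
                          index=["a", "b"])
        out = beta.hellinger_transform(df)
        assert np.allclose(out.loc["a"], [1, 0, 0])
        assert np.allclose(out.loc["b"], [0.5, 0.5, 0.70710678])
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0)

    def test_zero_sum_row_names_cell(self):
        df = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            beta.hellinger_transform(df)

    def test_distance_equals_direct_formula(self):
        rng = np.random.default_rng(1)
        df = random_matrix(rng, 7, 6)
        h = beta.hellinger_transform(df)
        dm = beta.distance_matrix(h)
        p = df.to_numpy() / df.to_numpy().sum(axis=1, keepdims=True)
        for i in range(7):
            for j in range(7):
                expected = math.sqrt(((np.sqrt(p[i]) - np.sqrt(p[j])) ** 2)
                                     .sum())
                assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_triangle_inequality(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            df = random_matrix(rng, 6, 4)
            d = beta.distance_matrix(beta.hellinger_transform(df)).data
            assert d.max() <= beta.HELLINGER_MAX + 1e-12
            for i, j, k in itertools.permutations(range(6), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_disjoint_compositions_reach_sqrt2(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        d = beta.distance_matrix(beta.hellinger_transform(df)).data
        assert d[0, 1] == pytest.approx(math.sqrt(2), abs=1e-12)


class TestPcoa:
    def test_two_sites(self):
        dm = beta.DissimilarityMatrix(("a", "b"),
                                      np.array([[0.0, 1.2], [1.2, 0.0]]))
        res = beta.pcoa(dm)
        coords = res.coordinates.to_numpy().ravel()
        assert np.allclose(np.abs(coords), 0.6)

    def test_hellinger_input_has_no_real_negative_eigenvalues(self):
        rng = np.random.default_rng(3)
        df = random_matrix(rng, 10, 8)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        res = beta.pcoa(dm)
        assert res.eigenvalues.min() >= -1e-9

    def test_coordinates_reconstruct_distances(self):
        rng = np.random.default_rng(4)
        df = random_matrix(rng, 9, 7)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        res = beta.pcoa(dm)
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rebuilt, dm.data, atol=1e-6)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        df = random_matrix(rng, 8, 6)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        ours = beta.pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.data, ids=list(dm.labels)))
        n_pos = ours.coordinates.shape[1]
        assert np.allclose(ours.eigenvalues[:n_pos],
                           theirs.eigvals.to_numpy()[:n_pos], atol=1e-8)


def exhaustive_p(d: np.ndarray, n1: int, stat_fn, f_obs):
    """Independent enumeration oracle over all two-group assignments."""
    n = d.shape[0]
    count = total = 0
    for comb in itertools.combinations(range(n), n1):
        codes = np.ones(n, dtype=int)
        codes[list(comb)] = 0
        total += 1
        if stat_fn(codes) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestDispersion:
    def test_mirrored_clouds_give_f_zero(self):
        pts = np.array([[0, 0], [2, 0], [0, 2], [10, 10], [12, 10], [10, 12]],
                       dtype=float)
        d = squareform(pdist(pts))
        dm = beta.DissimilarityMatrix(tuple("abcdef"), d)
        res = beta.dispersion_test(dm, ["T1"] * 3 + ["T2"] * 3, n_perm=99,
                                   seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p_perm == 1.0

    def test_f_matches_anova_on_z(self):
        rng = np.random.default_rng(6)
        df = random_matrix(rng, 10, 6)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        groups = ["T1"] * 5 + ["T2"] * 5
        res = beta.dispersion_test(dm, groups, n_perm=99, seed=0)
        f_direct = stats.f_oneway(res.z[:5], res.z[5:]).statistic
        assert res.F == pytest.approx(f_direct, rel=1e-10)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        df = random_matrix(rng, 6, 5)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        groups = ["T1"] * 3 + ["T2"] * 3
        res = beta.dispersion_test(dm, groups, method="exhaustive")
        assert res.n_perm == 20

        z = res.z.to_numpy()

        def f_of(codes):
            zz = [z[codes == g] for g in (0, 1)]
            return stats.f_oneway(*zz).statistic

        codes_obs = np.array([0, 0, 0, 1, 1, 1])
        expected = exhaustive_p(dm.data, 3, f_of, f_of(codes_obs))
        assert res.p_perm == pytest.approx(expected, abs=1e-12)

    def test_direction_labels_decline_as_homogenization(self):
        rng = np.random.default_rng(8)
        wide = rng.normal(0, 1.0, size=(6, 3))
        tight = rng.normal(0, 0.05, size=(6, 3))
        d = squareform(pdist(np.vstack([wide, tight])))
        dm = beta.DissimilarityMatrix(tuple(range(12)), d)
        res = beta.dispersion_test(dm, ["T1"] * 6 + ["T2"] * 6, n_perm=99,
                                   seed=1)
        assert res.direction == "homogenization"
        assert res.group_means["T2"] < res.group_means["T1"]

    def test_matches_vegan_betadisper(self, tmp_path):
        """Distances to centroids and F agree with R vegan's betadisper."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(17)
        df = random_matrix(rng, 8, 6)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        res = beta.dispersion_test(dm, ["T1"] * 4 + ["T2"] * 4, n_perm=99,
                                   seed=0)
        dpath = tmp_path / "d.csv"
        pd.DataFrame(dm.data).to_csv(dpath, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(vegan))\n'
            f'd <- as.dist(as.matrix(read.csv("{dpath}")))\n'
            'g <- factor(rep(c("T1","T2"), each=4))\n'
            'b <- betadisper(d, g, type="centroid")\n'
            'a <- anova(b)\n'
            'cat(b$distances, a$`F value`[1], sep=",")\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout
        vals = np.array([float(v) for v in out.strip().split(",")])
        assert np.allclose(res.z.to_numpy(), vals[:8], atol=1e-6)
        assert res.F == pytest.approx(vals[8], rel=1e-6)


class TestPermanova:
    def test_ss_total_is_label_free(self):
        rng = np.random.default_rng(9)
        df = random_matrix(rng, 8, 5)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        labels = ["a"] * 4 + ["b"] * 4
        r1 = beta.permanova(dm, labels, n_perm=49, seed=0)
        r2 = beta.permanova(dm, list(reversed(labels)), n_perm=49, seed=0)
        assert r1.ss_total == pytest.approx(r2.ss_total, rel=1e-12)
        assert r1.ss_between + r1.ss_within == pytest.approx(r1.ss_total,
                                                             abs=1e-9)
        assert 0.0 <= r1.r2 <= 1.0

    def test_identical_groups_high_p(self):
        base = random_matrix(np.random.default_rng(10), 4, 5)
        stacked = pd.concat([base, base.set_index(base.index + "x")])
        dm = beta.distance_matrix(beta.hellinger_transform(stacked))
        res = beta.permanova(dm, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=0)
        assert res.p_perm > 0.5

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        df = random_matrix(rng, 6, 5)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        res = beta.permanova(dm, ["a"] * 3 + ["b"] * 3, method="exhaustive")
        assert res.n_perm == 20

        d2 = dm.data ** 2
        n = 6
        ss_total = d2.sum() / (2 * n)

        def f_of(codes):
            ssw = sum(d2[np.ix_(np.flatnonzero(codes == g),
                                np.flatnonzero(codes == g))].sum()
                      / (2 * (codes == g).sum()) for g in (0, 1))
            ssb = ss_total - ssw
            return (ssb / 1) / (ssw / (n - 2))

        expected = exhaustive_p(dm.data, 3, f_of,
                                f_of(np.array([0, 0, 0, 1, 1, 1])))
        assert res.p_perm == pytest.approx(expected, abs=1e-12)

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(12)
        df = random_matrix(rng, 10, 6)
        dm = beta.distance_matrix(beta.hellinger_transform(df))
        groups = ["a"] * 5 + ["b"] * 5
        ours = beta.permanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=list(dm.labels)), groups,
            permutations=99)
        assert ours.F == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestBetaPartition:
    def test_two_symmetric_cells(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        bp = beta.lcbd_scbd(beta.hellinger_transform(df))
        assert np.allclose(bp.lcbd, [0.5, 0.5])

    def test_identical_cells_undefined(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValidationError, match="undefined"):
            beta.lcbd_scbd(beta.hellinger_transform(df))

    def test_ss_total_equals_pairwise_distance_identity(self):
        rng = np.random.default_rng(13)
        h = beta.hellinger_transform(random_matrix(rng, 5, 4))
        bp = beta.lcbd_scbd(h)
        d2 = pdist(h.to_numpy(), metric="sqeuclidean").sum()
        assert bp.ss_total == pytest.approx(d2 / 5, abs=1e-9)
        assert bp.lcbd.sum() == pytest.approx(1.0, abs=1e-12)
        assert bp.scbd.sum() == pytest.approx(1.0, abs=1e-12)
        assert (bp.lcbd >= 0).all() and (bp.scbd >= 0).all()

    def test_delta_lcbd_hand_computed(self):
        # three cells on two species; hand Hellinger: rows are (1,0),
        # (0,1), (.5,.5)->(sqrt.5, sqrt.5)
        y1 = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]],
                          index=list("abc"))
        y2 = pd.DataFrame([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]],
                          index=list("abc"))
        bp1 = beta.lcbd_scbd(beta.hellinger_transform(y1))
        bp2 = beta.lcbd_scbd(beta.hellinger_transform(y2))
        out = beta.delta_lcbd(bp1, bp2)
        # period 1: s_i = |y'_i - mean|^2; by symmetry a and b equal
        r = math.sqrt(0.5)
        m1 = np.array([(1 + r) / 3, (1 + r) / 3])
        s_a = (1 - m1[0]) ** 2 + m1[1] ** 2
        s_c = 2 * (r - m1[0]) ** 2
        lcbd_a1 = s_a / (2 * s_a + s_c)
        # period 2: two cells at (1,0), one at (0,1); mean (2/3, 1/3)
        s_dup = (1 / 3) ** 2 + (1 / 3) ** 2
        s_uni = (2 / 3) ** 2 + (2 / 3) ** 2
        lcbd_a2 = s_dup / (2 * s_dup + s_uni)
        assert out.loc["a", "delta_lcbd"] == pytest.approx(lcbd_a2 - lcbd_a1,
                                                           abs=1e-12)
        assert out["delta_lcbd"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_delta_lcbd_identical_periods_zero(self):
        h = beta.hellinger_transform(random_matrix(np.random.default_rng(14),
                                                   5, 4))
        bp = beta.lcbd_scbd(h)
        out = beta.delta_lcbd(bp, bp)
        assert np.allclose(out["delta_lcbd"], 0.0)

    def test_mismatched_cells_rejected(self):
        h1 = beta.hellinger_transform(random_matrix(np.random.default_rng(1),
                                                    4, 3))
        h2 = h1.set_index(h1.index + "_other")
        with pytest.raises(ValidationError):
            beta.delta_lcbd(beta.lcbd_scbd(h1), beta.lcbd_scbd(h2))


class TestComponents:
    def test_identical_sites_all_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        cp = beta.beta_components(df)
        assert cp.d.loc["a", "b"] == 0.0
        assert cp.replacement.loc["a", "b"] == 0.0

    def test_nested_sites_have_no_replacement(self):
        df = pd.DataFrame([[1, 1, 1, 1], [1, 1, 0, 0]], index=["sup", "sub"],
                          dtype=float)
        cp = beta.beta_components(df, quantitative=False)
        assert cp.replacement.loc["sup", "sub"] == 0.0
        assert cp.d.loc["sup", "sub"] == \
            cp.richness_difference.loc["sup", "sub"]

    def test_hand_computed_three_sites(self):
        # pair (a,b): A=2, B=2, C=2 -> D=.5, Repl=.5, Rich=0
        # pair (a,c): A=0, B=4, C=2 -> D=1,  Repl=2/3, Rich=1/3
        # pair (b,c): A=2, B=2, C=0 -> D=1/3, Repl=0,  Rich=1/3
        df = pd.DataFrame([[3, 1, 0], [1, 1, 2], [0, 0, 2]],
                          index=list("abc"), dtype=float)
        cp = beta.beta_components(df)
        assert cp.d.loc["a", "b"] == pytest.approx(0.5)
        assert cp.replacement.loc["a", "b"] == pytest.approx(0.5)
        assert cp.richness_difference.loc["a", "b"] == 0.0
        assert cp.d.loc["a", "c"] == pytest.approx(1.0)
        assert cp.replacement.loc["a", "c"] == pytest.approx(2 / 3)
        assert cp.richness_difference.loc["a", "c"] == pytest.approx(1 / 3)
        assert cp.d.loc["b", "c"] == pytest.approx(1 / 3)
        assert cp.replacement.loc["b", "c"] == 0.0

    def test_podani_parts_sum_to_d_and_lie_in_unit_interval(self):
        rng = np.random.default_rng(15)
        df = random_matrix(rng, 7, 6)
        cp = beta.beta_components(df)
        total = cp.replacement.to_numpy() + cp.richness_difference.to_numpy()
        assert np.allclose(total, cp.d.to_numpy(), atol=1e-12)
        for m in (cp.d, cp.replacement, cp.richness_difference):
            assert ((m.to_numpy() >= -1e-12) & (m.to_numpy() <= 1 + 1e-12)).all()

    def test_baselga_family_is_alternative_split(self):
        rng = np.random.default_rng(16)
        df = random_matrix(rng, 5, 5)
        cp = beta.beta_components(df, family="baselga")
        total = cp.replacement.to_numpy() + cp.richness_difference.to_numpy()
        assert np.allclose(total, cp.d.to_numpy(), atol=1e-12)
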