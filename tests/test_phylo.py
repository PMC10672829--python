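import itertools

import numpy as np
import pytest

from ecoassembly import phylo as ph
from ecoassembly import synthetic as syn
from ecoassembly.containers import ValidationError
from ecoassembly.io import patristic_distances, tree_from_newick

from .conftest import CATERPILLAR_TIPS, make_table


@pytest.fixture(scope="module")
def cat_D():
    tree = tree_from_newick("((((A:1,B:2):1,C:3):1,D:4):1,E:5):0;")
    return patristic_distances(tree, CATERPILLAR_TIPS)


def brute_force_mntd(present, D, weights=None):
    """Independent nearest-neighbour scan."""
    vals = []
    for i in present:
        vals.append(min(D[i, j] for j in present if j != i))
    if weights is None:
        return float(np.mean(vals))
    w = np.asarray(weights, dtype=float)
    return float(np.dot(w / w.sum(), vals))


def brute_force_beta_mntd(pa, pb, D, wa=None, wb=None):
    d_ab = [min(D[i, j] for j in pb) for i in pa]
    d_ba = [min(D[j, i] for i in pa) for j in pb]
    ma = np.mean(d_ab) if wa is None else np.dot(np.asarray(wa) / np.sum(wa), d_ab)
    mb = np.mean(d_ba) if wb is None else np.dot(np.asarray(wb) / np.sum(wb), d_ba)
    return 0.5 * (ma + mb)


class TestMntd:
    def test_two_taxa_is_their_distance(self, cat_D):
        comm = [1, 0, 0, 1, 0]
        assert ph.mntd(comm, cat_D) == pytest.approx(cat_D[0, 3])
        assert ph.mntd([3, 0, 0, 9, 0], cat_D, weighted=True) == pytest.approx(cat_D[0, 3])

    def test_star_tree_equals_two_ell(self):
        tree = tree_from_newick("(A:1.5,B:1.5,C:1.5,D:1.5):0;")
        D = patristic_distances(tree, list("ABCD"))
        for comm in ([1, 1, 1, 0], [1, 0, 1, 1], [2, 5, 1, 9]):
            assert ph.mntd(comm, D) == pytest.approx(3.0)

    def test_caterpillar_matches_brute_force(self, cat_D):
        comm = np.array([2, 0, 1, 5, 1])
        present = np.flatnonzero(comm)
        assert ph.mntd(comm, cat_D) == pytest.approx(brute_force_mntd(present, cat_D))
        assert ph.mntd(comm, cat_D, weighted=True) == pytest.approx(
            brute_force_mntd(present, cat_D, weights=comm[present]))

    def test_needs_two_taxa(self, cat_D):
        with pytest.raises(ValidationError):
            ph.mntd([0, 0, 1, 0, 0], cat_D)


class TestSesMntd:
    def test_star_tree_degenerate(self):
        tree = tree_from_newick("(A:1,B:1,C:1,D:1,E:1):0;")
        D = patristic_distances(tree, list("ABCDE"))
        res = ph.ses_mntd([1, 1, 0, 1, 0], D, n_null=99, seed=0)
        assert res.degenerate
        assert res.z == 0.0
        assert res.nti == 0.0

    def test_full_pool_community_degenerate(self, cat_D):
        res = ph.ses_mntd([1, 1, 1, 1, 1], cat_D, n_null=99, seed=0)
        assert res.degenerate

    def test_nti_is_negative_z(self, cat_D):
        res = ph.ses_mntd([1, 1, 0, 0, 1], cat_D, n_null=199, seed=3)
        assert res.nti == -res.z

    def test_sampled_null_matches_exhaustive_enumeration(self):
        # 6-taxon tree, 3-taxon community: the label shuffle induces a
        # uniform distribution over all C(6,3) possible placements
        tree = syn.simulate_tree(6, seed=12)
        ids = [t.name for t in tree.tips()]
        D = patristic_distances(tree, ids)
        comm = np.array([1, 1, 0, 1, 0, 0])
        exact_vals = []
        for subset in itertools.combinations(range(6), 3):
            exact_vals.append(brute_force_mntd(list(subset), D))
        exact_mean, exact_sd = np.mean(exact_vals), np.std(exact_vals, ddof=0)  # population sd: the enumeration IS the null law
        n_null = 4000
        res = ph.ses_mntd(comm, D, n_null=n_null, seed=5)
        se_mean = exact_sd / np.sqrt(n_null)
        assert res.null_mean == pytest.approx(exact_mean, abs=3 * se_mean)
        from .conftest import mc_se_of_sd

        assert res.null_sd == pytest.approx(
            exact_sd, abs=3 * mc_se_of_sd(exact_vals, n_null))


class TestBetaMntd:
    def test_identical_communities_zero(self, cat_D):
        assert ph.beta_mntd([1, 0, 2, 0, 1], [1, 0, 2, 0, 1], cat_D) == pytest.approx(0.0)

    def test_singletons(self, cat_D):
        assert ph.beta_mntd([1, 0, 0, 0, 0], [0, 0, 0, 1, 0], cat_D) == pytest.approx(
            cat_D[0, 3])

    def test_three_v_three_brute_force(self, cat_D):
        a = np.array([2, 1, 0, 3, 0])
        b = np.array([0, 1, 4, 0, 2])
        pa, pb = np.flatnonzero(a), np.flatnonzero(b)
        assert ph.beta_mntd(a, b, cat_D, weighted=False) == pytest.approx(
            brute_force_beta_mntd(pa, pb, cat_D))
        assert ph.beta_mntd(a, b, cat_D, weighted=True) == pytest.approx(
            brute_force_beta_mntd(pa, pb, cat_D, wa=a[pa], wb=b[pb]))


class TestBetaNti:
    def test_identical_samples_non_positive(self, cat_D):
        table = make_table([[1, 0, 2, 0, 1], [1, 0, 2, 0, 1], [3, 1, 0, 0, 1]],
                           otu_ids=CATERPILLAR_TIPS)
        res = ph.beta_nti(table, D=cat_D, n_null=199, seed=1)
        assert res.bnti[0, 1] <= 0.0

    def test_matrix_structure(self, cat_D):
        table = make_table([[1, 2, 0, 0, 1], [0, 1, 3, 1, 0], [2, 0, 0, 1, 1]],
                           otu_ids=CATERPILLAR_TIPS)
        res = ph.beta_nti(table, D=cat_D, n_null=99, seed=2)
        assert np.isnan(np.diag(res.bnti)).all()
        off = ~np.eye(3, dtype=bool)
        assert res.bnti[off] == pytest.approx(res.bnti.T[off])

    def test_seed_reproducibility(self, cat_D):
        table = make_table([[1, 2, 0, 0, 1], [0, 1, 3, 1, 0]], otu_ids=CATERPILLAR_TIPS)
        r1 = ph.beta_nti(table, D=cat_D, n_null=199, seed=7)
        r2 = ph.beta_nti(table, D=cat_D, n_null=199, seed=7)
        assert np.array_equal(r1.bnti, r2.bnti, equal_nan=True)

    def test_branch_length_scale_equivariance(self, cat_D):
        table = make_table([[1, 2, 0, 0, 1], [0, 1, 3, 1, 0], [2, 0, 1, 1, 0]],
                           otu_ids=CATERPILLAR_TIPS)
        r1 = ph.beta_nti(table, D=cat_D, n_null=199, seed=4)
        r2 = ph.beta_nti(table, D=3.5 * cat_D, n_null=199, seed=4)
        off = ~np.eye(3, dtype=bool)
        assert r2.observed[off] == pytest.approx(3.5 * r1.observed[off])
        assert r2.bnti[off] == pytest.approx(r1.bnti[off], abs=1e-9)

    def test_sampled_null_matches_exhaustive_enumeration(self):
        # all 6! label permutations of the distance matrix give the exact
        # null distribution of betaMNTD for one pair
        tree = syn.simulate_tree(6, seed=3)
        ids = [t.name for t in tree.tips()]
        D = patristic_distances(tree, ids)
        a = np.array([3, 1, 0, 0, 2, 0])
        b = np.array([0, 0, 2, 1, 0, 4])
        table = make_table([a, b], otu_ids=ids)
        exact_vals = []
        for perm in itertools.permutations(range(6)):
            Dp = D[np.ix_(perm, perm)]
            exact_vals.append(ph.beta_mntd(a, b, Dp, weighted=True))
        exact_mean, exact_sd = np.mean(exact_vals), np.std(exact_vals, ddof=0)  # population sd: the enumeration IS the null law
        from .conftest import mc_se_of_sd

        n_null = 4000
        res = ph.beta_nti(table, D=D, n_null=n_null, seed=11)
        assert res.null_mean[0, 1] == pytest.approx(
            exact_mean, abs=3 * exact_sd / np.sqrt(n_null))
        assert res.null_sd[0, 1] == pytest.approx(
            exact_sd, abs=3 * mc_se_of_sd(exact_vals, n_null))

    def test_iid_samples_are_mostly_unflagged(self):
        # samples drawn iid from one pool should rarely cross |betaNTI| > 2
        hits = []
        for seed in (1, 2, 3):
            table, tree = syn.regime_fixture("drift", seed=seed, generations=0,
                                             n_samples=8, n_otus=200,
                                             library_size=2000)
            D = patristic_distances(tree, table.otu_ids)
            res = ph.beta_nti(table, D=D, n_null=299, seed=seed + 30)
            iu, ju = np.triu_indices(8, 1)
            hits.append((np.abs(res.bnti[iu, ju]) < 2).mean())
        assert min(hits) >= 0.8


def test_nti_table_against_single_community_path(cat_D):
    table = make_table([[1, 2, 0, 0, 1], [0, 1, 3, 1, 0]], otu_ids=CATERPILLAR_TIPS)
    report = ph.nti_table(table, D=cat_D, n_null=999, seed=8)
    solo = ph.ses_mntd(table.counts.iloc[0].to_numpy(), cat_D, n_null=999, seed=8)
    # same observed statistic; null draws differ only in shuffle stream usage
    assert report.mntd_obs.iloc[0] == pytest.approx(solo.observed)
    assert report.nti.iloc[0] == pytest.approx(solo.nti, abs=0.2)
    assert list(report.columns) == [
        "sample_id", "mntd_obs", "null_mean", "null_sd", "nti", "degenerate"]
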