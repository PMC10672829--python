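import numpy as np
import pandas as pd
import pytest

from ecoassembly import assembly as asm
from ecoassembly import synthetic as syn
from ecoassembly.containers import SampleFrame, ValidationError
from ecoassembly.phylo import BetaNtiMatrix

from .conftest import make_table


def _bnti_from(values: np.ndarray, labels) -> BetaNtiMatrix:
    z = np.array(values, dtype=float)
    np.fill_diagonal(z, np.nan)
    shape = z.shape
    return BetaNtiMatrix(labels=list(labels), bnti=z, observed=np.zeros(shape),
                         null_mean=np.zeros(shape), null_sd=np.ones(shape),
                         degenerate=np.zeros(shape, bool), n_null=999, seed=0,
                         weighted=True)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "bnti, rc, expected",
        [
            (3.0, 0.1, "variable_selection"),
            (-2.5, 0.99, "homogeneous_selection"),  # selection precedence
            (1.0, 0.99, "dispersal_limitation"),
            (0.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "drift"),
        ],
    )
    def test_five_rules(self, bnti, rc, expected):
        assert asm.classify_pair(bnti, rc) == expected

    @pytest.mark.parametrize(
        "bnti, rc, expected",
        [
            # betaNTI exactly at +/-2 is NOT selection; falls through to RC
            (2.0, 0.0, "drift"),
            (-2.0, 0.0, "drift"),
            (2.0, 0.96, "dispersal_limitation"),
            (-2.0, -0.96, "homogenizing_dispersal"),
            # just past the betaNTI thresholds: selection regardless of RC
            (2.0001, 0.99, "variable_selection"),
            (-2.0001, -0.99, "homogeneous_selection"),
            (2.0001, -0.99, "variable_selection"),
            (-2.0001, 0.99, "homogeneous_selection"),
            # RC exactly at +/-0.95 is NOT a dispersal verdict
            (0.0, 0.95, "drift"),
            (0.0, -0.95, "drift"),
            (1.9999, 0.95, "drift"),
            (-1.9999, -0.95, "drift"),
            # just past the RC thresholds
            (0.0, 0.9501, "dispersal_limitation"),
            (0.0, -0.9501, "homogenizing_dispersal"),
            (1.9999, 0.9501, "dispersal_limitation"),
            (-1.9999, -0.9501, "homogenizing_dispersal"),
        ],
    )
    def test_strict_boundary_semantics(self, bnti, rc, expected):
        assert asm.classify_pair(bnti, rc) == expected

    def test_nan_yields_none(self):
        assert asm.classify_pair(float("nan"), 0.0) is None
        assert asm.classify_pair(0.0, float("nan")) is None


class TestRaupCrick:
    def test_identical_samples_at_lower_extreme(self):
        # pool populated by other samples so nulls vary; the identical pair's
        # observed BC of 0 can never exceed a null draw
        counts = [[50, 50, 0, 0, 0],
                  [50, 50, 0, 0, 0],
                  [10, 10, 30, 30, 20]]
        res = asm.raup_crick_bray(make_table(counts), n_null=499, seed=0)
        assert res.rc[0, 1] <= 0.0

    def test_disjoint_samples_in_rich_pool_near_plus_one(self):
        # two disjoint richness-20 samples in a 100-OTU pool: null pairs of
        # that richness almost surely share taxa (expected overlap = 4), so
        # observed BC = 1 exceeds almost every null draw
        rng = np.random.default_rng(1)
        pool_rows = []
        for i in range(6):  # occupancy donors covering the whole pool
            row = np.zeros(100, int)
            idx = rng.choice(100, 60, replace=False)
            row[idx] = rng.integers(1, 20, 60)
            pool_rows.append(row)
        a = np.zeros(100, int)
        a[:20] = 50
        b = np.zeros(100, int)
        b[20:40] = 50
        table = make_table([a, b] + pool_rows)
        res = asm.raup_crick_bray(table, n_null=999, seed=2)
        assert res.rc[0, 1] > 0.9

    def test_exhaustive_enumeration_three_otu_pool(self):
        # richness-1 samples over a 3-OTU pool with equal occurrence: the
        # null BC is 0 (same member) with probability 1/3, else 1. With
        # observed BC = 1: RC = 2*(1/3 + 0.5*2/3) - 1 = 1/3 exactly.
        counts = [[100, 0, 0], [0, 100, 0], [0, 0, 100]]
        res = asm.raup_crick_bray(make_table(counts), n_null=9999, seed=3)
        p = 2 / 3  # exact tie-corrected probability
        se = np.sqrt(p * (1 - p) / 9999)
        assert res.rc[0, 1] == pytest.approx(1 / 3, abs=2 * 3 * se)

    def test_bounds_symmetry_and_nan_diagonal(self):
        table, _ = syn.regime_fixture("drift", seed=4, n_samples=5, n_otus=40,
                                      library_size=300)
        res = asm.raup_crick_bray(table, n_null=199, seed=5)
        off = ~np.eye(5, dtype=bool)
        assert (res.rc[off] >= -1).all() and (res.rc[off] <= 1).all()
        assert res.rc[off] == pytest.approx(res.rc.T[off])
        assert np.isnan(np.diag(res.rc)).all()

    def test_column_and_sample_order_invariance_statistical(self):
        # RC is defined on the table's content, not its layout; with finite
        # nulls the agreement is within Monte-Carlo error
        table, _ = syn.regime_fixture("drift", seed=6, n_samples=4, n_otus=50,
                                      library_size=500)
        rng = np.random.default_rng(7)
        perm = rng.permutation(50)
        shuffled = make_table(table.counts.to_numpy()[:, perm],
                              sample_ids=table.sample_ids,
                              otu_ids=[table.otu_ids[k] for k in perm])
        r1 = asm.raup_crick_bray(table, n_null=999, seed=8)
        r2 = asm.raup_crick_bray(shuffled, n_null=999, seed=8)
        iu, ju = np.triu_indices(4, 1)
        assert np.abs(r1.rc[iu, ju] - r2.rc[iu, ju]).max() < 0.12


class TestPartition:
    def _frame(self, labels, treatments):
        return SampleFrame(pd.DataFrame({
            "sample_id": labels,
            "habitat": ["water"] * len(labels),
            "treatment": treatments,
            "season": ["spring"] * len(labels),
            "tank": range(1, len(labels) + 1),
        }))

    def test_all_drift_pairs(self):
        labels = [f"s{i}" for i in range(4)]
        bnti = _bnti_from(np.zeros((4, 4)), labels)
        rc = asm.RcbrayMatrix(labels, np.zeros((4, 4)), 999, 0)
        part = asm.partition_processes(bnti, rc)
        drift = part.proportions.query("process == 'drift'").proportion
        assert (drift == 1.0).all()
        assert part.stochastic.stochastic_fraction.iloc[0] == 1.0

    def test_pair_count_is_n_choose_two(self):
        labels = [f"s{i}" for i in range(4)]
        bnti = _bnti_from(np.zeros((4, 4)), labels)
        rc = asm.RcbrayMatrix(labels, np.zeros((4, 4)), 999, 0)
        part = asm.partition_processes(bnti, rc)
        assert part.proportions.n_pairs.unique().tolist() == [6]

    def test_proportions_sum_to_one_and_split_identity(self):
        labels = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        z = rng.normal(0, 3, (6, 6))
        z = 0.5 * (z + z.T)
        r = np.clip(rng.normal(0, 0.8, (6, 6)), -1, 1)
        r = 0.5 * (r + r.T)
        bnti = _bnti_from(z, labels)
        rc = asm.RcbrayMatrix(labels, r, 999, 0)
        part = asm.partition_processes(
            bnti, rc, self._frame(labels, ["C"] * 3 + ["T"] * 3),
            grouping=("treatment",))
        sums = part.proportions.groupby("group").proportion.sum()
        assert sums.to_numpy() == pytest.approx(np.ones(len(sums)))
        merged = part.proportions.pivot(index="group", columns="process",
                                        values="proportion")
        det = merged.variable_selection + merged.homogeneous_selection
        stoch = part.stochastic.set_index("group").stochastic_fraction
        assert (det + stoch).to_numpy() == pytest.approx(np.ones(len(det)))

    def test_nan_pairs_excluded_and_counted(self):
        labels = [f"s{i}" for i in range(3)]
        z = np.zeros((3, 3))
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = np.nan
        bnti = _bnti_from(z, labels)
        rc = asm.RcbrayMatrix(labels, r, 999, 0)
        part = asm.partition_processes(bnti, rc)
        assert part.stochastic.n_excluded.iloc[0] == 1
        assert part.stochastic.n_pairs.iloc[0] == 2

    def test_small_group_skipped_with_warning(self):
        labels = ["a", "b", "c"]
        bnti = _bnti_from(np.zeros((3, 3)), labels)
        rc = asm.RcbrayMatrix(labels, np.zeros((3, 3)), 999, 0)
        frame = self._frame(labels, ["C", "C", "T"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            part = asm.partition_processes(bnti, rc, frame, grouping=("treatment",))
        assert part.proportions.group.unique().tolist() == ["C"]

    def test_label_mismatch_rejected(self):
        bnti = _bnti_from(np.zeros((2, 2)), ["a", "b"])
        rc = asm.RcbrayMatrix(["a", "c"], np.zeros((2, 2)), 999, 0)
        with pytest.raises(ValidationError):
            asm.partition_processes(bnti, rc)
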