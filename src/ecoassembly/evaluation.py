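"""Recovery and calibration diagnostics for the null-model stack.

These routines generate fixtures with known assembly processes, push them
through betaNTI + RCbray + classification, and measure how often the
generating process is recovered — plus type-I-error checks for the
permutation statistics. They exist so that the package's central claims are
recomputable with one call each.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from skbio import DistanceMatrix

from . import stats as st
from .assembly import classify_pair, raup_crick_bray
from .io import patristic_distances
from .phylo import beta_nti
from .synthetic import calibration_fixture, regime_fixture

# which classified labels count as "recovered" for each generating regime;
# selection counts both selection labels because the fixture contains
# same-optimum (convergent) and different-optimum (divergent) pairs
RECOVERY_LABELS = {
    "selection": {"variable_selection", "homogeneous_selection"},
    "drift": {"drift"},
    "dispersal_limitation": {"dispersal_limitation"},
    "homogenizing_dispersal": {"homogenizing_dispersal"},
}


def regime_recovery(
    regime: str,
    seed: int,
    n_samples: int = 12,
    n_otus: int = 200,
    library_size: int = 2000,
    n_null: int = 999,
) -> tuple[float, Counter]:
    """Fraction of sample pairs classified as the generating process."""
    table, tree = regime_fixture(regime, seed=seed, n_samples=n_samples,
                                 n_otus=n_otus, library_size=library_size)
    D = patristic_distances(tree, table.otu_ids)
    bnti = beta_nti(table, D=D, n_null=n_null, seed=seed + 100)
    rc = raup_crick_bray(table, n_null=n_null, seed=seed + 200)
    iu, ju = np.triu_indices(n_samples, 1)
    labels = Counter(classify_pair(bnti.bnti[i, j], rc.rc[i, j])
                     for i, j in zip(iu, ju))
    hits = sum(labels[l] for l in RECOVERY_LABELS[regime])
    return hits / len(iu), labels


def null_calibration(seed: int, n_null: int = 999) -> tuple[float, float]:
    """Type-I behaviour of betaNTI and RCbray on iid samples from one pool.

    Returns the fractions of pairs with |betaNTI| < 2 and |RCbray| < 0.95.
    """
    table, tree = calibration_fixture(seed)
    D = patristic_distances(tree, table.otu_ids)
    n = table.shape[0]
    bnti = beta_nti(table, D=D, n_null=n_null, seed=seed + 100)
    rc = raup_crick_bray(table, n_null=n_null, seed=seed + 200)
    iu, ju = np.triu_indices(n, 1)
    return (
        float((np.abs(bnti.bnti[iu, ju]) < 2).mean()),
        float((np.abs(rc.rc[iu, ju]) < 0.95).mean()),
    )


def _euclidean_dm(points: np.ndarray, ids) -> DistanceMatrix:
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=ids)


def mantel_type1(n_reps: int = 200, n: int = 20, n_perm: int = 99,
                 alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the Mantel test on independent random point sets."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    hits = 0
    for rep in range(n_reps):
        d1 = _euclidean_dm(rng.normal(size=(n, 2)), ids)
        d2 = _euclidean_dm(rng.normal(size=(n, 2)), ids)
        res = st.mantel(d1, d2, n_perm=n_perm, seed=int(rng.integers(2**31)))
        hits += res.p_value <= alpha
    return hits / n_reps


def permanova_type1(n_reps: int = 200, n: int = 20, n_perm: int = 99,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of PERMANOVA with labels independent of distances."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    groups = ["a"] * (n // 2) + ["b"] * (n - n // 2)
    hits = 0
    for rep in range(n_reps):
        dm = _euclidean_dm(rng.normal(size=(n, 2)), ids)
        res = st.permanova(dm, groups, n_perm=n_perm,
                           seed=int(rng.integers(2**31)))
        hits += res.p_value <= alpha
    return hits / n_reps


def kruskal_type1(n_reps: int = 500, group_size: int = 10,
                  alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of Kruskal-Wallis on three groups from one distribution."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(["a", "b", "c"], group_size)
    hits = 0
    for rep in range(n_reps):
        values = rng.normal(size=3 * group_size)
        hits += st.kruskal_wallis(values, groups).p_value <= alpha
    return hits / n_reps
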