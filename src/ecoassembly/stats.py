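"""Permutation and rank statistics: Spearman, BH adjustment, Mantel,
PERMANOVA, Kruskal-Wallis and Wilcoxon rank-sum.

Permutation p-values use the +1 correction, p = (1 + #{perm >= obs}) /
(1 + n_perm), so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permanova as _skbio_permanova
from statsmodels.stats.multitest import multipletests

from .containers import SampleFrame, ValidationError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    extra: dict | None = None

    def __iter__(self):
        yield self.statistic
        yield self.p_value


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties; analytic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if x.size < 5:
        raise ValidationError("need at least 5 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("rank correlation is undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _as_dm(d, labels=None) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    return DistanceMatrix(np.asarray(d, dtype=float), ids=labels)


def mantel(
    d1,
    d2,
    n_perm: int = 999,
    method: str = "spearman",
    seed: int = 0,
    labels=None,
    alternative: str = "greater",
) -> TestResult:
    """Mantel correlation between two distance matrices.

    The statistic is the rank (or Pearson) correlation over upper-triangle
    entries; the null permutes the labels of one matrix jointly over rows
    and columns.
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    dm1, dm2 = _as_dm(d1, labels), _as_dm(d2, labels)
    if dm1.ids != dm2.ids:
        raise ValidationError("distance matrices carry different labels")
    r, p, _ = _skbio_mantel(
        dm1, dm2, method=method, permutations=n_perm,
        alternative=alternative, seed=seed,
    )
    return TestResult(float(r), float(p), n_permutations=n_perm, seed=seed)


def permanova(
    d,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    labels=None,
) -> TestResult:
    """One-factor PERMANOVA: pseudo-F, R-squared, permutation p.

    R-squared is the among-group share of the total sum of squared
    distances, computed from the same decomposition that yields pseudo-F.
    """
    dm = _as_dm(d, labels)
    groups = pd.Series(list(groups), index=dm.ids)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if (sizes < 2).any():
        singles = sizes.index[sizes < 2].tolist()
        raise ValidationError(f"singleton group(s): {singles}")
    res = _skbio_permanova(dm, groups.to_numpy(), permutations=n_perm, seed=seed)
    # among/within decomposition for R^2 (Gower): SST = sum d^2 / N,
    # SSW = within-group pair sums / group size
    data = np.asarray(dm.data)
    n = data.shape[0]
    sst = (data**2).sum() / (2 * n)
    ssw = 0.0
    for g in sizes.index:
        idx = np.flatnonzero(groups.to_numpy() == g)
        sub = data[np.ix_(idx, idx)]
        ssw += (sub**2).sum() / (2 * idx.size)
    r2 = (sst - ssw) / sst if sst > 0 else float("nan")
    return TestResult(
        float(res["test statistic"]),
        float(res["p-value"]),
        n_permutations=n_perm,
        seed=seed,
        extra={"R2": float(r2), "n_groups": int(len(sizes))},
    )


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H with tie correction, chi-square approximation."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValidationError("need at least 2 non-empty groups")
    stat, p = sps.kruskal(*samples)
    return TestResult(float(stat), float(p))


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sample Wilcoxon rank-sum (normal approximation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    stat, p = sps.ranksums(a, b)
    return TestResult(float(stat), float(p))


def mantel_env_table(
    bnti_values: np.ndarray,
    labels: list[str],
    frame: SampleFrame,
    variables: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> pd.DataFrame:
    """Mantel correlations of a betaNTI matrix against environmental
    variables, one row per covariate.

    Each covariate is z-standardised and turned into a Euclidean distance
    matrix over the same samples. Covariates missing for any of the samples
    are skipped with an ``NaN`` row rather than an error, since habitats
    carry different covariate sets.
    """
    bnti = np.array(bnti_values, dtype=float)
    np.fill_diagonal(bnti, 0.0)
    if np.isnan(bnti).any():
        raise ValidationError("betaNTI matrix contains NaN off-diagonal entries")
    dm1 = DistanceMatrix(0.5 * (bnti + bnti.T), ids=labels)
    variables = variables or frame.env_columns
    rows = []
    rng_children = np.random.SeedSequence(seed).spawn(len(variables))
    for var, child in zip(variables, rng_children):
        series = frame.data[var].reindex(labels) if var in frame.data.columns else None
        if series is None or series.isna().any():
            rows.append({"variable": var, "r": np.nan, "p": np.nan})
            continue
        z = (series - series.mean()) / series.std()
        env_d = np.abs(z.to_numpy()[:, None] - z.to_numpy()[None, :])
        res = mantel(dm1, DistanceMatrix(env_d, ids=labels),
                     n_perm=n_perm, method=method,
                     seed=int(child.generate_state(1)[0] % (2**31)))
        rows.append({"variable": var, "r": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows, columns=["variable", "r", "p"])
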