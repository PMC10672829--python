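"""Phylogenetic null models: MNTD, NTI, betaMNTD and betaNTI.

The nearest-taxon statistics measure how phylogenetically clustered a
community (MNTD) or the turnover between two communities (betaMNTD) is.
Each observed value is compared against a null distribution obtained by
shuffling taxon labels across the patristic distance matrix ("taxa labels"
randomisation): the z-score of observed betaMNTD is betaNTI, and the
negative z-score of observed MNTD is NTI. |betaNTI| > 2 flags deterministic
(selection-driven) turnover; positive NTI flags phylogenetic clustering.

All null draws for a table are generated from one seeded shuffle sequence,
so (i, j) and (j, i) see identical nulls and results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable, ValidationError
from .io import patristic_distances

_DEGENERATE_TOL = 1e-12


@dataclass
class SesResult:
    """Standardised effect size of MNTD for one community.

    ``z = (observed - null_mean) / null_sd`` and ``nti = -z``. When the null
    distribution has zero spread (e.g. a star tree, or the community spans
    the whole taxon pool) the result is flagged degenerate and z is
    reported as 0.
    """

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_null: int
    seed: int
    degenerate: bool = False

    @property
    def nti(self) -> float:
        return -self.z


@dataclass
class BetaNtiMatrix:
    """Pairwise betaNTI panel for a sample set.

    ``bnti`` is symmetric with NaN diagonal; degenerate pairs (null sd = 0)
    carry betaNTI 0 and are flagged in ``degenerate``.
    """

    labels: list[str]
    bnti: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    degenerate: np.ndarray
    n_null: int
    seed: int
    weighted: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bnti, index=self.labels, columns=self.labels)


def _as_vector(community, n: int) -> np.ndarray:
    v = np.asarray(community, dtype=float)
    if v.shape != (n,):
        raise ValidationError(f"community vector must have length {n}")
    if (v < 0).any():
        raise ValidationError("community abundances must be non-negative")
    return v


def mntd(community, D: np.ndarray, weighted: bool = False) -> float:
    """Mean nearest taxon distance within one community.

    For each present taxon, the patristic distance to its closest other
    present taxon; averaged either equally or by relative abundance of the
    focal taxa.
    """
    D = np.asarray(D, dtype=float)
    v = _as_vector(community, D.shape[0])
    present = np.flatnonzero(v > 0)
    if present.size < 2:
        raise ValidationError("MNTD needs at least 2 present taxa")
    sub = D[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if weighted:
        w = v[present] / v[present].sum()
        return float(np.dot(w, nearest))
    return float(nearest.mean())


def ses_mntd(
    community,
    D: np.ndarray,
    weighted: bool = False,
    n_null: int = 999,
    seed: int = 0,
) -> SesResult:
    """SES of MNTD under taxon-label shuffles of the distance matrix."""
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    v = _as_vector(community, n)
    present = np.flatnonzero(v > 0)
    obs = mntd(v, D, weighted=weighted)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    w = v[present] / v[present].sum() if weighted else None
    for t in range(n_null):
        perm = rng.permutation(n)
        sub = D[np.ix_(perm[present], perm[present])].copy()
        np.fill_diagonal(sub, np.inf)
        nearest = sub.min(axis=1)
        nulls[t] = np.dot(w, nearest) if weighted else nearest.mean()
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if n_null > 1 else 0.0
    if sd <= _DEGENERATE_TOL:
        return SesResult(obs, mu, sd, 0.0, n_null, seed, degenerate=True)
    return SesResult(obs, mu, sd, (obs - mu) / sd, n_null, seed)


def nti_table(
    table: OtuTable,
    tree: TreeNode | None = None,
    D: np.ndarray | None = None,
    weighted: bool = False,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample NTI report (sample_id, mntd_obs, null_mean, null_sd, nti,
    degenerate).

    One shuffle sequence is shared by all samples, matching the pairwise
    betaNTI convention.
    """
    D = _resolve_distances(table, tree, D)
    counts = table.counts.to_numpy(dtype=float)
    n_samples, n_taxa = counts.shape
    present = [np.flatnonzero(counts[j] > 0) for j in range(n_samples)]
    for j, pres in enumerate(present):
        if pres.size < 2:
            raise ValidationError(
                f"sample {table.sample_ids[j]!r} has fewer than 2 OTUs")
    weights = None
    if weighted:
        weights = [counts[j][p] / counts[j][p].sum() for j, p in enumerate(present)]

    def all_mntd(perm: np.ndarray | None) -> np.ndarray:
        out = np.empty(n_samples)
        for j, pres in enumerate(present):
            idx = pres if perm is None else perm[pres]
            sub = D[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, np.inf)
            nearest = sub.min(axis=1)
            out[j] = np.dot(weights[j], nearest) if weighted else nearest.mean()
        return out

    obs = all_mntd(None)
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_samples)
    acc2 = np.zeros(n_samples)
    for _ in range(n_null):
        nb = all_mntd(rng.permutation(n_taxa))
        acc += nb
        acc2 += nb**2
    mu = acc / n_null
    var = (acc2 - n_null * mu**2) / max(n_null - 1, 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    degenerate = sd <= _DEGENERATE_TOL
    z = np.where(degenerate, 0.0, (obs - mu) / np.where(degenerate, 1.0, sd))
    return pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "mntd_obs": obs,
            "null_mean": mu,
            "null_sd": sd,
            "nti": -z,
            "degenerate": degenerate,
        }
    )


def beta_mntd(comm_a, comm_b, D: np.ndarray, weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance (betaMNTD).

    For each taxon in community a, the distance to its nearest taxon in
    community b (zero when shared), averaged with weights equal to relative
    abundances when ``weighted``; symmetrised with the b-to-a direction.
    """
    D = np.asarray(D, dtype=float)
    a = _as_vector(comm_a, D.shape[0])
    b = _as_vector(comm_b, D.shape[0])
    pa, pb = np.flatnonzero(a > 0), np.flatnonzero(b > 0)
    if pa.size == 0 or pb.size == 0:
        raise ValidationError("betaMNTD needs non-empty communities")
    d_ab = D[np.ix_(pa, pb)].min(axis=1)
    d_ba = D[np.ix_(pb, pa)].min(axis=1)
    if weighted:
        wa = a[pa] / a[pa].sum()
        wb = b[pb] / b[pb].sum()
        return 0.5 * (float(np.dot(wa, d_ab)) + float(np.dot(wb, d_ba)))
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


def beta_nti(
    table: OtuTable,
    tree: TreeNode | None = None,
    D: np.ndarray | None = None,
    weighted: bool = True,
    n_null: int = 999,
    seed: int = 0,
) -> BetaNtiMatrix:
    """Pairwise betaNTI for all sample pairs of a table.

    Observed betaMNTD is z-scored against ``n_null`` taxon-label shuffles of
    the patristic matrix; the same shuffle sequence serves every pair.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    D = _resolve_distances(table, tree, D)
    counts = table.counts.to_numpy(dtype=float)
    n_samples, n_taxa = counts.shape
    if n_samples < 2:
        raise ValidationError("betaNTI needs at least 2 samples")
    present = [np.flatnonzero(counts[j] > 0) for j in range(n_samples)]
    if weighted:
        P = counts / counts.sum(axis=1, keepdims=True)
    else:
        inc = (counts > 0).astype(float)
        P = inc / inc.sum(axis=1, keepdims=True)

    def bmntd_matrix(dist: np.ndarray) -> np.ndarray:
        # Dmin[j, k]: distance from taxon k to its nearest taxon in sample j
        dmin = np.empty((n_samples, n_taxa))
        for j, pres in enumerate(present):
            dmin[j] = dist[:, pres].min(axis=1)
        m = P @ dmin.T
        return 0.5 * (m + m.T)

    obs = bmntd_matrix(D)
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        nb = bmntd_matrix(D[np.ix_(perm, perm)])
        acc += nb
        acc2 += nb**2
    mu = acc / n_null
    var = (acc2 - n_null * mu**2) / max(n_null - 1, 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    degenerate = sd <= _DEGENERATE_TOL
    with np.errstate(invalid="ignore"):
        z = np.where(degenerate, 0.0, (obs - mu) / np.where(degenerate, 1.0, sd))
    np.fill_diagonal(z, np.nan)
    return BetaNtiMatrix(
        labels=table.sample_ids,
        bnti=z,
        observed=obs,
        null_mean=mu,
        null_sd=sd,
        degenerate=degenerate,
        n_null=n_null,
        seed=seed,
        weighted=weighted,
    )


def _resolve_distances(table: OtuTable, tree: TreeNode | None, D: np.ndarray | None) -> np.ndarray:
    if D is None:
        if tree is None:
            raise ValidationError("provide either a tree or a patristic distance matrix")
        D = patristic_distances(tree, table.otu_ids)
    D = np.asarray(D, dtype=float)
    n_taxa = table.shape[1]
    if D.shape != (n_taxa, n_taxa):
        raise ValidationError(
            f"distance matrix shape {D.shape} does not match {n_taxa} OTUs")
    return D
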