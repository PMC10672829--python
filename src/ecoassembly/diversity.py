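"""Rarefaction, alpha diversity (Chao1, Shannon) and Bray-Curtis dissimilarity.

Counts are normalised by subsampling each library without replacement to a
common depth (typically the minimum library size of the sample set), after
which richness is estimated with the bias-corrected Chao1 estimator and
diversity with the Shannon index (natural log by default, switchable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as _alpha

from .containers import OtuTable, ValidationError


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    OTUs that become all-zero are retained so table dimensions stay stable.
    A depth exceeding the smallest library is an error naming that sample.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    sums = table.sample_sums()
    if (sums < depth).any():
        offender = sums.idxmin()
        raise ValidationError(
            f"depth {depth} exceeds the library of sample {offender!r} ({sums.min()})")
    rng = np.random.default_rng(seed)
    counts = table.counts.to_numpy()
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return OtuTable(pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValidationError("Chao1 is undefined for an all-zero sample")
    return float(_alpha.chao1(counts, bias_corrected=True))


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy -sum p ln p; natural log unless ``base`` is given."""
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise ValidationError("Shannon is undefined for an all-zero sample")
    return float(_alpha.shannon(counts, base=base if base is not None else np.e))


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample alpha diversity report: sample_id, chao1, shannon, depth."""
    rows = []
    for sid, row in table.counts.iterrows():
        c = row.to_numpy()
        rows.append({"sample_id": sid, "chao1": chao1(c),
                     "shannon": shannon(c), "depth": int(c.sum())})
    return pd.DataFrame(rows)


def bray_curtis(table: OtuTable, use_relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, by default on relative abundances.

    BC(u, v) = sum |u_i - v_i| / sum (u_i + v_i); values lie in [0, 1].
    """
    if table.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    data = table.relative_abundance() if use_relative else table.counts.astype(float)
    condensed = pdist(data.to_numpy(), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def rarefaction_curve(sample_counts, depths, reps: int, seed: int) -> pd.DataFrame:
    """Mean observed richness of repeated subsamples at each depth."""
    counts = np.asarray(sample_counts)
    total = counts.sum()
    depths = sorted(int(d) for d in depths)
    if depths and depths[-1] > total:
        raise ValidationError(f"depth {depths[-1]} exceeds the sample total {total}")
    rng = np.random.default_rng(seed)
    rows = []
    for d in depths:
        rich = [
            int((rng.multivariate_hypergeometric(counts, d) > 0).sum())
            for _ in range(reps)
        ]
        rows.append({"depth": d, "mean_richness": float(np.mean(rich))})
    return pd.DataFrame(rows)
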