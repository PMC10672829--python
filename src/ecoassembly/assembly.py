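"""Raup-Crick (Bray-Curtis) null model and the five-process partitioning.

betaNTI separates deterministic turnover (|betaNTI| > 2: variable or
homogeneous selection) from stochastic turnover; among the stochastic pairs,
the Bray-Curtis-based Raup-Crick statistic (RCbray) separates dispersal
limitation (RCbray > +0.95) from homogenizing dispersal (RCbray < -0.95),
with the remainder attributed to drift / undominated processes. All
inequalities are strict: a value exactly at a threshold falls through to the
next rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OtuTable, SampleFrame, ValidationError
from .phylo import BetaNtiMatrix

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

STOCHASTIC_PROCESSES = ("dispersal_limitation", "homogenizing_dispersal", "drift")

_BC_TOL = 1e-12


@dataclass
class RcbrayMatrix:
    """Pairwise RCbray panel: symmetric, entries in [-1, +1], NaN diagonal."""

    labels: list[str]
    rc: np.ndarray
    n_null: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rc, index=self.labels, columns=self.labels)


def _null_pair_bc(
    rng: np.random.Generator,
    richness: tuple[int, int],
    totals: tuple[int, int],
    occ_w: np.ndarray,
    abund_w: np.ndarray,
    n_null: int,
) -> np.ndarray:
    """Bray-Curtis between ``n_null`` pairs of null-assembled communities.

    Each null community preserves its sample's observed richness and total
    abundance: taxa join with probability proportional to their occurrence
    frequency across the table (Gumbel top-k sampling without replacement),
    receive one individual each, and the remaining individuals are
    distributed multinomially in proportion to total relative abundance.
    """
    pool = occ_w.size
    members = []
    log_w = np.log(occ_w)
    for n_taxa in richness:
        keys = log_w[None, :] + rng.gumbel(size=(n_null, pool))
        if n_taxa >= pool:
            members.append(np.tile(np.arange(pool), (n_null, 1)))
        else:
            members.append(np.argpartition(-keys, n_taxa, axis=1)[:, :n_taxa])
    bc = np.empty(n_null)
    u = np.zeros(pool)
    v = np.zeros(pool)
    for t in range(n_null):
        for vec, side in ((u, 0), (v, 1)):
            vec[:] = 0.0
            idx = members[side][t]
            n_taxa, total = richness[side], totals[side]
            fill = abund_w[idx]
            fill = fill / fill.sum()
            vec[idx] = 1.0 + rng.multinomial(total - n_taxa, fill)
            vec /= total
        bc[t] = 0.5 * np.abs(u - v).sum()
    return bc


def raup_crick_bray(table: OtuTable, n_null: int = 999, seed: int = 0) -> RcbrayMatrix:
    """RCbray for every sample pair of a count table.

    RCbray = 2 * (#(null BC < observed BC) + 0.5 * #(ties)) / n_null - 1,
    so values near +1 mean the observed pair is more dissimilar than null
    assembly expects and values near -1 more similar. Each pair gets an
    independent child seed spawned from the master seed.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    counts = table.counts.to_numpy()
    n_samples, pool = counts.shape
    if n_samples < 2:
        raise ValidationError("RCbray needs at least 2 samples")
    occ = (counts > 0).sum(axis=0).astype(float)
    abund = counts.sum(axis=0).astype(float)
    usable = occ > 0
    if not usable.all():
        counts = counts[:, usable]
        occ, abund = occ[usable], abund[usable]
        pool = int(usable.sum())
    rel = counts / counts.sum(axis=1, keepdims=True)
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)

    pairs = [(i, j) for i in range(n_samples) for j in range(i + 1, n_samples)]
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    rc = np.full((n_samples, n_samples), np.nan)
    for (i, j), child in zip(pairs, children):
        obs = 0.5 * np.abs(rel[i] - rel[j]).sum()
        nulls = _null_pair_bc(
            np.random.default_rng(child),
            (int(richness[i]), int(richness[j])),
            (int(totals[i]), int(totals[j])),
            occ, abund, n_null,
        )
        less = int((nulls < obs - _BC_TOL).sum())
        ties = int((np.abs(nulls - obs) <= _BC_TOL).sum())
        rc[i, j] = rc[j, i] = 2.0 * (less + 0.5 * ties) / n_null - 1.0
    return RcbrayMatrix(labels=table.sample_ids, rc=rc, n_null=n_null, seed=seed)


def classify_pair(bnti: float, rc: float) -> str | None:
    """Assign one of the five assembly processes to a (betaNTI, RCbray) pair.

    Selection takes precedence: betaNTI > +2 is variable selection and
    betaNTI < -2 homogeneous selection regardless of RCbray. Otherwise
    RCbray > +0.95 is dispersal limitation, RCbray < -0.95 homogenizing
    dispersal, and anything else drift. NaN inputs yield ``None``.
    """
    if bnti is None or rc is None or np.isnan(bnti) or np.isnan(rc):
        return None
    if bnti > 2.0:
        return "variable_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class ProcessPartition:
    """Per-group process proportions plus the underlying pair-level labels."""

    proportions: pd.DataFrame  # group, process, proportion, n_pairs
    stochastic: pd.DataFrame  # group, stochastic_fraction, n_pairs, n_excluded
    pairs: pd.DataFrame  # group, sample_a, sample_b, bnti, rcbray, process


def partition_processes(
    bnti: BetaNtiMatrix,
    rc: RcbrayMatrix,
    frame: SampleFrame | None = None,
    grouping: tuple[str, ...] = ("habitat", "treatment", "season"),
) -> ProcessPartition:
    """Classify every within-group sample pair and aggregate proportions.

    Groups are formed from metadata design factors; with ``frame=None`` all
    samples form one group. Groups with fewer than two samples are skipped
    with a warning; NaN-valued pairs are excluded and counted.
    """
    if bnti.labels != rc.labels:
        raise ValidationError("betaNTI and RCbray matrices carry different labels")
    labels = bnti.labels
    if frame is not None:
        keys = frame.group_key(grouping).reindex(labels)
        if keys.isna().any():
            missing = [l for l in labels if l not in frame.data.index]
            raise ValidationError(f"metadata missing sample id(s): {missing}")
    else:
        keys = pd.Series("all", index=labels)

    pair_rows = []
    prop_rows = []
    stoch_rows = []
    for group in sorted(keys.unique()):
        members = [i for i, l in enumerate(labels) if keys.loc[l] == group]
        if len(members) < 2:
            warnings.warn(f"group {group!r} has fewer than 2 samples; skipped")
            continue
        counts = dict.fromkeys(PROCESSES, 0)
        n_excluded = 0
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                label = classify_pair(bnti.bnti[i, j], rc.rc[i, j])
                pair_rows.append(
                    {
                        "group": group,
                        "sample_a": labels[i],
                        "sample_b": labels[j],
                        "bnti": bnti.bnti[i, j],
                        "rcbray": rc.rc[i, j],
                        "process": label,
                    }
                )
                if label is None:
                    n_excluded += 1
                else:
                    counts[label] += 1
        n_pairs = sum(counts.values())
        for process in PROCESSES:
            prop_rows.append(
                {
                    "group": group,
                    "process": process,
                    "proportion": counts[process] / n_pairs if n_pairs else np.nan,
                    "n_pairs": n_pairs,
                }
            )
        stoch = sum(counts[p] for p in STOCHASTIC_PROCESSES)
        stoch_rows.append(
            {
                "group": group,
                "stochastic_fraction": stoch / n_pairs if n_pairs else np.nan,
                "n_pairs": n_pairs,
                "n_excluded": n_excluded,
            }
        )
    return ProcessPartition(
        proportions=pd.DataFrame(prop_rows, columns=["group", "process", "proportion", "n_pairs"]),
        stochastic=pd.DataFrame(stoch_rows, columns=["group", "stochastic_fraction", "n_pairs", "n_excluded"]),
        pairs=pd.DataFrame(pair_rows, columns=["group", "sample_a", "sample_b", "bnti", "rcbray", "process"]),
    )
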