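"""Core in-memory containers: OTU abundance tables and sample metadata.

The package works on three coupled objects: an :class:`OtuTable`
(samples x OTUs integer counts), a :class:`SampleFrame` (per-sample design
factors and environmental covariates), and a rooted phylogeny
(``skbio.TreeNode``) whose tips cover the OTUs used in phylogenetic
statistics. Cross-object identifier consistency is validated by
:func:`ecoassembly.io.validate_consistency`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HABITATS = ("water", "sediment")
TREATMENTS = ("C", "T", "H")
SEASONS = ("spring", "summer", "autumn", "winter")

#: metadata columns that must always be present, in on-disk order
METADATA_COLUMNS = ("sample_id", "habitat", "treatment", "season", "tank")


class ValidationError(ValueError):
    """Raised when an input table, tree or metadata frame violates its contract."""


class ConsistencyError(ValidationError):
    """Raised when identifier sets disagree across table / tree / metadata."""


def _check_unique(labels, kind: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {kind} identifier(s): {dups}")


class OtuTable:
    """An integer OTU abundance matrix, samples as rows, OTUs as columns.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with OTU ids as columns. Values must
        be non-negative integers. All-zero OTU columns are permitted (they
        arise from subsetting and rarefaction) and are reported by
        :attr:`zero_otus`; all-zero sample rows are rejected.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        _check_unique(counts.index, "sample")
        _check_unique(counts.columns, "OTU")
        values = counts.to_numpy()
        if values.size == 0:
            raise ValidationError("empty OTU table")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0, rtol=0):
                bad = np.argwhere(values != np.round(values))[0]
                raise ValidationError(
                    f"non-integer count at sample {counts.index[bad[0]]!r}, "
                    f"OTU {counts.columns[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
            values = counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {counts.index[bad[0]]!r}, "
                f"OTU {counts.columns[bad[1]]!r}"
            )
        zero_rows = values.sum(axis=1) == 0
        if zero_rows.any():
            offenders = counts.index[zero_rows].tolist()
            raise ValidationError(f"all-zero sample row(s): {offenders}")
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def zero_otus(self) -> list[str]:
        """OTU ids whose total count is zero (kept, but flagged)."""
        totals = self.counts.sum(axis=0)
        return totals.index[totals == 0].tolist()

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised abundances (each sample sums to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    # -- subsetting ------------------------------------------------------

    def select_samples(self, sample_ids) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown sample id(s): {missing}")
        return OtuTable(self.counts.loc[list(sample_ids)])

    def drop_zero_otus(self) -> "OtuTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return OtuTable(self.counts[keep])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.shape
        return f"<OtuTable: {n} samples x {p} OTUs>"

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.counts.equals(other.counts)


class SampleFrame:
    """Per-sample design factors and environmental covariates.

    The frame is indexed by ``sample_id`` and carries the mesocosm design
    factors (habitat, warming treatment C/T/H, season, tank) plus any number
    of numeric environmental covariates (temperature, nutrients, pH, ...).
    Covariates may be missing (NaN) for samples where they were not
    measured — e.g. water-column chemistry is undefined for sediment — and
    operations that need a covariate fail fast naming it.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValidationError("metadata needs a 'sample_id' column or index")
        df.index = df.index.astype(str)
        _check_unique(df.index, "sample")
        for col in ("habitat", "treatment", "season", "tank"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        for col, allowed in (
            ("habitat", HABITATS),
            ("treatment", TREATMENTS),
            ("season", SEASONS),
        ):
            bad = sorted(set(df[col].astype(str)) - set(allowed))
            if bad:
                raise ValidationError(f"invalid {col} value(s) {bad}; allowed: {allowed}")
        df["tank"] = df["tank"].astype(int)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def env_columns(self) -> list[str]:
        """Names of the numeric covariate columns (everything non-design)."""
        design = {"habitat", "treatment", "season", "tank"}
        return [c for c in self.data.columns if c not in design]

    def env(self, name: str, sample_ids=None) -> pd.Series:
        """Return one covariate, failing fast if absent or all-missing."""
        if name not in self.data.columns:
            raise ValidationError(f"covariate {name!r} not present in metadata")
        series = self.data[name]
        if sample_ids is not None:
            series = series.loc[list(sample_ids)]
        if series.isna().all():
            raise ValidationError(f"covariate {name!r} is missing for all requested samples")
        return series.astype(float)

    def subset(self, sample_ids) -> "SampleFrame":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ConsistencyError(f"metadata missing sample id(s): {missing}")
        return SampleFrame(self.data.loc[list(sample_ids)].reset_index())

    def group_key(self, factors) -> pd.Series:
        """Concatenate design factors into one label per sample."""
        for f in factors:
            if f not in self.data.columns:
                raise ValidationError(f"grouping factor {f!r} not in metadata")
        parts = [self.data[f].astype(str) for f in factors]
        out = parts[0]
        for p in parts[1:]:
            out = out + ":" + p
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<SampleFrame: {len(self.data)} samples, {len(self.env_columns)} covariates>"
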