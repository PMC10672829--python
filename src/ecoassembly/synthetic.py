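"""Synthetic mesocosm communities with known assembly processes.

This module generates everything the analysis stack consumes — a phylogeny,
per-sample metadata with environmental covariates, and OTU count tables —
under controllable assembly regimes:

``selection``
    OTU sampling weights are Gaussian filters of a phylogenetically
    conserved trait (Brownian motion on the tree) around a per-sample
    environmental optimum; shared optima emulate homogeneous selection,
    divergent optima variable selection.
``drift``
    Each sample drifts independently from a common metacommunity by
    ``generations`` rounds of multinomial resampling at the library size.
``dispersal_limitation``
    Drift between fully isolated patches seeded from disjoint subsets of
    the metacommunity, so compositional turnover is high but phylogenetically
    random.
``homogenizing_dispersal``
    Every generation each sample's pool is pulled toward the global mean
    pool with migration rate ``m`` near one, forcing compositional
    convergence.

The mesocosm designer emulates the study design these tools target: 18
outdoor tanks under three warming scenarios (ambient control C, constant
+4 °C warming T, and a heatwave treatment H fluctuating ±4 °C around T),
sampled over four seasons in two habitats (water column and sediment), with
seasonal, treatment-linked environmental covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import HABITATS, SEASONS, TREATMENTS, OtuTable, SampleFrame, ValidationError

REGIMES = ("selection", "drift", "dispersal_limitation", "homogenizing_dispersal")

# Metacommunity rank-abundance: lognormal with a heavy tail, which is what
# rarefaction behaviour of real amplicon libraries requires.
LOGNORMAL_MEANLOG = 0.0
LOGNORMAL_SDLOG = 1.5


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> TreeNode:
    """Simulate a pure-birth (Yule) tree with exponential waiting times.

    Tips are labelled ``OTU_1 .. OTU_n``. The same seed always yields the
    same newick string.
    """
    if n_tips < 2:
        raise ValidationError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    root = TreeNode(length=0.0)
    t = 0.0
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode(length=None)
        root.append(child)
        active.append((child, 0.0))
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = rng.integers(k)
        node, born = active.pop(idx)
        node.length = t - born
        for _ in range(2):
            child = TreeNode(length=None)
            node.append(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, born in active:
        node.length = t - born
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"OTU_{i}"
    return root


def simulate_traits(tree: TreeNode, rate: float, seed: int) -> pd.Series:
    """Evolve a Brownian-motion trait along the tree from a root value of 0.

    Each branch adds an independent Normal(0, rate * branch_length)
    increment, so tip variance equals ``rate`` times root-to-tip depth and
    tip covariance equals ``rate`` times shared path length.
    """
    if rate < 0:
        raise ValidationError("trait rate must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(rate * node.length)) if node.length > 0 else 0.0
        values[id(node)] = parent_val + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait")


# ---------------------------------------------------------------------------
# Assembly regimes
# ---------------------------------------------------------------------------

@dataclass
class RegimeSpec:
    """Parameters of one simulated assembly regime.

    sigma is the Gaussian niche breadth (selection only; trait units);
    generations the number of multinomial drift rounds; migration the
    per-generation mixing fraction toward the global pool (homogenizing
    dispersal only); n_patches the number of isolated patches (dispersal
    limitation; defaults to one patch per sample).
    """

    regime: str
    n_samples: int = 12
    n_otus: int = 200
    library_size: int = 2000
    sigma: float | None = None
    generations: int = 5
    migration: float | None = None
    n_patches: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.n_samples < 2 or self.n_otus < 2 or self.library_size < 1:
            raise ValidationError("need n_samples >= 2, n_otus >= 2, library_size >= 1")
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if self.regime == "selection" and (self.sigma is None or self.sigma <= 0):
            raise ValidationError("selection requires sigma > 0")
        if self.regime == "homogenizing_dispersal":
            if self.migration is None:
                self.migration = 0.8
            if not 0.0 <= self.migration <= 1.0:
                raise ValidationError("migration must be in [0, 1]")


def metacommunity_abundances(n_otus: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal metacommunity relative abundances (heavy-tailed)."""
    base = rng.lognormal(LOGNORMAL_MEANLOG, LOGNORMAL_SDLOG, size=n_otus)
    return base / base.sum()


def _drift_rounds(p: np.ndarray, generations: int, library_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    for _ in range(generations):
        p = rng.multinomial(library_size, p) / library_size
    return p


def simulate_regime(
    spec: RegimeSpec,
    tree: TreeNode | None = None,
    env_optima: np.ndarray | None = None,
    traits: pd.Series | None = None,
    sample_ids: list[str] | None = None,
    base_abundance: np.ndarray | None = None,
) -> OtuTable:
    """Generate an OTU table under one assembly regime.

    Every sample's counts sum to ``spec.library_size`` exactly. For the
    selection regime a phylogeny (or a precomputed trait series) and
    per-sample environmental optima are required.
    """
    rng = np.random.default_rng(spec.seed)
    n, p_otus, lib = spec.n_samples, spec.n_otus, spec.library_size
    if tree is not None:
        otu_ids = [t.name for t in tree.tips()]
        if len(otu_ids) != p_otus:
            raise ValidationError(
                f"tree has {len(otu_ids)} tips but spec.n_otus = {p_otus}")
    else:
        otu_ids = [f"OTU_{i}" for i in range(1, p_otus + 1)]
    if base_abundance is None:
        base = metacommunity_abundances(p_otus, rng)
    else:
        base = np.asarray(base_abundance, dtype=float)
        base = base / base.sum()

    if spec.regime == "selection":
        if traits is None:
            if tree is None:
                raise ValidationError("selection requires a tree or a trait series")
            traits = simulate_traits(tree, rate=1.0, seed=spec.seed + 1)
        if env_optima is None:
            raise ValidationError("selection requires per-sample env_optima")
        optima = np.asarray(env_optima, dtype=float)
        if optima.shape != (n,):
            raise ValidationError(f"env_optima must have length {n}")
        tvals = traits.reindex(otu_ids).to_numpy()
        counts = np.empty((n, p_otus), dtype=np.int64)
        for j in range(n):
            w = base * np.exp(-((tvals - optima[j]) ** 2) / (2.0 * spec.sigma**2))
            if w.sum() == 0:  # numerically possible for extreme optima
                w = base.copy()
            counts[j] = rng.multinomial(lib, w / w.sum())

    elif spec.regime == "drift":
        counts = np.empty((n, p_otus), dtype=np.int64)
        for j in range(n):
            pj = _drift_rounds(base, spec.generations, lib, rng)
            counts[j] = rng.multinomial(lib, pj)

    elif spec.regime == "dispersal_limitation":
        k = spec.n_patches or max(2, n // 3)
        perm = rng.permutation(p_otus)
        subsets = np.array_split(perm, k)
        counts = np.empty((n, p_otus), dtype=np.int64)
        for j in range(n):
            pool = np.zeros(p_otus)
            idx = subsets[j % k]
            pool[idx] = base[idx]
            pool /= pool.sum()
            pj = _drift_rounds(pool, spec.generations, lib, rng)
            counts[j] = rng.multinomial(lib, pj)

    else:  # homogenizing_dispersal
        m = spec.migration
        pools = np.tile(base, (n, 1))
        for _ in range(spec.generations):
            for j in range(n):
                pools[j] = rng.multinomial(lib, pools[j]) / lib
            mean_pool = pools.mean(axis=0)
            pools = (1.0 - m) * pools + m * mean_pool
        counts = np.empty((n, p_otus), dtype=np.int64)
        for j in range(n):
            counts[j] = rng.multinomial(lib, pools[j])

    if sample_ids is None:
        sample_ids = [f"S{j + 1:02d}" for j in range(n)]
    return OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))


def calibration_fixture(
    seed: int,
    n_samples: int = 12,
    n_otus: int = 100,
    library_size: int = 10000,
) -> tuple[OtuTable, TreeNode]:
    """iid multinomial samples from one deeply sequenced pool.

    Used to check the type-I behaviour of the pairwise null models. The pool
    is mildly heavy-tailed (lognormal, sdlog 1) and the library deep enough
    that occupancy is near-saturated: in that regime the Raup-Crick null
    assembly is exchangeable with the iid generative process, which is the
    condition under which its score is interpretable as calibrated. (With an
    unsaturated heavy tail, iid pairs are genuinely more similar than
    membership-randomising null assembly expects and RCbray sits near -1 by
    construction.)
    """
    rng = np.random.default_rng(seed + 50)
    base = rng.lognormal(0.0, 1.0, size=n_otus)
    tree = simulate_tree(n_otus, seed=seed)
    spec = RegimeSpec("drift", n_samples=n_samples, n_otus=n_otus,
                      library_size=library_size, generations=0, seed=seed + 7)
    table = simulate_regime(spec, tree=tree, base_abundance=base)
    return table, tree


def selection_optima(traits: pd.Series, n_samples: int, spread: float = 1.5) -> np.ndarray:
    """Three-group optima at mean - spread·SD, mean, and mean + spread·SD.

    Three environments mirror the three warming scenarios of the mesocosm
    design; samples sharing an optimum experience homogeneous selection,
    samples with different optima variable selection.
    """
    mu, sd = float(traits.mean()), float(traits.std())
    levels = np.array([mu - spread * sd, mu, mu + spread * sd])
    return levels[np.arange(n_samples) * 3 // n_samples]


def regime_fixture(
    regime: str,
    seed: int,
    n_samples: int = 12,
    n_otus: int = 200,
    library_size: int = 2000,
    **kwargs,
) -> tuple[OtuTable, TreeNode]:
    """Convenience constructor: a tree plus a table under one regime.

    For the selection regime the niche breadth defaults to 0.3 tip-trait
    standard deviations (strong filtering) and optima to three equal groups
    spanning mean ± 1.5 SD.
    """
    tree = simulate_tree(n_otus, seed=seed)
    spec_kwargs = dict(
        regime=regime, n_samples=n_samples, n_otus=n_otus,
        library_size=library_size, seed=seed + 7, **kwargs,
    )
    traits = None
    optima = None
    if regime == "selection":
        traits = simulate_traits(tree, rate=1.0, seed=seed + 3)
        optima = selection_optima(traits, n_samples)
        spec_kwargs.setdefault("sigma", 0.3 * float(traits.std()))
    spec = RegimeSpec(**spec_kwargs)
    table = simulate_regime(spec, tree=tree, env_optima=optima, traits=traits)
    return table, tree


# ---------------------------------------------------------------------------
# Mesocosm design
# ---------------------------------------------------------------------------

@dataclass
class MesocosmDesign:
    """The warming-experiment layout: tanks x treatments x seasons x habitats.

    Temperatures follow a seasonal sinusoid around ``baseline_mean_temp``;
    the constant-warming treatment adds ``warming_offset`` (+4 °C); the
    heatwave treatment oscillates ±``heatwave_amplitude`` around the
    constant-warming level with zero annual mean, so T and H share the same
    annual mean temperature.
    """

    n_tanks: int = 18
    replicates_per_treatment: int = 6
    seasons: tuple[str, ...] = SEASONS
    habitats: tuple[str, ...] = HABITATS
    baseline_mean_temp: float = 19.5
    seasonal_amplitude: float = 10.0
    warming_offset: float = 4.0
    heatwave_amplitude: float = 4.0
    temp_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_tanks != self.replicates_per_treatment * len(TREATMENTS):
            raise ValidationError(
                "n_tanks must equal replicates_per_treatment x number of treatments")

    def tank_treatments(self) -> dict[int, str]:
        out = {}
        for i, tr in enumerate(TREATMENTS):
            for r in range(self.replicates_per_treatment):
                out[i * self.replicates_per_treatment + r + 1] = tr
        return out


# Per-habitat covariate baselines and the direction/size of warming and
# seasonal effects. Values are plausible shallow-lake magnitudes; only the
# monotone structure (warming raises TN, NH4, Chl-a, conductivity; seasonal
# cycles) matters downstream.
_WATER_COVARIATES = {
    # name: (baseline, seasonal_amplitude, per-degree warming effect, noise sd)
    "TN": (1.2, 0.3, 0.05, 0.1),
    "TP": (0.08, 0.02, 0.002, 0.008),
    "NH4_N": (0.30, 0.08, 0.02, 0.03),
    "NO3_N": (0.50, 0.15, -0.01, 0.05),
    "PO4_P": (0.02, 0.005, 0.0, 0.003),
    "pH": (8.2, 0.3, 0.02, 0.08),
    "DO": (8.5, 1.5, -0.15, 0.4),
    "conductivity": (350.0, 40.0, 6.0, 15.0),
    "Chl_a": (25.0, 10.0, 1.5, 3.0),
}
_SEDIMENT_COVARIATES = {
    "TN": (2.1, 0.2, 0.06, 0.15),
    "TP": (0.6, 0.05, 0.01, 0.04),
    "NH4_N": (0.9, 0.15, 0.04, 0.08),
    "NO3_N": (0.35, 0.10, -0.02, 0.04),
    "NO2_N": (0.05, 0.01, 0.002, 0.006),
    "IP": (0.45, 0.05, 0.01, 0.03),
}


@dataclass
class MesocosmFixture:
    table: OtuTable
    frame: SampleFrame
    tree: TreeNode
    truth: pd.DataFrame  # sample_a, sample_b, regime
    traits: pd.Series = field(repr=False, default=None)


def _season_phase(season: str) -> float:
    return 2.0 * np.pi * SEASONS.index(season) / len(SEASONS)


def build_mesocosm_fixture(
    design: MesocosmDesign | None = None,
    regimes: dict[str, RegimeSpec] | None = None,
    seed: int = 0,
    n_otus: int = 1000,
    library_size: int = 10000,
) -> MesocosmFixture:
    """Assemble the full mesocosm dataset: table + metadata + tree + truth.

    One metacommunity phylogeny is shared by both habitats; the water-column
    community assembles under temperature-driven selection (so warming
    detectably shifts composition) and the sediment community under drift,
    unless ``regimes`` overrides either. Ground-truth regime labels are
    returned for every within-habitat sample pair.
    """
    design = design or MesocosmDesign()
    rng = np.random.default_rng(seed)
    tank_treatment = design.tank_treatments()

    rows = []
    for habitat in design.habitats:
        for tank in range(1, design.n_tanks + 1):
            for season in design.seasons:
                treatment = tank_treatment[tank]
                phase = _season_phase(season)
                temp = design.baseline_mean_temp + design.seasonal_amplitude * np.sin(phase)
                if treatment in ("T", "H"):
                    temp += design.warming_offset
                if treatment == "H":
                    # alternate the heatwave excursion across seasons: zero
                    # annual mean, strictly larger variance than T
                    temp += design.heatwave_amplitude * (1 if SEASONS.index(season) % 2 == 0 else -1)
                temp += rng.normal(0.0, design.temp_noise_sd)
                row = {
                    "sample_id": f"{habitat}_tank{tank:02d}_{season}",
                    "habitat": habitat,
                    "treatment": treatment,
                    "season": season,
                    "tank": tank,
                    "temperature": temp,
                }
                covs = _WATER_COVARIATES if habitat == "water" else _SEDIMENT_COVARIATES
                warming_deg = temp - (design.baseline_mean_temp
                                      + design.seasonal_amplitude * np.sin(phase))
                for name, (base, amp, slope, noise) in covs.items():
                    val = base + amp * np.sin(phase + 0.5) + slope * warming_deg
                    val += rng.normal(0.0, noise)
                    row[name] = max(val, 0.0) if name != "pH" else val
                rows.append(row)
    meta = pd.DataFrame(rows)
    frame = SampleFrame(meta)

    tree = simulate_tree(n_otus, seed=seed + 11)
    traits = simulate_traits(tree, rate=1.0, seed=seed + 13)
    base = metacommunity_abundances(n_otus, np.random.default_rng(seed + 17))

    tables = []
    truth_rows = []
    for hi, habitat in enumerate(design.habitats):
        ids = meta.loc[meta.habitat == habitat, "sample_id"].tolist()
        n = len(ids)
        if regimes and habitat in regimes:
            spec = regimes[habitat]
            spec.n_samples, spec.n_otus, spec.library_size = n, n_otus, library_size
        elif habitat == "water":
            spec = RegimeSpec("selection", n_samples=n, n_otus=n_otus,
                              library_size=library_size,
                              sigma=0.3 * float(traits.std()), seed=seed + 19 + hi)
        else:
            spec = RegimeSpec("drift", n_samples=n, n_otus=n_otus,
                              library_size=library_size, seed=seed + 19 + hi)
        optima = None
        if spec.regime == "selection":
            temp = meta.set_index("sample_id").loc[ids, "temperature"].to_numpy()
            z = (temp - temp.mean()) / temp.std()
            optima = float(traits.mean()) + z * float(traits.std())
        tables.append(simulate_regime(spec, tree=tree, env_optima=optima,
                                      traits=traits, sample_ids=ids))
        for a in range(n):
            for b in range(a + 1, n):
                truth_rows.append({"sample_a": ids[a], "sample_b": ids[b],
                                   "regime": spec.regime})

    table = OtuTable(pd.concat([t.counts for t in tables], axis=0))
    truth = pd.DataFrame(truth_rows, columns=["sample_a", "sample_b", "regime"])
    return MesocosmFixture(table=table, frame=frame, tree=tree, truth=truth, traits=traits)


def write_fixture(fixture: MesocosmFixture, outdir) -> dict[str, str]:
    """Write table/metadata/tree/truth in the formats the readers accept."""
    import pathlib

    from . import io as eio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": str(outdir / "otu_table.tsv"),
        "metadata": str(outdir / "metadata.csv"),
        "tree": str(outdir / "tree.nwk"),
        "truth": str(outdir / "truth.csv"),
    }
    eio.write_otu_table(fixture.table, paths["table"])
    eio.write_metadata(fixture.frame, paths["metadata"])
    eio.write_tree(fixture.tree, paths["tree"])
    fixture.truth.to_csv(paths["truth"], index=False)
    return paths
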