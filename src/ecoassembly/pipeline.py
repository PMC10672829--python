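"""End-to-end orchestration: from an OTU table + tree + metadata (or a
synthetic fixture) to the full set of report tables.

The pipeline runs, per habitat: rarefaction to the minimum library, alpha
diversity, Bray-Curtis + PERMANOVA, co-occurrence networks per sample group,
per-sample NTI, betaNTI + RCbray with five-process partitioning, and Mantel
tests of betaNTI against environmental covariates. Every stochastic stage
derives its own seed from the master seed and the stage name, and a manifest
records enough to reproduce every output bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assembly as asm
from . import diversity as dv
from . import io as eio
from . import network as net
from . import phylo as ph
from . import stats as st
from . import synthetic as syn
from .containers import OtuTable, ValidationError


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def derive_seed(master: int, tag: str) -> int:
    """Stable per-stage seed: mixes the master seed with the stage name."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a run needs; serialised verbatim into the manifest."""

    outdir: str
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    fixture: dict | None = None  # kwargs for build_mesocosm_fixture
    rarefaction: str | int | None = "min"  # per-habitat minimum, fixed int, or off
    network_grouping: tuple[str, ...] = ("habitat", "treatment")
    assembly_grouping: tuple[str, ...] = ("habitat", "treatment", "season")
    r_threshold: float = 0.6
    alpha: float = 0.05
    n_null_bnti: int = 999
    n_null_rc: int = 999
    n_perm: int = 999
    weighted_bnti: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("network_grouping", "assembly_grouping"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["network_grouping"] = list(self.network_grouping)
        d["assembly_grouping"] = list(self.assembly_grouping)
        return d


@dataclass
class PipelineResult:
    outdir: pathlib.Path
    alpha_diversity: pd.DataFrame
    permanova: pd.DataFrame
    topology: pd.DataFrame
    nti: pd.DataFrame
    partition: dict[str, asm.ProcessPartition]
    mantel: pd.DataFrame
    manifest: dict = field(repr=False, default=None)


def _load_inputs(config: PipelineConfig):
    if config.fixture is not None:
        kwargs = dict(config.fixture)
        if isinstance(kwargs.get("design"), dict):  # YAML configs carry plain dicts
            kwargs["design"] = syn.MesocosmDesign(**kwargs["design"])
        fx = syn.build_mesocosm_fixture(seed=derive_seed(config.seed, "fixture"),
                                        **kwargs)
        return fx.table, fx.frame, fx.tree
    if not (config.table_path and config.tree_path and config.metadata_path):
        raise ValidationError("provide table/tree/metadata paths or a fixture spec")
    table = eio.read_otu_table(config.table_path)
    frame = eio.read_metadata(config.metadata_path)
    tree = eio.read_tree(config.tree_path)
    return table, frame, tree


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict = {"config": config.to_dict(), "stages": {}, "status": "running"}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def finish(status: str) -> None:
        manifest["status"] = status
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                log(f"stage {name}: start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    log(f"stage {name}: FAILED ({exc})")
                    finish(f"failed at {name}")
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log(f"stage {name}: done")

        return _Stage()

    with stage("load"):
        table, frame, tree = _load_inputs(config)
        eio.validate_consistency(table, frame, tree, require_tree_cover=True)
        habitats = [h for h in ("water", "sediment")
                    if (frame.data.loc[table.sample_ids, "habitat"] == h).any()]
        log(f"loaded {table.shape[0]} samples x {table.shape[1]} OTUs; habitats: {habitats}")

    per_habitat: dict[str, OtuTable] = {}
    with stage("rarefaction"):
        for hab in habitats:
            ids = [s for s in table.sample_ids if frame.data.loc[s, "habitat"] == hab]
            sub = table.select_samples(ids)
            if config.rarefaction is None or config.rarefaction == "off":
                per_habitat[hab] = sub
                continue
            depth = (int(sub.sample_sums().min()) if config.rarefaction == "min"
                     else int(config.rarefaction))
            seed = derive_seed(config.seed, f"rarefy:{hab}")
            manifest["stages"][f"rarefy:{hab}"] = {"depth": depth, "seed": seed}
            log(f"rarefying {hab} to depth {depth} (seed {seed})")
            per_habitat[hab] = dv.rarefy(sub, depth, seed=seed)

    with stage("alpha_diversity"):
        alpha = pd.concat(
            [dv.alpha_diversity_table(per_habitat[h]) for h in habitats],
            ignore_index=True,
        )
        alpha.insert(1, "habitat", frame.data.loc[alpha.sample_id, "habitat"].to_numpy())
        eio.write_report_table(alpha, outdir / "alpha_diversity.tsv")

    with stage("bray_curtis_permanova"):
        permanova_rows = []
        for hab in habitats:
            dm = dv.bray_curtis(per_habitat[hab])
            eio.write_distance_matrix(list(dm.ids), dm.data, outdir / f"bray_curtis_{hab}.tsv")
            for factor in ("treatment", "season"):
                groups = frame.data.loc[list(dm.ids), factor]
                seed = derive_seed(config.seed, f"permanova:{hab}:{factor}")
                res = st.permanova(dm, groups, n_perm=config.n_perm, seed=seed)
                permanova_rows.append(
                    {"habitat": hab, "factor": factor, "pseudo_F": res.statistic,
                     "R2": res.extra["R2"], "p_value": res.p_value,
                     "n_permutations": res.n_permutations}
                )
                manifest["stages"][f"permanova:{hab}:{factor}"] = {"seed": seed}
        permanova_table = pd.DataFrame(permanova_rows)
        eio.write_report_table(permanova_table, outdir / "permanova.tsv")

    with stage("networks"):
        topo_rows = []
        group_keys = frame.group_key(config.network_grouping)
        for group in sorted(group_keys.unique()):
            ids = [s for s in table.sample_ids if group_keys.loc[s] == group]
            hab = frame.data.loc[ids[0], "habitat"]
            sub = per_habitat[hab].select_samples(
                [s for s in ids if s in per_habitat[hab].sample_ids]).drop_zero_otus()
            if sub.shape[0] < 5:
                log(f"network group {group}: fewer than 5 samples, skipped")
                continue
            filtered = net.filter_otus(sub)
            cand = net.correlation_edges(filtered, r_threshold=config.r_threshold,
                                         alpha=config.alpha)
            graph = net.build_network(cand, table=filtered)
            summary = net.topology(graph, modularity_seed=derive_seed(config.seed, f"mod:{group}"))
            row = summary.to_frame()
            row.insert(0, "group", group)
            topo_rows.append(row)
            safe = group.replace(":", "_")
            eio.write_edge_list(graph, outdir / f"network_{safe}_nodes.csv",
                                outdir / f"network_{safe}_edges.csv")
            eio.write_graphml(graph, outdir / f"network_{safe}.graphml")
            log(f"network {group}: {summary.nodes} nodes, {summary.edges} edges "
                f"({cand.n_tested} pairs tested, {cand.n_constant_excluded} constant OTUs)")
        topology_table = (pd.concat(topo_rows, ignore_index=True)
                          if topo_rows else pd.DataFrame())
        eio.write_report_table(topology_table, outdir / "network_topology.tsv")

    with stage("nti"):
        nti_frames = []
        for hab in habitats:
            sub = per_habitat[hab].drop_zero_otus()
            D = eio.patristic_distances(tree, sub.otu_ids)
            seed = derive_seed(config.seed, f"nti:{hab}")
            manifest["stages"][f"nti:{hab}"] = {"seed": seed, "n_null": config.n_null_bnti}
            t = ph.nti_table(sub, D=D, n_null=config.n_null_bnti, seed=seed)
            t.insert(1, "habitat", hab)
            nti_frames.append(t)
        nti = pd.concat(nti_frames, ignore_index=True)
        eio.write_report_table(nti, outdir / "nti_per_sample.tsv")
        summary = nti.merge(frame.data[["treatment"]], left_on="sample_id", right_index=True)
        nti_summary = (summary.groupby(["habitat", "treatment"])["nti"]
                       .agg(["mean", "std", "min", "max", "count"]).reset_index())
        eio.write_report_table(nti_summary, outdir / "nti_group_summary.tsv")

    partition: dict[str, asm.ProcessPartition] = {}
    with stage("assembly"):
        prop_frames, stoch_frames = [], []
        for hab in habitats:
            sub = per_habitat[hab].drop_zero_otus()
            D = eio.patristic_distances(tree, sub.otu_ids)
            bseed = derive_seed(config.seed, f"bnti:{hab}")
            rseed = derive_seed(config.seed, f"rcbray:{hab}")
            manifest["stages"][f"bnti:{hab}"] = {"seed": bseed, "n_null": config.n_null_bnti}
            manifest["stages"][f"rcbray:{hab}"] = {"seed": rseed, "n_null": config.n_null_rc}
            bnti = ph.beta_nti(sub, D=D, weighted=config.weighted_bnti,
                               n_null=config.n_null_bnti, seed=bseed)
            rc = asm.raup_crick_bray(sub, n_null=config.n_null_rc, seed=rseed)
            eio.write_distance_matrix(bnti.labels, bnti.bnti, outdir / f"bnti_{hab}.tsv")
            eio.write_distance_matrix(rc.labels, rc.rc, outdir / f"rcbray_{hab}.tsv")
            part = asm.partition_processes(bnti, rc, frame, grouping=config.assembly_grouping)
            partition[hab] = part
            prop_frames.append(part.proportions)
            stoch_frames.append(part.stochastic)
            eio.write_report_table(part.pairs, outdir / f"assembly_pairs_{hab}.tsv")
        eio.write_report_table(pd.concat(prop_frames, ignore_index=True),
                               outdir / "process_proportions.tsv")
        eio.write_report_table(pd.concat(stoch_frames, ignore_index=True),
                               outdir / "stochastic_fraction.tsv")

    with stage("mantel"):
        mantel_rows = []
        for hab in habitats:
            labels, values = eio.read_distance_matrix(outdir / f"bnti_{hab}.tsv")
            t = st.mantel_env_table(values, labels, frame,
                                    n_perm=config.n_perm,
                                    seed=derive_seed(config.seed, f"mantel:{hab}"))
            t.insert(0, "habitat", hab)
            mantel_rows.append(t)
        mantel_table = pd.concat(mantel_rows, ignore_index=True)
        eio.write_report_table(mantel_table, outdir / "mantel_bnti_env.tsv")

    finish("ok")
    return PipelineResult(
        outdir=outdir,
        alpha_diversity=alpha,
        permanova=permanova_table,
        topology=topology_table,
        nti=nti,
        partition=partition,
        mantel=mantel_table,
        manifest=manifest,
    )
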