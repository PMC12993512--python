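"""End-to-end orchestration: simulate/ingest -> filter -> infer -> analyze ->
ordinate -> report, stratified the way the study design is (floodplain x
stream type x deglaciation class), with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .datatypes import AbundanceTable, SampleMetadata, metadata_frame, stack_tables
from .graph import (
    centrality,
    fragmentation,
    louvain_communities,
    removal_trajectory,
    select_keystones,
    topology,
)
from .inference import EnsembleConfig, infer_network
from .ordination import family_enrichment, keystone_vs_environment
from .preprocess import aggregate_family, prevalence_filter, relative_abundance, singleton_filter
from .simulate import SimulationConfig, simulate


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    table16_path: str | None = None
    table18_path: str | None = None
    taxonomy16_path: str | None = None
    taxonomy18_path: str | None = None
    metadata_path: str | None = None
    prevalence_threshold: float = 0.05
    prevalence_on_18s: bool = True
    drop_singletons: bool = True
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    min_cluster_size: int = 5
    k_keystones: int = 10
    recompute_keystones: bool = False
    original_denominator: bool = False
    alpha: float = 0.01
    n_permutations: int = 999
    min_stratum_samples: int = 10
    seed: int = 0
    outdir: str = "coocnet_out"


def _config_hash(config: PipelineConfig) -> str:
    def encode(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: encode(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    fields = encode(config)
    fields.pop("outdir", None)  # analytical identity only, not output location
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage_seed(root: int, label: str) -> int:
    return (root * 1_000_003 + zlib.crc32(label.encode())) % (2**31)


def _load_inputs(
    config: PipelineConfig,
) -> tuple[AbundanceTable, AbundanceTable, list[SampleMetadata]]:
    if config.simulation is not None:
        sim = simulate(config.simulation)
        return sim.table16, sim.table18, sim.metadata
    t16 = cio.read_abundance_table(
        config.table16_path, "16S", config.taxonomy16_path
    )
    t18 = cio.read_abundance_table(
        config.table18_path, "18S", config.taxonomy18_path
    )
    meta = cio.read_metadata(config.metadata_path)
    return t16, t18, meta


def _analyze_stratum(
    t16: AbundanceTable,
    t18: AbundanceTable,
    config: PipelineConfig,
    seed: int,
    outdir: Path,
    label: str,
) -> dict:
    if config.drop_singletons:
        t16 = singleton_filter(t16)
        t18 = singleton_filter(t18)
    t16, rep16 = prevalence_filter(t16, config.prevalence_threshold)
    if config.prevalence_on_18s:
        t18, rep18 = prevalence_filter(t18, config.prevalence_threshold)
        rep18 = rep18.to_dict()
    else:
        rep18 = None

    stacked = stack_tables(t16, t18)
    ens = EnsembleConfig(**{
        **{k: getattr(config.ensemble, k) for k in
           ("sparcc", "spearman", "mb", "consensus")},
        "seed": seed,
    })
    net = infer_network(stacked, ens)

    part = louvain_communities(
        net, min_size=config.min_cluster_size, seed=seed
    )
    for v, c in part.assignment.items():
        net.graph.nodes[v]["community"] = c
    topo = topology(net, part)
    cent = centrality(net)

    rel16 = relative_abundance(t16).mean(axis=1)
    rel18 = relative_abundance(t18).mean(axis=1)
    rel = {t: float(v) for t, v in zip(t16.taxon_ids, rel16)}
    rel.update({t: float(v) for t, v in zip(t18.taxon_ids, rel18)})

    keystones = select_keystones(cent, k=config.k_keystones, relative_abundance=rel)
    baseline_f = fragmentation(net) if net.n_nodes else float("nan")
    traj = removal_trajectory(
        net, keystones,
        recompute=config.recompute_keystones,
        original_denominator=config.original_denominator,
        min_cluster_size=config.min_cluster_size,
        seed=seed,
    ) if net.n_nodes > len(keystones.keystones) else None

    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_network(net, outdir / f"{label}.graphml", "graphml")
    cio.write_network(net, outdir / f"{label}_edges.tsv", "edge_tsv")
    pd.DataFrame({
        "node": keystones.keystones,
        "domain": [net.graph.nodes[v].get("domain_label", "unknown")
                   for v in keystones.keystones],
        "degree": [keystones.degree[v] for v in keystones.keystones],
        "betweenness": [keystones.betweenness[v] for v in keystones.keystones],
        "rank_sum": [keystones.score[v] for v in keystones.keystones],
        "relative_abundance": [keystones.relative_abundance[v]
                               for v in keystones.keystones],
    }).to_csv(outdir / f"{label}_keystones.tsv", sep="\t", index=False)
    if traj is not None:
        pd.DataFrame([s.__dict__ for s in traj.steps]).to_csv(
            outdir / f"{label}_trajectory.tsv", sep="\t", index=False
        )

    result = {
        "label": label,
        "seed": seed,
        "filter_report_16S": rep16.to_dict(),
        "filter_report_18S": rep18,
        "topology": topo.to_dict(),
        "keystones": keystones.keystones,
        "baseline_f": baseline_f,
        "f_mean": traj.f_mean if traj else None,
        "isolated_nodes": len(getattr(net, "isolated_nodes", [])),
    }
    (outdir / f"{label}_topology.json").write_text(
        json.dumps(result, indent=2, default=float)
    )
    result["_network"] = net
    result["_keystones"] = keystones
    result["_tables"] = (t16, t18)
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage per stratum and write the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t16_all, t18_all, meta = _load_inputs(config)
    t16_all, t18_all = cio.pair_samples(t16_all, t18_all, meta)

    mframe = metadata_frame(meta)
    for col in ("floodplain", "stream_type", "deglaciation"):
        if col not in mframe.columns:
            raise ValueError(f"metadata is missing the {col} column")
    mframe = mframe.loc[t16_all.sample_ids]

    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_paired_samples": t16_all.n_samples,
        "strata": [],
        "skipped_strata": [],
        "ordination": {},
    }

    strata = sorted(
        mframe.groupby(["floodplain", "stream_type", "deglaciation"]).groups.items()
    )
    results = []
    for key, sample_index in strata:
        label = "_".join(key)
        samples = [s for s in t16_all.sample_ids if s in set(sample_index)]
        if len(samples) < config.min_stratum_samples:
            manifest["skipped_strata"].append(
                {"label": label, "n_samples": len(samples),
                 "reason": "below sample floor"}
            )
            continue
        res = _analyze_stratum(
            t16_all.select_samples(samples),
            t18_all.select_samples(samples),
            config,
            _stage_seed(config.seed, label),
            outdir / "networks",
            label,
        )
        res["n_samples"] = len(samples)
        results.append(res)
        manifest["strata"].append(
            {k: v for k, v in res.items() if not k.startswith("_")}
        )

    # floodplain-level ordination: bacterial community vs keystones/environment
    for fp in sorted(mframe["floodplain"].unique()):
        fp_results = [r for r in results if r["label"].startswith(fp + "_")]
        if not fp_results:
            continue
        samples = [
            s for s in t16_all.sample_ids if mframe.loc[s, "floodplain"] == fp
        ]
        t16 = t16_all.select_samples(samples)
        t18 = t18_all.select_samples(samples)
        if config.drop_singletons:
            t16, t18 = singleton_filter(t16), singleton_filter(t18)
        t16, _ = prevalence_filter(t16, config.prevalence_threshold)
        if config.prevalence_on_18s:
            t18, _ = prevalence_filter(t18, config.prevalence_threshold)
        k16, k18 = set(), set()
        for r in fp_results:
            for v in r["_keystones"].keystones:
                dom = r["_network"].graph.nodes[v].get("domain_label")
                (k16 if dom == "bacteria" else k18).add(v)
        k16 = sorted(k16 & set(t16.taxon_ids))
        k18 = sorted(k18 & set(t18.taxon_ids))
        if not k16 or not k18:
            manifest["ordination"][fp] = {"skipped": "no keystones in tables"}
            continue
        fp_meta = [m for m in meta if m.sample_id in set(samples)]
        report = keystone_vs_environment(
            t16, k16, k18, t16, t18, fp_meta,
            alpha=config.alpha, n_perm=config.n_permutations,
            seed=_stage_seed(config.seed, f"ord_{fp}"),
        )
        manifest["ordination"][fp] = {
            k: v.to_dict() for k, v in report.items()
        }

        # family-level enrichment over network nodes
        node_ids = sorted(
            set().union(*(r["_network"].graph.nodes for r in fp_results))
        )
        fam16 = aggregate_family(t16, [t for t in node_ids if t in set(t16.taxon_ids)]) \
            if set(node_ids) & set(t16.taxon_ids) else None
        if fam16 is not None and fam16.shape[0] > 0:
            enr = family_enrichment(fam16, fp_meta)
            manifest["ordination"][fp]["enrichment"] = [
                {
                    "family": e.family,
                    "adjusted_p": e.adjusted_p,
                }
                for e in enr
            ]

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float)
    )
    manifest["_results"] = results
    return manifest
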