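"""Stage orchestration: simulate -> signatures -> enrich -> neighborhood -> benchmark.

``run_pipeline`` executes the enabled stages in dependency order against
one configuration, writing each stage's outputs under the working
directory and recording a manifest (input hashes, parameters, output
paths) so that a rerun with identical configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import benchmark as bm
from . import enrichment as en
from . import io_formats as io
from . import neighborhoods as nb
from . import signatures as sg
from . import synthetic_data as syn

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_STAGE_ERROR = 3


@dataclass
class PipelineConfig:
    """Paths, stage toggles and numeric parameters for one run."""

    outdir: str = "seclocus_out"
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "signatures", "enrich", "neighborhood", "benchmark",
        ]
    )
    rng_seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    component: str = "SecA"
    signature_domain: str = syn.SECA_DEAD
    discriminator_domain: str = syn.SECA_SW
    fragment_fraction: float = 0.5
    sp_classes: list[str] = field(default_factory=lambda: ["SPI", "SPII"])
    sp_threshold: float = 0.5
    tail_convention: str = "exclusive"
    window: int = 10
    identity_threshold: float = 25.0
    coverage_threshold: float = 0.60
    coverage_rule: str = "both"
    benchmark_thresholds: tuple[int, int] = (0, 905)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    sim_cfg = syn.SimulationConfig(rng_seed=config.rng_seed, **config.simulation)
    bundle = truth = None

    for stage in config.stages:
        try:
            if stage == "simulate":
                bundle, truth = syn.generate_pangenome(sim_cfg)
                paths = bundle.write(outdir / "bundle")
                (outdir / "bundle" / "ground_truth.json").write_text(truth.to_json())
                edges = syn.generate_similarity_table(truth, sim_cfg)
                io.write_similarity_tsv(edges, outdir / "bundle" / "similarity.tsv")
                problems = syn.audit_bundle(outdir / "bundle", truth)
                if problems:
                    raise RuntimeError(f"bundle self-audit failed: {problems}")
                manifest["stages"]["simulate"] = {
                    "n_proteins": len(bundle.proteins),
                    "inputs": {},
                }
                manifest["outputs"]["bundle"] = {
                    name: _hash_file(p) for name, p in paths.items()
                }

            elif stage == "signatures":
                bundle, truth = _require_bundle(outdir, bundle, truth)
                hits = io.read_domain_annotations(
                    outdir / "bundle" / "domains.tsv", mode="evalue_le_1"
                )
                archs = sg.architectures_from_hits(hits)
                references = [
                    archs[pid] for pid in truth.canonical_ids if pid in archs
                ]
                signature = sg.infer_signature(config.component, references[:6])
                genome_of = {pid: pid.split("|", 1)[0] for pid in archs}
                genomes = sorted({g for g in genome_of.values()})
                homologs = sg.find_homologs(signature, hits, genome_of, genomes)
                calls = sg.classify_copies(
                    config.component, homologs, hits,
                    config.discriminator_domain,
                    config.fragment_fraction,
                    model_length=syn.SECA_SW_LEN,
                )
                sig_path = outdir / "signatures.json"
                sig_path.write_text(json.dumps({
                    "component": signature.component_name,
                    "required_domains": sorted(signature.required_domains),
                }, indent=1))
                paralog_path = outdir / "paralogs.tsv"
                with open(paralog_path, "w") as fh:
                    fh.write("genome_id\tcomponent\tcopy_count\tprotein_id\tclass\n")
                    for call in calls:
                        for pid, cls in call.copies:
                            fh.write(
                                f"{call.genome_id}\t{call.component_name}\t"
                                f"{call.copy_count}\t{pid}\t{cls}\n"
                            )
                manifest["stages"]["signatures"] = {
                    "signature": sorted(signature.required_domains),
                    "n_multi_copy_genomes": sum(1 for c in calls if c.copy_count >= 2),
                }
                manifest["outputs"]["signatures"] = _hash_file(sig_path)
                manifest["outputs"]["paralogs"] = _hash_file(paralog_path)

            elif stage == "enrich":
                bundle, truth = _require_bundle(outdir, bundle, truth)
                table = io.read_family_table(outdir / "bundle" / "families.tsv")
                calls = io.read_sp_calls(outdir / "bundle" / "sp_calls.tsv")
                families = en.build_families(
                    table, calls, frozenset(config.sp_classes), config.sp_threshold
                )
                result = en.enrich(families, primary_convention=config.tail_convention)
                payload = {
                    "counts": dataclasses.asdict(result.counts),
                    "p_exclusive": result.format_p(result.p_exclusive),
                    "p_inclusive": result.format_p(result.p_inclusive),
                    "primary_convention": result.primary_convention,
                }
                path = outdir / "enrichment.json"
                path.write_text(json.dumps(payload, indent=1))
                manifest["stages"]["enrich"] = payload
                manifest["outputs"]["enrichment"] = _hash_file(path)

            elif stage == "neighborhood":
                bundle, truth = _require_bundle(outdir, bundle, truth)
                gene_order = io.read_gene_order(outdir / "bundle" / "genes.gff")
                edges = io.read_similarity_tsv(outdir / "bundle" / "similarity.tsv")
                windows = nb.extract_windows(
                    gene_order, truth.secondary_ids, config.window
                )
                members = sorted(set().union(*(w.member_ids for w in windows)))
                params = nb.ClusteringParams(
                    config.identity_threshold, config.coverage_threshold,
                    config.coverage_rule,
                )
                edges = [e for e in edges
                         if e.protein_a in set(members) and e.protein_b in set(members)]
                clusters = nb.single_linkage(members, edges, params)
                genome_of = {pid: pid.split("|", 1)[0] for pid in members}
                report = nb.conservation_report(clusters, windows, genome_of)
                hist = nb.cluster_size_histogram(clusters)
                report.to_csv(outdir / "conservation_report.tsv", sep="\t", index=False)
                hist.to_csv(outdir / "size_histogram.tsv", sep="\t", index=False)
                with open(outdir / "clusters.tsv", "w") as fh:
                    fh.write("cluster_id\tprotein_id\n")
                    for cluster in clusters:
                        for pid in cluster.members:
                            fh.write(f"{cluster.cluster_id}\t{pid}\n")
                manifest["stages"]["neighborhood"] = {
                    "n_windows": len(windows),
                    "n_clusters": len(clusters),
                    "top_clusters": report.head(3)["cluster_id"].tolist(),
                }
                manifest["outputs"]["conservation_report"] = _hash_file(
                    outdir / "conservation_report.tsv"
                )

            elif stage == "benchmark":
                complexes, pathways, scores = syn.generate_benchmark_tables(
                    seed=config.rng_seed
                )
                proteins = sorted({p for ms in complexes.values() for p in ms}
                                  | {p for ms in pathways.values() for p in ms}
                                  | {p for pair in scores for p in pair})
                truth_sets = bm.build_truth_sets(complexes, pathways, proteins)
                pair_scores = bm.pair_scores(scores, truth_sets.universe)
                tmin, tmax = config.benchmark_thresholds
                thresholds = np.arange(tmin, tmax + 1)
                summary = {}
                for name, pairs in [
                    ("complexes", truth_sets.pairs_complexes),
                    ("pathways", truth_sets.pairs_pathways),
                    ("both", truth_sets.pairs_both),
                ]:
                    if not pairs:
                        continue
                    confusion, points = bm.roc_sweep(pair_scores, pairs, thresholds)
                    out = outdir / f"roc_{name}.tsv"
                    with open(out, "w") as fh:
                        fh.write("threshold\tTP\tFP\tTN\tFN\tsensitivity\tone_minus_specificity\n")
                        for c, p in zip(confusion, points):
                            fh.write(
                                f"{c.threshold:g}\t{c.TP}\t{c.FP}\t{c.TN}\t{c.FN}\t"
                                f"{p.sensitivity:.6f}\t{p.one_minus_specificity:.6f}\n"
                            )
                    summary[name] = {"auc": round(bm.roc_auc(points), 4),
                                     "n_truth": len(pairs)}
                manifest["stages"]["benchmark"] = summary

            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - stage failures become exit codes
            raise PipelineStageError(stage, str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require_bundle(outdir: Path, bundle, truth):
    """Load a previously simulated bundle from disk if not in memory."""
    if truth is not None:
        return bundle, truth
    truth_path = outdir / "bundle" / "ground_truth.json"
    if not truth_path.exists():
        raise FileNotFoundError(
            "no simulated bundle found; run the simulate stage first"
        )
    truth = syn.GroundTruth.from_json(truth_path.read_text())
    return None, truth
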