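"""End-to-end orchestration: simulate/load -> QC -> GWAS -> AWM -> PCIT ->
regulator trios, with a run manifest of artifact checksums and counts.

All randomness flows from one root seed, expanded into independent
per-stage streams, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as awmio
from .awm import annotate_snps, build_awm, select_snps, trait_relationships
from .containers import TraitSpec
from .gwas import build_grm, run_gwas, subset_h2_validation
from .network import build_network, gene_correlations, topology_stats, write_graphml
from .pcit import pcit
from .qc import qc_filter
from .regulators import rank_trios, select_key_regulators, target_sets, trio_table
from .simulate import SimConfig, simulate_study

log = logging.getLogger("awmnet")

STAGES = ["inputs", "qc", "gwas", "awm", "pcit", "trios", "validate_h2"]


@dataclass
class RunConfig:
    """Single structured configuration for a pipeline run.

    Exactly one of ``inputs`` (paths to ped/map or raw + phenotype TSV +
    GFF3/BED + census) or ``simulate`` (SimConfig fields) must be given.
    """

    out_dir: str = "awmnet_run"
    seed: int = 0
    key_trait: str = "gdT"
    alpha: float = 0.05
    min_traits: int = 3
    window: int = 5000
    per_gene_rule: str = "most_pleiotropic"
    maf_min: float = 0.05
    miss_max: float = 0.10
    pcit_max_nodes: int = 5000
    top_k_trios: int = 10
    n_key_regulators: int = 5
    validation_n_iter: int = 100
    validation_traits: list[str] | None = None
    run_validation: bool = False
    log_transform_traits: list[str] = field(default_factory=list)
    lab_batch_traits: list[str] | None = None
    simulate: dict | None = None
    inputs: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: RunConfig) -> list[str]:
    """Collect every violation at once; an empty list means valid."""
    v: list[str] = []
    if (config.simulate is None) == (config.inputs is None):
        v.append("exactly one of 'simulate' or 'inputs' must be set")
    if not (0 < config.alpha < 1):
        v.append(f"alpha={config.alpha} outside (0, 1)")
    if config.min_traits < 1:
        v.append(f"min_traits={config.min_traits} must be >= 1")
    if config.window < 0:
        v.append(f"window={config.window} must be >= 0")
    if not (0 <= config.maf_min < 0.5):
        v.append(f"maf_min={config.maf_min} outside [0, 0.5)")
    if not (0 <= config.miss_max <= 1):
        v.append(f"miss_max={config.miss_max} outside [0, 1]")
    if config.validation_n_iter < 1:
        v.append("validation_n_iter must be >= 1")
    if config.inputs is not None:
        for key in ("phenotypes", "census"):
            if key not in config.inputs:
                v.append(f"inputs missing '{key}'")
        has_geno = ("raw" in config.inputs) or (
            "ped" in config.inputs and "map" in config.inputs
        )
        if not has_geno:
            v.append("inputs need either 'raw' or 'ped'+'map'")
        if "gff3" not in config.inputs and "bed" not in config.inputs:
            v.append("inputs need 'gff3' or 'bed' annotation")
        for key, p in config.inputs.items():
            if not Path(p).exists():
                v.append(f"input file missing: {key}={p}")
    if config.simulate is not None:
        try:
            SimConfig(**{**config.simulate, "seed": config.seed})
        except (TypeError, ValueError) as exc:
            v.append(f"invalid simulate block: {exc}")
    return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, force: bool = False, stop_after: str | None = None) -> dict:
    """Execute the pipeline and return the manifest dict.

    Every stage writes its artifacts under ``out_dir``; the manifest records
    per-stage counts and artifact checksums and is written even when a stage
    fails (with the failing stage named), so a run is resumable by
    inspection.  ``stop_after`` truncates the run after the named stage.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
        "counts": {},
        "status": "running",
    }
    manifest_path = out / "manifest.json"

    def record(path: Path) -> None:
        manifest["artifacts"][path.name] = _sha256(path)

    def done(stage: str) -> bool:
        manifest["stages"][stage] = "ok"
        log.info("stage %s complete", stage)
        return stop_after == stage

    try:
        # ------------------------------------------------------ inputs
        t0 = time.time()
        if config.simulate is not None:
            sim_cfg = SimConfig(**{**config.simulate, "seed": config.seed})
            geno, traits, annotation, census, truth = simulate_study(sim_cfg)
            truth_path = out / "truth.json"
            truth_path.write_text(json.dumps(truth.to_json_dict(), indent=1))
            record(truth_path)
        else:
            inp = config.inputs
            if "raw" in inp:
                snp_meta = None
                if "map" in inp:
                    mp = pd.read_csv(
                        inp["map"], sep=r"\s+", header=None,
                        names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str},
                    )
                    snp_meta = pd.DataFrame(
                        {
                            "snp": mp["snp"],
                            "chrom": mp["chrom"],
                            "pos": mp["pos"].astype(np.int64),
                            "allele_counted": "?",
                            "allele_other": "?",
                        }
                    )
                geno = awmio.read_plink_raw(inp["raw"], snp_meta=snp_meta)
            else:
                geno = awmio.read_plink_ped_map(inp["ped"], inp["map"])
            specs = {}
            for t in config.log_transform_traits:
                specs.setdefault(t, TraitSpec()).log_transform = True
            if config.lab_batch_traits:
                for t in config.lab_batch_traits:
                    specs.setdefault(t, TraitSpec()).batch_factor = "lab_batch"
            traits = awmio.read_phenotypes(inp["phenotypes"], trait_specs=specs)
            annotation = (
                awmio.read_gff3(inp["gff3"]) if "gff3" in inp else awmio.read_bed(inp["bed"])
            )
            census = awmio.read_census(inp["census"])
            annotation = annotation.flag_regulators(census)
        if config.key_trait not in traits.trait_names:
            raise ValueError(
                f"key trait {config.key_trait!r} not among traits "
                f"{traits.trait_names[:8]}..."
            )
        manifest["counts"]["n_individuals"] = len(traits.sample_ids)
        manifest["counts"]["n_snps_input"] = geno.n_snps
        manifest["counts"]["n_traits"] = len(traits.trait_names)
        manifest["counts"]["n_genes_annotation"] = len(annotation)
        log.info(
            "inputs: %d individuals, %d SNPs, %d traits, %d genes (%.1fs)",
            len(traits.sample_ids), geno.n_snps, len(traits.trait_names),
            len(annotation), time.time() - t0,
        )
        if done("inputs"):
            raise StopIteration

        # ---------------------------------------------------------- qc
        geno_qc, qc_report = qc_filter(geno, config.maf_min, config.miss_max)
        (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=1))
        record(out / "qc_report.json")
        manifest["counts"]["n_snps_qc"] = geno_qc.n_snps
        log.info("qc: retained %d / %d SNPs", geno_qc.n_snps, geno.n_snps)
        if done("qc"):
            raise StopIteration

        # -------------------------------------------------------- gwas
        t0 = time.time()
        grm = build_grm(geno_qc)
        assoc, vcs = run_gwas(geno_qc, traits, grm=grm)
        h2 = pd.DataFrame(
            {
                "trait": list(vcs),
                "h2": [vcs[t].h2 for t in vcs],
                "se": [vcs[t].h2_se for t in vcs],
            }
        )
        h2.to_csv(out / "h2_whole_panel.tsv", sep="\t", index=False, float_format="%.4f")
        record(out / "h2_whole_panel.tsv")
        gwas_dir = out / "gwas"
        gwas_dir.mkdir(exist_ok=True)
        for t in traits.trait_names:
            df = pd.DataFrame(
                {
                    "snp": assoc.snp_ids,
                    "chrom": geno_qc.snp_meta["chrom"].to_numpy(),
                    "pos": geno_qc.snp_meta["pos"].to_numpy(),
                    "beta": assoc.beta[t].to_numpy(),
                    "se": assoc.se[t].to_numpy(),
                    "p": assoc.p[t].to_numpy(),
                    "n": assoc.n_used[t],
                }
            )
            df.to_csv(gwas_dir / f"{t}.tsv", sep="\t", index=False, float_format="%.6g")
            record(gwas_dir / f"{t}.tsv")
        log.info("gwas: %d traits x %d SNPs (%.1fs)", len(traits.trait_names),
                 geno_qc.n_snps, time.time() - t0)
        if done("gwas"):
            raise StopIteration

        # --------------------------------------------------------- awm
        selection = select_snps(assoc, config.key_trait, config.alpha, config.min_traits)
        n_key = len(selection.key_trait_snps)
        n_pleio = len(selection.pleiotropic_snps)
        n_merged = len(selection.merged)
        assert n_merged == n_key + n_pleio - len(
            selection.key_trait_snps & selection.pleiotropic_snps
        )
        pairs = annotate_snps(
            geno_qc.snp_meta, annotation, config.window, snp_ids=selection.merged
        )
        awm = build_awm(assoc, pairs, config.key_trait, selection, config.per_gene_rule)
        awm_out = awm.z.copy()
        awm_out.insert(0, "snp", awm.gene_to_snp)
        awm_out.to_csv(out / "awm.tsv", sep="\t", float_format="%.6g")
        record(out / "awm.tsv")
        rel = trait_relationships(awm)
        rel.corr.to_csv(out / "trait_correlations.tsv", sep="\t", float_format="%.6g")
        (out / "trait_dendrogram.nwk").write_text(rel.newick + "\n")
        record(out / "trait_correlations.tsv")
        record(out / "trait_dendrogram.nwk")
        manifest["counts"].update(
            {
                "n_key_trait_snps": n_key,
                "n_pleiotropic_snps": n_pleio,
                "n_merged_snps": n_merged,
                "n_annotated_snps": int(pairs["snp"].nunique()),
                "n_awm_genes": len(awm.genes),
            }
        )
        log.info(
            "awm: %d key-trait SNPs, %d pleiotropic, %d merged, %d annotated -> %d genes",
            n_key, n_pleio, n_merged, pairs["snp"].nunique(), len(awm.genes),
        )
        if done("awm"):
            raise StopIteration

        # -------------------------------------------------------- pcit
        t0 = time.time()
        corr = gene_correlations(awm)
        if len(corr) > config.pcit_max_nodes:
            raise ValueError(
                f"{len(corr)} genes exceeds pcit_max_nodes={config.pcit_max_nodes}; "
                "raise the limit explicitly to proceed"
            )
        mask = pcit(corr)
        net = build_network(mask, corr, census=census)
        net.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False, float_format="%.6g")
        record(out / "edges.tsv")
        write_graphml(out / "network.graphml", net)
        record(out / "network.graphml")
        stats = topology_stats(net)
        (out / "topology.json").write_text(json.dumps(stats.to_dict(), indent=1))
        record(out / "topology.json")
        mask_arr = mask.to_numpy()
        assert stats.n_edges == int(mask_arr.sum()) // 2
        manifest["counts"].update(
            {
                "n_nodes": stats.n_nodes,
                "n_edges": stats.n_edges,
                "n_isolated_nodes": len(net.isolated_nodes()),
                "n_regulators": len(net.regulators()),
            }
        )
        log.info(
            "pcit: %d nodes, %d edges, %d regulators (%.1fs)",
            stats.n_nodes, stats.n_edges, len(net.regulators()), time.time() - t0,
        )
        if done("pcit"):
            raise StopIteration

        # ------------------------------------------------------- trios
        tmap = target_sets(net)
        if len(tmap) >= 3:
            trios = rank_trios(tmap, top_k=config.top_k_trios)
            trio_table(trios).to_csv(out / "trios.tsv", sep="\t", index=False)
            record(out / "trios.tsv")
            top_trio = trios[0].union_targets
        else:
            top_trio = None
            log.warning("fewer than 3 regulators; skipping trio ranking")
        key = select_key_regulators(tmap, k=min(config.n_key_regulators, len(tmap)))
        (out / "key_regulators.json").write_text(
            json.dumps(
                {
                    "members": key.members,
                    "coverage": key.coverage,
                    "marginal_gains": key.marginal_gains,
                },
                indent=1,
            )
        )
        record(out / "key_regulators.json")
        manifest["counts"]["top_trio_unique_targets"] = top_trio
        manifest["counts"]["key_regulator_coverage"] = key.coverage
        log.info("trios: top trio covers %s; %d key regulators cover %d genes",
                 top_trio, len(key.members), key.coverage)
        if done("trios"):
            raise StopIteration

        # ------------------------------------------------- validate h2
        if config.run_validation:
            subset = sorted(set(pairs["snp"]))
            val = subset_h2_validation(
                geno_qc,
                traits,
                subset,
                n_iter=config.validation_n_iter,
                seed=config.seed + 1,
                trait_names=config.validation_traits,
            )
            val.to_csv(out / "h2_validation.tsv", sep="\t", index=False, float_format="%.4f")
            record(out / "h2_validation.tsv")
            log.info("validate_h2: %d traits x %d iterations", len(val), config.validation_n_iter)
        done("validate_h2")
        manifest["status"] = "ok"
    except StopIteration:
        manifest["status"] = f"stopped_after:{stop_after}"
    except Exception as exc:
        failed = next((s for s in STAGES if s not in manifest["stages"]), "unknown")
        manifest["status"] = f"failed:{failed}"
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        raise
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
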