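"""Stage orchestration: scan -> tree -> groups -> clusters/dating ->
introns/events -> expression, driven by a YAML config, emitting plain
TSV/Newick/JSON artifacts plus a run manifest.

The manifest records the config echo, SHA-256 digests of every input and
output file, the package version, the seed, and per-stage row counts; two
runs with identical inputs and seed produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import duplication as dup
from . import expression as expr
from . import gene_structure as gs
from . import motif as motif_mod
from . import phylo
from . import seqio

logger = logging.getLogger(__name__)

ALL_STAGES = ("scan", "tree", "groups", "clusters", "date", "introns", "express")

_ALLOWED_TOP_KEYS = {"schema_version", "seed", "inputs", "stages", "params", "outdir"}
_ALLOWED_PARAMS = {
    "bootstrap_replicates",
    "cluster_window",
    "cluster_min_size",
    "up_threshold",
    "pseudocount",
    "retention_min_tpm",
    "ks_ceiling",
    "lambda_rate",
    "coexpression_threshold",
    "column_tolerance",
    "deletion_mode",
}
_ALLOWED_INPUTS = {
    "proteome",
    "alignment",
    "anchors_fasta",
    "anchors_map",
    "species_map",
    "loci_bed",
    "cds_fasta",
    "pairs",
    "gff3",
    "struct_alignment",
    "counts",
    "conditions",
    "lengths",
    "expression_groups",
}


class ConfigError(ValueError):
    """Raised for an invalid pipeline configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _ALLOWED_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if cfg.get("schema_version") != 1:
        raise ConfigError("schema_version must be 1")
    unknown = set(cfg.get("params", {})) - _ALLOWED_PARAMS
    if unknown:
        raise ConfigError(f"unknown params: {sorted(unknown)}")
    unknown = set(cfg.get("inputs", {})) - _ALLOWED_INPUTS
    if unknown:
        raise ConfigError(f"unknown inputs: {sorted(unknown)}")
    stages = cfg.get("stages", list(ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "seed": self.seed,
                "input_digests": self.input_digests,
                "output_digests": self.output_digests,
                "stage_counts": self.stage_counts,
                "failed_stage": self.failed_stage,
            },
            indent=1,
            sort_keys=True,
        )


def run_pipeline(config: dict | str | Path, outdir=None) -> RunManifest:
    """Execute the configured stages in order; write artifacts and manifest.

    Missing inputs for enabled stages fail before any stage runs.  A stage
    failure is recorded in the manifest (and re-raised) so the failure point
    is preserved.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {k: Path(v) for k, v in config.get("inputs", {}).items()}
    params = dict(config.get("params", {}))
    stages = list(config.get("stages", ALL_STAGES))
    seed = int(config.get("seed", 0))

    required = {
        "scan": ["proteome"],
        "tree": ["alignment"],
        "groups": ["alignment", "anchors_map"],
        "clusters": ["loci_bed"],
        "date": ["cds_fasta", "pairs", "loci_bed"],
        "introns": ["gff3"],
        "express": ["counts", "conditions", "lengths"],
    }
    missing = [
        f"{stage}:{key}"
        for stage in stages
        for key in required[stage]
        if key not in inputs or not inputs[key].exists()
    ]
    if missing:
        raise ConfigError(f"missing inputs for enabled stages: {missing}")

    manifest = RunManifest(config=_plain(config), version=__version__, seed=seed)
    for key in sorted(inputs):
        if inputs[key].exists():
            manifest.input_digests[key] = _sha256(inputs[key])

    tree = None
    clusters = None
    try:
        if "scan" in stages:
            proteins = seqio.read_fasta(inputs["proteome"])
            pattern = motif_mod.parse_pattern(motif_mod.PSPG_PATTERN)
            members, boxes = motif_mod.classify_family(proteins, pattern)
            motif_mod.write_matches_tsv(boxes, outdir / "matches.tsv")
            manifest.stage_counts["scan"] = {
                "proteins": len(proteins),
                "members": len(members),
            }
            logger.info("scan: %d proteins, %d family members", len(proteins), len(members))

        if "tree" in stages or "groups" in stages:
            aln = phylo.read_alignment_fasta(inputs["alignment"])
            replicates = int(params.get("bootstrap_replicates", 100))
            deletion = params.get("deletion_mode", "pairwise")
            tree = phylo.bootstrap_support(aln, replicates, seed, deletion=deletion)
            with open(outdir / "tree.nwk", "w") as fh:
                fh.write(tree.to_newick() + "\n")
            manifest.stage_counts["tree"] = {
                "taxa": len(aln.ids),
                "positions": aln.n_positions,
                "replicates": replicates,
            }
            logger.info("tree: %d taxa, %d bootstrap replicates", len(aln.ids), replicates)

        if "groups" in stages:
            anchor_map = (
                pd.read_csv(inputs["anchors_map"], sep="\t", index_col=0)
                .iloc[:, 0]
                .to_dict()
            )
            calls = phylo.assign_groups(tree, anchor_map)
            phylo.write_groups_tsv(calls, outdir / "groups.tsv")
            manifest.stage_counts["groups"] = {
                "queries": len(calls),
                "assigned": sum(c.group != "unassigned" for c in calls),
            }
            if "species_map" in inputs and inputs["species_map"].exists():
                species = (
                    pd.read_csv(inputs["species_map"], sep="\t", index_col=0)
                    .iloc[:, 0]
                    .to_dict()
                )
                _, n_dups, _ = phylo.count_duplications(tree, species)
                manifest.stage_counts["groups"]["min_duplications"] = n_dups
            logger.info("groups: %d queries assigned", len(calls))

        if "clusters" in stages or "date" in stages:
            loci = seqio.read_bed_loci(inputs["loci_bed"])
            clusters = dup.detect_clusters(
                loci,
                window=int(params.get("cluster_window", 200_000)),
                min_size=int(params.get("cluster_min_size", 2)),
            )
            dup.write_clusters_tsv(clusters, outdir / "clusters.tsv")
            manifest.stage_counts["clusters"] = {
                "loci": len(loci),
                "clusters": len(clusters),
            }
            logger.info("clusters: %d loci -> %d clusters", len(loci), len(clusters))

        if "date" in stages:
            cds = seqio.read_cds_fasta(inputs["cds_fasta"])
            pair_list = pd.read_csv(inputs["pairs"], sep="\t")
            loci_by_id = {l.gene_id: l for l in seqio.read_bed_loci(inputs["loci_bed"])}
            clock = dup.ClockParams(float(params.get("lambda_rate", 9.1e-9)))
            ks_ceiling = float(params.get("ks_ceiling", 3.0))
            pairs = []
            for _, row in pair_list.iterrows():
                a, b = row["gene_a"], row["gene_b"]
                la, lb = loci_by_id.get(a), loci_by_id.get(b)
                dtype = (
                    dup.classify_pair(la, lb, clusters)
                    if la is not None and lb is not None
                    else "segmental"
                )
                pairs.append(
                    dup.build_pair(a, b, cds[a], cds[b], dtype, clock, ks_ceiling)
                )
            dup.write_pairs_tsv(pairs, outdir / "pairs.tsv")
            dup.pair_table(pairs).to_csv(outdir / "pair_summary.tsv", sep="\t", index=False)
            manifest.stage_counts["date"] = {
                "pairs": len(pairs),
                "tandem": sum(p.dup_type == "tandem" for p in pairs),
            }
            logger.info("date: %d pairs", len(pairs))

        if "introns" in stages:
            models = seqio.read_gff3_gene_models(inputs["gff3"])
            introns = {m.gene_id: gs.extract_introns(m) for m in models}
            marks = None
            if "struct_alignment" in inputs and inputs["struct_alignment"].exists():
                struct_aln = phylo.read_alignment_fasta(inputs["struct_alignment"])
                marks = gs.map_introns_to_alignment(introns, struct_aln)
                events = gs.call_insertion_events(
                    marks, int(params.get("column_tolerance", 0))
                )
                gs.write_events_tsv(events, outdir / "events.tsv")
                manifest.stage_counts.setdefault("introns", {})["events"] = len(events)
            gs.write_introns_tsv(introns, outdir / "introns.tsv", marks)
            summary = gs.structure_summary(models)
            with open(outdir / "structure_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            manifest.stage_counts.setdefault("introns", {}).update(
                {"genes": len(models), "introns": summary["n_introns"]}
            )
            logger.info("introns: %d genes, %d introns", len(models), summary["n_introns"])

        if "express" in stages:
            counts = seqio.read_expression_tsv(
                inputs["counts"], inputs["conditions"], unit="counts"
            )
            lengths = (
                pd.read_csv(inputs["lengths"], sep="\t", index_col=0)
                .iloc[:, 0]
                .astype(int)
                .to_dict()
            )
            tpm = seqio.compute_tpm(counts, lengths)
            conditions = sorted(set(tpm.condition_map.values()))
            if len(conditions) != 2:
                raise ConfigError("express stage needs exactly two conditions")
            control, stress = conditions  # alphabetical: control < drought/stress
            retained = expr.retention_filter(
                tpm, (control, stress), float(params.get("retention_min_tpm", 1.0))
            )
            calls = expr.call_regulation(
                retained,
                control,
                stress,
                float(params.get("up_threshold", expr.DEFAULT_UP_THRESHOLD)),
                float(params.get("pseudocount", expr.DEFAULT_PSEUDOCOUNT)),
            )
            expr.write_calls_tsv(calls, outdir / "regulation_calls.tsv")
            if "expression_groups" in inputs and inputs["expression_groups"].exists():
                grp = (
                    pd.read_csv(inputs["expression_groups"], sep="\t", index_col=0)
                    .iloc[:, 0]
                    .to_dict()
                )
                expr.group_regulation_summary(calls, grp).to_csv(
                    outdir / "regulation_by_group.tsv", sep="\t", index=False
                )
            order, Z = expr.heatmap_order(retained)
            with open(outdir / "heatmap_dendrogram.nwk", "w") as fh:
                fh.write(expr.linkage_to_newick(Z, sorted(retained.gene_ids)) + "\n")
            edges = expr.coexpression_edges(
                retained, float(params.get("coexpression_threshold", 0.9))
            )
            expr.write_edges_tsv(edges, outdir / "coexpression_edges.tsv")
            manifest.stage_counts["express"] = {
                "genes": len(tpm.gene_ids),
                "retained": len(retained.gene_ids),
                "up": sum(c.label == "up" for c in calls),
                "down": sum(c.label == "down" for c in calls),
                "edges": len(edges),
            }
            logger.info(
                "express: %d genes, %d retained", len(tpm.gene_ids), len(retained.gene_ids)
            )
    except Exception as exc:
        manifest.failed_stage = _current_stage(manifest, stages)
        with open(outdir / "manifest.json", "w") as fh:
            fh.write(manifest.to_json() + "\n")
        raise

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.output_digests[f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest


def _current_stage(manifest: RunManifest, stages: list[str]) -> str:
    done = set(manifest.stage_counts)
    for stage in stages:
        if stage not in done:
            return stage
    return "unknown"


def _plain(obj):
    """YAML/JSON-safe deep copy (paths to strings)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
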