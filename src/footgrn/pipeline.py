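"""End-to-end orchestration: simulate -> atlas -> footprints -> catalog ->
link -> network, as one configured, seeded, logged run.

Every stage writes its outputs under the run directory and the run ends
with a JSON manifest recording file paths, SHA-256 checksums, package
version and the full parameter set; identical seeds give identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from footgrn import io as fio
from footgrn.atlas import (
    QuantConfig,
    call_peaks_merged,
    classify_distal,
    cluster_samples,
    normalize_rank,
    quantify_matrix,
    subtype_specific_dhs,
)
from footgrn.footprints import FootprintParams, detect_footprints
from footgrn.linking import link_all, link_stats
from footgrn.motifs import condense, filter_expressed, scan_footprints, summarize_catalog
from footgrn.network import (
    NetworkConfig,
    build_edges,
    co_occupancy,
    export_network,
    score_edge_recovery,
    upregulated_families,
)
from footgrn.simulate import (
    CONTROL_LABEL,
    SimConfig,
    merge_profiles,
    simulate_cohort,
)

log = logging.getLogger("footgrn")


class ValidationError(ValueError):
    """Configuration or input problems detected before any compute."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "footgrn_run"
    seed: int = 0
    simulate: bool = True
    simulate_only: bool = False
    write_profiles: bool = False
    log_level: str = "INFO"
    sim: SimConfig = None
    quant: QuantConfig = None
    footprint: FootprintParams = None
    network: NetworkConfig = None
    # external inputs, used when simulate=False
    genome_fasta: str | None = None
    genes_tsv: str | None = None
    metadata_tsv: str | None = None
    profiles_dir: str | None = None
    expression_tsv: str | None = None
    interactions_bedpe: str | None = None
    motifs_jaspar: str | None = None
    tf_annotation_tsv: str | None = None
    # stage knobs
    cluster_k: int | None = None
    subtype_fold: float = 2.0
    presence_fraction: float = 0.5
    condense_threshold: float = 0.8
    promoter_margin_bp: int = 2000

    def __post_init__(self) -> None:
        self.sim = self.sim or SimConfig(seed=self.seed)
        if self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.quant = self.quant or QuantConfig()
        self.footprint = self.footprint or FootprintParams()
        self.network = self.network or NetworkConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        nested = {
            "sim": SimConfig,
            "quant": QuantConfig,
            "footprint": FootprintParams,
            "network": NetworkConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                if key == "footprint" and "footprint_lengths" in value:
                    value["footprint_lengths"] = tuple(value["footprint_lengths"])
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate(config: PipelineConfig) -> None:
    if not config.simulate:
        required = {
            "genome_fasta": config.genome_fasta,
            "genes_tsv": config.genes_tsv,
            "metadata_tsv": config.metadata_tsv,
            "profiles_dir": config.profiles_dir,
            "expression_tsv": config.expression_tsv,
            "motifs_jaspar": config.motifs_jaspar,
            "tf_annotation_tsv": config.tf_annotation_tsv,
        }
        missing = [k for k, v in required.items() if not v]
        if missing:
            raise ValidationError(f"simulate=false but inputs not configured: {missing}")
        absent = [k for k, v in required.items() if v and not Path(v).exists()]
        if absent:
            raise ValidationError(f"configured inputs do not exist: {absent}")


def _load_external(config: PipelineConfig) -> dict:
    from footgrn.simulate import Annotation, StrandedCutProfile

    seqs = fio.read_fasta(config.genome_fasta)
    genome = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy() for c, s in seqs.items()}
    genes = fio.read_genes_tsv(config.genes_tsv)
    annotation = Annotation(genome=genome, genes=genes)
    metadata = pd.read_csv(config.metadata_tsv, sep="\t")
    lengths = {c: len(s) for c, s in seqs.items()}
    profiles = []
    pdir = Path(config.profiles_dir)
    for sid in metadata["sample_id"]:
        profiles.append(fio.read_profile(
            sid, pdir / f"{sid}.fwd.bedGraph", pdir / f"{sid}.rev.bedGraph", lengths
        ))
    expression = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
    interactions = (
        fio.read_bedpe(config.interactions_bedpe)
        if config.interactions_bedpe and Path(config.interactions_bedpe).exists()
        else None
    )
    pwms = fio.read_jaspar(config.motifs_jaspar)
    tf_annotation = fio.read_tf_annotation(config.tf_annotation_tsv)
    return {
        "annotation": annotation,
        "metadata": metadata,
        "profiles": profiles,
        "expression": expression,
        "interactions": interactions,
        "pwms": pwms,
        "tf_annotation": tf_annotation,
        "truth": None,
    }


def _write_simulation(bundle: dict, outdir: Path, write_profiles: bool) -> dict[str, Path]:
    truth = bundle["truth"]
    files: dict[str, Path] = {}

    def record(key, path):
        files[key] = Path(path)
        return path

    fio.write_fasta(bundle["annotation"], record("genome_fasta", outdir / "genome.fa"))
    fio.write_genes_tsv(bundle["annotation"].genes, record("genes_tsv", outdir / "genes.tsv"))
    peaks = truth.peaks.assign(name=truth.peaks["subtype"])
    fio.write_bed6(peaks, record("true_peaks_bed", outdir / "true_peaks.bed"))
    fps = truth.footprints.assign(name=truth.footprints["family_id"])
    fio.write_bed6(fps, record("true_footprints_bed", outdir / "true_footprints.bed"))
    fio.write_bedpe(truth.interactions, record("interactions_bedpe", outdir / "interactions.bedpe"))
    bundle["expression"].to_csv(record("expression_tsv", outdir / "expression.tsv"), sep="\t")
    bundle["metadata"].to_csv(record("metadata_tsv", outdir / "metadata.tsv"), sep="\t", index=False)
    fio.write_jaspar(truth.pwms, record("motifs_jaspar", outdir / "motifs.pfm"))
    fio.write_tf_annotation(truth.tf_annotation, record("tf_annotation_tsv", outdir / "tf_annotation.tsv"))
    fio.write_truth_json(truth, record("truth_json", outdir / "truth.json"))
    if write_profiles:
        pdir = outdir / "profiles"
        pdir.mkdir(exist_ok=True)
        for profile in bundle["profiles"]:
            f, r = fio.write_profile(profile, pdir / profile.sample_id)
            files[f"profile_{profile.sample_id}_fwd"] = f
            files[f"profile_{profile.sample_id}_rev"] = r
    return files


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    logging.basicConfig(level=config.log_level)
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    manifest: dict = {"parameters": _config_dict(config), "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("inputs")
        if config.simulate:
            bundle = simulate_cohort(config.sim)
            bundle["interactions"] = bundle["truth"].interactions
            bundle["pwms"] = bundle["truth"].pwms
            bundle["tf_annotation"] = bundle["truth"].tf_annotation
            files.update(_write_simulation(bundle, outdir, config.write_profiles))
        else:
            bundle = _load_external(config)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc

    results = {"bundle": bundle}
    if config.simulate_only:
        return _finish(manifest, files, outdir, results)

    metadata = bundle["metadata"]
    subtypes = sorted(metadata.loc[~metadata["is_control"], "subtype"].unique())

    try:
        stage("atlas")
        atlas = call_peaks_merged(bundle["profiles"])
        raw = quantify_matrix(atlas, bundle["profiles"], config.quant)
        norm = normalize_rank(raw, config.quant)
        distal_ids = classify_distal(atlas, bundle["annotation"], config.promoter_margin_bp)
        k = config.cluster_k or len(subtypes)
        z, groups = cluster_samples(norm, distal_ids, k=k)
        dhs_sets = subtype_specific_dhs(
            norm, metadata, fold=config.subtype_fold,
            presence_fraction=config.presence_fraction,
        )
        atlas_df = pd.DataFrame(
            [(p.chrom, p.start, p.end, p.id, 0, ".") for p in atlas],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        fio.write_bed6(atlas_df, outdir / "atlas.bed")
        files["atlas_bed"] = outdir / "atlas.bed"
        norm.values.to_csv(outdir / "counts_normalized.tsv", sep="\t")
        files["counts_tsv"] = outdir / "counts_normalized.tsv"
        fio.write_newick(z, sorted(norm.values.columns), outdir / "dendrogram.nwk")
        files["dendrogram"] = outdir / "dendrogram.nwk"
        pd.DataFrame(
            [(s, pid) for s, ids in sorted(dhs_sets.sets.items()) for pid in ids],
            columns=["subtype", "peak_id"],
        ).to_csv(outdir / "subtype_dhs.tsv", sep="\t", index=False)
        files["subtype_dhs_tsv"] = outdir / "subtype_dhs.tsv"
        results.update(atlas=atlas, matrix=norm, distal_ids=distal_ids,
                       groups=groups, dhs_sets=dhs_sets)
    except Exception as exc:  # noqa: BLE001
        raise StageError("atlas", exc) from exc

    try:
        stage("footprints")
        calls_by_subtype = {}
        for s in subtypes:
            members = [p for p, row in zip(bundle["profiles"], metadata.itertuples())
                       if row.subtype == s]
            merged = merge_profiles(members, sample_id=f"{s}_merged")
            calls_by_subtype[s] = detect_footprints(merged, atlas, config.footprint)
        rows = []
        for s, calls in sorted(calls_by_subtype.items()):
            for c in calls:
                rows.append((c.chrom, c.start, c.end, f"{s}:{c.id}",
                             min(1000, int(round(c.score * 10))), "."))
        fio.write_bed6(
            pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]),
            outdir / "footprints.bed",
        )
        files["footprints_bed"] = outdir / "footprints.bed"
        results["calls_by_subtype"] = calls_by_subtype
    except Exception as exc:  # noqa: BLE001
        raise StageError("footprints", exc) from exc

    try:
        stage("catalog")
        families = condense(bundle["pwms"], bundle["tf_annotation"],
                            threshold=config.condense_threshold)
        genome_seqs = bundle["annotation"].sequences()
        occurrences = {
            s: scan_footprints(calls, genome_seqs, families)
            for s, calls in calls_by_subtype.items()
        }
        fio.write_catalog_tsv(families, outdir / "catalog.tsv")
        files["catalog_tsv"] = outdir / "catalog.tsv"
        n_fam, n_genes = summarize_catalog(families)
        results.update(families=families, occurrences=occurrences,
                       catalog_counts=(n_fam, n_genes))
    except Exception as exc:  # noqa: BLE001
        raise StageError("catalog", exc) from exc

    try:
        stage("linking")
        distal_peaks = [p for p in atlas if p.id in set(distal_ids)]
        links = link_all(distal_peaks, bundle.get("interactions"),
                         bundle["annotation"], config.promoter_margin_bp)
        deregulated = {pid for ids in dhs_sets.sets.values() for pid in ids}
        stats = link_stats(links, distal_peaks, deregulated, bundle["annotation"])
        pd.DataFrame(
            [(l.peak_id, l.gene_id, l.method, l.n_supporting_interactions) for l in links],
            columns=["peak_id", "gene_id", "method", "n_interactions"],
        ).to_csv(outdir / "links.tsv", sep="\t", index=False)
        files["links_tsv"] = outdir / "links.tsv"
        (outdir / "link_stats.json").write_text(json.dumps(asdict(stats), indent=1))
        files["link_stats_json"] = outdir / "link_stats.json"
        results.update(links=links, stats=stats)
    except Exception as exc:  # noqa: BLE001
        raise StageError("linking", exc) from exc

    try:
        stage("network")
        expressed_samples = {
            s: [r.sample_id for r in metadata.itertuples() if r.subtype == s]
            for s in subtypes
        }
        nodes = upregulated_families(bundle["expression"], metadata, families,
                                     config.network, subtypes=subtypes)
        tf_genes = {g for f in families for g in f.member_tf_genes}
        edges = build_edges(nodes, occurrences, dhs_sets.sets, links,
                            config.network, tf_genes=tf_genes,
                            atlas_peak_ids={p.id for p in atlas})
        cooc = []
        for s in subtypes:
            occ = occurrences.get(s, [])
            if len({o.family_id for o in occ}) >= 2:
                cooc.extend(co_occupancy(occ, config.network, seed=config.seed, subtype=s))
        export_network(nodes, edges, outdir / "network.graphml", outdir / "edges.tsv")
        files["network_graphml"] = outdir / "network.graphml"
        files["edges_tsv"] = outdir / "edges.tsv"
        pd.DataFrame(
            [asdict(r) for r in cooc],
            columns=["family_a", "family_b", "subtype", "observed",
                     "null_mean", "p_value", "q_value"],
        ).to_csv(outdir / "cooccupancy.tsv", sep="\t", index=False)
        files["cooccupancy_tsv"] = outdir / "cooccupancy.tsv"
        results.update(nodes=nodes, edges=edges, cooccupancy=cooc)
        if bundle.get("truth") is not None:
            precision, recall = score_edge_recovery(edges, bundle["truth"])
            results["edge_precision"] = precision
            results["edge_recall"] = recall
            manifest["edge_recovery"] = {"precision": precision, "recall": recall}
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", exc) from exc

    return _finish(manifest, files, outdir, results)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["footprint"]["footprint_lengths"] = list(d["footprint"]["footprint_lengths"])
    return d


def _finish(manifest: dict, files: dict[str, Path], outdir: Path, results: dict) -> dict:
    from footgrn import __version__

    manifest["version"] = __version__
    manifest["files"] = {
        key: {"path": str(path), "sha256": _sha256(path)}
        for key, path in sorted(files.items())
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["results"] = results
    return manifest
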