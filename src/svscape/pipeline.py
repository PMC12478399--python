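"""End-to-end orchestration: configured, logged, reproducible runs.

A :class:`RunConfig` names the inputs, assets, parameters, and output
directory.  :func:`run_hotspot_analysis` executes the hotspot chain and its
annotation; :func:`run_full_report` adds burden, signature, chromothripsis,
evolution, and driver reports.  Every run writes a ``manifest.yaml``
recording the package version, parameters, and seed; missing optional
assets degrade gracefully with a logged warning instead of aborting.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import burden as bd
from . import catalog as cat
from . import chromothripsis as ct
from . import evolution as evo
from . import hotspots as hs
from . import io as svio
from . import signatures as sig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sv_path: str
    metadata_path: str | None = None
    cn_path: str | None = None
    rss_path: str | None = None
    immune_bed: str | None = "asset"     # "asset" -> packaged default
    gene_model_bed: str | None = "asset"
    rules_yaml: str | None = "asset"
    dialect: str = "simple_tsv"
    genome_build: str = "hg19"
    cutoff: int | str = "auto"
    fdr_threshold: float = 0.05
    k_range: tuple[int, int] = (1, 8)
    n_replicates: int = 30
    min_svs_signature: int = 20
    seed: int = 0
    output_dir: str = "svscape_out"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not Path(self.sv_path).exists():
            raise FileNotFoundError(self.sv_path)
        for p in (self.metadata_path, self.cn_path, self.rss_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, stages: list[str]) -> None:
    manifest = {
        "svscape_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "cutoff": config.cutoff,
        "fdr_threshold": config.fdr_threshold,
        "genome_build": config.genome_build,
        "stages": stages,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def _load_optional_bed(path: str | None, asset_name: str) -> pd.DataFrame | None:
    if path is None:
        return None
    if path == "asset":
        return ann.load_asset_bed(asset_name)
    return svio.read_bed(path)


def run_hotspot_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Hotspot chain + annotation; writes BED/TSV artifacts and a manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = svio.read_sv_table(config.sv_path, dialect=config.dialect)
    svs = table.svs
    if table.n_rejected:
        logger.warning("%d rows rejected on input", table.n_rejected)
        table.rejected.to_csv(outdir / "rejected_rows.tsv", sep="\t", index=False)
    svs = svio.deduplicate_svs(svs)
    from .records import assign_sv_ids
    svs = assign_sv_ids(svs)

    metadata = (
        svio.read_metadata(config.metadata_path)
        if config.metadata_path else None
    )
    rss = None
    if config.rss_path:
        try:
            rss = svio.read_rss_table(config.rss_path)
        except Exception as exc:  # degraded, not fatal
            logger.warning("RSS asset unreadable (%s); RSS annotation skipped", exc)
    immune = _load_optional_bed(config.immune_bed, "immune_loci.hg19.bed")
    genes = _load_optional_bed(config.gene_model_bed, "driver_genes.hg19.bed")

    result = hs.call_hotspots(
        svs, cutoff_bp=config.cutoff, fdr_threshold=config.fdr_threshold,
        seed=config.seed,
    )
    annotated = ann.annotate_hotspots(
        result.hotspots, result.members, svs, metadata=metadata,
        immune_loci=immune, rss_sites=rss, gene_model=genes,
    )

    bps = hs.breakpoints_from_svs(svs)
    dist = hs.nn_distances(bps)
    dist_table = pd.DataFrame({
        "chrom": bps["chrom"], "pos": bps["pos"],
        "sample_id": bps["sample_id"], "nn_distance": dist,
    })

    hs.write_hotspot_bed(result.hotspots, outdir / "hotspots.bed")
    result.tested.to_csv(outdir / "hotspots_tested.tsv", sep="\t", index=False)
    annotated.to_csv(outdir / "hotspots_annotated.tsv", sep="\t", index=False)
    dist_table.to_csv(outdir / "nn_distances.tsv", sep="\t", index=False)
    _write_manifest(outdir, config, ["hotspots"])
    logger.info(
        "hotspot analysis: %d tested, %d reported (cutoff %d bp)",
        len(result.tested), len(result.hotspots), result.cutoff_bp,
    )
    return {"hotspots": result.hotspots, "tested": result.tested,
            "annotated": annotated, "nn_distances": dist_table}


def run_full_report(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Hotspots plus burden, signatures, chromothripsis, evolution, drivers."""
    out = run_hotspot_analysis(config)
    outdir = Path(config.output_dir)

    table = svio.read_sv_table(config.sv_path, dialect=config.dialect)
    from .records import assign_sv_ids
    svs = assign_sv_ids(svio.deduplicate_svs(table.svs))
    metadata = (
        svio.read_metadata(config.metadata_path)
        if config.metadata_path else None
    )
    cn = svio.read_cn_segments(config.cn_path) if config.cn_path else None

    stages = ["hotspots"]

    if metadata is not None:
        summary = bd.burden_summary(svs, metadata)
        for name, tbl in summary.items():
            tbl.to_csv(outdir / f"burden_{name}.tsv", sep="\t", index=False)
        out["burden"] = summary["per_type"]
        stages.append("burden")

    classified = cat.classify_cohort(svs)
    matrix = cat.build_matrix(classified, min_svs=config.min_svs_signature)
    matrix.to_csv(outdir / "channel_matrix.tsv", sep="\t")
    out["channel_matrix"] = matrix
    stages.append("catalog")

    lo, hi = config.k_range
    if matrix.shape[1] >= 2:
        ranks = sig.extract_signatures(
            matrix, k_range=range(lo, min(hi, matrix.shape[1]) + 1),
            n_replicates=config.n_replicates, seed=config.seed,
        )
        k = sig.select_k(ranks)
        profiles = pd.DataFrame(
            ranks[k].profiles,
            index=[f"SVsig{i+1}" for i in range(k)],
            columns=list(matrix.index),
        )
        exposures, cosines = sig.assign_exposures(matrix, profiles)
        profiles.T.to_csv(outdir / "signature_profiles.tsv", sep="\t")
        exposures.to_csv(outdir / "signature_exposures.tsv", sep="\t")
        if metadata is not None:
            prev = sig.prevalence(exposures, cosines, metadata)
            prev.to_csv(outdir / "signature_prevalence.tsv", sep="\t", index=False)
        out["signature_profiles"] = profiles
        stages.append("signatures")
    else:
        logger.warning("fewer than 2 qualifying samples; signatures skipped")

    if cn is not None:
        calls = ct.screen_cohort(svs, cn)
        calls.to_csv(outdir / "chromothripsis_screen.tsv", sep="\t", index=False)
        out["chromothripsis"] = calls
        stages.append("chromothripsis")

    if metadata is not None:
        multi = metadata.groupby("patient_id")["sample_id"].nunique()
        ev_rows = []
        for patient in multi[multi >= 2].index:
            sids = metadata[metadata["patient_id"] == patient]["sample_id"]
            psvs = svs[svs["sample_id"].isin(sids)]
            if psvs["sample_id"].nunique() < 2:
                continue
            presence = evo.match_svs_across_samples(psvs)
            groups = evo.group_svs(presence)
            for key, grp in groups.items():
                ev_rows.append({"patient_id": patient, "sv_key": key, "group": grp})
        if ev_rows:
            pd.DataFrame(ev_rows).to_csv(
                outdir / "evolution_groups.tsv", sep="\t", index=False
            )
            stages.append("evolution")

    genes = _load_optional_bed(config.gene_model_bed, "driver_genes.hg19.bed")
    if genes is not None and metadata is not None:
        fragile = set(ann.load_asset_bed("fragile_site_genes.hg19.bed")["name"])
        genic = bd.annotate_genic(svs, genes, fragile)
        rules = bd.load_regulatory_rules(
            None if config.rules_yaml == "asset" else config.rules_yaml
        )
        reg = bd.classify_regulatory_cohort(svs, rules)
        genic.to_csv(outdir / "genic_annotation.tsv", sep="\t", index=False)
        reg.to_csv(outdir / "regulatory_annotation.tsv", sep="\t", index=False)
        if len(genic):
            prev = bd.disruption_prevalence(genic, metadata, feature_col="gene")
            prev.to_csv(outdir / "gene_prevalence.tsv", sep="\t", index=False)
        stages.append("drivers")

    _write_manifest(outdir, config, stages)
    return out
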