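"""End-to-end workflow: indices -> transforms -> clustering -> ordination ->
partition tree, with a reproducible output bundle and run manifest.

``run_all`` executes every stage on one set of inputs and writes plain-text
outputs (CSV tables, a Newick dendrogram, JSON summaries) plus a
``manifest.json`` recording the effective configuration, input digests,
per-stage status and the SHA-256 digest of every output file, so a rerun
with identical inputs and seeds can be verified byte-for-byte for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import cut_dendrogram, ward_cluster
from .indices import foram_index_table, indices_table, site_foram_index, ternary_table
from .io import (
    AnalysisConfig,
    AssemblageMatrix,
    SampleEnvironment,
    TaxonAnnotation,
    ValidationError,
    join_environment,
    island_of,
)
from .ordination import cca, triplot_coordinates
from .transforms import chord_distance, hellinger
from .tree import grow_tree, tree_to_json, tree_to_text

__all__ = ["StageError", "run_all"]

log = logging.getLogger("foramstats")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    config: AnalysisConfig,
    assemblage: AssemblageMatrix,
    taxa: list[TaxonAnnotation],
    environment: list[SampleEnvironment],
    out_dir,
) -> dict:
    """Run every analysis stage and write the output bundle.

    Returns the manifest dict (also written to ``manifest.json``).  Any stage
    error aborts with a :class:`StageError` naming the stage; outputs written
    by earlier stages are left in place and the half-written stage's files
    are renamed with a ``.partial`` suffix.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "stages": {},
        "outputs": {},
    }
    stage_files: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        stage_files.append(path)
        return path

    def finish_stage(stage: str) -> None:
        for p in stage_files:
            manifest["outputs"][p.name] = _sha256(p)
        manifest["stages"][stage] = "ok"
        stage_files.clear()

    def fail_stage(stage: str, exc: Exception):
        for p in stage_files:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    env_frame = pd.DataFrame([asdict(e) for e in environment]).set_index("sample_id")

    # ---- indices -----------------------------------------------------------
    stage = "indices"
    try:
        log.info("indices: %d samples x %d taxa (%s mode)",
                 len(assemblage.sample_ids), len(assemblage.taxon_ids), assemblage.mode)
        idx = indices_table(assemblage, taxa)
        emit("indices.csv", lambda p: idx.to_csv(p))
        fi = foram_index_table(assemblage, taxa)
        site_fi = site_foram_index(fi, method=config.fi_site_averaging)
        emit("site_fi.csv", lambda p: site_fi.to_csv(p))
        tern = ternary_table(assemblage, taxa, by_island=True)
        emit("ternary.csv", lambda p: tern.to_csv(p))
        log.info("indices: site FI %.2f..%.2f", site_fi["fi"].min(), site_fi["fi"].max())
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001
        fail_stage(stage, exc)

    # ---- transforms --------------------------------------------------------
    stage = "transforms"
    try:
        work = assemblage
        if config.merge_unidentified:
            pool = [t for t in work.taxon_ids if str(t).startswith("Usp")]
            if len(pool) > 1:
                work = work.merge_taxa(pool, "Usp")
        hel = hellinger(work, sqrt=config.hellinger_sqrt)
        dist = chord_distance(hel)
        emit("distances.csv", lambda p: dist.write(p))
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001
        fail_stage(stage, exc)

    # ---- clustering --------------------------------------------------------
    stage = "clustering"
    try:
        dend = ward_cluster(dist, variant=config.ward_variant)
        emit("dendrogram.nwk", lambda p: p.write_text(dend.to_newick() + "\n"))
        k = config.cut_k
        clusters = cut_dendrogram(dend, k)
        groups = cut_dendrogram(dend, 2)
        table = pd.DataFrame({
            "sample_id": list(clusters.labels),
            "cluster": [clusters.labels[s] for s in clusters.labels],
            "group": [groups.labels[s] for s in clusters.labels],
        }).set_index("sample_id")
        emit("clusters.csv", lambda p: table.to_csv(p))
        log.info("clustering: k=%d, top split sizes %s", k,
                 table["group"].value_counts().to_dict())
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001
        fail_stage(stage, exc)

    # ---- ordination --------------------------------------------------------
    stage = "ordination"
    try:
        env = join_environment(work, environment, include_depth=config.include_depth)
        result = cca(
            work, env,
            n_permutations=config.n_permutations,
            rng_seed=config.rng_seed,
            drop_collinear=True,
        )
        emit("cca_sites.csv", lambda p: result.site_scores_wa.to_csv(p))
        emit("cca_sites_lc.csv", lambda p: result.site_scores_lc.to_csv(p))
        emit("cca_species.csv", lambda p: result.species_scores.to_csv(p))
        emit("cca_biplot.csv", lambda p: result.biplot_scores.to_csv(p))
        tri = triplot_coordinates(result, (1, 2), sites=config.site_scores)
        emit("cca_triplot.csv", lambda p: pd.concat(
            [tri["sites"].assign(kind="site"),
             tri["species"].assign(kind="species"),
             tri["arrows"].assign(kind="arrow")]
        ).to_csv(p))
        emit("cca_summary.json", lambda p: p.write_text(
            json.dumps(result.summary(), indent=2)))
        log.info("ordination: total inertia %.4f, constrained %.4f, p=%s",
                 result.total_inertia, result.constrained_inertia,
                 result.permutation_p)
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001
        fail_stage(stage, exc)

    # ---- partition tree ----------------------------------------------------
    stage = "tree"
    try:
        root = grow_tree(
            env, clusters,
            min_node=config.tree_min_node,
            min_deviance_fraction=config.tree_min_deviance_fraction,
        )
        emit("tree.json", lambda p: p.write_text(tree_to_json(root)))
        emit("tree.txt", lambda p: p.write_text(tree_to_text(root) + "\n"))
        log.info("tree: root deviance %.4f, root split %s", root.deviance,
                 root.split_variable)
        finish_stage(stage)
    except Exception as exc:  # noqa: BLE001
        fail_stage(stage, exc)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
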