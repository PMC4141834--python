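"""End-to-end orchestration: preprocess -> call -> consensus -> roll-up ->
matrices -> transforms -> {cluster, MRPP, INDVAL, UniFrac, PCoA}.

A :class:`PipelineConfig` names the input files and the knobs of every stage;
:func:`run_pipeline` executes the enabled stages, writes TSV/JSON outputs into
the output directory and returns a :class:`RunManifest`.  Outputs are
deterministic under a fixed config and seed (the manifest's stage timings are
the one exception, so reproducibility checks should compare the data files or
the manifest's checksum inventory).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .chip_io import (
    ReferenceSet,
    read_intensity_table,
    read_newick,
    read_probe_annotation,
)
from .community_matrix import (
    CommunityMatrix,
    arcsine_sqrt,
    build_matrix,
    relativize_columns,
    write_matrix,
)
from .ecology_stats import (
    GroupLabels,
    bray_curtis,
    cluster,
    cut_dendrogram,
    indval,
    matrix_groups,
    mrpp,
    write_dendrogram,
    write_distance_matrix,
    write_indval,
    write_mrpp,
)
from .otu_calling import (
    CallThresholds,
    PresenceProfile,
    call_array,
    consensus_presence,
    rollup_taxa,
    taxon_counts,
)
from .phylo_ordination import leaf_weights, pcoa, unifrac_matrix, write_pcoa


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    annotation: str
    taxonomy: str
    intensities: str
    tree: str | None = None
    outdir: str = "phylarray_out"
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    spikein_level: float = 5000.0
    pooled: bool = False
    transform: str = "arcsine"  # distance input: "arcsine" or "relativized"
    linkage: str = "group_average"
    beta: float = -0.25
    cluster_level: int | None = None  # default: number of groups
    n_permutations: int = 1000
    seed: int = 0
    skip_cluster: bool = False
    skip_mrpp: bool = False
    skip_indval: bool = False
    skip_unifrac: bool = False
    skip_pcoa: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = CallThresholds(**thr)
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def validate(self) -> None:
        for name in ("annotation", "taxonomy", "intensities"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", f"{name} path {p!r} does not exist")
        if self.tree is not None and not Path(self.tree).exists():
            raise PipelineError("config", f"tree path {self.tree!r} does not exist")
        if self.tree is None and not self.skip_unifrac:
            raise PipelineError(
                "unifrac", "UniFrac enabled but no tree was provided"
            )
        if self.transform not in ("arcsine", "relativized"):
            raise PipelineError("config", f"unknown transform {self.transform!r}")


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_seconds: "OrderedDict[str, float]"
    warnings: list[str]
    outputs: dict[str, dict]  # filename -> {sha256, bytes}

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "stage_seconds": dict(self.stage_seconds),
            "warnings": self.warnings,
            "outputs": self.outputs,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: "OrderedDict[str, float]" = OrderedDict()
    warnings: list[str] = []
    emitted: list[Path] = []

    def stage(name: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 6)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _T()

    with stage("read"):
        reference = read_probe_annotation(config.annotation, config.taxonomy)
        arrays, io_warnings = read_intensity_table(config.intensities, reference)
        warnings.extend(io_warnings)
        tree = read_newick(config.tree, reference) if config.tree else None

    with stage("call"):
        call_rows = []
        by_sample: "OrderedDict[tuple[str, str], OrderedDict]" = OrderedDict()
        for arr in arrays:
            calls = call_array(
                reference, arr, config.thresholds,
                spikein_level=config.spikein_level,
            )
            key = (arr.sample_id, arr.condition_label)
            by_sample.setdefault(key, OrderedDict())[arr.replicate_id] = calls
            for otu, c in calls.items():
                call_rows.append(
                    (arr.sample_id, arr.replicate_id, otu,
                     c.hybridization_score, c.n_pairs_scored, c.n_positive,
                     round(c.positive_fraction, 6),
                     round(c.r_quartiles[0], 6), round(c.r_quartiles[1], 6),
                     round(c.r_quartiles[2], 6),
                     int(c.stage1_pass), int(c.stage2_pass), int(c.present))
                )
        call_table = pd.DataFrame(
            call_rows,
            columns=["sample_id", "replicate_id", "otu_id",
                     "hybridization_score", "n_pairs", "n_positive",
                     "positive_fraction", "r_q1", "r_q2", "r_q3",
                     "stage1", "stage2", "present"],
        )
        p = outdir / "call_table.tsv"
        call_table.to_csv(p, sep="\t", index=False)
        emitted.append(p)

    with stage("consensus"):
        profiles: list[PresenceProfile] = []
        for (sample_id, condition), reps in by_sample.items():
            prof = consensus_presence(
                sample_id, condition, reps, config.thresholds,
                pooled=config.pooled,
            )
            profiles.append(rollup_taxa(prof, reference.taxonomy))
        cons = pd.DataFrame(
            {prof.sample_id: pd.Series(prof.consensus) for prof in profiles}
        ).fillna(False).astype(int)
        cons.index.name = "otu_id"
        p = outdir / "consensus.tsv"
        cons.to_csv(p, sep="\t")
        emitted.append(p)
        counts = pd.DataFrame(
            {prof.sample_id: pd.Series(taxon_counts(prof)) for prof in profiles}
        )
        counts.index.name = "rank"
        p = outdir / "taxon_counts.tsv"
        counts.to_csv(p, sep="\t")
        emitted.append(p)

    with stage("matrix"):
        raw = build_matrix(profiles)
        rel = relativize_columns(raw)
        asin = arcsine_sqrt(rel)
        for m, name in ((raw, "matrix_raw"), (rel, "matrix_relativized"),
                        (asin, "matrix_arcsine")):
            pt, ps = outdir / f"{name}.tsv", outdir / f"{name}.json"
            write_matrix(m, pt, ps)
            emitted.extend([pt, ps])
        dist_input = asin if config.transform == "arcsine" else rel
        groups = matrix_groups(raw)

    with stage("bray_curtis"):
        bc = bray_curtis(dist_input)
        p = outdir / "bray_curtis.tsv"
        write_distance_matrix(bc, p)
        emitted.append(p)

    dend = None
    if not config.skip_cluster:
        with stage("cluster"):
            dend = cluster(bc, config.linkage, config.beta)
            p = outdir / "dendrogram.json"
            write_dendrogram(dend, p)
            emitted.append(p)
            level = config.cluster_level or len(groups.group_names)
            assignment = cut_dendrogram(dend, level)
            p = outdir / "clusters.tsv"
            pd.Series(assignment, name="cluster").rename_axis("id").to_csv(
                p, sep="\t"
            )
            emitted.append(p)

    if not config.skip_mrpp:
        with stage("mrpp"):
            res = mrpp(bc, groups, config.n_permutations, seed=config.seed)
            p = outdir / "mrpp.json"
            write_mrpp(res, p)
            emitted.append(p)

    if not config.skip_indval:
        with stage("indval"):
            presence = raw.presence()
            table = indval(rel, groups, presence=presence,
                           n_permutations=config.n_permutations,
                           seed=config.seed)
            pt, pj = outdir / "indval.tsv", outdir / "indval.json"
            write_indval(table, pt, pj)
            emitted.extend([pt, pj])

    unifrac_dm = None
    if not config.skip_unifrac:
        with stage("unifrac"):
            if tree is None:
                raise PipelineError("unifrac", "no tree provided")
            from .phylo_ordination import prune_zero_weight
            pruned = prune_zero_weight(
                tree, [t.name for t in tree.tips() if t.name in set(raw.otu_ids)]
            )
            weights = [leaf_weights(raw, col) for col in raw.array_ids]
            unifrac_dm = unifrac_matrix(pruned, weights)
            p = outdir / "unifrac.tsv"
            write_distance_matrix(unifrac_dm, p)
            emitted.append(p)

    if not config.skip_pcoa:
        with stage("pcoa"):
            source = unifrac_dm if unifrac_dm is not None else bc
            res = pcoa(source)
            pt, pj = outdir / "pcoa_coordinates.tsv", outdir / "pcoa.json"
            write_pcoa(res, pt, pj)
            emitted.extend([pt, pj])

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        stage_seconds=timings,
        warnings=warnings,
        outputs={
            p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in emitted
        },
    )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
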