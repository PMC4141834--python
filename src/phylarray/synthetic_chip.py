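"""Synthetic chip experiments with known ground truth.

The generator emulates the structure of a 16S phylogenetic-microarray study
end to end: a chip design whose per-OTU probe-pair counts follow the
published distribution (mean 37, s.d. 9.6, truncated below at ``pairs_min``),
a six-rank taxonomy whose clades align with a random rooted reference tree,
group-structured communities (shared log-normal baseline, per-group
multiplicative shifts, planted indicator OTUs that are present in every
replicate of their group and absent elsewhere), and probe-level PM/MM
intensities: present OTUs drive PM strongly and MM at a sub-unity leak
fraction, absent OTUs show only background noise, and cross-hybridization
both shares probes among same-species sibling OTUs and bleeds signal from
the tree-nearest present OTU into a random fraction of probes.

Everything is deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .chip_io import (
    CONTROL_PREFIX,
    ProbePair,
    ProbeSet,
    ReferenceSet,
    SampleArray,
    TaxonomyLineage,
    write_intensity_table,
    write_probe_annotation,
    write_taxonomy,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic experiment (defaults are the
    conditions every stochastic test and the acceptance run use)."""

    # chip design
    n_otus: int = 120
    n_species: int = 60
    n_phyla: int = 5
    lineage_fanout: int = 2  # children per internal taxonomy rank
    pairs_mean: float = 37.0
    pairs_sd: float = 9.6
    pairs_min: int = 10
    at_count_low: int = 8  # inclusive; probes carry no sequence, only A+T count
    at_count_high: int = 17
    n_spikeins: int = 24
    # design of the experiment
    n_groups: int = 3
    samples_per_group: int = 1
    replicates_per_sample: int = 3
    pooled: bool = False
    # community structure
    presence_prob: float = 0.4
    abundance_log_mean: float = 3.0  # natural-log scale of the lognormal baseline
    abundance_log_sd: float = 0.8
    effect_size: float = 2.0  # log2-fold between-group shift
    shifted_fraction: float = 0.2
    n_indicators: int = 2  # planted per group, exclusive presence
    # array physics
    crosshyb_rate: float = 0.05
    crosshyb_strength: float = 0.5
    # bleed only reaches OTUs whose nearest present neighbour is this close
    # on the tree (cross-hybridization is a close-relative phenomenon)
    crosshyb_max_dist: float = 0.5
    noise_sd: float = 0.15
    leak: float = 0.15  # MM response as a fraction of PM response
    gain: float = 100.0  # intensity units per abundance unit
    background_level: float = 50.0
    background_sd: float = 10.0
    # PM and MM of a pair share one nonspecific-binding level; this is the
    # small independent multiplicative jitter on top of it (scaled by
    # noise_sd so noise_sd = 0 yields fully deterministic arrays)
    background_pair_noise: float = 0.3
    spikein_level: float = 5000.0
    array_scale_sd: float = 0.1  # per-array global lognormal scale jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_otus, self.n_species, self.n_phyla, self.n_groups,
               self.samples_per_group, self.replicates_per_sample,
               self.pairs_min, self.n_spikeins) < 1:
            raise ConfigError("all counts must be positive")
        if self.n_otus < self.n_groups * self.n_indicators:
            raise ConfigError(
                f"n_otus={self.n_otus} < n_groups*n_indicators="
                f"{self.n_groups * self.n_indicators}"
            )
        if self.n_species > self.n_otus or self.n_phyla > self.n_species:
            raise ConfigError("need n_phyla <= n_species <= n_otus")
        for name in ("crosshyb_rate", "presence_prob", "shifted_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if not 0 <= self.leak < 1:
            raise ConfigError("leak must be in [0, 1)")
        if not 0 <= self.at_count_low <= self.at_count_high <= 25:
            raise ConfigError("at_count range outside 0..25")


@dataclass
class GroundTruth:
    """What the simulator actually planted, for recovery scoring."""

    presence: pd.DataFrame  # otu x sample_id, bool
    abundance: pd.DataFrame  # otu x array_id, true per-replicate abundance
    sample_groups: dict[str, str]  # sample_id -> group
    array_groups: dict[str, str]  # "sample/replicate" -> group
    indicators: dict[str, list[str]]  # group -> planted indicator OTUs
    shifted: dict[str, list[str]]  # group -> up-shifted OTUs
    tree_newick: str
    config: SimulationConfig = field(repr=False, default=None)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _group_labels(items: list[str], n_parents: int, prefix: str,
                  rng: np.random.Generator) -> dict[str, str]:
    """Assign child labels to n_parents parents, each parent non-empty."""
    n_parents = min(n_parents, len(items))
    order = list(rng.permutation(len(items)))
    out = {}
    for pos, idx in enumerate(order):
        out[items[idx]] = f"{prefix}{(pos % n_parents) + 1:03d}"
    return out


def _combine(nodes: list[TreeNode], rng: np.random.Generator) -> TreeNode:
    """Join subtrees pairwise (random order) into a single binary subtree."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        for child in (a, b):
            if child.length is None:
                child.length = round(float(rng.uniform(0.02, 0.3)), 6)
        nodes.append(parent)
    return nodes[0]


def simulate_reference(config: SimulationConfig) -> ReferenceSet:
    """Chip design: probe sets, six-rank taxonomy, and a matching rooted tree."""
    rng = _rng(config, 0)
    otus = [f"OTU{i + 1:04d}" for i in range(config.n_otus)]
    species_of = _group_labels(otus, config.n_species, "s_", rng)

    # taxonomy: group species into genera, genera into families, ... phyla
    species_labels = sorted(set(species_of.values()))
    level_of: dict[str, dict[str, str]] = {"species": {s: s for s in species_labels}}
    child_labels = species_labels
    for rank, prefix in (("genus", "g_"), ("family", "f_"), ("order", "o_"),
                         ("class", "c_")):
        n_parents = max(config.n_phyla,
                        (len(child_labels) + config.lineage_fanout - 1)
                        // config.lineage_fanout)
        mapping = _group_labels(child_labels, n_parents, prefix, rng)
        # compose with previous level: species -> this rank
        prev = level_of[list(level_of)[-1]]
        level_of[rank] = {s: mapping[prev[s]] for s in species_labels}
        child_labels = sorted(set(mapping.values()))
    phylum_map = _group_labels(child_labels, config.n_phyla, "p_", rng)
    level_of["phylum"] = {s: phylum_map[level_of["class"][s]]
                          for s in species_labels}

    taxonomy: "OrderedDict[str, TaxonomyLineage]" = OrderedDict()
    for otu in otus:
        s = species_of[otu]
        taxonomy[otu] = TaxonomyLineage(
            otu,
            (level_of["phylum"][s], level_of["class"][s], level_of["order"][s],
             level_of["family"][s], level_of["genus"][s], s),
        )

    # probe sets: pair counts ~ Normal(37, 9.6) truncated below
    counts = np.maximum(
        np.rint(rng.normal(config.pairs_mean, config.pairs_sd, config.n_otus)),
        config.pairs_min,
    ).astype(int)
    probesets: "OrderedDict[str, ProbeSet]" = OrderedDict()
    pair_lists: dict[str, list[ProbePair]] = {}
    for i, otu in enumerate(otus):
        ats = rng.integers(config.at_count_low, config.at_count_high + 1,
                           size=counts[i])
        pair_lists[otu] = [
            ProbePair(f"P{i + 1:04d}_{j + 1:03d}", int(ats[j]))
            for j in range(counts[i])
        ]

    # cross-hybridization at the design level: share probes among
    # same-species sibling OTUs so the stage-2 divisor s can exceed 1
    by_species: dict[str, list[str]] = {}
    for otu in otus:
        by_species.setdefault(species_of[otu], []).append(otu)
    for otu in otus:
        siblings = [o for o in by_species[species_of[otu]] if o != otu]
        if not siblings:
            continue
        for pair in list(pair_lists[otu]):
            if rng.random() < config.crosshyb_rate:
                sib = siblings[int(rng.integers(len(siblings)))]
                if all(p.probe_id != pair.probe_id for p in pair_lists[sib]):
                    pair_lists[sib].append(pair)
    for otu in otus:
        probesets[otu] = ProbeSet(otu, species_of[otu], tuple(pair_lists[otu]))

    # tree aligned with the taxonomy: join OTUs within species, species
    # within genera, and so on up to a two-child root
    nodes: dict[str, TreeNode] = {}
    for otu in otus:
        nodes[otu] = TreeNode(name=otu)
    for rank in ("species", "genus", "family", "order", "class", "phylum"):
        grouped: dict[str, list[TreeNode]] = {}
        if rank == "species":
            for otu in otus:
                grouped.setdefault(species_of[otu], []).append(nodes[otu])
        else:
            for label, node in nodes.items():
                parent = (level_of[rank][label] if rank != "phylum"
                          else level_of["phylum"][label])
                grouped.setdefault(parent, []).append(node)
        new_nodes = {}
        for label, children in grouped.items():
            sub = _combine(children, rng)
            new_nodes[label] = sub
        nodes = {}
        # keyed by a representative species so level_of lookups keep working
        for label, node in new_nodes.items():
            rep = next(s for s in species_labels
                       if (level_of[rank][s] if rank != "phylum"
                           else level_of["phylum"][s]) == label)
            nodes[rep] = node
    root = _combine(list(nodes.values()), rng)
    if len(root.children) != 2:  # single phylum: force a two-child root
        only = root
        other = TreeNode(name="OUTGROUP", length=1.0)
        only.length = round(float(rng.uniform(0.02, 0.3)), 6)
        root = TreeNode(children=[only, other])
    root.length = None
    newick = str(root).strip()
    return ReferenceSet(probesets, taxonomy, tree_source=newick)


def simulate_communities(
    config: SimulationConfig, reference: ReferenceSet
) -> GroundTruth:
    """Group-structured true communities with planted indicators."""
    rng = _rng(config, 1)
    otus = list(reference.otu_ids)
    groups = [f"G{g + 1}" for g in range(config.n_groups)]

    base_present = rng.random(len(otus)) < config.presence_prob
    indicator_pool = rng.permutation(len(otus)).tolist()
    indicators: dict[str, list[str]] = {}
    taken: set[int] = set()
    cursor = 0
    for g in groups:
        picked = []
        while len(picked) < config.n_indicators:
            idx = indicator_pool[cursor]
            cursor += 1
            if idx in taken:
                continue
            taken.add(idx)
            picked.append(idx)
        indicators[g] = [otus[i] for i in picked]
    for idx in taken:
        base_present[idx] = False  # indicators are exclusively group-driven

    baseline = np.exp(
        rng.normal(config.abundance_log_mean, config.abundance_log_sd, len(otus))
    )
    shifted: dict[str, list[str]] = {}
    group_abund: dict[str, np.ndarray] = {}
    group_present: dict[str, np.ndarray] = {}
    for g in groups:
        present = base_present.copy()
        for otu in indicators[g]:
            present[otus.index(otu)] = True
        abund = baseline * present
        shift_mask = (rng.random(len(otus)) < config.shifted_fraction) & base_present
        abund = np.where(shift_mask, abund * 2.0 ** config.effect_size, abund)
        shifted[g] = [otus[i] for i in np.flatnonzero(shift_mask)]
        for otu in indicators[g]:
            i = otus.index(otu)
            abund[i] = np.exp(
                rng.normal(config.abundance_log_mean, config.abundance_log_sd)
            )
        group_abund[g] = abund
        group_present[g] = present

    sample_groups: dict[str, str] = {}
    array_groups: dict[str, str] = {}
    presence_cols = {}
    abund_cols = {}
    for g in groups:
        for s in range(config.samples_per_group):
            sample_id = f"{g}_S{s + 1}"
            sample_groups[sample_id] = g
            presence_cols[sample_id] = group_present[g].astype(bool)
            n_reps = 1 if config.pooled else config.replicates_per_sample
            for r in range(n_reps):
                array_id = f"{sample_id}/R{r + 1}"
                array_groups[array_id] = g
                jitter = np.exp(rng.normal(0.0, config.noise_sd, len(otus)))
                abund_cols[array_id] = group_abund[g] * jitter * group_present[g]
    return GroundTruth(
        presence=pd.DataFrame(presence_cols, index=otus),
        abundance=pd.DataFrame(abund_cols, index=otus),
        sample_groups=sample_groups,
        array_groups=array_groups,
        indicators=indicators,
        shifted=shifted,
        tree_newick=reference.tree_source,
        config=config,
    )


def simulate_arrays(
    truth: GroundTruth, reference: ReferenceSet, config: SimulationConfig
) -> list[SampleArray]:
    """Probe-level PM/MM intensities for every replicate array."""
    rng = _rng(config, 2)
    otus = list(reference.otu_ids)
    otu_index = {o: i for i, o in enumerate(otus)}

    # (probe row, otu) assignment structure; shared probes appear once per owner
    probe_ids: list[str] = []
    probe_pos: dict[str, int] = {}
    assign_probe: list[int] = []
    assign_otu: list[int] = []
    for otu, ps in reference.probesets.items():
        for pair in ps.pairs:
            if pair.probe_id not in probe_pos:
                probe_pos[pair.probe_id] = len(probe_ids)
                probe_ids.append(pair.probe_id)
            assign_probe.append(probe_pos[pair.probe_id])
            assign_otu.append(otu_index[otu])
    assign_probe = np.array(assign_probe)
    assign_otu = np.array(assign_otu)
    n_probes = len(probe_ids)

    tipdist = reference.tree().tip_tip_distances(list(otus))
    D = tipdist.filter(otus).data  # reorder to otu order
    np.fill_diagonal(D, np.inf)

    arrays: list[SampleArray] = []
    for array_id in truth.abundance.columns:
        sample_id, rep_id = array_id.split("/")
        a = truth.abundance[array_id].to_numpy()
        signal_per_otu = config.gain * a
        signal = np.zeros(n_probes)
        np.add.at(signal, assign_probe, signal_per_otu[assign_otu])
        # cross-hybridization bleed from the tree-nearest present OTU
        present_idx = np.flatnonzero(a > 0)
        if present_idx.size and config.crosshyb_rate > 0:
            sub = D[:, present_idx]
            pick = np.argmin(sub, axis=1)
            nearest = present_idx[pick]
            nearest_dist = sub[np.arange(len(a)), pick]
            draws = rng.random(len(assign_probe))
            eligible = nearest_dist[assign_otu] <= config.crosshyb_max_dist
            bleed = (draws < config.crosshyb_rate) & eligible
            src = nearest[assign_otu[bleed]]
            np.add.at(
                signal,
                assign_probe[bleed],
                config.crosshyb_strength * config.gain * a[src],
            )
        e1 = rng.normal(0.0, config.noise_sd, n_probes)
        e2 = rng.normal(0.0, config.noise_sd, n_probes)
        # nonspecific binding + optical background act on the pair jointly:
        # one shared level per pair, with small independent jitter on top
        u = np.clip(rng.normal(config.background_level, config.background_sd,
                               n_probes), 1, None)
        bsd = config.background_pair_noise * config.noise_sd
        b1 = 1.0 + rng.normal(0.0, bsd, n_probes)
        b2 = 1.0 + rng.normal(0.0, bsd, n_probes)
        sf = float(np.exp(rng.normal(0.0, config.array_scale_sd)))
        pm = np.clip(u * b1 + signal * (1.0 + e1), 0, None) * sf
        mm = np.clip(u * b2 + config.leak * signal * (1.0 + e2), 0, None) * sf
        spike = (
            config.spikein_level
            * (1.0 + rng.normal(0.0, config.noise_sd, config.n_spikeins))
        )
        spike = np.clip(spike + np.clip(
            rng.normal(config.background_level, config.background_sd,
                       config.n_spikeins), 1, None), 0, None) * sf
        intens = OrderedDict(
            (probe_ids[k], (float(pm[k]), float(mm[k]))) for k in range(n_probes)
        )
        spikein = {
            f"{CONTROL_PREFIX}{k + 1:04d}": float(spike[k])
            for k in range(config.n_spikeins)
        }
        arrays.append(
            SampleArray(sample_id, rep_id, truth.array_groups[array_id],
                        intens, spikein)
        )
    return arrays


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ReferenceSet, GroundTruth, list[SampleArray]]:
    reference = simulate_reference(config)
    truth = simulate_communities(config, reference)
    arrays = simulate_arrays(truth, reference, config)
    return reference, truth, arrays


def write_fixture(
    outdir, reference: ReferenceSet, truth: GroundTruth,
    arrays: list[SampleArray],
) -> dict[str, str]:
    """Emit the full fixture directory of TSV/Newick/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "probe_annotation.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "intensities": outdir / "intensities.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_probe_annotation(reference, paths["annotation"])
    write_taxonomy(reference.taxonomy, paths["taxonomy"])
    write_intensity_table(arrays, paths["intensities"])
    with open(paths["tree"], "w", encoding="utf-8") as fh:
        fh.write(truth.tree_newick + "\n")
    pd.DataFrame(
        [(a.sample_id, a.replicate_id, a.condition_label) for a in arrays],
        columns=["sample_id", "replicate_id", "condition_label"],
    ).to_csv(paths["metadata"], sep="\t", index=False)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "presence": {
                    s: [o for o in truth.presence.index if truth.presence.at[o, s]]
                    for s in truth.presence.columns
                },
                "sample_groups": truth.sample_groups,
                "array_groups": truth.array_groups,
                "indicators": truth.indicators,
                "shifted": truth.shifted,
                "config": asdict(truth.config) if truth.config else None,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
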