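"""Probe-pair scoring and two-stage OTU present/absent calling.

The calling procedure works per array:

1. **Preprocessing** — intensities are background-subtracted (background =
   2nd percentile of all PM/MM values on the array), floored at 1 intensity
   unit, and scaled so the mean spike-in control intensity matches a fixed
   reference level.
2. **Pair scoring** — each PM/MM pair gets a response score
   ``d = (PM - MM) / (PM + MM)`` (0 when the denominator is 0) and a ranked
   response score ``r``: the fraction of *background* pairs with the same
   A+T content (bins of width 5 on the A+T count) whose ``d`` is strictly
   smaller.  The background pool consists of the probe pairs of all OTUs
   whose positive fraction falls below the stage-1 cutoff — probes that, by
   the calling's own standard, are not responding to a target.
3. **Stage 1** — an OTU passes when (i) at least 7 pairs were scored,
   (ii) at least 7 pairs are positive (PM strictly greater than MM),
   (iii) the quartiles of its ``r`` scores reach 0.80 / 0.93 / 0.98, and
   (iv) its positive fraction is at least 0.92.
4. **Stage 2** — cross-hybridization adjustment: each pair's ``rx = r / s``
   where ``s`` counts the stage-1-passing OTUs on this array whose probe sets
   contain the same probe.  A *species* is present when the quartiles of the
   pooled ``rx`` scores of its stage-1-passing OTUs reach 0.22 / 0.40 / 0.42;
   an OTU is present iff it passed stage 1 and its species is present.
5. **Consensus** — an OTU is present in a sample when called present on at
   least 2 of its 3 replicate arrays (or on the single array when replicates
   were pooled into one hybridization).  Higher taxa (phylum..genus) are
   present when at least one present species lies in their lineage.

The OTU abundance proxy is the *hybridization score*: the mean PM intensity
after discarding exactly one maximum and one minimum occurrence.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np

from .chip_io import RANK_NAMES, ProbeSet, ReferenceSet, SampleArray

AT_BIN_WIDTH = 5


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class CallThresholds:
    """Cutoffs of the two-stage calling procedure (defaults as published)."""

    stage1_min_pairs: int = 7
    stage1_min_positive: int = 7
    stage1_r_quartiles: tuple[float, float, float] = (0.80, 0.93, 0.98)
    stage1_positive_fraction: float = 0.92
    stage2_rx_quartiles: tuple[float, float, float] = (0.22, 0.40, 0.42)
    consensus_min_replicates: int = 2

    def __post_init__(self) -> None:
        for q in (self.stage1_r_quartiles, self.stage2_rx_quartiles):
            if not (0 <= q[0] <= q[1] <= q[2] <= 1):
                raise ValueError(f"quartile cutoffs not ordered in [0,1]: {q}")
        if not 0 <= self.stage1_positive_fraction <= 1:
            raise ValueError("positive fraction cutoff outside [0,1]")
        if min(self.stage1_min_pairs, self.stage1_min_positive,
               self.consensus_min_replicates) < 1:
            raise ValueError("count thresholds must be positive")


@dataclass
class ProbePairScore:
    probe_id: str
    positive: bool
    d: float
    r: float
    rx: float | None = None


@dataclass
class OtuCall:
    otu_id: str
    hybridization_score: float
    n_pairs_scored: int
    n_positive: int
    positive_fraction: float
    r_quartiles: tuple[float, float, float]
    criteria: dict[str, bool]
    stage1_pass: bool
    stage2_pass: bool = False
    present: bool = False


@dataclass
class PresenceProfile:
    """Per-sample consensus over replicate-level calls."""

    sample_id: str
    condition_label: str
    replicate_calls: "OrderedDict[str, dict[str, OtuCall]]"
    consensus: dict[str, bool]
    pooled: bool = False
    taxon_presence: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def present_otus(self) -> list[str]:
        return [o for o, p in self.consensus.items() if p]


def quartiles(values) -> tuple[float, float, float]:
    """25th/50th/75th percentiles by linear interpolation (type-7 rule)."""
    q = np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75])
    return (float(q[0]), float(q[1]), float(q[2]))


def hybridization_score(pm_values) -> float:
    """Trimmed-mean PM intensity: drop exactly one max and one min occurrence."""
    pm = np.sort(np.asarray(pm_values, dtype=float))
    if pm.size < 3:
        raise CallingError(
            f"hybridization score undefined for {pm.size} pairs (need >= 3)"
        )
    return float(pm[1:-1].mean())


def preprocess_array(
    array: SampleArray,
    spikein_level: float = 5000.0,
    background_percentile: float = 2.0,
    floor: float = 1.0,
) -> SampleArray:
    """Background-subtract and spike-in-scale one array.

    Background is the ``background_percentile``-th percentile of every PM and
    MM value on the array; subtracted intensities are floored at ``floor`` (so
    downstream log2 weights stay non-negative), then all intensities are
    multiplied by ``spikein_level / mean(background-subtracted spike-ins)``.
    """
    if not array.spikein:
        raise CallingError(f"array {array.array_id}: no spike-in controls")
    values = np.array([v for pair in array.intensities.values() for v in pair])
    if values.size == 0:
        raise CallingError(f"array {array.array_id}: no probe intensities")
    b = float(np.percentile(values, background_percentile))
    spike = np.maximum(np.array(list(array.spikein.values())) - b, floor)
    mean_spike = float(spike.mean())
    if mean_spike <= 0:
        raise CallingError(f"array {array.array_id}: zero mean spike-in")
    scale = spikein_level / mean_spike
    intens = OrderedDict(
        (pid, (max(pm - b, floor) * scale, max(mm - b, floor) * scale))
        for pid, (pm, mm) in array.intensities.items()
    )
    spikein = {pid: max(v - b, floor) * scale for pid, v in array.spikein.items()}
    return SampleArray(
        array.sample_id, array.replicate_id, array.condition_label, intens, spikein
    )


def _at_bin(at_count: int) -> int:
    return at_count // AT_BIN_WIDTH


def _pairs_on_array(probeset: ProbeSet, array: SampleArray):
    """The scored pairs of an OTU: annotation pairs measured on this array."""
    out = []
    for p in probeset.pairs:
        hit = array.intensities.get(p.probe_id)
        if hit is not None:
            out.append(p._replace(pm=hit[0], mm=hit[1]))
    return out


def _d_score(pm: float, mm: float) -> float:
    tot = pm + mm
    return (pm - mm) / tot if tot > 0 else 0.0


def response_scores(
    reference: ReferenceSet,
    array: SampleArray,
    thresholds: CallThresholds = CallThresholds(),
) -> dict[str, list[ProbePairScore]]:
    """Compute d and r scores for every scored pair of every OTU.

    The background pool is array-specific and label-free: the pairs of all
    OTUs whose positive fraction is below ``thresholds.stage1_positive_fraction``.
    An empty A+T bin in the pool raises (wider binning or more background
    probes needed).
    """
    pairs = {
        otu: _pairs_on_array(ps, array) for otu, ps in reference.probesets.items()
    }
    d = {
        otu: np.array([_d_score(p.pm, p.mm) for p in ps])
        for otu, ps in pairs.items()
    }
    # non-responders by the positive-fraction standard form the background
    background_bins: dict[int, list[float]] = {}
    for otu, ps in pairs.items():
        if len(ps) == 0:
            continue
        pos_frac = float(np.mean(d[otu] > 0))
        if pos_frac < thresholds.stage1_positive_fraction:
            for p, dv in zip(ps, d[otu]):
                background_bins.setdefault(_at_bin(p.at_count), []).append(dv)
    # a non-responding pair's d is sign-symmetric, while cross-hybridizing
    # pairs contaminate only the positive side; the per-bin null is therefore
    # the pool's non-positive d values reflected about zero
    sorted_bins = {}
    for b, v in background_bins.items():
        lo = np.asarray([x for x in v if x <= 0])
        sorted_bins[b] = np.sort(np.concatenate([lo, -lo]))

    scores: dict[str, list[ProbePairScore]] = {}
    for otu, ps in pairs.items():
        row = []
        for p, dv in zip(ps, d[otu]):
            b = _at_bin(p.at_count)
            pool = sorted_bins.get(b)
            if pool is None or pool.size == 0:
                raise CallingError(
                    f"no background pairs in A+T bin {b} "
                    f"(A+T {b * AT_BIN_WIDTH}-{(b + 1) * AT_BIN_WIDTH - 1}); "
                    "widen the binning or add background probes"
                )
            r = float(np.searchsorted(pool, dv, side="left")) / pool.size
            row.append(ProbePairScore(p.probe_id, positive=dv > 0, d=float(dv), r=r))
        scores[otu] = row
    return scores


def stage1_call(
    probeset: ProbeSet,
    scores: list[ProbePairScore],
    array: SampleArray,
    thresholds: CallThresholds = CallThresholds(),
) -> OtuCall:
    """Apply the four stage-1 criteria to one OTU's scored pairs."""
    n = len(scores)
    n_pos = sum(s.positive for s in scores)
    frac = n_pos / n if n else 0.0
    rq = quartiles([s.r for s in scores]) if n else (0.0, 0.0, 0.0)
    tq = thresholds.stage1_r_quartiles
    criteria = {
        "min_pairs": n >= thresholds.stage1_min_pairs,
        "min_positive": n_pos >= thresholds.stage1_min_positive,
        "r_quartiles": rq[0] >= tq[0] and rq[1] >= tq[1] and rq[2] >= tq[2],
        "positive_fraction": frac >= thresholds.stage1_positive_fraction,
    }
    pms = [array.intensities[s.probe_id][0] for s in scores
           if s.probe_id in array.intensities]
    hyb = hybridization_score(pms) if len(pms) >= 3 else float("nan")
    return OtuCall(
        otu_id=probeset.otu_id,
        hybridization_score=hyb,
        n_pairs_scored=n,
        n_positive=n_pos,
        positive_fraction=frac,
        r_quartiles=rq,
        criteria=criteria,
        stage1_pass=all(criteria.values()),
    )


def stage2_call(
    calls: dict[str, OtuCall],
    scores: dict[str, list[ProbePairScore]],
    reference: ReferenceSet,
    thresholds: CallThresholds = CallThresholds(),
) -> dict[str, OtuCall]:
    """Cross-hybridization adjustment and species-level presence.

    Mutates the ``rx`` fields of ``scores`` and returns calls with
    ``stage2_pass``/``present`` decided.  ``rx = r / s`` with ``s`` the number
    of stage-1-passing OTUs (on this array) whose probe sets contain the same
    probe; species presence requires the pooled rx quartiles of its passing
    OTUs to reach the stage-2 cutoffs.
    """
    passing = {o for o, c in calls.items() if c.stage1_pass}
    probe_owners = reference.probes_to_otus()
    share_count = {
        pid: len(owners & passing) for pid, owners in probe_owners.items()
    }
    by_species: dict[str, list[float]] = {}
    for otu in passing:
        sp = reference.probesets[otu].species_id
        pooled = by_species.setdefault(sp, [])
        for s in scores[otu]:
            s.rx = s.r / max(share_count.get(s.probe_id, 1), 1)
            pooled.append(s.rx)
    tq = thresholds.stage2_rx_quartiles
    species_present = {}
    for sp, rx in by_species.items():
        q = quartiles(rx)
        species_present[sp] = q[0] >= tq[0] and q[1] >= tq[1] and q[2] >= tq[2]
    out = {}
    for otu, call in calls.items():
        sp = reference.probesets[otu].species_id
        s2 = call.stage1_pass and species_present.get(sp, False)
        out[otu] = replace(call, stage2_pass=s2, present=s2)
    return out


def call_array(
    reference: ReferenceSet,
    array: SampleArray,
    thresholds: CallThresholds = CallThresholds(),
    preprocess: bool = True,
    spikein_level: float = 5000.0,
) -> dict[str, OtuCall]:
    """Full per-array pipeline: preprocess, score, stage 1, stage 2."""
    if preprocess:
        array = preprocess_array(array, spikein_level=spikein_level)
    scores = response_scores(reference, array, thresholds)
    calls = {
        otu: stage1_call(reference.probesets[otu], scores[otu], array, thresholds)
        for otu in reference.probesets
    }
    return stage2_call(calls, scores, reference, thresholds)


def consensus_presence(
    sample_id: str,
    condition_label: str,
    replicate_calls: "OrderedDict[str, dict[str, OtuCall]]",
    thresholds: CallThresholds = CallThresholds(),
    pooled: bool = False,
) -> PresenceProfile:
    """Replicate consensus: present in >= 2 of 3 replicates, or on the single
    pooled array when the replicates were pooled before hybridization."""
    if not replicate_calls:
        raise CallingError(f"sample {sample_id!r}: no replicate calls")
    if pooled and len(replicate_calls) != 1:
        raise CallingError(
            f"sample {sample_id!r}: pooled consensus expects exactly one array"
        )
    otus: list[str] = []
    for calls in replicate_calls.values():
        for otu in calls:
            if otu not in otus:
                otus.append(otu)
    need = 1 if pooled else thresholds.consensus_min_replicates
    consensus = {
        otu: sum(
            calls.get(otu) is not None and calls[otu].present
            for calls in replicate_calls.values()
        ) >= need
        for otu in otus
    }
    return PresenceProfile(
        sample_id, condition_label, replicate_calls, consensus, pooled=pooled
    )


def rollup_taxa(profile: PresenceProfile, taxonomy) -> PresenceProfile:
    """Mark a taxon present at every rank with >= 1 present species below it.

    Presence propagates through the species rank: a genus (family, ...) is
    present iff at least one *species* containing a present OTU lies in it.
    """
    present_lineages = []
    for otu in profile.present_otus:
        lin = taxonomy.get(otu)
        if lin is None:
            raise CallingError(f"OTU {otu!r} has no taxonomy lineage")
        present_lineages.append(lin)
    taxon_presence: dict[tuple[str, str], bool] = {}
    for otu, lin in taxonomy.items():
        for rank, label in zip(RANK_NAMES, lin.ranks):
            taxon_presence.setdefault((rank, label), False)
    for lin in present_lineages:
        for rank, label in zip(RANK_NAMES, lin.ranks):
            taxon_presence[(rank, label)] = True
    profile.taxon_presence = taxon_presence
    return profile


def taxon_counts(profile: PresenceProfile) -> dict[str, int]:
    """Numbers of present taxa per rank (phyla, ..., species) plus OTUs."""
    counts = {rank: 0 for rank in RANK_NAMES}
    for (rank, _label), present in profile.taxon_presence.items():
        if present:
            counts[rank] += 1
    counts["otu"] = len(profile.present_otus)
    return counts
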