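"""Scoring and two-stage calling: hand-computed examples, truth tables,
oracle checks against brute-force ranking, and recovery on clean arrays."""

import itertools
from collections import OrderedDict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylarray import SimulationConfig, simulate_experiment
from phylarray.otu_calling import (
    CallThresholds,
    CallingError,
    OtuCall,
    ProbePairScore,
    call_array,
    consensus_presence,
    hybridization_score,
    preprocess_array,
    quartiles,
    response_scores,
    rollup_taxa,
    stage1_call,
    stage2_call,
    taxon_counts,
)

from conftest import make_array, make_reference


# ---------------------------------------------------------------------------
# hybridization score

@pytest.mark.parametrize(
    "pm,expected",
    [
        ([5, 5, 5, 5], 5.0),
        ([1, 2, 3, 4, 5], 3.0),  # mean of {2, 3, 4}
        ([1, 1, 9], 1.0),  # one min occurrence removed, not all ties
    ],
)
def test_hybridization_score_trims_one_max_one_min(pm, expected):
    assert hybridization_score(pm) == pytest.approx(expected)


def test_hybridization_score_needs_three_pairs():
    with pytest.raises(CallingError):
        hybridization_score([1, 2])


# ---------------------------------------------------------------------------
# response scores

def _scored(reference, pm_mm):
    array = make_array(reference, pm_mm)
    return response_scores(reference, array), array


def test_d_score_symmetry_and_rank_extremes():
    # O1 responds strongly; O2 is flat background (pm == mm -> d = 0)
    ref = make_reference([10, 60])
    pm_mm = {f"O1_p{j}": (900.0, 100.0) for j in range(1, 11)}
    pm_mm.update({f"O2_p{j}": (50.0, 50.0) for j in range(1, 61)})
    scores, _ = _scored(ref, pm_mm)
    for s in scores["O1"]:
        assert s.d == pytest.approx(0.8)
        assert s.r == 1.0  # above every background d
        assert s.positive
    for s in scores["O2"]:
        assert s.d == 0.0
        assert not s.positive  # pm == mm is not positive


def test_r_matches_brute_force_rank_oracle():
    rng = np.random.default_rng(11)
    ref = make_reference([10, 100])
    pm_mm = {}
    for j in range(1, 11):  # the scored OTU, mixed response
        pm = rng.uniform(50, 500)
        pm_mm[f"O1_p{j}"] = (pm, rng.uniform(20, pm))
    for j in range(1, 101):  # flat background OTU
        base = rng.uniform(30, 80)
        pm_mm[f"O2_p{j}"] = (base + rng.normal(0, 5), base + rng.normal(0, 5))
    scores, _ = _scored(ref, pm_mm)
    # independent oracle: reflected non-positive background d's, counted
    bg_d = [(pm - mm) / (pm + mm) for pm, mm in
            (pm_mm[f"O2_p{j}"] for j in range(1, 101))]
    null = sorted([x for x in bg_d if x <= 0] + [-x for x in bg_d if x <= 0])
    for s in scores["O1"]:
        expected = sum(1 for x in null if x < s.d) / len(null)
        assert s.r == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= s.r <= 1.0


def test_empty_background_bin_raises():
    ref = make_reference([10])  # every OTU responds -> empty pool
    pm_mm = {f"O1_p{j}": (900.0, 100.0) for j in range(1, 11)}
    with pytest.raises(CallingError, match="background"):
        _scored(ref, pm_mm)


# ---------------------------------------------------------------------------
# stage 1: all feasible combinations of the four criteria

def _mk_call(n, n_pos, r, thresholds=CallThresholds()):
    ref = make_reference([n, 60])
    pm_mm = {}
    for j in range(1, n + 1):
        pm_mm[f"O1_p{j}"] = (300.0, 100.0) if j <= n_pos else (100.0, 300.0)
    pm_mm.update({f"O2_p{j}": (50.0, 50.0) for j in range(1, 61)})
    array = make_array(ref, pm_mm)
    scores = [
        ProbePairScore(f"O1_p{j}", positive=j <= n_pos,
                       d=0.5 if j <= n_pos else -0.5, r=r)
        for j in range(1, n + 1)
    ]
    return stage1_call(ref.probesets["O1"], scores, array, thresholds)


# (min_pairs, min_positive, r_quartiles, positive_fraction) -> constructor
FEASIBLE = {
    (True, True, True, True): (13, 13, 1.0),
    (True, True, True, False): (13, 7, 1.0),
    (True, True, False, True): (13, 13, 0.5),
    (True, True, False, False): (13, 7, 0.5),
    (True, False, True, False): (13, 6, 1.0),
    (True, False, False, False): (13, 6, 0.5),
    (False, False, True, True): (6, 6, 1.0),
    (False, False, True, False): (6, 3, 1.0),
    (False, False, False, True): (6, 6, 0.5),
    (False, False, False, False): (6, 3, 0.5),
}


@pytest.mark.parametrize("flags,args", sorted(FEASIBLE.items()), ids=str)
def test_stage1_criterion_combinations(flags, args):
    call = _mk_call(*args)
    got = (
        call.criteria["min_pairs"],
        call.criteria["min_positive"],
        call.criteria["r_quartiles"],
        call.criteria["positive_fraction"],
    )
    assert got == flags
    assert call.stage1_pass == all(flags)


def test_stage1_infeasible_combinations_are_entailed():
    """min_positive implies min_pairs; (min_pairs & fraction) implies
    min_positive — so 6 of the 16 combinations cannot occur."""
    for n in range(1, 16):
        for n_pos in range(0, n + 1):
            c = _mk_call(n, n_pos, 1.0).criteria
            assert not (c["min_positive"] and not c["min_pairs"])
            assert not (
                c["min_pairs"] and c["positive_fraction"]
                and not c["min_positive"]
            )


def test_stage1_boundary_arithmetic():
    # 12/13 = 0.923 >= 0.92 passes; 7/8 = 0.875 < 0.92 fails criterion 4 only
    c = _mk_call(13, 12, 1.0)
    assert c.positive_fraction == pytest.approx(12 / 13)
    assert c.criteria == {
        "min_pairs": True, "min_positive": True,
        "r_quartiles": True, "positive_fraction": True,
    }
    c = _mk_call(8, 7, 1.0)
    assert c.positive_fraction == pytest.approx(0.875)
    assert c.criteria["min_positive"] and not c.criteria["positive_fraction"]


def test_quartiles_are_type7():
    assert quartiles([1, 2, 3, 4, 5]) == (2.0, 3.0, 4.0)
    assert quartiles([0, 1]) == (0.25, 0.5, 0.75)


# ---------------------------------------------------------------------------
# stage 2

def _stage2_setup(n_otus, share_all, r_value=1.0):
    """n_otus one-species stage-1 passers; optionally all sharing every probe."""
    if share_all:
        # all OTUs carry the same 10 probes
        from phylarray.chip_io import ProbePair, ProbeSet, ReferenceSet, TaxonomyLineage
        pairs = tuple(ProbePair(f"shared_p{j}", 10) for j in range(1, 11))
        probesets = OrderedDict(
            (f"O{i}", ProbeSet(f"O{i}", "S1", pairs)) for i in range(1, n_otus + 1)
        )
        taxonomy = OrderedDict(
            (o, TaxonomyLineage(o, ("p", "c", "o", "f", "g", "S1")))
            for o in probesets
        )
        ref = ReferenceSet(probesets, taxonomy)
    else:
        ref = make_reference([10] * n_otus, n_species=1)
    calls = {}
    scores = {}
    for otu, ps in ref.probesets.items():
        scores[otu] = [
            ProbePairScore(p.probe_id, True, 0.5, r_value) for p in ps.pairs
        ]
        calls[otu] = OtuCall(otu, 100.0, 10, 10, 1.0, (r_value,) * 3,
                             {}, stage1_pass=True)
    return ref, calls, scores


def test_stage2_unshared_probes_rx_equals_r():
    ref, calls, scores = _stage2_setup(3, share_all=False)
    out = stage2_call(calls, scores, ref)
    for otu in ref.probesets:
        assert all(s.rx == s.r for s in scores[otu])
        assert out[otu].present  # quartiles (1,1,1) >= (0.22, 0.40, 0.42)


def test_stage2_five_way_sharing_discounts_to_absent():
    ref, calls, scores = _stage2_setup(5, share_all=True)
    out = stage2_call(calls, scores, ref)
    for otu in ref.probesets:
        assert all(s.rx == pytest.approx(0.2) for s in scores[otu])
        assert not out[otu].present  # 0.2 < 0.22 at every quartile


def test_stage2_presence_subset_of_stage1_and_rx_le_r(small_experiment):
    reference, _, arrays = small_experiment
    arr = preprocess_array(arrays[0])
    scores = response_scores(reference, arr)
    calls = {
        otu: stage1_call(reference.probesets[otu], scores[otu], arr)
        for otu in reference.probesets
    }
    out = stage2_call(calls, scores, reference)
    for otu, call in out.items():
        if call.present:
            assert call.stage1_pass
        for s in scores[otu]:
            if s.rx is not None:
                assert s.rx <= s.r + 1e-15


def test_stage2_species_with_no_passer_is_absent():
    ref, calls, scores = _stage2_setup(2, share_all=False)
    for otu in calls:
        calls[otu].stage1_pass = False
    out = stage2_call(calls, scores, ref)
    assert not any(c.present for c in out.values())


# ---------------------------------------------------------------------------
# consensus & roll-up

def _stub_calls(present: bool) -> dict:
    return {"O1": OtuCall("O1", 10.0, 10, 10, 1.0, (1, 1, 1), {}, True,
                          present, present)}


@pytest.mark.parametrize(
    "reps", list(itertools.product([False, True], repeat=3)), ids=str
)
def test_consensus_majority_truth_table(reps):
    calls = OrderedDict(
        (f"R{i + 1}", _stub_calls(p)) for i, p in enumerate(reps)
    )
    prof = consensus_presence("S1", "G", calls)
    assert prof.consensus["O1"] == (sum(reps) >= 2)


def test_consensus_pooled_single_array():
    prof = consensus_presence(
        "S1", "G", OrderedDict(R1=_stub_calls(True)), pooled=True
    )
    assert prof.consensus["O1"]
    prof = consensus_presence(
        "S1", "G", OrderedDict(R1=_stub_calls(False)), pooled=True
    )
    assert not prof.consensus["O1"]


def test_consensus_errors():
    with pytest.raises(CallingError):
        consensus_presence("S1", "G", OrderedDict())
    with pytest.raises(CallingError, match="pooled"):
        consensus_presence(
            "S1", "G",
            OrderedDict(R1=_stub_calls(True), R2=_stub_calls(True)),
            pooled=True,
        )


def test_rollup_single_present_otu_lights_whole_lineage():
    ref = make_reference([10, 10])
    calls = OrderedDict(
        R1={"O1": OtuCall("O1", 1, 10, 10, 1.0, (1, 1, 1), {}, True, True, True),
            "O2": OtuCall("O2", 1, 10, 0, 0.0, (0, 0, 0), {}, False)},
    )
    prof = consensus_presence("S1", "G", calls, pooled=True)
    prof = rollup_taxa(prof, ref.taxonomy)
    lin = ref.taxonomy["O1"]
    for rank, label in zip(
        ("phylum", "class", "order", "family", "genus", "species"), lin.ranks
    ):
        assert prof.taxon_presence[(rank, label)]
    assert not prof.taxon_presence[("species", ref.taxonomy["O2"].species)]
    counts = taxon_counts(prof)
    assert counts["otu"] == 1 and counts["species"] == 1


def test_rollup_counts_equal_set_union_oracle(default_experiment):
    reference, truth, arrays = default_experiment
    arr = arrays[0]
    calls = call_array(reference, arr)
    prof = consensus_presence(arr.sample_id, arr.condition_label,
                              OrderedDict({arr.replicate_id: calls}), pooled=True)
    prof = rollup_taxa(prof, reference.taxonomy)
    counts = taxon_counts(prof)
    present = set(prof.present_otus)
    for i, rank in enumerate(
        ("phylum", "class", "order", "family", "genus", "species")
    ):
        expected = {reference.taxonomy[o].ranks[i] for o in present}
        assert counts[rank] == len(expected)


# ---------------------------------------------------------------------------
# preprocessing

def test_preprocess_scale_invariance(small_experiment):
    reference, _, arrays = small_experiment
    a = arrays[0]
    doubled = type(a)(
        a.sample_id, a.replicate_id, a.condition_label,
        OrderedDict((k, (2 * pm, 2 * mm)) for k, (pm, mm) in a.intensities.items()),
        {k: 2 * v for k, v in a.spikein.items()},
    )
    p1 = preprocess_array(a)
    p2 = preprocess_array(doubled)
    # identical up to the floor: probes clamped at 1 intensity unit are the
    # only place the two scales can disagree
    values = np.array([v for pair in a.intensities.values() for v in pair])
    b = np.percentile(values, 2.0)
    compared = 0
    for k, (pm, mm) in a.intensities.items():
        if pm - b >= 1 and mm - b >= 1:
            assert p1.intensities[k][0] == pytest.approx(
                p2.intensities[k][0], rel=1e-9)
            assert p1.intensities[k][1] == pytest.approx(
                p2.intensities[k][1], rel=1e-9)
            compared += 1
    assert compared > 0.8 * len(a.intensities)


def test_preprocess_removes_known_offset():
    ref = make_reference([100])
    base = {f"O1_p{j}": (float(10 * j), float(5 * j)) for j in range(1, 101)}
    offset = 37.0
    shifted = {k: (pm + offset, mm + offset) for k, (pm, mm) in base.items()}
    a0 = make_array(ref, base)
    a1 = make_array(ref, shifted)
    a1.spikein = {k: v + offset for k, v in a1.spikein.items()}
    p0, p1 = preprocess_array(a0), preprocess_array(a1)
    for k in p0.intensities:
        for i in range(2):
            v0, v1 = p0.intensities[k][i], p1.intensities[k][i]
            if v0 > 2 and v1 > 2:  # away from the floor
                assert v1 == pytest.approx(v0, abs=1.0, rel=0.05)


def test_preprocess_requires_spikeins(small_experiment):
    reference, _, arrays = small_experiment
    a = arrays[0]
    bare = type(a)(a.sample_id, a.replicate_id, a.condition_label,
                   a.intensities, {})
    with pytest.raises(CallingError, match="spike"):
        preprocess_array(bare)


# ---------------------------------------------------------------------------
# properties

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 9), st.floats(1.05, 20.0))
def test_stage1_monotone_in_pm(pair_idx, factor):
    """Raising any PM of a passing OTU never flips stage 1 to fail."""
    ref = make_reference([10, 60])
    pm_mm = {f"O1_p{j}": (400.0 + 10 * j, 100.0) for j in range(1, 11)}
    rng = np.random.default_rng(3)
    for j in range(1, 61):
        base = rng.uniform(30, 80)
        pm_mm[f"O2_p{j}"] = (base + rng.normal(0, 5), base + rng.normal(0, 5))
    array = make_array(ref, pm_mm)
    scores = response_scores(ref, array)
    before = stage1_call(ref.probesets["O1"], scores["O1"], array)
    assert before.stage1_pass

    pid = f"O1_p{pair_idx + 1}"
    pm_mm[pid] = (pm_mm[pid][0] * factor, pm_mm[pid][1])
    array2 = make_array(ref, pm_mm)
    scores2 = response_scores(ref, array2)
    after = stage1_call(ref.probesets["O1"], scores2["O1"], array2)
    assert after.stage1_pass


def test_noise_free_arrays_recover_truth_exactly():
    """No noise, no cross-hybridization: sensitivity = specificity = 1."""
    cfg = SimulationConfig(n_otus=40, n_species=20, n_phyla=3, n_groups=2,
                           noise_sd=0.0, crosshyb_rate=0.0, array_scale_sd=0.0,
                           n_indicators=1, seed=9)
    reference, truth, arrays = simulate_experiment(cfg)
    for arr in arrays:
        calls = call_array(reference, arr)
        called = {o for o, c in calls.items() if c.present}
        true = set(truth.presence.index[truth.presence[arr.sample_id]])
        eligible = {o for o in reference.otu_ids
                    if len(reference.probesets[o].pairs) >= 7}
        assert called & eligible == true & eligible
        # present OTUs have every pair strictly positive; absent none
        scores = response_scores(reference, preprocess_array(arr))
        for otu in reference.otu_ids:
            n_pos = sum(s.positive for s in scores[otu])
            if otu in true:
                assert n_pos == len(scores[otu])
            else:
                assert n_pos == 0


def test_pure_noise_arrays_rarely_called():
    """Null chip: fewer than 5% of OTU calls are positive on average."""
    cfg = SimulationConfig(n_otus=40, n_species=20, n_phyla=3, n_groups=2,
                           samples_per_group=17, presence_prob=0.0,
                           n_indicators=0, shifted_fraction=0.0, seed=13)
    reference, truth, arrays = simulate_experiment(cfg)
    assert len(arrays) >= 100
    n_calls = n_total = 0
    for arr in arrays:
        calls = call_array(reference, arr)
        n_calls += sum(c.present for c in calls.values())
        n_total += len(calls)
    assert n_calls / n_total < 0.05
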