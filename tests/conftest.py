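"""Shared fixtures: small synthetic experiments and hand-built references."""

from collections import OrderedDict

import pytest

from phylarray import (
    ProbePair,
    ProbeSet,
    ReferenceSet,
    SampleArray,
    SimulationConfig,
    TaxonomyLineage,
    simulate_experiment,
)

SMALL = SimulationConfig(
    n_otus=30, n_species=15, n_phyla=3, n_groups=2, n_indicators=1, seed=5
)


@pytest.fixture(scope="session")
def small_experiment():
    """A 30-OTU, 2-group synthetic experiment (reference, truth, arrays)."""
    return simulate_experiment(SMALL)


@pytest.fixture(scope="session")
def default_experiment():
    """The default study conditions (3 groups x 3 replicates, 120 OTUs)."""
    return simulate_experiment(SimulationConfig(seed=1))


def make_reference(pair_counts, n_species=None, at_count=10):
    """Hand-built reference: OTU ``Oi`` with ``pair_counts[i]`` probe pairs."""
    probesets = OrderedDict()
    taxonomy = OrderedDict()
    for i, n in enumerate(pair_counts):
        otu = f"O{i + 1}"
        sp = f"S{(i % n_species) + 1}" if n_species else f"S{i + 1}"
        pairs = tuple(
            ProbePair(f"{otu}_p{j + 1}", at_count) for j in range(n)
        )
        probesets[otu] = ProbeSet(otu, sp, pairs)
        taxonomy[otu] = TaxonomyLineage(
            otu, ("ph1", "cl1", "or1", "fa1", f"ge{i + 1}", sp)
        )
    return ReferenceSet(probesets, taxonomy)


def make_array(reference, pm_mm, sample_id="S", replicate_id="R1",
               condition="grp", spikein_level=5000.0):
    """Array with explicit (pm, mm) per probe; unlisted probes omitted."""
    intens = OrderedDict()
    for ps in reference.probesets.values():
        for p in ps.pairs:
            if p.probe_id in pm_mm and p.probe_id not in intens:
                intens[p.probe_id] = pm_mm[p.probe_id]
    spike = {f"CTRL_{k}": spikein_level for k in range(1, 5)}
    return SampleArray(sample_id, replicate_id, condition, intens, spike)
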