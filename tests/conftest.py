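"""Shared fixtures: synthetic corpora reused across the suite."""

import pytest

from nrekit import motif as mo
from nrekit import nre, pipeline, simulate, topology


@pytest.fixture(scope="session")
def corpus1000():
    """Default 4-class, 1000-protein corpus with exact ground truth."""
    return simulate.generate(simulate.GeneratorParams(seed=101))


@pytest.fixture(scope="session")
def analyzed1000(corpus1000):
    """Topology calls, extraction result and trimmed segments for the
    1000-protein corpus."""
    topo = topology.classify_all(corpus1000.records)
    ext = nre.extract_all(corpus1000.records, topo)
    trimmed, dropped = pipeline.trim_segments(ext.segments, 14)
    return topo, ext, trimmed, dropped


@pytest.fixture(scope="session")
def discovery200():
    """Single-class corpus of 200 proteins with a planted 21-mer
    (planting rate 0.8, substitution 0.1) and the fitted ZOOPS model."""
    spec = simulate.ClassSpec(
        "LRR-VI-2", 200,
        motif="VGPWKTGLSGQLQKAFVTGVP",
        planting_rate=0.8,
        substitution_rate=0.1,
        phospho_offsets=(6, 9),
    )
    ds = simulate.generate(simulate.GeneratorParams(classes=(spec,), seed=7))
    topo = topology.classify_all(ds.records)
    ext = nre.extract_all(ds.records, topo)
    trimmed, _ = pipeline.trim_segments(ext.segments, 14)
    disc = mo.ZoopsDiscovery(width_range=(21, 21), n_motifs=1, seed=3)
    disc.fit(trimmed)
    return ds, trimmed, disc
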