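"""End-to-end orchestration: classify -> extract -> trim -> discover ->
scan -> enrich -> phospho-map.

Each stage is importable on its own; this module only wires them together
so the command-line interface and scripted analyses share one code path.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from . import enrichment as en
from . import motif as mo
from . import nre, topology
from .model import NRESegment, PhosphoSite, PipelineConfig, ProteinRecord


@dataclass
class PipelineResult:
    topologies: dict = field(default_factory=dict)
    extraction: nre.ExtractionResult | None = None
    trimmed: list[NRESegment] = field(default_factory=list)
    too_short: int = 0
    motifs: list[mo.MotifModel] = field(default_factory=list)
    matches: list[mo.MotifMatch] = field(default_factory=list)
    enrichment: list[en.EnrichmentResult] = field(default_factory=list)
    conservation: dict[str, en.ConservationResult] = field(default_factory=dict)
    contained_sites: list[en.ContainedSite] = field(default_factory=list)
    report: list[dict] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)


def trim_segments(
    segments: list[NRESegment], n: int
) -> tuple[list[NRESegment], int]:
    """Strip the conserved C-terminal block; count segments too short to
    survive."""
    trimmed, dropped = [], 0
    for seg in segments:
        t = nre.strip_cterminal(seg, n)
        if t is None:
            dropped += 1
        else:
            trimmed.append(t)
    return trimmed, dropped


def run_pipeline(
    records: list[ProteinRecord],
    sites: list[PhosphoSite] | None = None,
    config: PipelineConfig | None = None,
    motifs: list[mo.MotifModel] | None = None,
    width_range: tuple[int, int] = (10, 22),
    width_step: int = 1,
    n_motifs: int = 1,
    discover_per_class: bool = False,
) -> PipelineResult:
    """Run the full analysis.

    When ``motifs`` is supplied, discovery is skipped and the given models
    are scanned instead.  ``discover_per_class`` runs discovery separately
    within each class's segments (class-characteristic motifs) instead of
    corpus-wide; scanning and enrichment are corpus-wide either way.
    """
    config = config or PipelineConfig()
    sites = sites or []
    result = PipelineResult()

    t0 = time.perf_counter()
    result.topologies = topology.classify_all(records, config)
    result.timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result.extraction = nre.extract_all(records, result.topologies)
    result.timings["extract"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result.trimmed, result.too_short = trim_segments(
        result.extraction.segments, config.cterm_strip
    )
    result.timings["trim"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if motifs is not None:
        result.motifs = motifs
    elif discover_per_class:
        classes = sorted({s.class_label for s in result.trimmed})
        for cls in classes:
            subset = [s for s in result.trimmed if s.class_label == cls]
            if len(subset) < 10:
                continue
            disc = mo.ZoopsDiscovery(
                width_range=width_range,
                width_step=width_step,
                n_motifs=n_motifs,
                p_threshold=config.discovery_p,
                seed=config.random_seed,
            )
            disc.fit(subset)
            for m in disc.motifs_:
                m.id = f"{cls}:{m.id}"
                result.motifs.append(m)
    else:
        disc = mo.ZoopsDiscovery(
            width_range=width_range,
            width_step=width_step,
            n_motifs=n_motifs,
            p_threshold=config.discovery_p,
            seed=config.random_seed,
        )
        disc.fit(result.trimmed)
        result.motifs = disc.motifs_
    result.timings["discover"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result.matches = mo.scan_all(result.motifs, result.trimmed, config.scan_p)
    result.timings["scan"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result.enrichment = en.filter_overrepresented(
        en.enrich(result.matches, result.trimmed), config.nf_threshold
    )
    result.contained_sites = en.map_phosphosites(result.matches, sites, result.trimmed)
    for m in result.motifs:
        cons = en.conservation_summary(
            m, result.matches, result.trimmed, result.contained_sites,
            config.identity_high, config.identity_moderate,
        )
        if cons is not None:
            result.conservation[m.id] = cons
    result.report = en.build_report(result.enrichment, result.conservation, result.motifs)
    result.timings["enrich"] = time.perf_counter() - t0
    return result
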