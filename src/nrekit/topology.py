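"""Topology assignment: RK / RLCK-with-TM / RLCK-without-TM.

TM helices normally come from external predictor annotations; when several
sources are available they are reconciled by a conservative consensus
(intersection of intervals corroborated by at least two sources).  A built-in
Kyte-Doolittle hydropathy detector serves as a fallback for proteins with no
TM annotation at all; it never overrides provided annotations.
"""

from __future__ import annotations

import logging

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .model import (
    AnnotationKind,
    PipelineConfig,
    ProteinRecord,
    TMInterval,
    TopologyCall,
    TopologyCategory,
    expand,
)

logger = logging.getLogger("nrekit")

MIN_CONSENSUS_OVERLAP = 5


def consensus_tm(intervals_by_source: dict[str, list[tuple[int, int]]]) -> list[TMInterval]:
    """Reconcile TM intervals from multiple prediction sources.

    An interval corroborated by a second source (pairwise overlap of at least
    five residues) is reported as the intersection of the overlapping pair;
    intervals with no corroboration pass through flagged ``single_source``.
    Symmetric in its sources and idempotent.
    """
    flat = [
        (start, end, src)
        for src in sorted(intervals_by_source)
        for (start, end) in sorted(intervals_by_source[src])
    ]
    out: list[TMInterval] = []
    used = set()
    for i, (s1, e1, src1) in enumerate(flat):
        if i in used:
            continue
        partner = None
        for j in range(i + 1, len(flat)):
            if j in used:
                continue
            s2, e2, src2 = flat[j]
            if src2 == src1:
                continue
            overlap = min(e1, e2) - max(s1, s2) + 1
            if overlap >= MIN_CONSENSUS_OVERLAP:
                partner = j
                break
        if partner is None:
            out.append(TMInterval(start=s1, end=e1, source=src1, single_source=True))
        else:
            s2, e2, src2 = flat[partner]
            used.add(partner)
            out.append(
                TMInterval(
                    start=max(s1, s2),
                    end=min(e1, e2),
                    source=f"consensus({src1},{src2})",
                    single_source=False,
                )
            )
    return sorted(out, key=lambda t: (t.start, t.end))


def _hydropathy(sequence: str) -> np.ndarray:
    """Per-residue Kyte-Doolittle values; degenerate letters average their
    expansion set."""
    return np.array(
        [np.mean([KYTE_DOOLITTLE[a] for a in expand(c)]) for c in sequence], dtype=float
    )


def detect_tm_fallback(
    sequence: str, window: int = 19, gravy_threshold: float = 1.6, min_length: int = 15
) -> list[TMInterval]:
    """Single-pass hydropathy TM detector (fallback when no annotation exists).

    A position qualifies when the mean Kyte-Doolittle value of the centred
    ``window`` reaches ``gravy_threshold``; maximal runs of qualifying
    positions of at least ``min_length`` residues are reported.
    """
    if window < 11 or window % 2 == 0:
        raise ValueError("window must be odd and >= 11")
    n = len(sequence)
    if n < window:
        return []
    h = _hydropathy(sequence)
    half = window // 2
    means = np.convolve(h, np.ones(window) / window, mode="valid")  # centre half..n-half-1
    qualifying = means >= gravy_threshold
    out = []
    i = 0
    while i < len(qualifying):
        if qualifying[i]:
            j = i
            while j + 1 < len(qualifying) and qualifying[j + 1]:
                j += 1
            start0, end0 = i + half, j + half  # centre positions, 0-based
            if end0 - start0 + 1 >= min_length:
                out.append(TMInterval(start=start0 + 1, end=end0 + 1, source="fallback"))
            i = j + 1
        else:
            i += 1
    return out


def tm_intervals_for(record: ProteinRecord, config: PipelineConfig | None = None) -> list[TMInterval]:
    """Annotated TM intervals grouped by source through the consensus rule;
    hydropathy fallback only when no annotation exists."""
    config = config or PipelineConfig()
    by_source: dict[str, list[tuple[int, int]]] = {}
    for a in record.annotations_of(AnnotationKind.transmembrane):
        by_source.setdefault(a.source or "annotation", []).append((a.start, a.end))
    if by_source:
        return consensus_tm(by_source)
    return detect_tm_fallback(
        record.sequence, window=config.tm_window, gravy_threshold=config.tm_gravy_threshold
    )


def assign_topology(
    record: ProteinRecord,
    tm_intervals: list[TMInterval],
    config: PipelineConfig | None = None,
) -> TopologyCall:
    """Place a protein in one of the three topological groups.

    RK: extracellular domain plus TM helix.  RLCK with TM: a TM helix, no
    ECD, and an extracellular stretch shorter than ``extracellular_max_len``
    residues.  RLCK without TM: no TM helix at all.  Anything else is
    unclassified.  With several TM helices the most N-terminal one defines
    the extracellular length.
    """
    config = config or PipelineConfig()
    has_ecd = bool(record.annotations_of(AnnotationKind.ecd))
    has_tm = bool(tm_intervals)
    extracellular_len = 0
    if has_tm:
        if len(tm_intervals) > 1:
            logger.info("%s: %d TM intervals; most N-terminal defines the extracellular length",
                        record.id, len(tm_intervals))
        first_tm = min(tm_intervals, key=lambda t: t.start)
        extracellular_len = first_tm.start - 1
        sp = record.annotations_of(AnnotationKind.signal_peptide)
        if sp:
            extracellular_len = max(0, extracellular_len - (sp[0].end - sp[0].start + 1))
    if has_ecd and has_tm:
        category = TopologyCategory.RK
    elif has_tm and not has_ecd and extracellular_len < config.extracellular_max_len:
        category = TopologyCategory.RLCK_TM
    elif not has_tm:
        category = TopologyCategory.RLCK_noTM
    else:
        category = TopologyCategory.unclassified
    return TopologyCall(
        category=category,
        has_ecd=has_ecd,
        has_tm=has_tm,
        extracellular_len=extracellular_len,
    )


def classify_all(
    records: list[ProteinRecord], config: PipelineConfig | None = None
) -> dict[str, tuple[TopologyCall, list[TMInterval]]]:
    """Topology call + TM intervals for every record (a partition)."""
    config = config or PipelineConfig()
    return {
        rec.id: (assign_topology(rec, tms, config), tms)
        for rec in records
        for tms in [tm_intervals_for(rec, config)]
    }
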