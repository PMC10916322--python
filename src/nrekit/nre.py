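"""NRE boundary determination and segment extraction.

The C-terminal boundary of an NRE is the residue immediately before the
kinase domain.  The kinase-domain start supplied by annotation is refined
using the conserved (L/I/V)GXG anchor, a 4-mer that occupies positions 5-8
of the kinase domain in the profile families covering plant RLKs: the
refinement searches near the annotated start for a placement consistent with
that anchor rather than trusting the annotation blindly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .model import (
    AnnotationKind,
    KinaseBoundary,
    NRESegment,
    ProteinRecord,
    SegmentKind,
    TMInterval,
    TopologyCall,
    TopologyCategory,
)

logger = logging.getLogger("nrekit")

ANCHOR_RE = re.compile("[LIVJ]G.G")
#: anchor 4-mer starts at domain position 5 so it occupies positions 5-8
ANCHOR_OFFSET = 4


class BoundaryConflictError(ValueError):
    """TM helix end is not upstream of the kinase-domain start."""

    def __init__(self, protein_id: str, tm_end: int, domain_start: int):
        self.tm_end = tm_end
        self.domain_start = domain_start
        super().__init__(
            f"{protein_id}: TM end {tm_end} >= kinase-domain start {domain_start}"
        )


def locate_kinase_start(
    sequence: str, approx_start: int, search_radius: int = 30
) -> KinaseBoundary:
    """Refine a kinase-domain start using the (L/I/V)GXG anchor.

    Scans candidate starts ``d`` within ``search_radius`` of the annotated
    start for one where ``sequence[d+4 .. d+7]`` (1-based, domain positions
    5-8) matches ``[LIV]G.G``; among candidates the one nearest the
    annotation wins, ties going to the smaller ``d``.  Falls back to the
    annotated start, unrefined, when no candidate exists.
    """
    n = len(sequence)
    if not (1 <= approx_start <= n):
        raise ValueError(f"approx_start {approx_start} outside sequence of length {n}")
    candidates = []
    for d in range(max(1, approx_start - search_radius), min(n, approx_start + search_radius) + 1):
        a0 = d + ANCHOR_OFFSET - 1  # 0-based anchor index
        if a0 + 4 <= n and ANCHOR_RE.fullmatch(sequence[a0 : a0 + 4]):
            candidates.append(d)
    if not candidates:
        return KinaseBoundary(domain_start=approx_start, anchor_start=approx_start, refined=False)
    best = min(candidates, key=lambda d: (abs(d - approx_start), d))
    return KinaseBoundary(domain_start=best, anchor_start=best + ANCHOR_OFFSET, refined=True)


def extract_nre(
    record: ProteinRecord,
    topology: TopologyCall,
    kinase_boundary: KinaseBoundary,
    tm_intervals: list[TMInterval] | None = None,
) -> NRESegment | None:
    """Extract the NRE segment for one protein.

    JM (TM-bearing topologies) runs from the residue after the TM helix to
    the residue before the kinase domain; NKE (cytoplasmic RLCKs) runs from
    the protein start (after any annotated signal peptide) to the residue
    before the kinase domain.  Returns None for an empty interval.
    """
    if topology.category == TopologyCategory.unclassified:
        return None
    d = kinase_boundary.domain_start
    if topology.has_tm:
        tms = tm_intervals or []
        upstream = [t for t in tms if t.end < d]
        if not upstream:
            conflicting = min(tms, key=lambda t: t.end) if tms else None
            if conflicting is not None:
                raise BoundaryConflictError(record.id, conflicting.end, d)
            raise ValueError(f"{record.id}: TM-bearing topology but no TM interval supplied")
        tm = max(upstream, key=lambda t: t.end)  # helix nearest the kinase domain
        start, kind = tm.end + 1, SegmentKind.JM
    else:
        start, kind = 1, SegmentKind.NKE
        sp = record.annotations_of(AnnotationKind.signal_peptide)
        if sp:
            start = sp[0].end + 1
    end = d - 1
    if start > end:
        return None
    has_internal_domain = any(
        a.overlaps(start, end) for a in record.annotations_of(AnnotationKind.other_domain)
    )
    return NRESegment(
        protein_id=record.id,
        start=start,
        end=end,
        sequence=record.subsequence(start, end),
        kind=kind,
        has_internal_domain=has_internal_domain,
        species=record.species,
        class_label=record.class_label,
    )


def strip_cterminal(segment: NRESegment, n: int = 14) -> NRESegment | None:
    """Drop the conserved C-terminal block before motif analysis."""
    return segment.trimmed(n)


@dataclass
class ExtractionResult:
    """Dataset-wide extraction outcome with QC counters."""

    segments: list[NRESegment] = field(default_factory=list)
    boundaries: dict[str, KinaseBoundary] = field(default_factory=dict)
    empty_segments: int = 0
    boundary_conflicts: int = 0
    no_kinase_annotation: int = 0


def extract_all(
    records: list[ProteinRecord],
    topologies: dict[str, tuple[TopologyCall, list[TMInterval]]],
    search_radius: int = 30,
    refine: bool = True,
) -> ExtractionResult:
    """Locate kinase boundaries and extract NREs for a whole dataset.

    Deterministic and independent of record order (each record is handled
    in isolation; output sorted by protein id).
    """
    result = ExtractionResult()
    for rec in sorted(records, key=lambda r: r.id):
        kin = rec.annotations_of(AnnotationKind.kinase_domain)
        if not kin:
            result.no_kinase_annotation += 1
            continue
        if refine:
            boundary = locate_kinase_start(rec.sequence, kin[0].start, search_radius)
        else:
            boundary = KinaseBoundary(
                domain_start=kin[0].start, anchor_start=kin[0].start, refined=False
            )
        result.boundaries[rec.id] = boundary
        topology, tms = topologies[rec.id]
        try:
            seg = extract_nre(rec, topology, boundary, tms)
        except BoundaryConflictError:
            result.boundary_conflicts += 1
            continue
        if seg is None:
            result.empty_segments += 1
            continue
        result.segments.append(seg)
    return result
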