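"""Class-enrichment and phosphosite-conservation statistics.

The enrichment statistic is the normalized frequency

    F = Nm^2 * Ntotal / (P * Nc^2)

where Nm counts occurrences of a motif within a class, P counts its
occurrences in the whole corpus, Nc is the class size and Ntotal the corpus
size (domain-free NRE segments).  F factors as (Nm / (P * Ac)) * (Nm / Nc)
with the abundance score Ac = Nc / Ntotal: the class's share of the motif's
occurrences relative to its share of the corpus, times the per-segment
occurrence rate in the class.  F > 1 marks overrepresentation.

Conservation of a motif is the mean sequence identity between its consensus
and its ungapped matches, I = NIm / Nm; motifs tier as highly conserved
(mean > 80%), moderately conserved (50-80%), or low.  Experimentally
determined phosphosites are mapped into match intervals, and motifs whose
consensus lacks S/T/Y at a mapped offset are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import NRESegment, PhosphoSite, expand
from .motif import MotifMatch, MotifModel

logger = logging.getLogger("nrekit")


# --- class counts and the normalized frequency ------------------------------


@dataclass(frozen=True)
class ClassCounts:
    class_label: str
    Nc: int
    Ntotal: int

    @property
    def Ac(self) -> float:
        return self.Nc / self.Ntotal


def count_classes(segments: list[NRESegment]) -> list[ClassCounts]:
    """Per-class segment counts over the analyzed corpus.

    Segments flagged ``has_internal_domain`` are excluded: the corpus for
    enrichment is the domain-free NRE set.
    """
    retained = [s for s in segments if not s.has_internal_domain]
    ntotal = len(retained)
    by_class: dict[str, int] = {}
    for s in retained:
        by_class[s.class_label] = by_class.get(s.class_label, 0) + 1
    return [ClassCounts(c, n, ntotal) for c, n in sorted(by_class.items())]


def normalized_frequency(Nm: int, P: int, Nc: int, Ntotal: int) -> float:
    """F = Nm^2 * Ntotal / (P * Nc^2), cross-checked against its factored
    form (Nm / (P * Ac)) * (Nm / Nc)."""
    if P == 0:
        raise ValueError("normalized frequency undefined for P = 0 (no occurrences)")
    if not (0 <= Nm <= P):
        raise ValueError(f"require 0 <= Nm <= P, got Nm={Nm}, P={P}")
    if not (1 <= Nc <= Ntotal):
        raise ValueError(f"require 1 <= Nc <= Ntotal, got Nc={Nc}, Ntotal={Ntotal}")
    f = (Nm * Nm * Ntotal) / (P * Nc * Nc)
    ac = Nc / Ntotal
    f_factored = (Nm / (P * ac)) * (Nm / Nc)
    assert abs(f - f_factored) <= 1e-9 * max(1.0, abs(f)), "formula forms disagree"
    return f


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    class_label: str
    Nm: int
    P: int
    Nc: int
    Ntotal: int
    F: float
    species_count: int = 0


def enrich(
    matches: list[MotifMatch],
    segments: list[NRESegment],
) -> list[EnrichmentResult]:
    """Per-(motif, class) occurrence counts and normalized frequencies.

    Nm and P count occurrences (matches), not distinct sequences; matches in
    domain-bearing segments are ignored along with those segments.
    Guarantees sum over classes of Nm == P for every motif.
    """
    class_counts = {c.class_label: c for c in count_classes(segments)}
    if not class_counts:
        return []
    ntotal = next(iter(class_counts.values())).Ntotal
    seg_by_id = {s.protein_id: s for s in segments}
    per: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    species: dict[tuple[str, str], set] = {}
    for mm in matches:
        seg = seg_by_id.get(mm.protein_id)
        if seg is None or seg.has_internal_domain:
            continue
        key = (mm.motif_id, seg.class_label)
        per[key] = per.get(key, 0) + 1
        totals[mm.motif_id] = totals.get(mm.motif_id, 0) + 1
        species.setdefault(key, set()).add(seg.species)
    out = []
    for (motif_id, cls), nm in sorted(per.items()):
        cc = class_counts.get(cls)
        if cc is None:
            continue
        out.append(
            EnrichmentResult(
                motif_id=motif_id,
                class_label=cls,
                Nm=nm,
                P=totals[motif_id],
                Nc=cc.Nc,
                Ntotal=ntotal,
                F=normalized_frequency(nm, totals[motif_id], cc.Nc, ntotal),
                species_count=len(species[(motif_id, cls)]),
            )
        )
    return out


def filter_overrepresented(
    results: list[EnrichmentResult], threshold: float = 1.0
) -> list[EnrichmentResult]:
    """Keep rows with F strictly greater than the threshold."""
    return [r for r in results if r.F > threshold]


def species_presence(
    matches: list[MotifMatch], segments: list[NRESegment]
) -> dict[str, int]:
    """Distinct species with at least one match, per motif (corpus-wide)."""
    seg_by_id = {s.protein_id: s for s in segments}
    sp: dict[str, set] = {}
    for mm in matches:
        seg = seg_by_id.get(mm.protein_id)
        if seg is not None:
            sp.setdefault(mm.motif_id, set()).add(seg.species)
    return {m: len(s) for m, s in sorted(sp.items())}


# --- phosphosite containment ------------------------------------------------


@dataclass(frozen=True)
class ContainedSite:
    protein_id: str
    position: int      # protein coordinates
    residue: str
    motif_id: str
    motif_offset: int  # 1-based within the match


def map_phosphosites(
    matches: list[MotifMatch],
    sites: list[PhosphoSite],
    segments: list[NRESegment],
) -> list[ContainedSite]:
    """Sites entirely contained in a match interval (inclusive boundaries).

    Match coordinates live within the NRE segment; they convert to protein
    coordinates through the segment start before comparison with site
    positions.
    """
    seg_by_id = {s.protein_id: s for s in segments}
    sites_by_protein: dict[str, list[PhosphoSite]] = {}
    for s in sites:
        sites_by_protein.setdefault(s.protein_id, []).append(s)
    out = []
    for mm in matches:
        seg = seg_by_id.get(mm.protein_id)
        if seg is None:
            continue
        lo = seg.start + mm.start - 1
        hi = seg.start + mm.end - 1
        for site in sites_by_protein.get(mm.protein_id, []):
            if lo <= site.position <= hi:
                out.append(
                    ContainedSite(
                        protein_id=site.protein_id,
                        position=site.position,
                        residue=site.residue,
                        motif_id=mm.motif_id,
                        motif_offset=site.position - lo + 1,
                    )
                )
    return out


# --- sequence identity and conservation tiers -------------------------------


def sequence_identity(motif_consensus: str, matched_subsequence: str) -> float:
    """I = NIm / Nm: fraction of positions where the match agrees with the
    consensus; a degenerate consensus letter agrees with any member of its
    expansion set."""
    if len(motif_consensus) != len(matched_subsequence):
        raise ValueError("consensus and match must have equal lengths")
    agree = sum(
        1 for c, m in zip(motif_consensus, matched_subsequence) if m in expand(c)
    )
    return agree / len(motif_consensus)


@dataclass
class ConservationResult:
    motif_id: str
    identities: list[float]
    mean_SI: float  # percent
    tier: str       # high / moderate / low
    contained_sites: list[ContainedSite] = field(default_factory=list)
    sty_ok: bool = True


def conservation_summary(
    motif: MotifModel,
    matches: list[MotifMatch],
    segments: list[NRESegment],
    contained_sites: list[ContainedSite],
    identity_high: float = 0.80,
    identity_moderate: float = 0.50,
) -> ConservationResult | None:
    """Mean sequence identity, conservation tier, and the S/T/Y rule.

    Tier: high when mean identity exceeds ``identity_high``; moderate within
    [moderate, high] inclusive (the boundary values fall in the moderate
    tier); low below.  ``sty_ok`` is false when any contained phosphosite
    maps to a consensus position that cannot be S, T or Y — such motifs are
    excluded from the phospho-motif report.  Returns None for motifs with no
    matches.
    """
    mine = [mm for mm in matches if mm.motif_id == motif.id]
    if not mine:
        return None
    seq_by_id = {s.protein_id: s.sequence for s in segments}
    identities = []
    for mm in mine:
        word = seq_by_id[mm.protein_id][mm.start - 1 : mm.end]
        identities.append(sequence_identity(motif.consensus, word))
    mean_si = 100.0 * float(np.mean(identities))
    if mean_si > 100.0 * identity_high:
        tier = "high"
    elif mean_si >= 100.0 * identity_moderate:
        tier = "moderate"
    else:
        tier = "low"
    my_sites = [cs for cs in contained_sites if cs.motif_id == motif.id]
    sty_ok = all(
        set(expand(motif.consensus[cs.motif_offset - 1])) & set("STY")
        for cs in my_sites
    )
    return ConservationResult(
        motif_id=motif.id,
        identities=identities,
        mean_SI=mean_si,
        tier=tier,
        contained_sites=my_sites,
        sty_ok=sty_ok,
    )


# --- the final report -------------------------------------------------------

REPORT_COLUMNS = [
    "Motif", "Class", "PhosphoSites", "SpeciesCount", "MeanSI",
    "NormalizedFrequency", "Nm", "Nc", "P", "Tier",
]


def build_report(
    enrichment: list[EnrichmentResult],
    conservation: dict[str, ConservationResult],
    motifs: list[MotifModel],
) -> list[dict]:
    """One row per (motif, class): consensus, phospho offsets ('6;9' style),
    species count, mean SI, F and the raw counts; sorted by mean SI
    descending.  Motifs failing the S/T/Y rule are excluded and counted."""
    consensus_by_id = {m.id: m.consensus for m in motifs}
    excluded_sty = 0
    rows = []
    for er in enrichment:
        cons = conservation.get(er.motif_id)
        if cons is None:
            continue
        if not cons.sty_ok:
            excluded_sty += 1
            continue
        offsets = sorted({cs.motif_offset for cs in cons.contained_sites})
        rows.append(
            {
                "Motif": consensus_by_id.get(er.motif_id, er.motif_id),
                "Class": er.class_label,
                "PhosphoSites": ";".join(str(o) for o in offsets),
                "SpeciesCount": er.species_count,
                "MeanSI": round(cons.mean_SI, 1),
                "NormalizedFrequency": round(er.F, 1),
                "Nm": er.Nm,
                "Nc": er.Nc,
                "P": er.P,
                "Tier": cons.tier,
            }
        )
    if excluded_sty:
        logger.info("build_report: %d (motif, class) rows excluded by the S/T/Y rule",
                    excluded_sty)
    rows.sort(key=lambda r: (-r["MeanSI"], r["Motif"], r["Class"]))
    return rows
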