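"""Domain types shared across the NRE analysis pipeline.

The objects here mirror the biology: a plant receptor-like kinase (RLK) is
either a receptor kinase (RK: extracellular domain + transmembrane helix +
cytoplasmic kinase domain), a receptor-like cytoplasmic kinase with a
membrane anchor (RLCK with TM), or a fully cytoplasmic RLCK.  The N-terminal
regulatory element (NRE) is the stretch between the membrane (or the protein
start) and the kinase domain: the juxtamembrane segment (JM) for TM-bearing
proteins, the N-terminal kinase extension (NKE) otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

# --- alphabet ---------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Degenerate letters admitted in sequences and motif consensi, with their
#: expansion sets.  B/Z/J appear in published motif strings; X is fully
#: ambiguous.
DEGENERATE = {
    "B": "DN",
    "Z": "EQ",
    "J": "IL",
    "X": AMINO_ACIDS,
}

ALPHABET = set(AMINO_ACIDS) | set(DEGENERATE)


def expand(letter: str) -> str:
    """Expansion set of a (possibly degenerate) amino-acid letter."""
    return DEGENERATE.get(letter, letter)


def validate_sequence(seq: str) -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"sequence contains letters outside the alphabet: {sorted(bad)}")


# --- annotations and records ------------------------------------------------


class AnnotationKind(str, enum.Enum):
    transmembrane = "transmembrane"
    kinase_domain = "kinase_domain"
    ecd = "ecd"
    signal_peptide = "signal_peptide"
    other_domain = "other_domain"


@dataclass(frozen=True)
class DomainAnnotation:
    """A feature interval on a protein, 1-based and inclusive on both ends."""

    kind: AnnotationKind
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad annotation interval [{self.start}, {self.end}]")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class ProteinRecord:
    id: str
    species: str
    class_label: str
    sequence: str
    annotations: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        validate_sequence(self.sequence)

    def annotations_of(self, kind: AnnotationKind) -> list[DomainAnnotation]:
        return [a for a in self.annotations if a.kind == kind]

    def subsequence(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.sequence[start - 1 : end]


# --- topology ---------------------------------------------------------------


class TopologyCategory(str, enum.Enum):
    RK = "RK"
    RLCK_TM = "RLCK_TM"
    RLCK_noTM = "RLCK_noTM"
    unclassified = "unclassified"


@dataclass(frozen=True)
class TMInterval:
    """A transmembrane helix interval (1-based inclusive).

    ``single_source`` marks intervals that were not corroborated by a second
    prediction source.
    """

    start: int
    end: int
    source: str = ""
    single_source: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"bad TM interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TopologyCall:
    category: TopologyCategory
    has_ecd: bool
    has_tm: bool
    extracellular_len: int = 0

    def __post_init__(self):
        c = self.category
        if c == TopologyCategory.RK and not (self.has_ecd and self.has_tm):
            raise ValueError("RK requires both ECD and TM")
        if c == TopologyCategory.RLCK_TM and not (self.has_tm and not self.has_ecd):
            raise ValueError("RLCK_TM requires TM and no ECD")
        if c == TopologyCategory.RLCK_noTM and self.has_tm:
            raise ValueError("RLCK_noTM excludes TM")


# --- NRE segments -----------------------------------------------------------


class SegmentKind(str, enum.Enum):
    JM = "JM"    # juxtamembrane: TM end -> kinase-domain start
    NKE = "NKE"  # N-terminal kinase extension: protein start -> kinase-domain start


@dataclass(frozen=True)
class NRESegment:
    protein_id: str
    start: int
    end: int
    sequence: str
    kind: SegmentKind
    has_internal_domain: bool = False
    species: str = ""
    class_label: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"empty NRE interval [{self.start}, {self.end}]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("NRE sequence length disagrees with coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def trimmed(self, n: int) -> Optional["NRESegment"]:
        """Remove the last ``n`` residues (the conserved C-terminal block).

        Returns None when nothing would remain.
        """
        if n < 0:
            raise ValueError("n must be >= 0")
        if self.length <= n:
            return None
        if n == 0:
            return self
        return replace(self, end=self.end - n, sequence=self.sequence[:-n])


# --- kinase boundary --------------------------------------------------------


@dataclass(frozen=True)
class KinaseBoundary:
    """Kinase-domain start, optionally refined by the (L/I/V)GXG anchor.

    When ``refined`` the anchor 4-mer occupies positions 5-8 of the domain,
    i.e. ``anchor_start == domain_start + 4`` in protein coordinates.
    """

    domain_start: int
    anchor_start: int
    refined: bool

    @property
    def anchor_offset(self) -> int:
        """1-based position of the anchor's first residue within the domain."""
        return self.anchor_start - self.domain_start + 1


# --- phosphosites -----------------------------------------------------------


@dataclass(frozen=True)
class PhosphoSite:
    protein_id: str
    position: int  # 1-based residue index in the protein
    residue: str   # S, T or Y
    source: str = ""

    def __post_init__(self):
        if self.residue not in "STY":
            raise ValueError(f"phosphosite residue must be S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError("phosphosite position must be >= 1")


# --- configuration ----------------------------------------------------------


@dataclass
class PipelineConfig:
    """All pipeline tunables.

    extracellular_max_len: proteins with a TM but no ECD count as RLCK-with-TM
        only when fewer than this many residues precede the first TM helix
        (60 residues = 180 coding nucleotides).
    scale_bins: number of bins NRE segments are rescaled to for positional
        composition profiles.
    terminal_window: residues taken from each NRE end for logo matrices.
    discovery_p / scan_p: significance thresholds for motif discovery and for
        PWM scanning.
    cterm_strip: length of the conserved C-terminal block removed before
        motif discovery.
    identity_high / identity_moderate: conservation-tier cuts on mean
        sequence identity.
    nf_threshold: motifs are kept when normalized frequency exceeds this.
    tm_window / tm_gravy_threshold: fallback hydropathy TM detector settings.
    """

    extracellular_max_len: int = 60
    scale_bins: int = 200
    terminal_window: int = 20
    discovery_p: float = 0.005
    scan_p: float = 0.001
    cterm_strip: int = 14
    identity_high: float = 0.80
    identity_moderate: float = 0.50
    nf_threshold: float = 1.0
    tm_window: int = 19
    tm_gravy_threshold: float = 1.6
    random_seed: int = 0

    def __post_init__(self):
        for name in ("extracellular_max_len", "scale_bins", "terminal_window",
                     "discovery_p", "scan_p", "tm_window", "tm_gravy_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cterm_strip < 0:
            raise ValueError("cterm_strip must be >= 0")
        if not (self.identity_moderate < self.identity_high <= 1):
            raise ValueError("require identity_moderate < identity_high <= 1")
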