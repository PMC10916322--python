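"""Length, composition and signature profiling of NRE segments.

Covers: binned length distributions; position-scaled composition (every
segment rescaled onto a common 200-bin axis, each residue spreading its unit
mass over its exact fractional bin span so total mass is conserved);
terminal 20-residue logo matrices with per-column Shannon information
content; detection of the conserved 14-residue C-terminal consensus
FSYEELEKAT[D/N]NF[S/D] with its TxxF ST-motif; and the two-type rule for
the LRR-VI-2 class (phosphoserine at -28 plus the class motif).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AMINO_ACIDS, AA_INDEX, NRESegment, SegmentKind, expand

LOG2_20 = float(np.log2(20.0))

#: the 14-residue C-terminal consensus; degenerate positions hold the
#: alternatives seen in the family-wide logos
SIGNATURE = ("F", "S", "Y", "E", "E", "L", "E", "K", "A", "T", "DN", "N", "F", "SD")
SIGNATURE_WIDTH = len(SIGNATURE)


# --- length -----------------------------------------------------------------


def length_distribution(
    segments: list[NRESegment], bin_width: int = 2
) -> pd.DataFrame:
    """Histogram of NRE lengths, stratified by segment kind and class.

    Returns one row per (kind, class_label, bin_start) with the count; bins
    are [bin_start, bin_start + bin_width).
    """
    if not segments:
        raise ValueError("no segments")
    rows = []
    for (kind, cls), group in _group_by(segments):
        lengths = np.array([s.length for s in group])
        bins = (lengths // bin_width) * bin_width
        for b, n in sorted(Counter(bins.tolist()).items()):
            rows.append({"kind": kind, "class_label": cls, "bin_start": int(b),
                         "bin_width": bin_width, "count": int(n)})
    return pd.DataFrame(rows)


def length_summary(segments: list[NRESegment]) -> dict:
    lengths = np.array([s.length for s in segments])
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {
        "n": len(lengths),
        "mode": int(Counter(lengths.tolist()).most_common(1)[0][0]),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
    }


def _group_by(segments):
    keyed: dict[tuple[str, str], list[NRESegment]] = {}
    for s in segments:
        keyed.setdefault((s.kind.value, s.class_label), []).append(s)
    return sorted(keyed.items())


# --- scaled composition -----------------------------------------------------


@dataclass
class ScaledProfile:
    """Composition along a common position axis.

    ``matrix``: bins x 21 (20 amino acids + a final 'other' column for
    degenerate letters) of per-bin frequency; ``support``: per-bin total
    residue mass.  Each residue of a length-L segment spreads its unit mass
    over the fractional bin interval [(i-1)*B/L, i*B/L), so the grand total
    equals the summed segment lengths exactly.
    """

    matrix: np.ndarray
    support: np.ndarray
    letters: str = AMINO_ACIDS + "*"

    @property
    def bins(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.letters))
        df.insert(0, "bin", np.arange(self.bins))
        df["support"] = self.support
        return df


def scaled_composition(
    segments: list[NRESegment], bins: int = 200, weight: str = "residue"
) -> ScaledProfile:
    """Rescale every segment onto ``bins`` positions and tally composition.

    ``weight='residue'`` gives every residue unit mass (longer segments
    contribute more, as in pooling all residues); ``weight='sequence'``
    normalizes each segment to total mass 1 first.
    """
    if weight not in ("residue", "sequence"):
        raise ValueError("weight must be 'residue' or 'sequence'")
    mass = np.zeros((bins, 21), dtype=float)
    for seg in segments:
        L = seg.length
        seg_scale = 1.0 / L if weight == "sequence" else 1.0
        for i, letter in enumerate(seg.sequence):  # i is 0-based residue index
            col = AA_INDEX.get(letter, 20)
            lo = i * bins / L
            hi = (i + 1) * bins / L
            b0, b1 = int(np.floor(lo)), min(int(np.ceil(hi)), bins)
            for b in range(b0, b1):
                overlap = min(hi, b + 1) - max(lo, b)
                if overlap > 0:
                    # unit residue mass spread over a span of B/L bins
                    mass[b, col] += overlap * (L / bins) * seg_scale
    support = mass.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(support[:, None] > 0, mass / support[:, None], 0.0)
    return ScaledProfile(matrix=freq, support=support)


# --- terminal logos ---------------------------------------------------------


@dataclass
class LogoMatrix:
    """Per-position letter frequencies with information content in bits.

    ``ic[j] = log2(20) - H(column j)``; no small-sample correction (intended
    for large n; ``n`` is reported so users can judge).
    """

    columns: np.ndarray  # W x 20 frequencies
    ic: np.ndarray       # W, bits
    n: int
    skipped_short: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.columns, columns=list(AMINO_ACIDS))
        df.insert(0, "position", np.arange(1, len(self.ic) + 1))
        df["ic_bits"] = self.ic
        df["n"] = self.n
        return df


def terminal_logo(
    segments: list[NRESegment], window: int = 20, end: str = "C"
) -> LogoMatrix:
    """Logo matrix over the first/last ``window`` residues of each segment.

    Segments shorter than the window are excluded and counted; degenerate
    letters distribute fractionally over their expansion sets.
    """
    if end not in ("N", "C"):
        raise ValueError("end must be 'N' or 'C'")
    counts = np.zeros((window, 20), dtype=float)
    n = 0
    skipped = 0
    for seg in segments:
        if seg.length < window:
            skipped += 1
            continue
        chunk = seg.sequence[:window] if end == "N" else seg.sequence[-window:]
        for j, letter in enumerate(chunk):
            members = expand(letter)
            w = 1.0 / len(members)
            for m in members:
                counts[j, AA_INDEX[m]] += w
        n += 1
    if n == 0:
        raise ValueError("all segments shorter than the logo window")
    freqs = counts / n
    ic = np.empty(window)
    for j in range(window):
        p = freqs[j][freqs[j] > 0]
        ic[j] = LOG2_20 - float(-(p * np.log2(p)).sum())
    ic = np.clip(ic, 0.0, LOG2_20)
    return LogoMatrix(columns=freqs, ic=ic, n=n, skipped_short=skipped)


# --- the 14-residue C-terminal signature ------------------------------------


@dataclass
class SignatureHit:
    """Best match of the 14-residue consensus near a segment's C-terminus.

    ``st_motif_present`` marks the helix-capping ST motif (T-x-x-F read at
    segment positions -5..-2, -1 being the last residue); ``thr_minus5``
    marks the conserved threonine at -5 on its own.
    """

    start: int  # 1-based within the segment
    end: int
    agreements: int
    matched: tuple[bool, ...]
    st_motif_present: bool
    thr_minus5: bool


def find_signature(
    sequence: str, min_agreements: int = 10, search_window: int = 40
) -> SignatureHit | None:
    """Scan the C-terminal ``search_window`` residues for the 14-aa consensus.

    Returns the best ungapped placement with at least ``min_agreements``/14
    positional agreements (degenerate consensus positions agree on either
    alternative); ties go to the placement nearest the C-terminus.
    """
    n = len(sequence)
    if n < SIGNATURE_WIDTH:
        return None
    lo = max(0, n - search_window)
    best = None
    for off in range(lo, n - SIGNATURE_WIDTH + 1):
        word = sequence[off : off + SIGNATURE_WIDTH]
        matched = tuple(
            any(e in expand(c) for e in allowed) or c in allowed
            for c, allowed in zip(word, SIGNATURE)
        )
        agree = sum(matched)
        if best is None or agree >= best[0]:  # >= : later (more C-terminal) wins ties
            best = (agree, off, matched)
    if best is None or best[0] < min_agreements:
        return None
    agree, off, matched = best
    st = n >= 5 and sequence[-5] == "T" and sequence[-2] == "F"
    return SignatureHit(
        start=off + 1,
        end=off + SIGNATURE_WIDTH,
        agreements=agree,
        matched=matched,
        st_motif_present=st,
        thr_minus5=(n >= 5 and sequence[-5] == "T"),
    )


# --- LRR-VI-2 typing --------------------------------------------------------


class LRRVI2Type(str, enum.Enum):
    type1 = "type1"  # phosphosite region present: S at -28 plus the class motif
    type2 = "type2"


def classify_lrr_vi_2_type(
    segment: NRESegment, has_class_motif_match: bool
) -> tuple[LRRVI2Type, bool]:
    """Two-type rule for LRR-VI-2 NREs.

    Type 1 requires the phosphoserine position: S at -28 from the C-terminus
    (-1 = last residue) AND a scan match of the class motif; everything else
    is type 2.  Segments too short to reach -31 are type 2 with a flag.
    Returns (type, too_short_flag).
    """
    if segment.length < 31:
        return LRRVI2Type.type2, True
    s_at_28 = segment.sequence[-28] == "S"
    if s_at_28 and has_class_motif_match:
        return LRRVI2Type.type1, False
    return LRRVI2Type.type2, False


# --- occurrence summaries ---------------------------------------------------


def summarize_occurrence(
    records,
    topologies,
    species_to_group: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Contingency counts: plant group x class x topology category.

    Adds a per-(group, class) percentage of TM-bearing topologies.  Species
    absent from the mapping fall into group 'unknown'.
    """
    species_to_group = species_to_group or {}
    rows: dict[tuple[str, str, str], int] = {}
    for rec in records:
        call, _ = topologies[rec.id]
        group = species_to_group.get(rec.species, "unknown")
        key = (group, rec.class_label, call.category.value)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [{"group": g, "class_label": c, "category": cat, "count": n}
         for (g, c, cat), n in sorted(rows.items())]
    )
    if df.empty:
        return df
    out = []
    for (g, c), sub in df.groupby(["group", "class_label"]):
        total = sub["count"].sum()
        tm = sub.loc[sub["category"].isin(["RK", "RLCK_TM"]), "count"].sum()
        for _, r in sub.iterrows():
            out.append({**r.to_dict(), "tm_bearing_pct": 100.0 * tm / total})
    return pd.DataFrame(out)
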