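"""Synthetic RLK datasets with exact ground truth.

Each synthetic protein is assembled the way the real architectures read:
an optional signal peptide, an extracellular filler for receptor kinases, a
hydrophobic transmembrane 21-mer for TM-bearing topologies, then the NRE —
a basic (R/K-rich) N-terminal run, a serine-rich middle optionally carrying
a planted class motif with per-position substitution noise, a one-residue
spacer and the 14-residue C-terminal consensus FSYEELEKAT[D/N]NF[S/D] —
followed by a kinase-domain stub whose residues 5-8 form the (L/I/V)GXG
anchor.  Phosphosites are emitted at declared motif offsets.  The region
around the kinase-domain start is rejection-sampled so that no second
anchor 4-mer can confuse boundary refinement.  Everything is deterministic
given the seed.

The generator emulates letter-level features only (length mixture, serine
enrichment, basic N-terminus, planted motifs, terminal consensus); it makes
no attempt at realistic higher-order k-mer statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AMINO_ACIDS, ProteinRecord, DomainAnnotation, AnnotationKind
from . import io as nio

HYDROPHILIC = "DENQKRSTHAP"
TM_LETTERS = "LIVFMA"
TM_WEIGHTS = np.array([0.34, 0.22, 0.22, 0.10, 0.06, 0.06])
BASIC = "RK"
#: stub filler avoids G so the planted anchor stays unique near the boundary
STUB_LETTERS = "ADEFHIKLMNPQRSTVWY".replace("I", "").replace("L", "").replace("V", "")
SIGNATURE_TAIL = "FSYEELEKAT{x1}NF{x2}"
ANCHOR_GUARD = 45  # no second [LIV]G.G candidate within this radius


@dataclass(frozen=True)
class ClassSpec:
    """One Shiu class in the synthetic corpus."""

    name: str
    n_proteins: int
    motif: str | None = None         # planted consensus, or None
    planting_rate: float = 0.8
    substitution_rate: float = 0.1
    phospho_offsets: tuple[int, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.planting_rate <= 1.0):
            raise ValueError("planting_rate must be in [0, 1]")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("substitution_rate must be in [0, 1]")


#: default classes: motifs and phospho offsets follow published class motifs
#: (LRR-VI-2 carries pT at offset 6 and pS at offset 9 of its 21-mer)
DEFAULT_CLASSES = (
    ClassSpec("LRR-VI-2", 250, motif="VGPWKTGLSGQLQKAFVTGVP", phospho_offsets=(6, 9)),
    ClassSpec("PERK-2", 250, motif="SQPKVLRLNLVGSPKKEPEP", phospho_offsets=(13,)),
    ClassSpec("LRR-XI-1", 250, motif="SWPWKLTAFQ", phospho_offsets=(7,)),
    ClassSpec("RLCK-XII-2", 250, motif="NGSILLEKLIASCNGKSNPIR", phospho_offsets=()),
)


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic corpus.

    The topology mix follows the family-wide proportions of RKs, RLCKs with
    a TM helix, and cytoplasmic RLCKs (about 61/9/30); NRE lengths come
    from an equal mixture of normals with modes 40 and 50 residues (the
    observed length peak), resampled into the feasible range; the mid-NRE is
    serine-enriched.
    """

    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    topology_mix: tuple[float, float, float] = (0.61, 0.09, 0.30)  # RK, RLCK_TM, RLCK_noTM
    nre_length_modes: tuple[float, float] = (40.0, 50.0)
    nre_length_sds: tuple[float, float] = (8.0, 8.0)
    nre_length_weights: tuple[float, float] = (0.5, 0.5)
    serine_rate: float = 0.25
    basic_run: int = 6
    tail_dn_probs: tuple[float, float] = (0.7, 0.3)  # P(D), P(N) at consensus pos 11
    tail_sd_probs: tuple[float, float] = (0.6, 0.4)  # P(S), P(D) at consensus pos 14
    signal_peptide_prob: float = 0.5
    ecd_length: tuple[int, int] = (100, 160)
    tm_length: int = 21
    kinase_stub_length: int = 60
    background_sites_rate: float = 0.0  # extra random S/T/Y sites per protein
    n_species: int = 6
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.topology_mix) - 1.0) > 1e-9:
            raise ValueError("topology mix must sum to 1")
        for spec in self.classes:
            if spec.motif is not None:
                min_len = self.basic_run + len(spec.motif) + 1 + 14 + 2
                limit = max(self.nre_length_modes) + 4 * max(self.nre_length_sds)
                if min_len > limit:
                    raise ValueError(
                        f"class {spec.name}: NRE length distribution cannot fit "
                        f"motif + consensus tail (needs >= {min_len})"
                    )


@dataclass(frozen=True)
class ProteinTruth:
    protein_id: str
    category: str
    tm_interval: tuple[int, int] | None
    kinase_start: int
    nre_interval: tuple[int, int]
    motif_interval: tuple[int, int] | None  # protein coordinates
    phospho_positions: tuple[int, ...]


@dataclass
class SyntheticDataset:
    records: list[ProteinRecord]
    annotation_rows: list[dict]
    phospho_rows: list[dict]
    truth: dict[str, ProteinTruth]
    params: GeneratorParams = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit exactly the formats the readers consume, plus a truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "annotations": outdir / "annotations.tsv",
            "phosphosites": outdir / "phosphosites.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
        nio.write_table(
            self.annotation_rows, nio.ANNOTATION_COLUMNS, paths["annotations"],
            key_columns=["protein_id", "start", "kind"],
        )
        nio.write_table(
            self.phospho_rows, nio.PHOSPHOSITE_COLUMNS + ["source"], paths["phosphosites"],
            key_columns=["protein_id", "position"],
        )
        truth_rows = [
            {
                "protein_id": t.protein_id,
                "category": t.category,
                "tm_start": t.tm_interval[0] if t.tm_interval else "",
                "tm_end": t.tm_interval[1] if t.tm_interval else "",
                "kinase_start": t.kinase_start,
                "nre_start": t.nre_interval[0],
                "nre_end": t.nre_interval[1],
                "motif_start": t.motif_interval[0] if t.motif_interval else "",
                "motif_end": t.motif_interval[1] if t.motif_interval else "",
                "phospho_positions": ";".join(map(str, t.phospho_positions)),
            }
            for t in self.truth.values()
        ]
        nio.write_table(
            truth_rows,
            ["protein_id", "category", "tm_start", "tm_end", "kinase_start",
             "nre_start", "nre_end", "motif_start", "motif_end", "phospho_positions"],
            paths["truth"],
        )
        return paths


def _sample_letters(rng, letters: str, n: int, weights=None) -> str:
    idx = rng.choice(len(letters), size=n, p=weights)
    return "".join(letters[i] for i in idx)


def _mid_filler(rng, n: int, serine_rate: float) -> str:
    """Serine-enriched mid-NRE filler."""
    out = []
    others = "ADEFGHIKLMNPQRTVWY"  # includes G; anchor guard handles collisions
    for _ in range(n):
        if rng.random() < serine_rate:
            out.append("S")
        else:
            out.append(others[rng.integers(len(others))])
    return "".join(out)


def _noisy_motif(rng, consensus: str, sub_rate: float) -> str:
    out = []
    for c in consensus:
        if rng.random() < sub_rate:
            choices = AMINO_ACIDS.replace(c, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(c)
    return "".join(out)


def _draw_nre_length(rng, params: GeneratorParams, min_len: int) -> int:
    """Mixture-of-normals draw, resampled into the feasible range."""
    for _ in range(1000):
        k = int(rng.random() >= params.nre_length_weights[0])
        L = int(round(rng.normal(params.nre_length_modes[k], params.nre_length_sds[k])))
        if L >= min_len:
            return L
    return min_len


def _tail(rng, params: GeneratorParams) -> str:
    x1 = "D" if rng.random() < params.tail_dn_probs[0] else "N"
    x2 = "S" if rng.random() < params.tail_sd_probs[0] else "D"
    return SIGNATURE_TAIL.format(x1=x1, x2=x2)


def _kinase_stub(rng, n: int) -> str:
    head = _sample_letters(rng, STUB_LETTERS, 4)
    anchor = "LIV"[rng.integers(3)] + "G" + AMINO_ACIDS[rng.integers(20)] + "G"
    rest = _sample_letters(rng, STUB_LETTERS, n - 8)
    return head + anchor + rest


def _anchor_candidates(sequence: str, center: int, radius: int) -> list[int]:
    """Candidate domain starts d in [center-radius, center+radius] whose
    positions d+4..d+7 (1-based) match [LIV]G.G."""
    import re

    pat = re.compile("[LIV]G.G")
    n = len(sequence)
    out = []
    for d in range(max(1, center - radius), min(n, center + radius) + 1):
        a0 = d + 3
        if a0 + 4 <= n and pat.fullmatch(sequence[a0 : a0 + 4]):
            out.append(d)
    return out


def generate(params: GeneratorParams | None = None) -> SyntheticDataset:
    """Build a fully-annotated synthetic corpus with exact ground truth."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)
    records: list[ProteinRecord] = []
    annotation_rows: list[dict] = []
    phospho_rows: list[dict] = []
    truth: dict[str, ProteinTruth] = {}
    categories = ("RK", "RLCK_TM", "RLCK_noTM")
    pid_counter = 0

    for spec in params.classes:
        for _ in range(spec.n_proteins):
            pid_counter += 1
            pid = f"P{pid_counter:05d}"
            species = f"species{int(rng.integers(params.n_species)) + 1:02d}"
            category = categories[rng.choice(3, p=params.topology_mix)]
            planted = spec.motif is not None and rng.random() < spec.planting_rate

            for _attempt in range(200):
                seq, annots, t, sites = _assemble(
                    rng, params, spec, pid, category, planted
                )
                cands = _anchor_candidates(seq, t.kinase_start, ANCHOR_GUARD)
                if cands == [t.kinase_start]:
                    break
            else:
                raise RuntimeError(f"{pid}: could not satisfy anchor uniqueness")

            records.append(
                ProteinRecord(
                    id=pid, species=species, class_label=spec.name,
                    sequence=seq,
                    annotations=sorted(annots, key=lambda a: a.start),
                )
            )
            for a in annots:
                annotation_rows.append(
                    {
                        "protein_id": pid, "species": species, "class_label": spec.name,
                        "kind": a.kind.value, "start": a.start, "end": a.end,
                        "source": a.source,
                    }
                )
            for pos in sites:
                phospho_rows.append(
                    {
                        "protein_id": pid, "position": pos,
                        "residue": seq[pos - 1], "source": "synthetic",
                    }
                )
            if params.background_sites_rate > 0:
                n_extra = rng.poisson(params.background_sites_rate)
                sty_pos = [i + 1 for i, c in enumerate(seq) if c in "STY"]
                for _ in range(n_extra):
                    if sty_pos:
                        pos = int(sty_pos[rng.integers(len(sty_pos))])
                        phospho_rows.append(
                            {"protein_id": pid, "position": pos,
                             "residue": seq[pos - 1], "source": "background"}
                        )
            truth[pid] = t

    return SyntheticDataset(
        records=records,
        annotation_rows=annotation_rows,
        phospho_rows=phospho_rows,
        truth=truth,
        params=params,
    )


def _assemble(rng, params, spec, pid, category, planted):
    """One protein: sequence, annotations, truth, phosphosite positions."""
    annots: list[DomainAnnotation] = []
    parts: list[str] = []
    pos = 0  # length so far

    def push(s: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        parts.append(s)
        pos += len(s)
        return start, pos

    if category == "RK":
        if rng.random() < params.signal_peptide_prob:
            s, e = push(_sample_letters(rng, "LIVFMA", 16) + "ASA")
            annots.append(DomainAnnotation(AnnotationKind.signal_peptide, s, e, "synthetic"))
        ecd_len = int(rng.integers(*params.ecd_length))
        s, e = push(_sample_letters(rng, HYDROPHILIC, ecd_len))
        annots.append(DomainAnnotation(AnnotationKind.ecd, s, e, "synthetic"))
    elif category == "RLCK_TM":
        ext_len = int(rng.integers(5, 45))  # < 60-residue extracellular stretch
        push(_sample_letters(rng, HYDROPHILIC, ext_len))

    tm_interval = None
    if category in ("RK", "RLCK_TM"):
        s, e = push(_sample_letters(rng, TM_LETTERS, params.tm_length, TM_WEIGHTS))
        tm_interval = (s, e)
        annots.append(DomainAnnotation(AnnotationKind.transmembrane, s, e, "synthetic"))

    # --- the NRE ---
    tail = _tail(rng, params)
    motif_word = None
    if planted:
        motif_word = _noisy_motif(rng, spec.motif, spec.substitution_rate)
        min_len = params.basic_run + len(motif_word) + 1 + len(tail) + 2
    else:
        min_len = params.basic_run + len(tail) + 4
    L = _draw_nre_length(rng, params, min_len)

    nre_start = pos + 1
    push(_sample_letters(rng, BASIC, params.basic_run))
    motif_interval = None
    phospho_positions: list[int] = []
    if planted:
        fill = L - params.basic_run - len(motif_word) - 1 - len(tail)
        push(_mid_filler(rng, fill, params.serine_rate))
        ms, me = push(motif_word)
        motif_interval = (ms, me)
        for off in spec.phospho_offsets:
            p = ms + off - 1
            if motif_word[off - 1] in "STY":  # noise may have destroyed the site
                phospho_positions.append(p)
        push(_mid_filler(rng, 1, params.serine_rate))  # spacer
    else:
        push(_mid_filler(rng, L - params.basic_run - len(tail), params.serine_rate))
    push(tail)
    nre_end = pos

    kinase_start = pos + 1
    s, e = push(_kinase_stub(rng, params.kinase_stub_length))
    annots.append(DomainAnnotation(AnnotationKind.kinase_domain, s, e, "synthetic"))

    seq = "".join(parts)
    t = ProteinTruth(
        protein_id=pid,
        category=category,
        tm_interval=tm_interval,
        kinase_start=kinase_start,
        nre_interval=(nre_start, nre_end),
        motif_interval=motif_interval,
        phospho_positions=tuple(phospho_positions),
    )
    return seq, annots, t, phospho_positions


def corrupt(
    dataset: SyntheticDataset,
    annotation_jitter: int = 0,
    dropout: float = 0.0,
    seed: int = 0,
) -> list[dict]:
    """Perturbed annotation rows: kinase starts jittered, TM rows dropped.

    Truth is untouched; the returned rows exercise boundary refinement and
    the hydropathy fallback.
    """
    if annotation_jitter < 0:
        raise ValueError("annotation_jitter must be >= 0")
    if not (0.0 <= dropout < 1.0):
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lengths = {r.id: len(r.sequence) for r in dataset.records}
    out = []
    for row in dataset.annotation_rows:
        row = dict(row)
        if row["kind"] == "transmembrane" and rng.random() < dropout:
            continue
        if row["kind"] == "kinase_domain" and annotation_jitter > 0:
            shift = int(rng.integers(-annotation_jitter, annotation_jitter + 1))
            n = lengths[row["protein_id"]]
            row["start"] = int(np.clip(row["start"] + shift, 1, n))
            row["end"] = int(np.clip(row["end"], row["start"], n))
        out.append(row)
    return out
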