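"""Readers and writers for the pipeline's external formats.

Sequences travel as FASTA (via Biopython); annotations, phosphosites and all
reports are tab-separated tables with a header line.  Every reader keeps QC
counters so that dropped + kept always equals the number of input rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .model import (
    AnnotationKind,
    DomainAnnotation,
    PhosphoSite,
    PipelineConfig,
    ProteinRecord,
)

logger = logging.getLogger("nrekit")

ANNOTATION_COLUMNS = ["protein_id", "species", "class_label", "kind", "start", "end", "source"]
PHOSPHOSITE_COLUMNS = ["protein_id", "position", "residue"]


@dataclass
class QCSummary:
    """Row bookkeeping for a reader: kept + dropped == input."""

    input_rows: int = 0
    kept_rows: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    @property
    def dropped_rows(self) -> int:
        return sum(self.dropped.values())


def read_proteins(
    fasta_path: str | Path, annotation_table_path: str | Path
) -> tuple[list[ProteinRecord], QCSummary]:
    """Load proteins from FASTA plus a per-protein annotation table.

    The annotation table carries one row per feature interval with columns
    ``protein_id, species, class_label, kind, start, end, source``; rows whose
    interval exceeds the sequence, or that point at an unknown protein or an
    unknown feature kind, are dropped and counted in the QC summary.
    """
    fasta_path = Path(fasta_path)
    annotation_table_path = Path(annotation_table_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not annotation_table_path.exists():
        raise FileNotFoundError(annotation_table_path)

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(annotation_table_path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")

    qc = QCSummary(input_rows=len(table))
    meta: dict[str, tuple[str, str]] = {}
    annots: dict[str, list[DomainAnnotation]] = {pid: [] for pid in seqs}

    for row in table.itertuples(index=False):
        pid = row.protein_id
        if pid not in seqs:
            logger.warning("annotation row for unknown protein %s dropped", pid)
            qc.drop("unknown_protein")
            continue
        try:
            kind = AnnotationKind(row.kind)
        except ValueError:
            logger.warning("annotation row for %s has unknown kind %r", pid, row.kind)
            qc.drop("unknown_kind")
            continue
        start, end = int(row.start), int(row.end)
        if not (1 <= start <= end <= len(seqs[pid])):
            logger.warning(
                "annotation [%d,%d] exceeds %s (len %d); row dropped",
                start, end, pid, len(seqs[pid]),
            )
            qc.drop("interval_out_of_range")
            continue
        meta.setdefault(pid, (row.species, row.class_label))
        annots[pid].append(DomainAnnotation(kind=kind, start=start, end=end, source=row.source or ""))
        qc.kept_rows += 1

    records = []
    for pid, seq in seqs.items():
        species, class_label = meta.get(pid, ("", ""))
        records.append(
            ProteinRecord(
                id=pid,
                species=species,
                class_label=class_label,
                sequence=seq,
                annotations=sorted(annots[pid], key=lambda a: (a.start, a.end, a.kind.value)),
            )
        )
    logger.info("read_proteins: %d proteins, %d/%d annotation rows kept",
                len(records), qc.kept_rows, qc.input_rows)
    return records, qc


def read_phosphosites(
    tsv_path: str | Path, proteins: Sequence[ProteinRecord]
) -> tuple[list[PhosphoSite], QCSummary]:
    """Load experimentally determined phosphosites, validated against sequence.

    A site whose declared residue disagrees with the protein sequence, or that
    references an absent protein, is dropped and counted.
    """
    tsv_path = Path(tsv_path)
    if not tsv_path.exists():
        raise FileNotFoundError(tsv_path)
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = set(PHOSPHOSITE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phosphosite table lacks columns: {sorted(missing)}")
    by_id = {p.id: p for p in proteins}
    qc = QCSummary(input_rows=len(table))
    sites: list[PhosphoSite] = []
    for row in table.itertuples(index=False):
        pid = row.protein_id
        rec = by_id.get(pid)
        if rec is None:
            logger.warning("phosphosite for unknown protein %s dropped", pid)
            qc.drop("unknown_protein")
            continue
        pos = int(row.position)
        if not (1 <= pos <= len(rec.sequence)):
            qc.drop("position_out_of_range")
            continue
        if rec.sequence[pos - 1] != row.residue:
            logger.warning(
                "phosphosite %s:%d declares %s but sequence has %s; dropped",
                pid, pos, row.residue, rec.sequence[pos - 1],
            )
            qc.drop("residue_mismatch")
            continue
        source = getattr(row, "source", "") or ""
        sites.append(PhosphoSite(protein_id=pid, position=pos, residue=row.residue, source=source))
        qc.kept_rows += 1
    return sites, qc


def write_table(
    rows: Iterable[dict],
    schema: Sequence[str],
    path: str | Path,
    key_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Write rows as a TSV with a fixed column order and deterministic sort.

    ``key_columns`` default to the first schema column.  Returns the frame as
    written (useful for round-trip checks).
    """
    df = pd.DataFrame(list(rows), columns=list(schema))
    keys = list(key_columns) if key_columns else [schema[0]]
    if len(df):
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments_fasta(segments, path: str | Path) -> None:
    """NRE segments as FASTA with ids ``proteinid|start-end|kind``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for seg in sorted(segments, key=lambda s: (s.protein_id, s.start)):
            fh.write(f">{seg.protein_id}|{seg.start}-{seg.end}|{seg.kind.value}\n")
            for i in range(0, len(seg.sequence), 60):
                fh.write(seg.sequence[i : i + 60] + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a key-value (YAML) config file mirroring PipelineConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} is not a key-value mapping")
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=True)
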