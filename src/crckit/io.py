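"""Readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive GFF3 convention happens only in the writers.  Every
format written here that the pipeline consumes again has a matching
reader, and read(write(x)) round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO


@dataclass
class AnnotationRecord:
    """Unified feature record shared by all writers."""

    record_id: str
    genome_id: str
    interval: tuple  # 0-based half-open
    strand: str = "."
    feature_type: str = "region"
    score: float | None = None
    parent: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        s, e = self.interval
        if not (0 <= s < e):
            raise ValueError(f"invalid interval {self.interval} for {self.record_id}")


def read_fasta(path):
    """Sequences keyed by id; accepts wrapped, multi-record, mixed-case
    files.  Lowercase (soft-masked) input is uppercased with the masked
    fraction recorded.  Returns (sequences, metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs_out: dict = {}
    meta: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs_out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        raw = str(rec.seq)
        masked = sum(1 for c in raw if c.islower())
        seqs_out[rec.id] = raw.upper()
        meta[rec.id] = {"softmasked_bases": masked, "length": len(raw)}
    if not seqs_out:
        raise ValueError(f"no FASTA records in {path}")
    return seqs_out, meta


def write_fasta(path, seqs_by_id: dict, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in seqs_by_id.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _esc(v) -> str:
    return str(v).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(path, records, sequence_lengths: dict | None = None):
    """GFF3 (1-based inclusive), sorted by genome then start."""
    records = sorted(records, key=lambda r: (r.genome_id, r.interval))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            s, e = r.interval
            if sequence_lengths and e > sequence_lengths.get(r.genome_id, e):
                raise ValueError(f"{r.record_id}: interval beyond sequence end")
            attrs = [f"ID={_esc(r.record_id)}"]
            if r.parent:
                attrs.append(f"Parent={_esc(r.parent)}")
            attrs += [f"{k}={_esc(v)}" for k, v in r.attributes.items()]
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(
                "\t".join(
                    [r.genome_id, "crckit", r.feature_type, str(s + 1), str(e), score, r.strand or ".", ".", ";".join(attrs)]
                )
                + "\n"
            )


def read_gff3(path):
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            rid, parent = "", None
            for kv in f[8].split(";"):
                if not kv:
                    continue
                k, _, v = kv.partition("=")
                v = v.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")
                if k == "ID":
                    rid = v
                elif k == "Parent":
                    parent = v
                else:
                    attrs[k] = v
            out.append(
                AnnotationRecord(
                    record_id=rid,
                    genome_id=f[0],
                    interval=(int(f[3]) - 1, int(f[4])),
                    strand=f[6],
                    feature_type=f[2],
                    score=None if f[5] == "." else float(f[5]),
                    parent=parent,
                    attributes=attrs,
                )
            )
    return out


def write_bed(path, records):
    """BED6, 0-based half-open (the internal convention verbatim)."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.genome_id, r.interval)):
            score = 0 if r.score is None else r.score
            fh.write(f"{r.genome_id}\t{r.interval[0]}\t{r.interval[1]}\t{r.record_id}\t{score:g}\t{r.strand or '.'}\n")


def read_bed(path):
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split("\t")
            out.append(
                AnnotationRecord(
                    record_id=f[3],
                    genome_id=f[0],
                    interval=(int(f[1]), int(f[2])),
                    strand=f[5].strip(),
                    score=float(f[4]),
                )
            )
    return out


def write_bedgraph(path, track):
    with open(path, "w") as fh:
        for s, v in zip(track.starts, track.values):
            fh.write(f"{track.genome_id}\t{s}\t{s + track.window_bp}\t{v:g}\n")


def write_tsv(path, table: pd.DataFrame, index: bool = True):
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
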