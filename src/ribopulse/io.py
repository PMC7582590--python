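"""Plain-text readers and writers for the pipeline's external formats.

Transcript regions travel as FASTA (one record per region, id
``gene|region``) plus a region-length TSV; counts as TSV with sample
columns named ``assay_condition_rep``; aligned reads as TSV with columns
``gene_id``, ``pos5``, ``length``; ground truth as JSON.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import CountMatrix
from .simulate import Transcript

REGION_ORDER = ("utr5", "cds", "utr3")


def write_transcripts_fasta(transcripts: list[Transcript], path) -> None:
    records = []
    for t in transcripts:
        for region in REGION_ORDER:
            seq = getattr(t, region)
            if seq:
                records.append(SeqRecord(Seq(seq), id=f"{t.gene_id}|{region}",
                                         description=""))
    SeqIO.write(records, str(path), "fasta")


def read_transcripts_fasta(path) -> list[Transcript]:
    regions: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            gene, region = rec.id.rsplit("|", 1)
        except ValueError as err:
            raise ValueError(f"record id {rec.id!r} is not gene|region") from err
        if gene not in regions:
            regions[gene] = {}
            order.append(gene)
        regions[gene][region] = str(rec.seq).upper()
    return [Transcript(g, regions[g].get("utr5", ""), regions[g]["cds"],
                       regions[g].get("utr3", "")) for g in order]


def write_region_lengths(transcripts: list[Transcript], path) -> None:
    rows = [{"gene_id": t.gene_id, "utr5_len": len(t.utr5),
             "cds_len": len(t.cds), "utr3_len": len(t.utr3)}
            for t in transcripts]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_counts(counts: CountMatrix, path) -> None:
    frame = counts.counts.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_counts(path) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(frame)


def write_reads(reads: pd.DataFrame, path) -> None:
    reads[["gene_id", "pos5", "length"]].to_csv(path, sep="\t", index=False)


def read_reads(path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t")
    required = {"gene_id", "pos5", "length"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    return reads


def write_fasta(seqs: dict[str, str], path) -> None:
    SeqIO.write([SeqRecord(Seq(s), id=name, description="")
                 for name, s in seqs.items()], str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_landmarks(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"ref_id", "aa", "anticodon", "mature_start", "mature_end",
                "dloop_start", "dloop_end", "acloop_start", "acloop_end",
                "leader_len"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    return table.set_index("ref_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
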