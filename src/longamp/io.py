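"""File-format helpers: FASTA/FASTQ via Biopython, a minimal flat GFF3
reader/writer for rRNA features, and TSV report writers."""

from __future__ import annotations

import urllib.parse
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path, reads: Iterable[tuple[str, str]], quality: int = 40) -> None:
    """Write (read_id, sequence) pairs with a constant quality score."""
    recs = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# GFF3 (flat feature lists only; no hierarchy needed for rRNA parts)


def read_gff3(path) -> list[dict]:
    """Parse a GFF3 file into flat feature dicts with 0-based half-open
    coordinates (GFF3 itself is 1-based inclusive)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, source, ftype, start, end, score, strand, phase, attrs = parts
            attributes = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k] = urllib.parse.unquote(v)
            feats.append({
                "contig": seqid, "source": source, "type": ftype,
                "start": int(start) - 1, "end": int(end), "strand": strand,
                "attributes": attributes,
            })
    return feats


def write_gff3(path, features: Iterable[dict]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={urllib.parse.quote(str(v), safe='')}"
                             for k, v in f.get("attributes", {}).items())
            fh.write("\t".join([
                f["contig"], f.get("source", "longamp"), f["type"],
                str(f["start"] + 1), str(f["end"]), ".", f.get("strand", "+"),
                ".", attrs or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# tabular


def amplicon_report(hits) -> pd.DataFrame:
    """TSV-ready report of amplicon hits; coordinates 1-based inclusive."""
    rows = []
    for h in hits:
        rows.append({
            "genome": h.genome, "contig": h.contig,
            "insert_start": h.insert_start + 1, "insert_end": h.insert_end,
            "length": h.length, "strand": h.strand,
            "fwd_mismatches": h.fwd_mismatches, "rev_mismatches": h.rev_mismatches,
            "passed_length_filter": h.passed_length_filter,
        })
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
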