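"""FASTA / BED / TSV readers and writers used across the toolkit.

Genomes travel as ``dict[str, str]`` (chromosome id -> plus-strand sequence),
read and written with Biopython's SeqIO so records round-trip with standard
80-column wrapping.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Genome = dict  # chromosome id -> sequence string


def read_fasta(path) -> Genome:
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Genome, path=None) -> str:
    """Write a genome as wrapped FASTA; return the text (and write if path)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    buf = _io.StringIO()
    SeqIO.write(records, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def write_bed(rows, path=None) -> str:
    """Write rows (iterables of fields) as tab-separated BED-style text."""
    text = "".join("\t".join(str(f) for f in row) + "\n" for row in rows)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_tsv_map(path) -> dict:
    """Two-column TSV -> dict (e.g. ortholog maps, centromere tables)."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")[:2]
        out[a] = b
    return out


def write_tsv_map(mapping: dict, path=None) -> str:
    text = "".join(f"{k}\t{v}\n" for k, v in mapping.items())
    if path is not None:
        Path(path).write_text(text)
    return text
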