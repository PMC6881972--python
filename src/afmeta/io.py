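"""Sequence and table I/O: FASTA/FASTQ readers (gzip-transparent), sample
writers, and the genome-id mapping table."""

from __future__ import annotations

import gzip
import os

from Bio import SeqIO


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: str) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    ext = os.path.splitext(name)[1].lower()
    if ext in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"cannot determine sequence format of {path}")


def read_sequences(path: str, format: str = "auto"):
    """Yield (id, sequence) records from FASTA or FASTQ, gzip-transparent.

    Sequences are uppercased; FASTQ qualities are ignored.  Malformed
    records raise with the record index in the message.
    """
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with _open_text(path) as fh:
        i = 0
        try:
            for i, rec in enumerate(SeqIO.parse(fh, format), start=1):
                yield rec.id, str(rec.seq).upper()
        except ValueError as err:
            raise ValueError(
                f"malformed {format} record near record {i + 1} in {path}: "
                f"{err}"
            ) from err


def strip_sequence_suffixes(filename: str) -> str:
    """Sample name from a file name: strips .gz and sequence extensions
    only, so names containing dots survive."""
    name = os.path.basename(filename)
    if name.endswith(".gz"):
        name = name[:-3]
    for ext in (".fasta", ".fastq", ".fa", ".fq", ".fna", ".ffn"):
        if name.endswith(ext):
            name = name[: -len(ext)]
            break
    return name


def read_sequence_dict(path: str, format: str = "auto") -> dict:
    return dict(read_sequences(path, format))


def write_fasta(records, path: str, width: int = 80) -> None:
    """Write (id, sequence) pairs as (optionally gzipped) FASTA."""
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records, path: str, quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as FASTQ with a constant placeholder
    quality string."""
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_sample_fastq(sample, prefix: str, gzip_out: bool = True) -> tuple:
    """Write a simulated sample's mates as <prefix>_R1/_R2 FASTQ files."""
    suffix = ".fastq.gz" if gzip_out else ".fastq"
    r1_path = prefix + "_R1" + suffix
    r2_path = prefix + "_R2" + suffix
    strings = sample.read_strings()
    r1 = [
        (f"{sample.name}_pair{i}/1", strings[2 * i])
        for i in range(sample.n_pairs)
    ]
    r2 = [
        (f"{sample.name}_pair{i}/2", strings[2 * i + 1])
        for i in range(sample.n_pairs)
    ]
    write_fastq(r1, r1_path)
    write_fastq(r2, r2_path)
    return r1_path, r2_path


def write_truth_tsv(names, truth, path: str, column: str = "truth") -> None:
    with open(path, "w") as fh:
        fh.write(f"sample\t{column}\n")
        for name, value in zip(names, truth):
            fh.write(f"{name}\t{value}\n")


def read_truth_tsv(path: str) -> dict:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample"):
            raise ValueError(f"truth table {path} must start with 'sample'")
        for line in fh:
            if line.strip():
                name, value = line.rstrip("\n").split("\t")[:2]
                out[name] = value
    return out


def write_manifest(params: dict, path: str) -> None:
    """Flat key-value run manifest for reproducibility."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key}\t{params[key]}\n")
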