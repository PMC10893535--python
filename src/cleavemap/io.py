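"""Shared sequence containers, FASTA/FASTQ handling, and pipeline configuration.

Coordinates throughout the package are 1-based and fully closed, on the sense
strand only: the substrates are single-stranded RNAs read 5' to 3'.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("cleavemap")

#: Fixed 45-nt RNA barcode ligated to cleavage-generated 5' ends.  Contains no
#: occurrence of the UACAUA motif (nor the UACAU pentad) and no homopolymer
#: longer than three bases.
DEFAULT_BARCODE = "CCGGGUGGUGUACAGAGAACGCAGCUGGGUAUAGCCGCUUCCCGC"

RNA_ALPHABET = frozenset("ACGUN")
DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """A file does not conform to the expected format."""


@dataclass(frozen=True)
class Substrate:
    """A reference RNA with optionally annotated (planted) motif sites.

    ``planted_sites`` holds the 1-based position of the first base of each
    motif occurrence.  It is ground truth carried for test oracles; the
    site-calling pipeline never reads it.
    """

    id: str
    sequence: str
    planted_sites: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"substrate {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"substrate {self.id!r}: non-RNA characters {sorted(bad)}"
            )
        if self.planted_sites is not None:
            for p in self.planted_sites:
                if not 1 <= p <= len(self.sequence):
                    raise ValueError(
                        f"substrate {self.id!r}: planted site {p} out of range"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (id, sequence, optional Phred+33 qualities)."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages.

    Defaults mirror the study conditions: the ten highest-RCI sites with
    11-base windows centered on them, a 45-nt 5' barcode, and exclusion of
    fragments shorter than 200 nt.
    """

    K: int = 10
    window_w: int = 11
    barcode: str = DEFAULT_BARCODE
    min_fragment_len: int = 200
    rng_seed: int = 0
    # site calling
    min_depth: int = 5
    max_barcode_mismatches: int = 1
    max_mismatches: int = 2
    min_match_len: int = 20
    # motif calling
    core_threshold: float = 1.0
    low_consistency_threshold: float = 0.9
    # FRET classification
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.window_w < 3 or self.window_w % 2 == 0:
            raise ValueError(f"window_w must be odd and >= 3, got {self.window_w}")
        if self.min_fragment_len < 0:
            raise ValueError("min_fragment_len must be >= 0")
        bad = set(self.barcode) - RNA_ALPHABET
        if bad:
            raise ValueError(f"barcode contains non-RNA characters {sorted(bad)}")


def _clean_sequence(seq: str, alphabet: str, where: str) -> str:
    seq = seq.upper()
    if alphabet == "RNA":
        seq = seq.replace("T", "U")
        allowed = RNA_ALPHABET
    elif alphabet == "DNA":
        allowed = DNA_ALPHABET
    elif alphabet == "protein":
        allowed = PROTEIN_ALPHABET
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    bad = set(seq) - allowed
    if bad:
        raise FormatError(f"{where}: characters {sorted(bad)} not in {alphabet} alphabet")
    return seq


def _precheck_fasta(path: Path) -> None:
    # Light structural check so format errors can name a line number;
    # record-level parsing is delegated to Biopython.
    with open(path) as fh:
        lineno = 0
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith(">"):
                if len(line.strip()) == 1:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
            elif not seen_header:
                raise FormatError(
                    f"{path}: sequence before any header at line {lineno}"
                )
        if lineno == 0 or not seen_header:
            raise FormatError(f"{path}: empty FASTA file")


def read_fasta(path: str | Path, alphabet: str = "RNA") -> list[tuple[str, str]]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; for the RNA alphabet, T is transliterated to U.
    Record order is preserved.  The returned id is the full header text (so
    NCBI-style ``[locus_tag=...]`` attributes survive for downstream parsing).
    """
    path = Path(path)
    _precheck_fasta(path)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        seq = _clean_sequence(str(rec.seq), alphabet, f"{path}:{rec.id}")
        out.append((header, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read 4-line FASTQ records (Sanger/Phred+33)."""
    path = Path(path)
    records: list[ReadRecord] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"{path}: expected '@' header at line {lineno}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus or not qual and qual != "":
                raise FormatError(f"{path}: truncated record at line {lineno}")
            if not plus.startswith("+"):
                raise FormatError(f"{path}: expected '+' separator at line {lineno + 2}")
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}: quality/sequence length mismatch at line {lineno + 3}"
                )
            lineno += 3
            records.append(ReadRecord(id=header[1:].rstrip("\n"), sequence=seq, qualities=qual))
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as 4-line FASTQ; missing qualities are filled with 'I' (Q40)."""
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qualities if rec.qualities is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


_CONFIG_FIELDS = None  # populated lazily


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML key/value config, applying defaults for missing keys.

    Unknown keys raise (typos would otherwise silently revert a parameter to
    its default).  Keyword overrides take precedence over the file.
    """
    global _CONFIG_FIELDS
    if _CONFIG_FIELDS is None:
        _CONFIG_FIELDS = {f.name for f in fields(PipelineConfig)}
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a mapping of key: value pairs")
        data.update(loaded)
    data.update(overrides)
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
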