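"""Reading, validating and splitting siRNA records.

An :class:`SiRNARecord` holds the 21-nt guide (antisense) strand written
5'→3', the mRNA (sense) target-site context written 5'→3', and the observed
silencing efficacy in [0, 1] (missing for prediction-only records).  The
21-nt binding region is located inside the context by a 0-based, half-open
``binding_offset`` on the sense strand.  Both T and U are accepted on input
and stored as U.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

GUIDE_LEN = 21
#: Sentinel for a window position that falls outside the available context.
ABSENT = "-"

_ALPHABET = set("ACGU")


class RecordValidationError(ValueError):
    """A record violates an invariant; the message names the offending id."""


def normalize_rna(seq: str) -> str:
    """Uppercase and map T→U; raise on symbols outside {A,C,G,U,T}."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _ALPHABET
    if bad:
        raise RecordValidationError(f"invalid nucleotide symbol(s) {sorted(bad)} in {seq!r}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (U-based)."""
    return str(Seq(normalize_rna(seq)).reverse_complement_rna())


@dataclass
class SiRNARecord:
    """One siRNA: guide strand, target-site context, observed efficacy."""

    id: str
    guide_seq: str
    target_context: str
    binding_offset: int
    efficacy: Optional[float] = None
    source_tag: Optional[str] = None

    def __post_init__(self) -> None:
        self.guide_seq = normalize_rna(self.guide_seq)
        self.target_context = normalize_rna(self.target_context)
        if len(self.guide_seq) != GUIDE_LEN:
            raise RecordValidationError(
                f"record {self.id!r}: guide length {len(self.guide_seq)} != {GUIDE_LEN}"
            )
        if self.efficacy is not None and not (0.0 <= self.efficacy <= 1.0):
            raise RecordValidationError(
                f"record {self.id!r}: efficacy {self.efficacy} outside [0, 1]"
            )
        if not (0 <= self.binding_offset and self.binding_offset + GUIDE_LEN <= len(self.target_context)):
            raise RecordValidationError(
                f"record {self.id!r}: binding region [{self.binding_offset}, "
                f"{self.binding_offset + GUIDE_LEN}) not contained in context of "
                f"length {len(self.target_context)}"
            )

    @property
    def binding_region(self) -> str:
        """The 21-nt target site on the sense strand."""
        return self.target_context[self.binding_offset : self.binding_offset + GUIDE_LEN]


@dataclass
class DatasetSplit:
    train: list  # list[SiRNARecord]
    test: list
    seed: int


def extract_window(record: SiRNARecord, n: int) -> str:
    """Return the 21+2n window centered on the binding region.

    Positions beyond the available context are marked with :data:`ABSENT`
    (encoded downstream as uniform 0.05 rows).  ``n`` is the flank length
    on each side; the scanned range is 10–30 but any n ≥ 0 is accepted for
    degenerate and test use.
    """
    if n < 0:
        raise ValueError(f"flank length n must be >= 0, got {n}")
    ctx = record.target_context
    start = record.binding_offset - n
    end = record.binding_offset + GUIDE_LEN + n
    left_pad = max(0, -start)
    right_pad = max(0, end - len(ctx))
    window = ABSENT * left_pad + ctx[max(0, start) : min(len(ctx), end)] + ABSENT * right_pad
    assert len(window) == GUIDE_LEN + 2 * n
    return window


def read_records(fasta_path, table_path) -> list:
    """Read records from a context FASTA plus a TSV metadata/efficacy table.

    The TSV has a header ``id<TAB>efficacy<TAB>binding_offset<TAB>source``;
    efficacy may be '.' or empty for prediction-only records.  Every FASTA id
    must appear in the table and vice versa.  When ``binding_offset`` is
    given, the FASTA sequence is the mRNA context and the guide strand is
    derived as the reverse complement of the 21-nt binding region
    (perfect-match convention).  When ``binding_offset`` is '.' or empty,
    the FASTA sequence is the 21-nt guide itself and the sense-strand
    complement doubles as its (flankless) context.
    """
    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq)

    meta = _read_table(table_path)
    missing = set(seqs) ^ set(meta)
    if missing:
        raise RecordValidationError(
            f"id mismatch between FASTA and table: {sorted(missing)[:5]}"
        )

    records = []
    for rid, seq in seqs.items():
        eff, offset, source = meta[rid]
        seq = normalize_rna(seq)
        if offset is None:
            # Guide-only record: context is the sense-strand complement.
            if len(seq) != GUIDE_LEN:
                raise RecordValidationError(
                    f"record {rid!r}: no binding_offset, so the sequence must be "
                    f"the {GUIDE_LEN}-nt guide, got length {len(seq)}"
                )
            context = reverse_complement(seq)
            guide = seq
            offset = 0
        else:
            context = seq
            guide = reverse_complement(context[offset : offset + GUIDE_LEN])
        records.append(
            SiRNARecord(
                id=rid,
                guide_seq=guide,
                target_context=context,
                binding_offset=offset,
                efficacy=eff,
                source_tag=source,
            )
        )
    return records


def _read_table(table_path) -> dict:
    meta = {}
    with open(table_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "efficacy", "binding_offset", "source"]
        if header[: len(expected)] != expected:
            raise RecordValidationError(
                f"table header {header} does not start with {expected}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rid = parts[0]
            eff_str = parts[1] if len(parts) > 1 else ""
            eff = None if eff_str in ("", ".") else float(eff_str)
            if eff is not None and not (0.0 <= eff <= 1.0):
                raise RecordValidationError(
                    f"table line {lineno}: record {rid!r} efficacy {eff} outside [0, 1]"
                )
            offset_str = parts[2] if len(parts) > 2 else ""
            offset = None if offset_str in ("", ".") else int(offset_str)
            source = parts[3] if len(parts) > 3 and parts[3] else None
            if rid in meta:
                raise RecordValidationError(f"duplicate id {rid!r} in table")
            meta[rid] = (eff, offset, source)
    return meta


def write_records(records: Iterable[SiRNARecord], fasta_path, table_path) -> None:
    """Write records back to FASTA (context) + TSV; inverse of read_records."""
    records = list(records)
    with open(fasta_path, "w", encoding="utf-8") as fa:
        for r in records:
            fa.write(f">{r.id}\n{r.target_context}\n")
    with open(table_path, "w", encoding="utf-8") as tb:
        tb.write("id\tefficacy\tbinding_offset\tsource\n")
        for r in records:
            eff = "." if r.efficacy is None else repr(r.efficacy)
            src = r.source_tag or ""
            tb.write(f"{r.id}\t{eff}\t{r.binding_offset}\t{src}\n")


def split_records(records: list, test_fraction: float, seed: int) -> DatasetSplit:
    """Random train/test partition, deterministic given seed.

    Test size is round(test_fraction × N); train and test are disjoint and
    jointly cover the input.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    n_test = int(round(test_fraction * len(records)))
    rng = random.Random(seed)
    order = list(records)
    rng.shuffle(order)
    return DatasetSplit(train=order[n_test:], test=order[:n_test], seed=seed)
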