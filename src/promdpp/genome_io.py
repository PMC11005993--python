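"""Genome FASTA / TSS-table I/O and strand-aware promoter extraction.

Coordinates are 0-based internally; user-facing positions are TSS-relative
integers with the TSS at 0 and upstream negative, matching the convention of
CAGE-anchored promoter figures.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "TSSRecord",
    "PromoterRecord",
    "ExtractionSummary",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_tss_table",
    "write_tss_table",
    "select_representative_tss",
    "extract_promoter",
    "extract_promoters",
    "sample_records",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class TSSRecord:
    """A single-base transcription start site with score and group metadata.

    ``score`` is whatever the source ranks TSSs by (TIEScore for FANTOM-style
    lncRNA/mRNA tables, TPM for tRNA tables); ``group`` holds free-form
    metadata keys such as ``genomic_context`` or ``dhs_type``.
    """

    chrom: str
    pos: int
    strand: str
    gene_id: str
    score: float
    group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative TSS position {self.pos}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PromoterRecord:
    """A TSS-anchored, sense-strand promoter window.

    ``seq[anchor]`` is the transcribed TSS base in sense orientation;
    TSS-relative coordinate of ``seq[i]`` is ``i - anchor``.
    """

    gene_id: str
    seq: str
    anchor: int
    group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.anchor < len(self.seq)):
            raise ValueError("anchor outside sequence")

    def window(self, start: int, stop: int) -> str:
        """Sub-sequence covering TSS-relative positions start..stop inclusive."""
        i, j = start + self.anchor, stop + self.anchor
        if i < 0 or j >= len(self.seq):
            raise IndexError(f"window [{start},{stop}] outside promoter")
        return self.seq[i : j + 1]


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped) multi-record FASTA into a name → sequence map.

    Case is preserved so masking-aware callers can see soft-masked bases.
    Duplicate record names and empty files are errors.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq)
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_group_field(text: str) -> dict:
    group: dict = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, sep, val = item.partition("=")
        if not sep:
            raise ValueError(f"metadata item {item!r} is not key=value")
        group[key.strip()] = val.strip()
    return group


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a BED6(+metadata) TSS table.

    Columns: chrom, chromStart, chromEnd (must be chromStart+1: single-base,
    0-based half-open), name, score, strand, and an optional 7th column of
    semicolon-delimited ``key=value`` metadata.  Malformed rows raise with the
    line number.
    """
    records: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates/score") from exc
            if end != start + 1:
                raise ValueError(
                    f"{path}:{lineno}: TSS interval must be a single base "
                    f"(chromEnd == chromStart + 1), got [{start},{end})"
                )
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            group = _parse_group_field(fields[6]) if len(fields) > 6 and fields[6] else {}
            records.append(
                TSSRecord(chrom=chrom, pos=start, strand=strand, gene_id=name,
                          score=score, group=group)
            )
    return records


def write_tss_table(records: list[TSSRecord], path: str | Path) -> None:
    """Write TSSRecords in the BED6+metadata dialect read_tss_table reads."""
    with open(path, "w") as fh:
        for r in records:
            meta = ";".join(f"{k}={v}" for k, v in sorted(r.group.items()))
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.gene_id}\t{r.score:g}\t{r.strand}"
                + (f"\t{meta}" if meta else "")
                + "\n"
            )


def select_representative_tss(records: list[TSSRecord]) -> list[TSSRecord]:
    """One TSS per gene: the highest-scoring record.

    Ties are broken deterministically by smallest genomic coordinate, then
    lexicographic chromosome name.  Output is ordered by first appearance of
    each gene_id.
    """
    best: dict[str, TSSRecord] = {}
    order: list[str] = []
    for r in records:
        cur = best.get(r.gene_id)
        if cur is None:
            best[r.gene_id] = r
            order.append(r.gene_id)
            continue
        if (-r.score, r.pos, r.chrom) < (-cur.score, cur.pos, cur.chrom):
            best[r.gene_id] = r
    return [best[g] for g in order]


@dataclass
class ExtractionSummary:
    """Run summary: read = kept + skipped."""

    read: int = 0
    kept: int = 0
    skipped: int = 0

    def as_dict(self) -> dict:
        return {"read": self.read, "kept": self.kept, "skipped": self.skipped}


def extract_promoter(
    genome: dict[str, str],
    rec: TSSRecord,
    upstream: int,
    downstream: int,
) -> PromoterRecord | None:
    """Extract the sense-strand window [-upstream, +downstream] around a TSS.

    '+' strand: ``genome[pos-U .. pos+D]`` inclusive; '-' strand: the reverse
    complement of ``genome[pos-D .. pos+U]``.  The anchor is at index U in
    both cases.  Windows overrunning the contig return None (caller counts the
    skip); an unknown contig is a hard error.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window sizes must be non-negative")
    if rec.chrom not in genome:
        raise KeyError(f"contig {rec.chrom!r} not in genome")
    contig = genome[rec.chrom]
    if rec.strand == "+":
        lo, hi = rec.pos - upstream, rec.pos + downstream
    else:
        lo, hi = rec.pos - downstream, rec.pos + upstream
    if lo < 0 or hi >= len(contig):
        logger.warning(
            "skipping %s: window [%d,%d] overruns contig %s (len %d)",
            rec.gene_id, lo, hi, rec.chrom, len(contig),
        )
        return None
    seq = contig[lo : hi + 1]
    if rec.strand == "-":
        seq = reverse_complement(seq)
    return PromoterRecord(gene_id=rec.gene_id, seq=seq, anchor=upstream,
                          group=dict(rec.group))


def extract_promoters(
    genome: dict[str, str],
    records: list[TSSRecord],
    upstream: int,
    downstream: int,
) -> tuple[list[PromoterRecord], ExtractionSummary]:
    """Extract all promoters, counting contig-edge skips."""
    out: list[PromoterRecord] = []
    summary = ExtractionSummary()
    for rec in records:
        summary.read += 1
        p = extract_promoter(genome, rec, upstream, downstream)
        if p is None:
            summary.skipped += 1
        else:
            summary.kept += 1
            out.append(p)
    return out, summary


def sample_records(records: list[TSSRecord], n: int, seed: int) -> list[TSSRecord]:
    """Uniform random subsample without replacement, reproducible under seed."""
    if n > len(records):
        raise ValueError(f"cannot sample {n} from {len(records)} records")
    rng = random.Random(seed)
    return rng.sample(records, n)
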