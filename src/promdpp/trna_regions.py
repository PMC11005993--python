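"""The three profiled regions of a tRNA gene, each with its own anchor.

tRNA genes carry their Pol III promoter internally (A-box and B-box).  Three
regions are profiled, defined purely by three anchors — the A/B boxes are
never searched for, since their spacing is irregular (introns, variable
loop):

* upstream: TSS-relative −50..0, anchored at the CAGE TSS (51 nt);
* A-box region: 0..+30 anchored at the mature tRNA 5′ end (31 nt);
* B-box region: −30..0 anchored at the discriminator base (31 nt).

All endpoints are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_io import PromoterRecord, TSSRecord, extract_promoter

__all__ = [
    "TRNAGeneAnnotation",
    "read_trna_table",
    "write_trna_table",
    "upstream_region",
    "abox_region",
    "bbox_region",
    "REGION_ANCHORS",
]

#: region name → (anchor description, upstream span U, downstream span D)
REGION_ANCHORS = {
    "upstream": ("TSS", 50, 0),
    "abox": ("mature tRNA 5' end", 0, 30),
    "bbox": ("discriminator base", 30, 0),
}


@dataclass(frozen=True)
class TRNAGeneAnnotation:
    """Anchors of one tRNA gene (all coordinates 0-based genomic).

    In transcript orientation the anchors are ordered
    ``tss_pos <= mature5_pos < discriminator_pos``; on the '-' strand the
    genomic coordinates therefore decrease along that order.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_pos: int
    mature5_pos: int
    discriminator_pos: int
    tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        sign = 1 if self.strand == "+" else -1
        t, m, d = (sign * self.tss_pos, sign * self.mature5_pos,
                   sign * self.discriminator_pos)
        if not (t <= m < d):
            raise ValueError(
                f"{self.gene_id}: anchors violate tss <= mature5 < discriminator "
                "in transcript orientation"
            )


def read_trna_table(path: str | Path) -> list[TRNAGeneAnnotation]:
    """Read the tRNA annotation TSV.

    Columns (tab-separated, '#' comments allowed): gene_id, chrom, strand,
    tss, mature5, discriminator, tpm.
    """
    out: list[TRNAGeneAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns "
                                 "(gene_id chrom strand tss mature5 discriminator tpm)")
            try:
                out.append(
                    TRNAGeneAnnotation(
                        gene_id=fields[0], chrom=fields[1], strand=fields[2],
                        tss_pos=int(fields[3]), mature5_pos=int(fields[4]),
                        discriminator_pos=int(fields[5]), tpm=float(fields[6]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_trna_table(anns: list[TRNAGeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tmature5\tdiscriminator\ttpm\n")
        for a in anns:
            fh.write(
                f"{a.gene_id}\t{a.chrom}\t{a.strand}\t{a.tss_pos}\t"
                f"{a.mature5_pos}\t{a.discriminator_pos}\t{a.tpm:g}\n"
            )


def _region(ann: TRNAGeneAnnotation, genome: dict[str, str], pos: int,
            upstream: int, downstream: int) -> PromoterRecord | None:
    rec = TSSRecord(chrom=ann.chrom, pos=pos, strand=ann.strand,
                    gene_id=ann.gene_id, score=ann.tpm)
    return extract_promoter(genome, rec, upstream=upstream, downstream=downstream)


def upstream_region(ann: TRNAGeneAnnotation, genome: dict[str, str]) -> PromoterRecord | None:
    """51-nt sense-strand region −50..0 anchored at the TSS (anchor index 50)."""
    return _region(ann, genome, ann.tss_pos, upstream=50, downstream=0)


def abox_region(ann: TRNAGeneAnnotation, genome: dict[str, str]) -> PromoterRecord | None:
    """31-nt sense-strand region 0..+30 anchored at the mature 5′ end (anchor 0)."""
    return _region(ann, genome, ann.mature5_pos, upstream=0, downstream=30)


def bbox_region(ann: TRNAGeneAnnotation, genome: dict[str, str]) -> PromoterRecord | None:
    """31-nt sense-strand region −30..0 anchored at the discriminator (anchor 30)."""
    return _region(ann, genome, ann.discriminator_pos, upstream=30, downstream=0)
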