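"""Synthetic promoter and tRNA-gene sets with recorded ground truth.

The generator stands in for genome-scale inputs (CAGE TSS atlases + reference
genome): fixed-length promoter windows with the TSS at a known anchor, an
i.i.d. background of configurable GC content, core promoter elements planted
at their canonical TSS-relative positions with bounded uniform jitter, and a
mixture of promoter species (majority core-less, Inr-rich minority, as in
observed Pol II promoter sets).  Accidental background matches to element
consensus are possible and deliberately NOT suppressed — as in real genomes —
so classification tests must account for them (see
:func:`expected_species_fractions`).

tRNA genes are emulated as one contig per gene carrying the printed A-box
(TGGCNNAGTGG) and B-box (GGTTCGANNCC) consensus at biologically plausible
offsets, with variable A–B spacing, on a random strand.

All randomness derives from one integer seed; sequence i uses the
independent substream ``default_rng([seed, i])`` so earlier sequences are
unchanged when n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np

from .cpe_scan import CORE_LESS, IUPAC_CODES, CPEDefinition, find_element_matches
from .genome_io import PromoterRecord, TSSRecord, reverse_complement
from .trna_regions import TRNAGeneAnnotation

__all__ = [
    "SynthConfig",
    "PlantedElement",
    "SynthTruth",
    "ABOX_CONSENSUS",
    "ABOX_CONSENSUS_ALT",
    "BBOX_CONSENSUS",
    "LNCRNA_GROUPS",
    "generate_background",
    "plant_element",
    "generate_promoter_set",
    "generate_trna_set",
    "assign_lncrna_groups",
    "promoter_set_to_inputs",
    "measure_accidental_rates",
    "expected_species_fractions",
]

_BASES = "ACGT"

ABOX_CONSENSUS = "TGGCNNAGTGG"
ABOX_CONSENSUS_ALT = "TRGYNNARBGG"
BBOX_CONSENSUS = "GGTTCGANNCC"

#: the 16 lncRNA promoter groups: 4 genomic contexts × 4 DHS types
LNCRNA_GROUPS = [
    {"genomic_context": ctx, "dhs_type": dhs}
    for ctx, dhs in product(
        ("divergent_from_mRNA", "sense_intronic", "antisense_to_mRNA", "intergenic"),
        ("promoter", "enhancer", "dyadic", "no_DHS"),
    )
]

#: default species mixture: majority core-less, Inr-rich minority
DEFAULT_SPECIES_MIX = {CORE_LESS: 0.55, "Inr": 0.30, "TATA+Inr": 0.15}


@dataclass
class SynthConfig:
    """Stated world of a synthetic promoter set.

    Defaults: 151-nt windows (−100..+50 around the TSS), 50% GC background,
    species mixture {core-less 0.55, Inr 0.30, TATA+Inr 0.15}, planted-shift
    jitter uniform on [−5, +5].
    """

    n: int
    seed: int
    length: int = 151
    anchor: int = 100
    gc: float = 0.5
    species_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_MIX)
    )
    jitter: tuple[int, int] = (-5, 5)

    def __post_init__(self) -> None:
        if not (0 <= self.anchor < self.length):
            raise ValueError("anchor must lie within the sequence")
        if not np.isclose(sum(self.species_mix.values()), 1.0):
            raise ValueError("species_mix probabilities must sum to 1")
        if self.jitter[0] > self.jitter[1]:
            raise ValueError("jitter range reversed")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0, 1]")


@dataclass(frozen=True)
class PlantedElement:
    """One planted element occurrence: TSS-relative start and signed shift."""

    name: str
    start: int
    shift: int


@dataclass
class SynthTruth:
    """Ground truth for a generated set: species label and plants per sequence."""

    species: list[str]
    elements: list[list[PlantedElement]]


def generate_background(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. background with P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in idx)


def plant_element(
    seq: str, consensus: str, start: int, rng: np.random.Generator
) -> str:
    """Overwrite seq[start:] with a realization of an IUPAC consensus.

    Each consensus position is replaced by a base drawn uniformly from its
    IUPAC set, so the result always matches the consensus at ``start``.
    """
    m = len(consensus)
    if start < 0 or start + m > len(seq):
        raise ValueError(
            f"plant [{start},{start + m}) outside sequence of length {len(seq)}"
        )
    bases = []
    for c in consensus.upper():
        options = sorted(IUPAC_CODES[c])
        bases.append(options[int(rng.integers(len(options)))])
    return seq[:start] + "".join(bases) + seq[start + m :]


def _species_elements(label: str, by_name: dict[str, CPEDefinition]) -> list[CPEDefinition]:
    if label == CORE_LESS:
        return []
    defs = []
    for part in label.split("+"):
        if part not in by_name:
            raise ValueError(f"species label {label!r} uses unknown element {part!r}")
        defs.append(by_name[part])
    return defs


def generate_promoter_set(
    config: SynthConfig,
    defs: Sequence[CPEDefinition],
    group: dict | None = None,
) -> tuple[list[PromoterRecord], SynthTruth]:
    """Draw a promoter set from the configured species mixture.

    For each non-core-less sequence every element of its species is planted
    at ``canonical_start + shift`` with the shift uniform over the configured
    jitter range.  Accidental background matches are not suppressed.

    Elements are planted in the order listed in the species label; if two
    co-planted jitter windows overlap, the later plant overwrites the earlier
    one's bases and the recorded truth for the earlier element may no longer
    be realized in the sequence.  Choose species whose element windows are
    disjoint (the default elements overlap only among BREu/TATA/BREd).
    """
    by_name = {d.name: d for d in defs}
    mix_items = list(config.species_mix.items())
    for label, _ in mix_items:
        _species_elements(label, by_name)  # validate up front
    cum = np.cumsum([p for _, p in mix_items])
    records: list[PromoterRecord] = []
    truth = SynthTruth(species=[], elements=[])
    lo, hi = config.jitter
    for i in range(config.n):
        rng = np.random.default_rng([config.seed, i])
        u = rng.random()
        label = mix_items[int(np.searchsorted(cum, u, side="right"))][0]
        seq = generate_background(config.length, config.gc, rng)
        plants: list[PlantedElement] = []
        for d in _species_elements(label, by_name):
            shift = int(rng.integers(lo, hi + 1))
            start = d.canonical_start + shift
            seq = plant_element(seq, d.consensus, start + config.anchor, rng)
            plants.append(PlantedElement(name=d.name, start=start, shift=shift))
        records.append(
            PromoterRecord(
                gene_id=f"synth_{i:05d}", seq=seq, anchor=config.anchor,
                group=dict(group) if group else {},
            )
        )
        truth.species.append(label)
        truth.elements.append(plants)
    return records, truth


def assign_lncrna_groups(
    records: list[PromoterRecord], seed: int
) -> list[PromoterRecord]:
    """Assign each promoter one of the 16 context × DHS groups, uniformly."""
    rng = np.random.default_rng([seed, 16])
    for r in records:
        r.group.update(LNCRNA_GROUPS[int(rng.integers(len(LNCRNA_GROUPS)))])
    return records


def promoter_set_to_inputs(
    records: list[PromoterRecord],
) -> tuple[dict[str, str], list[TSSRecord]]:
    """Re-express a synthetic set as genome + TSS table, one contig per promoter.

    This lets synthetic data flow through the identical FASTA/BED path as real
    data (extract_promoter recovers each input sequence exactly).
    """
    genome: dict[str, str] = {}
    tss: list[TSSRecord] = []
    for r in records:
        genome[r.gene_id] = r.seq
        tss.append(
            TSSRecord(chrom=r.gene_id, pos=r.anchor, strand="+",
                      gene_id=r.gene_id, score=1.0, group=dict(r.group))
        )
    return genome, tss


def generate_trna_set(
    n: int,
    seed: int,
    abox_offset: int = 7,
    contig_length: int = 400,
    gc: float = 0.5,
) -> tuple[dict[str, str], list[TRNAGeneAnnotation]]:
    """Synthetic tRNA genes: one contig each, random strand, boxes planted.

    Transcript layout (sense coordinates): TSS, a 4–12 nt leader to the
    mature 5′ end, the A-box at ``abox_offset`` (default +7) from the mature
    5′ end, a variable 20–40 nt A–B spacer, the B-box, and the discriminator
    base 3–12 nt after the B-box end — so the B-box always lies inside the
    discriminator-anchored −30..0 window and the A-box inside the mature-5′
    0..+30 window.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= abox_offset <= 30 - len(ABOX_CONSENSUS) + 1):
        raise ValueError("abox_offset must keep the A-box inside 0..+30")
    genome: dict[str, str] = {}
    anns: list[TRNAGeneAnnotation] = []
    for i in range(n):
        rng = np.random.default_rng([seed, 1_000_000 + i])
        sense = generate_background(contig_length, gc, rng)
        tss_s = 80
        leader = int(rng.integers(4, 13))
        mature5_s = tss_s + leader
        abox_s = mature5_s + abox_offset
        sense = plant_element(sense, ABOX_CONSENSUS, abox_s, rng)
        spacing = int(rng.integers(20, 41))
        bbox_s = abox_s + len(ABOX_CONSENSUS) + spacing
        sense = plant_element(sense, BBOX_CONSENSUS, bbox_s, rng)
        gap = int(rng.integers(3, 13))
        disc_s = bbox_s + len(BBOX_CONSENSUS) - 1 + gap
        assert disc_s < contig_length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"synth_tRNA_{i:04d}"
        chrom = f"contig_{i:04d}"
        if strand == "+":
            genome[chrom] = sense
            tss_pos, mature5_pos, disc_pos = tss_s, mature5_s, disc_s
        else:
            genome[chrom] = reverse_complement(sense)
            conv = lambda s: contig_length - 1 - s
            tss_pos, mature5_pos, disc_pos = conv(tss_s), conv(mature5_s), conv(disc_s)
        anns.append(
            TRNAGeneAnnotation(
                gene_id=gene_id, chrom=chrom, strand=strand,
                tss_pos=tss_pos, mature5_pos=mature5_pos,
                discriminator_pos=disc_pos,
                tpm=float(np.round(rng.uniform(1.0, 100.0), 3)),
            )
        )
    return genome, anns


def measure_accidental_rates(
    defs: Sequence[CPEDefinition],
    n: int,
    seed: int,
    length: int = 151,
    anchor: int = 100,
    gc: float = 0.5,
) -> dict[str, float]:
    """Per-element accidental match rates on a zero-plant control set.

    Rate of element e = fraction of core-less background sequences with at
    least one in-window consensus match.
    """
    cfg = SynthConfig(n=n, seed=seed, length=length, anchor=anchor, gc=gc,
                      species_mix={CORE_LESS: 1.0})
    records, _ = generate_promoter_set(cfg, defs)
    rates = {}
    for d in defs:
        k = sum(1 for r in records if find_element_matches(r, d))
        rates[d.name] = k / n
    return rates


def expected_species_fractions(
    species_mix: dict[str, float],
    accidental_rates: dict[str, float],
    defs: Sequence[CPEDefinition],
) -> dict[str, float]:
    """Expected observed species fractions under independent accidental matches.

    A sequence planted with element set S acquires accidental set A ⊆ E∖S
    with probability Π_{e∈A} q_e Π_{e∉A∪S} (1−q_e) and is labelled by S ∪ A.
    Exact enumeration over the 2^|E| accidental subsets.
    """
    by_name = {d.name: d for d in defs}
    names = [d.name for d in defs]

    def label_of(elements: set[str]) -> str:
        if not elements:
            return CORE_LESS
        ordered = sorted(elements, key=lambda e: (by_name[e].canonical_start, e))
        return "+".join(ordered)

    out: dict[str, float] = {}
    for species, p_s in species_mix.items():
        planted = set() if species == CORE_LESS else set(species.split("+"))
        others = [e for e in names if e not in planted]
        for r in range(len(others) + 1):
            for acc in combinations(others, r):
                p = p_s
                for e in others:
                    q = accidental_rates[e]
                    p *= q if e in acc else (1.0 - q)
                lbl = label_of(planted | set(acc))
                out[lbl] = out.get(lbl, 0.0) + p
    return {lbl: p for lbl, p in out.items() if p > 0.0}
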