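"""Core promoter element (CPE) scanning and promoter species classification.

Each element is a short IUPAC consensus with a canonical TSS-relative start;
a promoter carries the element if the consensus matches the sense strand
anywhere within ±max_shift (default 5 bp) of that canonical start.  A
promoter's "species" is the set of elements it carries, ordered by canonical
position and joined with '+'; a promoter with none is "core-less".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .genome_io import PromoterRecord

__all__ = [
    "CPEDefinition",
    "CPEHit",
    "ScanResult",
    "CORE_LESS",
    "iupac_match",
    "find_element_matches",
    "scan_cpes",
    "classify_promoter",
    "tabulate_species",
    "top_species",
    "load_element_definitions",
    "default_element_definitions",
]

CORE_LESS = "core-less"

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class CPEDefinition:
    """A core promoter element: IUPAC consensus anchored at a canonical position.

    ``canonical_start`` is the TSS-relative coordinate of the consensus's
    first base (TSS = 0); matches are accepted within ``±max_shift`` of it.
    """

    name: str
    consensus: str
    canonical_start: int
    max_shift: int = 5
    source: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.name}: empty consensus")
        bad = [c for c in self.consensus.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC code(s) {bad}")
        if self.max_shift < 0:
            raise ValueError(f"{self.name}: max_shift must be >= 0")


@dataclass(frozen=True)
class CPEHit:
    """An observed element match: start (TSS-relative) and signed shift."""

    element: str
    start: int
    shift: int


@dataclass
class ScanResult:
    """Outcome of scanning one promoter.

    ``hits`` holds at most one best hit per element (minimal |shift|, ties to
    the upstream shift); ``all_matches`` every in-window match per element;
    ``unevaluable`` elements whose search window fell outside the promoter.
    """

    hits: list[CPEHit]
    all_matches: dict[str, list[CPEHit]]
    unevaluable: list[str]

    @property
    def evaluable(self) -> bool:
        """False when every element's window fell outside the promoter."""
        return bool(self.all_matches)


def iupac_match(window: str, consensus: str) -> bool:
    """True iff every base of window is in the set denoted by its IUPAC code.

    Non-ACGT characters in the *window* never match (an N in the subject is
    unknown, not a wildcard).  Lengths must be equal.
    """
    if len(window) != len(consensus):
        raise ValueError(
            f"window length {len(window)} != consensus length {len(consensus)}"
        )
    for b, c in zip(window.upper(), consensus.upper()):
        if b not in IUPAC_CODES[c]:
            return False
    return True


def find_element_matches(p: PromoterRecord, d: CPEDefinition) -> list[CPEHit] | None:
    """All in-window matches of one element, or None if unevaluable.

    The element is evaluable only if the promoter covers the full search
    range ``canonical_start - max_shift .. canonical_start + max_shift +
    len(consensus) - 1``.
    """
    m = len(d.consensus)
    lo = d.canonical_start - d.max_shift
    hi = d.canonical_start + d.max_shift
    if lo + p.anchor < 0 or hi + m - 1 + p.anchor >= len(p.seq):
        return None
    hits = []
    for start in range(lo, hi + 1):
        i = start + p.anchor
        if iupac_match(p.seq[i : i + m], d.consensus):
            hits.append(CPEHit(element=d.name, start=start, shift=start - d.canonical_start))
    return hits


def scan_cpes(p: PromoterRecord, defs: Sequence[CPEDefinition]) -> ScanResult:
    """Scan one promoter for every defined element (sense strand only).

    Per element at most one best hit is kept: minimal |shift|, with the
    upstream (negative) shift winning ties.
    """
    best: list[CPEHit] = []
    all_matches: dict[str, list[CPEHit]] = {}
    unevaluable: list[str] = []
    for d in defs:
        matches = find_element_matches(p, d)
        if matches is None:
            unevaluable.append(d.name)
            continue
        all_matches[d.name] = matches
        if matches:
            best.append(min(matches, key=lambda h: (abs(h.shift), h.shift)))
    return ScanResult(hits=best, all_matches=all_matches, unevaluable=unevaluable)


def classify_promoter(hits: Iterable[CPEHit]) -> str:
    """Species label: '+'-joined element names by canonical position, or core-less.

    Presence/absence only; observed shifts are not part of the label.  The
    canonical position of a hit is recovered as ``start - shift``.
    """
    uniq: dict[str, int] = {}
    for h in hits:
        uniq.setdefault(h.element, h.start - h.shift)
    if not uniq:
        return CORE_LESS
    ordered = sorted(uniq, key=lambda name: (uniq[name], name))
    return "+".join(ordered)


def tabulate_species(labels: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Per-group species counts and percentages.

    Parameters
    ----------
    labels : iterable of (group key, species label)

    Returns
    -------
    DataFrame with columns ``group, species, count, percent``; within each
    group percentages sum to 100 and rows are ordered by descending percent
    (ties lexicographic by species).
    """
    df = pd.DataFrame(list(labels), columns=["group", "species"])
    if df.empty:
        return pd.DataFrame(columns=["group", "species", "count", "percent"])
    counts = (
        df.groupby(["group", "species"], sort=True).size().rename("count").reset_index()
    )
    counts["percent"] = counts.groupby("group")["count"].transform(
        lambda c: 100.0 * c / c.sum()
    )
    counts = counts.sort_values(
        ["group", "percent", "species"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return counts


def top_species(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k species per group by percentage (ties broken lexicographically)."""
    return (
        table.sort_values(["group", "percent", "species"], ascending=[True, False, True])
        .groupby("group", sort=True)
        .head(k)
        .reset_index(drop=True)
    )


def load_element_definitions(path: str | Path) -> list[CPEDefinition]:
    """Load element definitions from a YAML config.

    Schema: top-level ``elements:`` list of mappings with keys ``name``,
    ``consensus``, ``canonical_start`` and optional ``max_shift`` (default 5)
    and ``source``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "elements" not in doc:
        raise ValueError(f"{path}: expected a top-level 'elements' list")
    defs = []
    for item in doc["elements"]:
        defs.append(
            CPEDefinition(
                name=str(item["name"]),
                consensus=str(item["consensus"]).upper(),
                canonical_start=int(item["canonical_start"]),
                max_shift=int(item.get("max_shift", 5)),
                source=str(item.get("source", "")),
            )
        )
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate element names")
    return defs


def default_element_definitions() -> list[CPEDefinition]:
    """The packaged human Pol II element set (BREu, TATA, BREd, Inr, DPE)."""
    return load_element_definitions(Path(resources.files("promdpp") / "data" / "elements.yaml"))
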