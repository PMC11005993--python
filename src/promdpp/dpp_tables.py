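"""Step-parameter tables for DNA physical properties and sequence → value chains.

A DNA physical property (DPP) is described by a table assigning a real number
to every k-mer "step" of duplex DNA (k = 2 for dinucleotide steps, k = 4 for
tetranucleotide steps).  A nucleotide sequence of length L is converted into a
chain of L − k + 1 values by sliding a k-window along it with a 1-bp
frameshift; each value is reported at the TSS-relative coordinate of the
step's *first* base.  Windows containing a non-ACGT character yield a missing
value (NaN) rather than an error.

Five tables ship with the package (duplex DNA free energy, base stacking
energy, protein-induced deformability, rigidity, Z-DNA(AS) stabilizing
energy); any user table following the same TSV schema can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "StepParamTable",
    "PropertyChain",
    "load_step_table",
    "builtin_tables",
    "builtin_table",
    "sequence_to_chain",
    "BUILTIN_PROPERTY_NAMES",
]

_BASES = "ACGT"

#: canonical property names of the five packaged tables, in a fixed order
BUILTIN_PROPERTY_NAMES = (
    "duplex_free_energy",
    "base_stacking_energy",
    "deformability",
    "rigidity",
    "zdna_as_energy",
)

_BUILTIN_FILES = {
    "duplex_free_energy": "duplex_free_energy.tsv",
    "base_stacking_energy": "base_stacking_energy.tsv",
    "deformability": "deformability.tsv",
    "rigidity": "rigidity.synthetic.tsv",
    "zdna_as_energy": "zdna_as_energy.synthetic.tsv",
}


class StepTableError(ValueError):
    """Raised when a step-parameter file violates the schema."""


@dataclass(frozen=True)
class StepParamTable:
    """One physical property's k-mer → value map.

    Parameters
    ----------
    property_name : str
        Label of the property (e.g. ``duplex_free_energy``).
    step_size : int
        k of the step, 2 or 4.
    units : str
        Unit label carried through to outputs; never converted.
    values : mapping
        Exactly ``4**step_size`` entries keyed by upper-case k-mers over ACGT.
    source : str
        Citation / provenance label from the file header.
    """

    property_name: str
    step_size: int
    units: str
    values: Mapping[str, float]
    source: str = ""
    # dense lookup indexed by base-4 encoded k-mer, built once for fast chains
    _dense: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.step_size not in (2, 4):
            raise StepTableError(
                f"step_size must be 2 or 4, got {self.step_size!r}"
            )
        k = self.step_size
        expected = {"".join(p) for p in product(_BASES, repeat=k)}
        keys = set(self.values)
        if keys != expected:
            missing = sorted(expected - keys)[:3]
            extra = sorted(keys - expected)[:3]
            parts = []
            if missing:
                parts.append(f"missing key(s) e.g. {missing}")
            if extra:
                parts.append(f"invalid key(s) e.g. {extra}")
            raise StepTableError(
                f"{self.property_name}: table must have exactly 4^{k} k-mers: "
                + "; ".join(parts)
            )
        dense = np.empty(4 ** k, dtype=float)
        for kmer, v in self.values.items():
            idx = 0
            for b in kmer:
                idx = idx * 4 + _BASES.index(b)
            dense[idx] = float(v)
        object.__setattr__(self, "_dense", dense)

    def value(self, kmer: str) -> float:
        """Value of one step (upper-case ACGT k-mer)."""
        return self.values[kmer]


@dataclass
class PropertyChain:
    """Per-position numeric values of one property along one sequence.

    ``values[i]`` is the step value of the k-mer starting at sequence index
    ``i`` (NaN where the window contains a non-ACGT base); its TSS-relative
    coordinate is ``i - anchor_index``.
    """

    property_name: str
    values: np.ndarray
    anchor_index: int

    def __len__(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        """TSS-relative coordinate of each entry (first base of the step)."""
        return np.arange(len(self.values)) - self.anchor_index


def _parse_header(lines: list[str], path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    for key in ("property_name", "step_size", "units"):
        if key not in meta:
            raise StepTableError(f"{path}: header missing '# {key}:' line")
    return meta


def load_step_table(path: str | Path) -> StepParamTable:
    """Read a step-parameter TSV and validate it.

    The schema is: ``#``-prefixed header lines carrying ``property_name``,
    ``step_size``, ``units`` and optionally ``source``; then one
    ``KMER<TAB>value`` row per k-mer.  Duplicate, missing or malformed rows
    raise :class:`StepTableError` naming the offending row.
    """
    path = Path(path)
    header: list[str] = []
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise StepTableError(f"{path}:{lineno}: expected 'KMER<TAB>value'")
            kmer, sval = fields
            kmer = kmer.upper()
            if any(b not in _BASES for b in kmer):
                raise StepTableError(f"{path}:{lineno}: invalid k-mer {kmer!r}")
            if kmer in values:
                raise StepTableError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            try:
                values[kmer] = float(sval)
            except ValueError as exc:
                raise StepTableError(
                    f"{path}:{lineno}: non-numeric value {sval!r}"
                ) from exc
    meta = _parse_header(header, path)
    try:
        k = int(meta["step_size"])
    except ValueError as exc:
        raise StepTableError(f"{path}: non-integer step_size") from exc
    bad_len = [kmer for kmer in values if len(kmer) != k]
    if bad_len:
        raise StepTableError(
            f"{path}: k-mer(s) of length != {k}, e.g. {sorted(bad_len)[:3]}"
        )
    return StepParamTable(
        property_name=meta["property_name"],
        step_size=k,
        units=meta["units"],
        values=values,
        source=meta.get("source", ""),
    )


def _data_path(fname: str) -> Path:
    return Path(resources.files("promdpp") / "data" / fname)


def builtin_table(name: str) -> StepParamTable:
    """Load one of the five packaged tables by property name."""
    if name not in _BUILTIN_FILES:
        raise KeyError(
            f"unknown builtin property {name!r}; choose from {BUILTIN_PROPERTY_NAMES}"
        )
    return load_step_table(_data_path(_BUILTIN_FILES[name]))


def builtin_tables() -> list[StepParamTable]:
    """The five packaged DNA physical-property tables, in canonical order."""
    return [builtin_table(n) for n in BUILTIN_PROPERTY_NAMES]


def _encode(seq: str) -> np.ndarray:
    """Map a (case-folded) sequence to base codes 0..3, -1 for non-ACGT."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[arr == ord(b)] = i
    return codes


def sequence_to_chain(
    seq: str, table: StepParamTable, anchor: int = 0
) -> PropertyChain:
    """Convert a sequence into its chain of step values (1-bp frameshift).

    Parameters
    ----------
    seq : str
        Nucleotide sequence; lowercase is folded to uppercase, any non-ACGT
        character makes every step covering it missing (NaN).
    table : StepParamTable
        The property to evaluate.
    anchor : int
        Index of the TSS (or other alignment anchor) within ``seq``.

    Returns
    -------
    PropertyChain of length ``len(seq) - k + 1``.
    """
    k = table.step_size
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    if L < k:
        raise ValueError(f"sequence length {L} shorter than step size {k}")
    if not (0 <= anchor < L):
        raise ValueError(f"anchor {anchor} outside sequence of length {L}")
    codes = _encode(seq)
    n = L - k + 1
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        cj = codes[j : j + n]
        idx = idx * 4 + np.where(cj >= 0, cj, 0)
        valid &= cj >= 0
    vals = table._dense[idx]
    vals[~valid] = np.nan
    return PropertyChain(
        property_name=table.property_name, values=vals, anchor_index=anchor
    )
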