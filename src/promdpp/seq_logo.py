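"""Position frequency matrices and information content for sequence logos.

The logo is the standard relative-entropy (KL) logo: at each column the
information content IC = Σ_b f_b log2(f_b / q_b) (0·log 0 := 0) against a
background q, and each base is drawn with height f_b · IC.  With a uniform
background IC lies in [0, 2] bits.  Non-ACGT bases are tallied as "other"
and excluded from the frequency denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import PromoterRecord

__all__ = [
    "PositionFrequencyMatrix",
    "UNIFORM_BACKGROUND",
    "build_pfm",
    "frequencies",
    "information_content",
    "write_pfm_tsv",
    "plot_logo",
]

_ALPHABET = "ACGT"
UNIFORM_BACKGROUND = {b: 0.25 for b in _ALPHABET}


@dataclass
class PositionFrequencyMatrix:
    """Base counts per anchor-relative position over an aligned sequence set.

    ``counts`` has shape (len(positions), 4) for A/C/G/T; ``other`` counts
    non-ACGT bases, and per position A+C+G+T+other == n.
    """

    positions: np.ndarray
    counts: np.ndarray
    other: np.ndarray
    n: int

    def __post_init__(self) -> None:
        total = self.counts.sum(axis=1) + self.other
        if not np.all(total == self.n):
            raise ValueError("per-position counts do not sum to n")


def build_pfm(
    promoters: list[PromoterRecord], window: tuple[int, int] = (-5, 5)
) -> PositionFrequencyMatrix:
    """Tally sense-strand bases column-by-column over a TSS-relative window.

    Every promoter must cover the window.
    """
    if not promoters:
        raise ValueError("no sequences for PFM")
    lo, hi = window
    if lo > hi:
        raise ValueError(f"bad window {window}")
    width = hi - lo + 1
    counts = np.zeros((width, 4), dtype=np.int64)
    other = np.zeros(width, dtype=np.int64)
    index = {b: i for i, b in enumerate(_ALPHABET)}
    for p in promoters:
        seg = p.window(lo, hi).upper()
        for j, b in enumerate(seg):
            i = index.get(b)
            if i is None:
                other[j] += 1
            else:
                counts[j, i] += 1
    return PositionFrequencyMatrix(
        positions=np.arange(lo, hi + 1), counts=counts, other=other, n=len(promoters)
    )


def frequencies(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-position base frequencies over ACGT (non-ACGT excluded).

    Zero-coverage columns (all bases "other") are NaN.
    """
    denom = pfm.counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = pfm.counts / denom
    f[denom[:, 0] == 0] = np.nan
    return f


def information_content(
    pfm: PositionFrequencyMatrix, background: dict[str, float] | None = None
) -> np.ndarray:
    """Per-position information content in bits (relative entropy vs background).

    ``background`` maps A/C/G/T to probabilities summing to 1 (uniform by
    default).  Columns with zero ACGT coverage are NaN.
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    q = np.array([background[b] for b in _ALPHABET], dtype=float)
    if not np.isclose(q.sum(), 1.0):
        raise ValueError("background must sum to 1")
    if np.any(q <= 0):
        raise ValueError("background must have full support")
    f = frequencies(pfm)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(f > 0, f * np.log2(f / q), 0.0)
    ic = terms.sum(axis=1)
    ic[np.isnan(f).any(axis=1)] = np.nan
    return ic


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path: str | Path,
                  background: dict[str, float] | None = None) -> None:
    """Write the PFM with per-position IC as TSV."""
    ic = information_content(pfm, background)
    with open(path, "w") as fh:
        fh.write(f"# n: {pfm.n}\n")
        fh.write("position\tA\tC\tG\tT\tother\tic_bits\n")
        for i, pos in enumerate(pfm.positions):
            a, c, g, t = pfm.counts[i]
            ic_s = "NA" if np.isnan(ic[i]) else repr(float(ic[i]))
            fh.write(f"{pos}\t{a}\t{c}\t{g}\t{t}\t{pfm.other[i]}\t{ic_s}\n")


def plot_logo(
    pfm: PositionFrequencyMatrix,
    path: str | Path,
    background: dict[str, float] | None = None,
) -> None:
    """Render a KL sequence logo (letter height = frequency × IC, in bits)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    f = frequencies(pfm)
    ic = information_content(pfm, background)
    fig, ax = plt.subplots(figsize=(max(3, 0.45 * len(pfm.positions)), 2.4))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for i, pos in enumerate(pfm.positions):
        if np.isnan(ic[i]):
            continue
        y = 0.0
        order = np.argsort(f[i])  # smallest at the bottom
        for bi in order:
            h = float(f[i, bi] * ic[i])
            if h <= 0:
                continue
            letter = _ALPHABET[bi]
            tp = TextPath((0, 0), letter, size=1.0, prop=font)
            bbox = tp.get_extents()
            scale = Affine2D().translate(-bbox.x0, -bbox.y0).scale(
                0.9 / bbox.width, h / bbox.height
            ).translate(pos - 0.45, y)
            ax.add_patch(PathPatch(scale.transform_path(tp),
                                   facecolor=colors[letter], edgecolor="none"))
            y += h
    ax.set_xlim(pfm.positions[0] - 0.6, pfm.positions[-1] + 0.6)
    max_bits = 2.0 if background in (None, UNIFORM_BACKGROUND) else float(np.nanmax(ic)) or 1.0
    ax.set_ylim(0, max_bits)
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("bits")
    ax.set_xticks(pfm.positions[:: max(1, len(pfm.positions) // 11)])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
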