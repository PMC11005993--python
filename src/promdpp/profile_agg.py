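"""Anchor-aligned averaging of property chains into per-position profiles.

Chains are aligned at their anchors (TSS-relative position 0) and, at every
position covered by at least one chain, the mean and sample standard
deviation (n−1 denominator) of the non-missing values are computed, along
with the contributing count n.  SD is undefined (NaN, serialized "NA") where
n < 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dpp_tables import PropertyChain

__all__ = [
    "AggregateProfile",
    "Landmark",
    "Landmarks",
    "aggregate",
    "write_profile_tsv",
    "read_profile_tsv",
    "locate_landmarks",
    "plot_profile",
]


@dataclass
class AggregateProfile:
    """Per-position mean/SD/n of one property over an aligned promoter set."""

    property_name: str
    positions: np.ndarray  # contiguous, strictly increasing TSS-relative ints
    mean: np.ndarray
    sd: np.ndarray  # NaN where n < 2
    n: np.ndarray
    n_input: int = 0
    units: str = ""
    sd_convention: str = "sample (n-1)"

    def __len__(self) -> int:
        return len(self.positions)

    def at(self, position: int) -> tuple[float, float, int]:
        """(mean, sd, n) at one TSS-relative position."""
        i = int(position - self.positions[0])
        if not (0 <= i < len(self.positions)) or self.positions[i] != position:
            raise KeyError(f"position {position} not in profile")
        return float(self.mean[i]), float(self.sd[i]), int(self.n[i])


def aggregate(chains: list[PropertyChain]) -> AggregateProfile:
    """Average aligned chains position-by-position.

    All chains must share a property name; each carries its own anchor.
    Missing values (NaN) reduce that position's n.  Positions covered by zero
    chains are omitted.
    """
    if not chains:
        raise ValueError("no chains to aggregate")
    prop = chains[0].property_name
    if any(c.property_name != prop for c in chains):
        raise ValueError("mixed property names in aggregate()")
    lo = min(-c.anchor_index for c in chains)
    hi = max(len(c.values) - 1 - c.anchor_index for c in chains)
    width = hi - lo + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    aligned = []
    for c in chains:
        off = -c.anchor_index - lo
        vals = np.asarray(c.values, dtype=float)
        ok = ~np.isnan(vals)
        sl = slice(off, off + len(vals))
        total[sl] += np.where(ok, vals, 0.0)
        count[sl] += ok
        aligned.append((sl, vals, ok))
    # every position lies within some chain's span, so coverage is contiguous;
    # columns where all spanning values are missing get NaN mean with n = 0
    positions = np.arange(lo, hi + 1)
    cnt = count
    mean = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
    # two-pass sample variance: numerically exact even when SD << |mean|
    dev_sq = np.zeros(width)
    for sl, vals, ok in aligned:
        dev = np.where(ok, vals - np.nan_to_num(mean[sl]), 0.0)
        dev_sq[sl] += dev * dev
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dev_sq / (cnt - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    sd[cnt < 2] = np.nan
    return AggregateProfile(
        property_name=prop, positions=positions, mean=mean, sd=sd, n=cnt,
        n_input=len(chains),
    )


def write_profile_tsv(profile: AggregateProfile, path: str | Path, **meta) -> None:
    """Write a profile as TSV (position, mean, sd, n) with a '#' metadata header.

    Extra keyword arguments become additional header lines (e.g. anchor
    labels); NaN SD is serialized as "NA".  Floats use repr-precision so the
    paired reader round-trips losslessly.
    """
    with open(path, "w") as fh:
        fh.write(f"# property: {profile.property_name}\n")
        fh.write(f"# units: {profile.units}\n")
        fh.write(f"# n_input: {profile.n_input}\n")
        fh.write(f"# sd_convention: {profile.sd_convention}\n")
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("position\tmean\tsd\tn\n")
        for pos, m, s, n in zip(profile.positions, profile.mean, profile.sd, profile.n):
            m_str = "NA" if math.isnan(m) else repr(float(m))
            s_str = "NA" if math.isnan(s) else repr(float(s))
            fh.write(f"{pos}\t{m_str}\t{s_str}\t{n}\n")


def read_profile_tsv(path: str | Path) -> AggregateProfile:
    """Read a profile TSV written by :func:`write_profile_tsv`."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, float, float, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
                continue
            if not line or line.startswith("position\t"):
                continue
            pos, m, s, n = line.split("\t")
            rows.append((int(pos), float("nan") if m == "NA" else float(m),
                         float("nan") if s == "NA" else float(s), int(n)))
    if not rows:
        raise ValueError(f"{path}: no profile rows")
    positions, mean, sd, n = map(np.array, zip(*rows))
    return AggregateProfile(
        property_name=meta.get("property", ""),
        positions=positions.astype(np.int64),
        mean=mean.astype(float), sd=sd.astype(float), n=n.astype(np.int64),
        n_input=int(meta.get("n_input", 0) or 0),
        units=meta.get("units", ""),
        sd_convention=meta.get("sd_convention", "sample (n-1)"),
    )


@dataclass(frozen=True)
class Landmark:
    """An extremum of the mean profile relative to the out-of-window baseline."""

    position: int
    direction: str  # "peak" or "trough"
    magnitude: float  # |mean - baseline| at the extremum
    distinctive: bool  # magnitude exceeds threshold_mads * out-of-window MAD


@dataclass(frozen=True)
class Landmarks:
    tss: Landmark
    upstream: Landmark
    baseline: float
    mad: float


def _window_mask(positions: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    if lo > hi:
        raise ValueError(f"bad window {window}")
    return (positions >= lo) & (positions <= hi)


def locate_landmarks(
    profile: AggregateProfile,
    window_tss: tuple[int, int] = (-5, 5),
    window_upstream: tuple[int, int] = (-35, -20),
    threshold_mads: float = 5.0,
) -> Landmarks:
    """Locate the profile extrema near the TSS and near position −27.

    Within each window the position maximizing |mean − baseline| is reported,
    where the baseline is the median of the mean over all positions outside
    both windows and the noise scale is the median absolute deviation (MAD)
    of those outside means.  A landmark is flagged ``distinctive`` when its
    magnitude exceeds ``threshold_mads × MAD``; a flat profile yields
    magnitude ≈ 0 and no flag.
    """
    pos = profile.positions
    m_tss = _window_mask(pos, window_tss)
    m_up = _window_mask(pos, window_upstream)
    if not m_tss.any() or not m_up.any():
        raise ValueError("profile does not cover the requested windows")
    outside = ~(m_tss | m_up)
    if not outside.any():
        raise ValueError("no positions outside the landmark windows for a baseline")
    base_vals = profile.mean[outside]
    baseline = float(np.median(base_vals))
    mad = float(np.median(np.abs(base_vals - baseline)))

    def _find(mask: np.ndarray) -> Landmark:
        dev = profile.mean[mask] - baseline
        i = int(np.argmax(np.abs(dev)))
        mag = float(abs(dev[i]))
        return Landmark(
            position=int(pos[mask][i]),
            direction="peak" if dev[i] >= 0 else "trough",
            magnitude=mag,
            distinctive=bool(mag > threshold_mads * mad),
        )

    return Landmarks(tss=_find(m_tss), upstream=_find(m_up), baseline=baseline, mad=mad)


def plot_profile(
    profile: AggregateProfile,
    path: str | Path,
    guides: tuple[int, ...] = (0, -27),
    show_sd: bool = False,
) -> None:
    """Plot mean (±SD band if requested) vs position with dotted guide lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(profile.positions, profile.mean, lw=1.2, color="tab:blue")
    if show_sd:
        ax.fill_between(
            profile.positions,
            profile.mean - np.nan_to_num(profile.sd),
            profile.mean + np.nan_to_num(profile.sd),
            alpha=0.2, color="tab:blue", linewidth=0,
        )
    for g in guides:
        if profile.positions[0] <= g <= profile.positions[-1]:
            ax.axvline(g, ls=":", color="k", lw=0.8)
    ax.set_xlabel("position relative to anchor (bp)")
    label = profile.property_name + (f" ({profile.units})" if profile.units else "")
    ax.set_ylabel(label)
    ax.set_title(f"{profile.property_name}  (n={profile.n_input})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
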