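"""Nucleosome-occupancy quantities derived from fragment sets.

Three related but distinct measures are computed around transcription
start sites:

* **TSS RPKM** — fragments whose midpoint falls in ``[tss - flank,
  tss + flank)`` counted per TSS and normalized as reads per kilobase
  per million mapped fragments. Midpoint counting means every fragment
  contributes to at most one position, matching the midpoint-density
  convention for nucleosome maps.
* **Metagene profile** — mean per-base read depth at strand-oriented
  offsets from a set of TSSs (upstream is always negative), averaged
  over TSSs and then over samples.
* **NDR depth** — total per-base depth summed over the nucleosome-
  depleted region, by default -150..+50 bp relative to the TSS,
  mirrored on the '-' strand.

Metagene and NDR depth use full per-base fragment coverage (read-depth
semantics); RPKM uses the midpoint rule.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import FragmentSet, TssTable

DEFAULT_FLANK = 1000
DEFAULT_NDR_WINDOW = (-150, 50)


@dataclasses.dataclass
class OccupancyMatrix:
    """Feature x sample matrix of TSS occupancy (RPKM)."""

    df: pd.DataFrame  # rows: tss_ids, columns: sample_ids
    window_flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if (self.df.to_numpy() < 0).any():
            raise ParameterError("occupancy values must be non-negative")

    @property
    def tss_ids(self) -> list:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


@dataclasses.dataclass
class MetageneProfile:
    """Mean depth per strand-oriented offset around a TSS set."""

    positions: np.ndarray  # signed offsets, -flank .. +flank-1
    mean_depth: np.ndarray
    n_tss: int
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "mean_depth": self.mean_depth})


@dataclasses.dataclass
class FragmentLengthSummary:
    mean: float
    sd: float
    histogram: pd.Series  # index: length in bp, values: counts


def _sorted_midpoints_by_chrom(fragments: FragmentSet) -> dict:
    out = {}
    mids = fragments.midpoints
    for chrom in pd.unique(fragments.chroms):
        m = mids[fragments.chroms == chrom]
        m.sort()
        out[str(chrom)] = m
    return out


def compute_tss_rpkm(
    fragments: FragmentSet, tss: TssTable, flank: int = DEFAULT_FLANK
) -> pd.Series:
    """RPKM of fragment midpoints in ``[tss - flank, tss + flank)`` per TSS.

    ``RPKM = count / ((2 * flank / 1000) * (total_count / 1e6))``. Windows
    clipped at a chromosome start simply lose the out-of-range territory;
    no rescaling is applied.
    """
    if fragments.total_count == 0:
        raise ParameterError(
            f"sample {fragments.sample_id!r} has no fragments; RPKM undefined"
        )
    if flank <= 0:
        raise ParameterError("flank must be positive")
    mids = _sorted_midpoints_by_chrom(fragments)
    counts = np.zeros(len(tss), dtype=np.int64)
    chrom_col = tss.df["chrom"].to_numpy()
    tss_col = tss.df["tss"].to_numpy()
    for chrom in np.unique(chrom_col):
        sel = chrom_col == chrom
        m = mids.get(str(chrom))
        if m is None:
            continue
        lo = np.searchsorted(m, tss_col[sel] - flank, side="left")
        hi = np.searchsorted(m, tss_col[sel] + flank, side="left")
        counts[sel] = hi - lo
    kb = 2.0 * flank / 1000.0
    per_million = fragments.total_count / 1e6
    rpkm = counts / (kb * per_million)
    return pd.Series(rpkm, index=tss.df.index, name=fragments.sample_id)


def occupancy_matrix(
    fragment_sets: Sequence[FragmentSet], tss: TssTable, flank: int = DEFAULT_FLANK
) -> OccupancyMatrix:
    """Stack per-sample RPKM columns into an OccupancyMatrix."""
    cols = [compute_tss_rpkm(fs, tss, flank) for fs in fragment_sets]
    df = pd.concat(cols, axis=1)
    return OccupancyMatrix(df=df, window_flank=flank)


def _depth_array(starts: np.ndarray, ends: np.ndarray, length: int) -> np.ndarray:
    """Per-base coverage depth over [0, length) via a difference array."""
    diff = np.zeros(length + 1, dtype=np.int64)
    s = np.clip(starts, 0, length)
    e = np.clip(ends, 0, length)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    return np.cumsum(diff[:-1])


def _chrom_depths(fragments: FragmentSet, needed_extent: dict) -> dict:
    depths = {}
    by_chrom = fragments.by_chrom()
    for chrom, extent in needed_extent.items():
        if chrom in by_chrom:
            s, e = by_chrom[chrom]
            length = max(extent, int(e.max()) if len(e) else 0)
        else:
            s = e = np.empty(0, dtype=np.int64)
            length = extent
        depths[chrom] = _depth_array(s, e, length)
    return depths


def ndr_genomic_window(tss_pos: int, strand: str, window=DEFAULT_NDR_WINDOW) -> tuple:
    """Genomic half-open interval of the NDR window, strand-mirrored.

    For window (a, b): '+' strand gives [t + a, t + b); '-' strand gives
    [t - b + 1, t - a + 1), so that an offset x upstream of the TSS is
    upstream on both strands.
    """
    a, b = window
    if strand == "+":
        return tss_pos + a, tss_pos + b
    return tss_pos - b + 1, tss_pos - a + 1


def compute_ndr_depth(
    fragments: FragmentSet, tss: TssTable, window=DEFAULT_NDR_WINDOW
) -> pd.Series:
    """Total per-base depth over the NDR window for every TSS."""
    a, b = window
    if not a < b:
        raise ParameterError("NDR window start must be below its end")
    extent: dict = {}
    windows = []
    for r in tss.records:
        lo, hi = ndr_genomic_window(r.tss, r.strand, window)
        windows.append((r.chrom, max(lo, 0), max(hi, 0)))
        extent[r.chrom] = max(extent.get(r.chrom, 0), hi)
    depths = _chrom_depths(fragments, extent)
    prefix = {c: np.concatenate(([0], np.cumsum(d))) for c, d in depths.items()}
    vals = np.empty(len(windows), dtype=np.int64)
    for i, (chrom, lo, hi) in enumerate(windows):
        p = prefix[chrom]
        vals[i] = p[min(hi, len(p) - 1)] - p[min(lo, len(p) - 1)]
    return pd.Series(vals, index=tss.df.index, name=fragments.sample_id)


def compute_metagene_profile(
    fragment_sets: Sequence[FragmentSet] | FragmentSet,
    tss: TssTable,
    subset_ids,
    flank: int = DEFAULT_FLANK,
) -> MetageneProfile:
    """Mean per-base depth at strand-oriented offsets -flank..flank-1.

    Depth at offset ``o`` for a '+' TSS at ``t`` is coverage of base
    ``t + o``; for a '-' TSS it is coverage of ``t - o``. Out-of-range
    bases contribute zero depth. The profile is averaged over the TSS
    subset, then over samples.
    """
    if isinstance(fragment_sets, FragmentSet):
        fragment_sets = [fragment_sets]
    subset_ids = list(subset_ids)
    if not subset_ids:
        raise ParameterError("TSS subset must be non-empty")
    missing = [g for g in subset_ids if g not in tss.df.index]
    if missing:
        raise ParameterError(f"TSS subset ids not in table: {missing[:3]}")
    sub = tss.df.loc[subset_ids]
    offsets = np.arange(-flank, flank)
    t = sub["tss"].to_numpy()
    sign = np.where(sub["strand"].to_numpy() == "+", 1, -1)
    # genomic base per (tss, offset)
    genomic = t[:, None] + sign[:, None] * offsets[None, :]
    chrom_col = sub["chrom"].to_numpy()
    extent = {c: int(genomic[chrom_col == c].max()) + 1 for c in np.unique(chrom_col)}

    acc = np.zeros(2 * flank, dtype=float)
    for fs in fragment_sets:
        depths = _chrom_depths(fs, extent)
        per_sample = np.zeros(2 * flank, dtype=float)
        for chrom in np.unique(chrom_col):
            d = depths[chrom]
            g = genomic[chrom_col == chrom]
            idx = np.clip(g, 0, len(d) - 1)
            vals = d[idx]
            vals[(g < 0) | (g >= len(d))] = 0
            per_sample += vals.sum(axis=0)
        acc += per_sample / len(subset_ids)
    return MetageneProfile(
        positions=offsets,
        mean_depth=acc / len(fragment_sets),
        n_tss=len(subset_ids),
        n_samples=len(fragment_sets),
    )


def fragment_length_summary(fragments: FragmentSet) -> FragmentLengthSummary:
    """Exact mean, population sd, and per-bp histogram of fragment lengths."""
    if fragments.total_count == 0:
        raise ParameterError("cannot summarize an empty fragment set")
    lengths = fragments.lengths
    hist = pd.Series(lengths).value_counts().sort_index()
    hist.index.name = "length_bp"
    return FragmentLengthSummary(
        mean=float(lengths.mean()),
        sd=float(lengths.std(ddof=0)),
        histogram=hist,
    )
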