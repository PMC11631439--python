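"""Depth-normalized CNV regions, per-CDS copy summaries, and aneuploidy calls.

Raw per-window depth (1-kb non-overlapping bins) is normalized by a
genome-wide center to a normalized read depth (RD). Runs of consecutive
windows with |RD − 1| above a threshold are merged into CNV regions carrying
the mean RD of their windows — a deliberately simple threshold-merge
segmenter; the downstream rules only need regions and their RD. Every
position outside a region has RD exactly 1; each CDS gets the median RD
over its positions; a chromosome is aneuploid when strictly more than half
its length lies in CNV regions.

Coordinates are BED-style 0-based half-open throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

WINDOW_SIZE = 1000


@dataclass
class DepthProfile:
    """Raw mean depth per 1-kb window, per chromosome, for one sample."""

    sample: str
    depths: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    window_size: int = WINDOW_SIZE


@dataclass
class NormalizedDepthTrack:
    sample: str
    rd: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    center: float
    window_size: int = WINDOW_SIZE


@dataclass(frozen=True)
class CNVRegion:
    chrom: str
    start: int  # 0-based half-open, bp
    end: int
    rd: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneCNVRecord:
    gene: str
    sample: str
    median_rd: float


@dataclass(frozen=True)
class AneuploidyCall:
    sample: str
    chrom: str
    cnv_fraction: float
    aneuploid: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_depth_bed(path: str, sample: str = "") -> DepthProfile:
    """Load a per-window depth table (chrom, start, end, depth; BED-like TSV)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"], comment="#"
    )
    depths: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        depths[str(chrom)] = grp["depth"].to_numpy(dtype=float)
        lengths[str(chrom)] = int(grp["end"].max())
    return DepthProfile(sample=sample, depths=depths, chrom_lengths=lengths)


def normalize_depth(profile: DepthProfile, center_method: str = "median") -> NormalizedDepthTrack:
    """RD = raw depth / genome-wide center.

    center_method 'median' (robust default) or 'mode' (argmax of a smoothed
    depth histogram; preferable when aneuploid chromosomes dominate and bias
    the median).
    """
    allw = np.concatenate([v for v in profile.depths.values()]) if profile.depths else np.array([])
    if allw.size == 0 or not (allw > 0).any():
        raise ValueError("depth profile is empty or all-zero")
    if center_method == "median":
        center = float(np.median(allw))
    elif center_method == "mode":
        pos = allw[allw > 0]
        hist, edges = np.histogram(pos, bins=min(200, max(10, pos.size // 5)))
        smooth = gaussian_filter1d(hist.astype(float), sigma=2)
        k = int(np.argmax(smooth))
        center = float((edges[k] + edges[k + 1]) / 2)
    else:
        raise ValueError(f"unknown center_method {center_method!r}")
    if center <= 0:
        raise ValueError("normalization center must be positive")
    rd = {c: d / center for c, d in profile.depths.items()}
    return NormalizedDepthTrack(
        sample=profile.sample,
        rd=rd,
        chrom_lengths=dict(profile.chrom_lengths),
        center=center,
        window_size=profile.window_size,
    )


def segment_cnv(
    track: NormalizedDepthTrack, delta: float = 0.25, min_windows: int = 2
) -> list[CNVRegion]:
    """Merge runs of >= min_windows consecutive windows with |RD − 1| > delta.

    Region RD is the mean of its member windows; coordinates are clipped to
    the chromosome length (the last window may be short).
    """
    regions: list[CNVRegion] = []
    w = track.window_size
    for chrom, rd in track.rd.items():
        is_cnv = np.abs(rd - 1.0) > delta
        clen = track.chrom_lengths.get(chrom, len(rd) * w)
        # run-length scan over the boolean mask
        i = 0
        n = len(rd)
        while i < n:
            if not is_cnv[i]:
                i += 1
                continue
            j = i
            while j < n and is_cnv[j]:
                j += 1
            if j - i >= min_windows:
                regions.append(
                    CNVRegion(
                        chrom=chrom,
                        start=i * w,
                        end=min(j * w, clen),
                        rd=float(np.mean(rd[i:j])),
                    )
                )
            i = j
    return regions


class PositionRD:
    """Per-position normalized depth: region RD inside a CNV, exactly 1 outside."""

    def __init__(self, regions: Sequence[CNVRegion], chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in chrom_lengths:
            regs = sorted((r for r in regions if r.chrom == chrom), key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping CNV regions on {chrom}")
            self._by_chrom[chrom] = (
                np.array([r.start for r in regs], dtype=np.int64),
                np.array([r.end for r in regs], dtype=np.int64),
                np.array([r.rd for r in regs], dtype=float),
            )

    def at(self, chrom: str, pos: int) -> float:
        """RD at a single 0-based position."""
        clen = self.chrom_lengths.get(chrom)
        if clen is None or not 0 <= pos < clen:
            raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
        starts, ends, rds = self._by_chrom[chrom]
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k >= 0 and pos < ends[k]:
            return float(rds[k])
        return 1.0

    def interval_segments(self, chrom: str, start: int, end: int) -> list[tuple[float, int]]:
        """Piecewise-constant (rd, length) decomposition of [start, end)."""
        clen = self.chrom_lengths.get(chrom)
        if clen is None or not (0 <= start < end <= clen):
            raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome bounds")
        starts, ends, rds = self._by_chrom[chrom]
        segs: list[tuple[float, int]] = []
        cur = start
        for s, e, r in zip(starts, ends, rds):
            if e <= cur or s >= end:
                continue
            if s > cur:
                segs.append((1.0, int(s - cur)))
                cur = int(s)
            stop = int(min(e, end))
            segs.append((float(r), stop - cur))
            cur = stop
        if cur < end:
            segs.append((1.0, int(end - cur)))
        return segs


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of a population where values[i] occurs weights[i] times."""
    order = np.argsort(values)
    v, w = values[order], weights[order].astype(np.int64)
    total = int(w.sum())
    cum = np.cumsum(w)
    if total % 2 == 1:
        k = total // 2  # 0-based middle
        return float(v[np.searchsorted(cum, k + 1)])
    k1, k2 = total // 2 - 1, total // 2
    lo = v[np.searchsorted(cum, k1 + 1)]
    hi = v[np.searchsorted(cum, k2 + 1)]
    return float((lo + hi) / 2)


def cds_median_rd(
    cds: pd.DataFrame, regions: Sequence[CNVRegion], chrom_lengths: dict[str, int],
    sample: str = "",
) -> list[GeneCNVRecord]:
    """Median normalized depth per CDS.

    ``cds`` is a BED-like frame (chrom, start, end, name); rows sharing a
    name (multi-exon CDS) pool all their positions before the median.
    """
    accessor = PositionRD(regions, chrom_lengths)
    records: list[GeneCNVRecord] = []
    for name, grp in cds.groupby("name", sort=False):
        vals: list[float] = []
        wts: list[int] = []
        for _, row in grp.iterrows():
            if row["end"] <= row["start"]:
                raise ValueError(f"zero-length CDS interval for {name!r}")
            for rd, length in accessor.interval_segments(
                str(row["chrom"]), int(row["start"]), int(row["end"])
            ):
                vals.append(rd)
                wts.append(length)
        records.append(
            GeneCNVRecord(
                gene=str(name),
                sample=sample,
                median_rd=_weighted_median(np.array(vals), np.array(wts)),
            )
        )
    return records


def call_aneuploidy(
    regions: Sequence[CNVRegion], chrom_lengths: dict[str, int], sample: str = ""
) -> list[AneuploidyCall]:
    """Aneuploid iff strictly more than half the chromosome length is in CNV."""
    calls = []
    for chrom, clen in chrom_lengths.items():
        covered = sum(r.length for r in regions if r.chrom == chrom)
        frac = covered / clen
        calls.append(AneuploidyCall(sample=sample, chrom=chrom, cnv_fraction=frac,
                                    aneuploid=frac > 0.5))
    return calls


def read_chrom_lengths(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return {str(r.chrom): int(r.length) for r in df.itertuples()}


def read_cds_bed(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"], comment="#"
    )
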