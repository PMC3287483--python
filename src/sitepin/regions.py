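"""Step 1: detect tag-enriched binding regions.

Tags from both strands are pooled and clustered by proximity; each cluster
is tested for enrichment against a dynamic local Poisson rate (the maximum
of the genome-wide background rate and rates measured in windows around the
cluster, control-normalized when control data are available), corrected for
multiple testing by Benjamini-Hochberg, filtered at the requested FDR and
finally trimmed to the bases whose smoothed tag density exceeds the local
noise level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .config import RunConfig
from .io import FORWARD, REVERSE, TagTrack
from .smoothing import smooth_counts

log = logging.getLogger(__name__)


@dataclass
class TagCluster:
    """A maximal run of tags in which successive positions differ by <= gap."""

    chrom: str
    start: int
    end: int  # half-open; start..end spans the member tag positions
    positions: np.ndarray = field(repr=False)
    strand_scope: str = "both"

    @property
    def count(self) -> int:
        return len(self.positions)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class LambdaContext:
    """Per-base Poisson rates entering the dynamic null for one cluster."""

    lambda_bg: float
    lambda_5k: float | None = None
    lambda_10k: float | None = None
    lambda_control: float | None = None
    lambda_control_1k: float | None = None
    r_control2chip: float | None = None
    lambda_local: float = 0.0


@dataclass
class BindingRegion:
    """A significantly tag-enriched region with annotation and refined bounds."""

    chrom: str
    start: int
    end: int
    count: int
    positions: np.ndarray = field(repr=False)
    lambda_ctx: LambdaContext | None = None
    pvalue: float = math.nan
    qvalue: float = math.nan
    refined_start: int | None = None
    refined_end: int | None = None
    region_id: str = ""

    @property
    def density(self) -> float:
        """Total tag count divided by the region length (tags/bp)."""
        return self.count / (self.end - self.start)

    @classmethod
    def spanning(cls, chrom: str, positions: np.ndarray, region_id: str = "") -> "BindingRegion":
        """Minimal region spanning a set of tag positions (used when regions
        are known a priori, e.g. for simulated data)."""
        positions = np.sort(np.asarray(positions, dtype=np.int64))
        if positions.size == 0:
            raise ValueError("cannot span an empty tag set")
        return cls(
            chrom=chrom,
            start=int(positions[0]),
            end=int(positions[-1]) + 1,
            count=len(positions),
            positions=positions,
            region_id=region_id,
        )


def cluster_tags(
    positions: np.ndarray, gap: int, chrom: str = "", strand_scope: str = "both"
) -> list[TagCluster]:
    """Partition sorted tag positions into maximal runs with inter-tag
    distance <= ``gap``.

    The cluster span is ``[first_tag, last_tag + 1)``.  Raises on unsorted
    input rather than silently sorting, since callers hold sorted tracks.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if positions.size == 0:
        return []
    if np.any(np.diff(positions) < 0):
        raise ValueError("tag positions must be sorted")
    breaks = np.flatnonzero(np.diff(positions) > gap) + 1
    return [
        TagCluster(chrom, int(run[0]), int(run[-1]) + 1, run, strand_scope)
        for run in np.split(positions, breaks)
    ]


def filter_clusters(
    clusters: list[TagCluster], min_tags: int = 10, min_len: int = 100
) -> list[TagCluster]:
    """Keep clusters with at least ``min_tags`` tags and span >= ``min_len`` bp."""
    return [c for c in clusters if c.count >= min_tags and (c.end - c.start) >= min_len]


def _window_rate(track: TagTrack, chrom: str, center: int, width: int) -> float:
    lo = max(0, center - width // 2)
    hi = center + width - width // 2
    if hi <= lo:
        return 0.0
    return track.count_in(chrom, lo, hi) / (hi - lo)


def local_lambda(
    cluster: TagCluster,
    chip: TagTrack,
    control: TagTrack | None,
    effective_genome: float,
) -> LambdaContext:
    """Dynamic per-base Poisson rate for one cluster.

    Without control data the rate is the maximum of the genome-wide
    background and the rates in 5-kb and 10-kb windows centered at the
    cluster midpoint.  With control data it is the maximum of the background
    and the depth-normalized control rates measured over the cluster's own
    interval and a 1-kb window at its midpoint.  Windows are truncated at
    coordinate 0 and rates use the actual truncated width.
    """
    if effective_genome <= 0:
        raise ValueError("effective_genome must be positive")
    lam_bg = chip.total() / effective_genome
    ctx = LambdaContext(lambda_bg=lam_bg)
    if control is None:
        ctx.lambda_5k = _window_rate(chip, cluster.chrom, cluster.midpoint, 5_000)
        ctx.lambda_10k = _window_rate(chip, cluster.chrom, cluster.midpoint, 10_000)
        ctx.lambda_local = max(lam_bg, ctx.lambda_5k, ctx.lambda_10k)
    else:
        total_control = control.total()
        if total_control == 0:
            raise ValueError("control track supplied but contains no tags")
        ratio = chip.total() / total_control
        ctx.r_control2chip = ratio
        span = cluster.end - cluster.start
        ctx.lambda_control = (
            control.count_in(cluster.chrom, cluster.start, cluster.end) / span
        )
        ctx.lambda_control_1k = _window_rate(control, cluster.chrom, cluster.midpoint, 1_000)
        ctx.lambda_local = max(
            lam_bg, ratio * ctx.lambda_control, ratio * ctx.lambda_control_1k
        )
    return ctx


def poisson_pvalue(count: int, lambda_local: float, region_len: int) -> float:
    """Upper-tail Poisson probability P(X >= count) with mean
    ``lambda_local * region_len``."""
    if count < 0 or lambda_local < 0 or region_len < 0:
        raise ValueError("count, rate and length must be nonnegative")
    mean = lambda_local * region_len
    if mean <= 0:
        raise ValueError("lambda_local * region_len must be positive")
    if count == 0:
        return 1.0
    return float(poisson.sf(count - 1, mean))


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, in the input order.

    q_raw = p * Count / Rank on the p-sorted list, then step-up
    monotonized (cumulative minimum from the least significant end) and
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def refine_boundaries(
    cluster: TagCluster | BindingRegion, lambda_local: float, smooth_b: int = 20
) -> tuple[int, int]:
    """Trim a cluster to the outermost bases whose smoothed per-base tag-start
    density (both strands pooled) exceeds ``lambda_local``.

    Falls back to the original bounds (with a warning) when no base clears
    the noise level.
    """
    span = cluster.end - cluster.start
    if span <= 0 or len(cluster.positions) == 0:
        raise ValueError("cluster must contain at least one tag")
    counts = np.bincount(cluster.positions - cluster.start, minlength=span)
    density = smooth_counts(counts, smooth_b)
    above = np.flatnonzero(density > lambda_local)
    if above.size == 0:
        log.warning(
            "no base above noise level in %s:%d-%d; keeping original bounds",
            cluster.chrom, cluster.start, cluster.end,
        )
        return cluster.start, cluster.end
    return cluster.start + int(above[0]), cluster.start + int(above[-1]) + 1


def detect_regions(
    chip: TagTrack, control: TagTrack | None = None, config: RunConfig | None = None
) -> list[BindingRegion]:
    """Run the full region-detection step and return regions with Q <= fdr,
    sorted by coordinate."""
    config = config or RunConfig()
    candidates: list[tuple[TagCluster, LambdaContext, float]] = []
    for chrom in chip.chroms:
        clusters = cluster_tags(chip.combined(chrom), config.gap, chrom)
        for cl in filter_clusters(clusters, config.min_tags, config.min_len):
            ctx = local_lambda(cl, chip, control, config.effective_genome)
            p = poisson_pvalue(cl.count, ctx.lambda_local, cl.end - cl.start)
            candidates.append((cl, ctx, p))
    if not candidates:
        return []
    qvals = bh_qvalues(np.array([p for _, _, p in candidates]))
    regions: list[BindingRegion] = []
    for (cl, ctx, p), q in zip(candidates, qvals):
        if q > config.fdr:
            continue
        r_start, r_end = refine_boundaries(cl, ctx.lambda_local, config.smooth_b)
        regions.append(
            BindingRegion(
                chrom=cl.chrom,
                start=cl.start,
                end=cl.end,
                count=cl.count,
                positions=cl.positions,
                lambda_ctx=ctx,
                pvalue=p,
                qvalue=float(q),
                refined_start=r_start,
                refined_end=r_end,
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    for i, r in enumerate(regions):
        r.region_id = f"region{i}"
    return regions


def rank_by_density(regions: list[BindingRegion], top_fraction: float) -> list[BindingRegion]:
    """The ceil(top_fraction * N) densest regions, densest first.

    Ties broken by higher tag count, then by coordinate.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if not regions:
        return []
    ordered = sorted(regions, key=lambda r: (-r.density, -r.count, r.chrom, r.start))
    k = math.ceil(top_fraction * len(ordered))
    return ordered[:k]
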