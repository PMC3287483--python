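"""Step 2: pinpoint binding sites within enriched regions.

Each strand is processed separately.  Per-base 5'-end counts are smoothed
with a moving average, then a window of width W slides base by base along
the region and the single-site template f_tag is fitted to the windowed
density by no-intercept least squares.  The slope is the relative binding
affinity and the (uncentered) goodness of fit R^2 peaks where the observed
pileup matches the template anchored at a binding site.  Peaks passing a
slope threshold become strand-level site calls, and calls from the two
strands closer than the merge distance are combined at their midpoint.

Geometry: forward-strand tags pile up upstream of the site (5' ends at
site - d), reverse-strand tags downstream (at site + d).  The reverse
profile therefore matches the template read left to right with the site at
the window start, while the forward profile is its coordinate mirror and is
scanned on the reversed count vector, positions mapped back afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io import FORWARD, REVERSE, TagTrack
from .regions import BindingRegion
from .smoothing import smooth_counts
from .tagmodel import ProfileModel

log = logging.getLogger(__name__)


@dataclass
class StrandProfile:
    """Raw and smoothed per-base tag-start counts of one strand in a region."""

    chrom: str
    start: int  # genomic coordinate of index 0
    strand: str
    t: np.ndarray = field(repr=False)
    s: np.ndarray | None = field(default=None, repr=False)

    @property
    def C(self) -> int:
        return len(self.t)


@dataclass
class FitCurve:
    """Per-window slopes and goodness of fit along a region, one strand.

    ``pos[k]`` is the genomic coordinate of the putative site (template
    position 0) for window k; positions are ascending.
    """

    pos: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    r2: np.ndarray = field(repr=False)
    W: int = 0
    strand: str = ""


@dataclass
class BindingSite:
    """A single-base binding-site call."""

    chrom: str
    pos: int
    affinity: float
    r2: float
    evidence: str  # F, R or FR
    region_id: str = ""


def window_fit(s: np.ndarray, j: int, x: np.ndarray) -> tuple[float, float]:
    """No-intercept least-squares fit of template ``x`` to ``s[j:j+W]``.

    Returns (beta, r2) with beta = sum(x*y)/sum(x^2) and
    r2 = 1 - SSE / sum(y^2) (uncentered total sum of squares, the natural
    choice for a through-the-origin model).  An all-zero window returns
    (0, 0) by convention.
    """
    W = len(x)
    if j < 0 or j + W > len(s):
        raise ValueError("window outside profile")
    y = np.asarray(s[j : j + W], dtype=float)
    syy = float(y @ y)
    if syy == 0.0:
        return 0.0, 0.0
    sxx = float(x @ x)
    sxy = float(x @ y)
    beta = sxy / sxx
    r2 = sxy * sxy / (sxx * syy)
    return beta, min(max(r2, 0.0), 1.0)


def scan_region(
    profile: StrandProfile, model: ProfileModel, W: int, smooth_b: int = 20
) -> FitCurve:
    """Slide the fitting window base by base along one strand of a region.

    Smoothing is applied in scan orientation (reversed for the forward
    strand) so that the procedure is exactly mirror symmetric between
    strands.  If the region is shorter than W the window shrinks to the
    region length with a warning.
    """
    C = profile.C
    if C == 0:
        return FitCurve(np.empty(0, dtype=np.int64), np.empty(0), np.empty(0), W, profile.strand)
    if W > C:
        log.warning("region length %d < window %d; shrinking window", C, W)
        W = C
    if W < 1:
        raise ValueError("window width must be >= 1")
    x = model.f_tag[:W]
    oriented = profile.t[::-1] if profile.strand == FORWARD else profile.t
    s = smooth_counts(oriented, smooth_b)
    profile.s = s[::-1].copy() if profile.strand == FORWARD else s.copy()

    ones = np.ones(W)
    sxy = np.correlate(s, x, mode="valid")
    syy = np.correlate(s * s, ones, mode="valid")
    sxx = float(x @ x)
    beta = sxy / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, (sxy * sxy) / (sxx * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    beta = np.where(syy > 0, beta, 0.0)

    k = np.arange(C - W + 1)
    if profile.strand == FORWARD:
        pos = profile.start + (C - 1 - k)
        return FitCurve(pos[::-1].copy(), beta[::-1].copy(), r2[::-1].copy(), W, profile.strand)
    return FitCurve(profile.start + k, beta, r2, W, profile.strand)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus contribute their first index, and a
    boundary window counts when it is >= its only neighbour."""
    n = len(values)
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([0])
    keep = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok:
            keep.append(i)
        i = j + 1
    return np.array(keep, dtype=int)


def extract_peaks(
    curve: FitCurve, min_sep: int = 20, slope_frac: float = 0.5
) -> list[tuple[int, float, float]]:
    """Strand-level site calls from one goodness-of-fit curve.

    Local maxima of R^2 with slope beta >= slope_frac * max(beta) (and
    beta > 0) are candidate sites; among candidates closer than ``min_sep``
    the one with higher R^2 wins (ties: higher beta, then leftmost).
    Returns (pos, beta, r2) triples sorted by position.
    """
    if curve.pos.size == 0:
        return []
    max_beta = float(curve.beta.max(initial=0.0))
    if max_beta <= 0:
        return []
    idx = _local_maxima(curve.r2)
    idx = idx[(curve.beta[idx] > 0) & (curve.beta[idx] >= slope_frac * max_beta)]
    if idx.size == 0:
        return []
    order = sorted(idx, key=lambda i: (-curve.r2[i], -curve.beta[i], curve.pos[i]))
    accepted: list[int] = []
    for i in order:
        if all(abs(int(curve.pos[i]) - int(curve.pos[a])) >= min_sep for a in accepted):
            accepted.append(i)
    accepted.sort(key=lambda i: curve.pos[i])
    return [(int(curve.pos[i]), float(curve.beta[i]), float(curve.r2[i])) for i in accepted]


def merge_strands(
    fwd_sites: list[tuple[int, float, float]],
    rev_sites: list[tuple[int, float, float]],
    merge_dist: int = 20,
    chrom: str = "",
    region_id: str = "",
) -> list[BindingSite]:
    """Combine strand-level calls into final binding sites.

    Forward/reverse pairs closer than ``merge_dist`` are merged at the
    floor of their midpoint (evidence FR, affinity = mean of the two
    slopes, pairs matched greedily nearest first); unpaired calls are kept
    with single-strand evidence, rescuing sites visible on one strand only.
    """
    pairs: list[tuple[int, int, int]] = []
    for i, (pf, _, _) in enumerate(fwd_sites):
        for j, (pr, _, _) in enumerate(rev_sites):
            dist = abs(pf - pr)
            if dist < merge_dist:
                pairs.append((dist, i, j))
    pairs.sort(key=lambda t: (t[0], fwd_sites[t[1]][0]))
    used_f: set[int] = set()
    used_r: set[int] = set()
    sites: list[BindingSite] = []
    for dist, i, j in pairs:
        if i in used_f or j in used_r:
            continue
        used_f.add(i)
        used_r.add(j)
        pf, bf, rf = fwd_sites[i]
        pr, br, rr = rev_sites[j]
        sites.append(
            BindingSite(
                chrom=chrom,
                pos=(pf + pr) // 2,
                affinity=(bf + br) / 2.0,
                r2=(rf + rr) / 2.0,
                evidence="FR",
                region_id=region_id,
            )
        )
    for i, (p, b, r) in enumerate(fwd_sites):
        if i not in used_f:
            sites.append(BindingSite(chrom, p, b, r, "F", region_id))
    for j, (p, b, r) in enumerate(rev_sites):
        if j not in used_r:
            sites.append(BindingSite(chrom, p, b, r, "R", region_id))
    sites.sort(key=lambda s: s.pos)
    return sites


def _strand_positions(track: TagTrack, region: BindingRegion, strand: str) -> np.ndarray:
    pos = track.positions(region.chrom, strand)
    lo = np.searchsorted(pos, region.start)
    hi = np.searchsorted(pos, region.end)
    return pos[lo:hi]


def detect_sites(
    region: BindingRegion,
    track: TagTrack,
    model: ProfileModel,
    config: RunConfig | None = None,
) -> list[BindingSite]:
    """Pinpoint binding sites within one enriched region.

    Per strand: count 5' ends per base, smooth, scan with the template
    (window W = round(window_frac * L)), extract slope-thresholded R^2
    peaks; then merge the two strands.  Calls outside the refined region
    bounds are clipped to them.
    """
    config = config or RunConfig()
    C = region.end - region.start
    if C <= 0:
        return []
    W = max(1, round(config.window_frac * model.L))
    strand_calls: dict[str, list[tuple[int, float, float]]] = {FORWARD: [], REVERSE: []}
    for strand in (FORWARD, REVERSE):
        positions = _strand_positions(track, region, strand)
        if positions.size == 0:
            continue
        t = np.bincount(positions - region.start, minlength=C)
        profile = StrandProfile(region.chrom, region.start, strand, t)
        curve = scan_region(profile, model, W, config.smooth_b)
        strand_calls[strand] = extract_peaks(curve, config.merge_dist, config.slope_frac)
    sites = merge_strands(
        strand_calls[FORWARD],
        strand_calls[REVERSE],
        config.merge_dist,
        chrom=region.chrom,
        region_id=region.region_id,
    )
    lo = region.refined_start if region.refined_start is not None else region.start
    hi = region.refined_end if region.refined_end is not None else region.end
    for s in sites:
        s.pos = int(min(max(s.pos, lo), hi - 1))
    return sites
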