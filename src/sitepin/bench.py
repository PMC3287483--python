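"""Simulation benchmarks of site-pinpointing resolution.

Reusable protocol pieces: simulate one region from the tag-density model,
run site detection on it, and sweep tag depth or inter-site distance while
scoring detected-to-true distances.  Distances are scored inclusively
(``within k`` means distance <= k bp).
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .evaluate import nearest_distances
from .io import FORWARD, REVERSE, TagTrack
from .regions import BindingRegion
from .simulate import SimConfig, simulate_region
from .sites import BindingSite, detect_sites
from .tagmodel import ProfileModel, build_profile


def pinpoint_once(
    sim: SimConfig,
    rng: np.random.Generator,
    model: ProfileModel | None = None,
    config: RunConfig | None = None,
) -> tuple[list[BindingSite], list[int]]:
    """Simulate one region and pinpoint its sites.

    The region handed to the detector spans the simulated tags, as after
    region detection on a noise-free pileup.  Returns (sites, true sites).
    """
    model = model or build_profile(sim.L, sim.alpha, sim.D)
    config = config or RunConfig()
    pooled, truth = simulate_region(sim, rng, model)
    allpos = np.concatenate([pooled[FORWARD], pooled[REVERSE]])
    region = BindingRegion.spanning(sim.chrom, allpos)
    track = TagTrack({sim.chrom: {FORWARD: pooled[FORWARD], REVERSE: pooled[REVERSE]}})
    return detect_sites(region, track, model, config), truth.sites


def single_site_sweep(
    tag_counts: list[int],
    reps: int,
    threshold: int,
    seed: int,
    L: float = 120.0,
    alpha: float = 10.0,
    D: int = 300,
    config: RunConfig | None = None,
) -> tuple[float, int]:
    """Fraction of runs whose nearest detected site is within ``threshold``
    bp of the single true site.

    Returns (percent, number of runs).  Runs with no detection count as
    misses.
    """
    model = build_profile(L, alpha, D)
    rng = np.random.default_rng(seed)
    hits = total = 0
    for w in tag_counts:
        sim = SimConfig(sites=[1000], w=w, L=L, alpha=alpha, D=D)
        for _ in range(reps):
            sites, truth = pinpoint_once(sim, rng, model, config)
            total += 1
            if sites and min(abs(s.pos - truth[0]) for s in sites) <= threshold:
                hits += 1
    return 100.0 * hits / total, total


def two_site_sweep(
    distances: list[int],
    tag_counts: list[int],
    reps: int,
    threshold: int,
    seed: int,
    L: float = 120.0,
    alpha: float = 10.0,
    D: int = 300,
    config: RunConfig | None = None,
    average_over_distances: bool = False,
) -> tuple[float, int]:
    """Percent of detected sites within ``threshold`` bp of the nearest of
    two true sites, over a (distance x depth) sweep.

    With ``average_over_distances`` the per-distance percentages are
    averaged (each distance weighted equally); otherwise all detected
    sites are pooled.  Returns (percent, number of detected sites scored).
    """
    model = build_profile(L, alpha, D)
    rng = np.random.default_rng(seed)
    per_distance: list[float] = []
    pooled_hits = pooled_total = 0
    for dist in distances:
        hits = total = 0
        for w in tag_counts:
            sim = SimConfig(sites=[1000, 1000 + dist], w=w, L=L, alpha=alpha, D=D)
            for _ in range(reps):
                sites, truth = pinpoint_once(sim, rng, model, config)
                if not sites:
                    continue
                d = nearest_distances(
                    np.array([s.pos for s in sites]), np.array(truth)
                )
                hits += int(np.sum(d <= threshold))
                total += len(d)
        per_distance.append(100.0 * hits / total if total else 0.0)
        pooled_hits += hits
        pooled_total += total
    if average_over_distances:
        return float(np.mean(per_distance)), pooled_total
    return 100.0 * pooled_hits / pooled_total, pooled_total
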