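"""Synthetic strand-specific tag data drawn from the tag-density model.

Region-level simulations place, for each binding site, w tag 5' ends per
strand at offsets drawn from the template f_tag: forward tags at
site - d, reverse tags at site + d.  Multi-site regions accumulate the
draws of every site.  Experiment-level simulations additionally plant
such regions at well-separated loci along a toy chromosome and add
uniform Poisson background tags on both strands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import FORWARD, REVERSE, TagTrack
from .tagmodel import ProfileModel, build_profile


@dataclass
class SimConfig:
    """Simulation conditions.

    ``sites`` are binding-site coordinates (region level) or offsets within
    each planted region (experiment level); ``w`` is the number of tags per
    site per strand.  ``background_rate`` (tags/bp/strand) and
    ``genome_len`` only matter for experiment-level simulations.
    """

    sites: list[int] = field(default_factory=lambda: [1000])
    w: int = 100
    L: float = 120.0
    alpha: float = 10.0
    D: int = 300
    n_reps: int = 1
    background_rate: float = 0.0
    genome_len: int = 0
    n_regions: int = 0
    chrom: str = "sim1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("site positions must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    sites: list[int]
    counts: dict[str, list[int]]  # strand -> tags drawn per site
    seed: int | None = None

    def write_bed(self, path: str, chrom: str = "sim1") -> None:
        with open(path, "w") as fh:
            for i, pos in enumerate(self.sites):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttrue_site{i}\t0\t.\n")


def sample_site_tags(
    p_bs: int, w: int, model: ProfileModel, strand: str, rng: np.random.Generator
) -> np.ndarray:
    """Draw w tag 5' positions for one site on one strand.

    Offsets d are multinomial draws from f_tag; forward tags land at
    p_bs - d, reverse tags at p_bs + d.  Positions are clipped at 0.
    """
    d = rng.choice(model.f_tag.size, size=w, p=model.f_tag)
    pos = p_bs - d if strand == FORWARD else p_bs + d
    return np.sort(np.clip(pos, 0, None).astype(np.int64))


def simulate_region(
    config: SimConfig, rng: np.random.Generator, model: ProfileModel | None = None
) -> tuple[dict[str, np.ndarray], TruthSet]:
    """Simulate one region: per-site draws on both strands, pooled.

    Returns {strand: sorted positions} and the matching truth.
    """
    model = model or build_profile(config.L, config.alpha, config.D)
    out: dict[str, list[np.ndarray]] = {FORWARD: [], REVERSE: []}
    counts: dict[str, list[int]] = {FORWARD: [], REVERSE: []}
    for p_bs in config.sites:
        for strand in (FORWARD, REVERSE):
            draws = sample_site_tags(p_bs, config.w, model, strand, rng)
            out[strand].append(draws)
            counts[strand].append(len(draws))
    pooled = {
        strand: np.sort(np.concatenate(chunks)) if chunks else np.empty(0, dtype=np.int64)
        for strand, chunks in out.items()
    }
    return pooled, TruthSet(sites=list(config.sites), counts=counts, seed=config.seed)


def simulate_experiment(config: SimConfig) -> tuple[TagTrack, TruthSet]:
    """Simulate a toy chromosome with planted regions plus uniform background.

    ``config.n_regions`` loci are drawn uniformly, kept pairwise separated
    by at least 4*D (redrawn up to a retry cap), and each receives sites at
    ``config.sites`` offsets.  Background tags are Poisson(genome_len *
    background_rate) per strand, uniform along the chromosome.
    """
    if config.genome_len <= 0:
        raise ValueError("genome_len must be positive")
    rng = np.random.default_rng(config.seed)
    model = build_profile(config.L, config.alpha, config.D)
    span = (config.sites[-1] - config.sites[0]) if config.sites else 0
    margin = config.D + 1
    min_sep = 4 * config.D + span
    n_regions = config.n_regions or 1
    lo, hi = margin, config.genome_len - margin - span
    if hi <= lo:
        raise ValueError("genome too short for the requested regions")
    for _ in range(1000):
        loci = np.sort(rng.integers(lo, hi, size=n_regions))
        if n_regions == 1 or np.all(np.diff(loci) >= min_sep):
            break
    else:
        raise RuntimeError("could not place non-overlapping regions; enlarge genome_len")

    offsets = [p - config.sites[0] for p in config.sites] if config.sites else []
    all_pos: dict[str, list[np.ndarray]] = {FORWARD: [], REVERSE: []}
    true_sites: list[int] = []
    counts: dict[str, list[int]] = {FORWARD: [], REVERSE: []}
    for locus in loci:
        for off in offsets:
            p_bs = int(locus) + off
            true_sites.append(p_bs)
            for strand in (FORWARD, REVERSE):
                draws = sample_site_tags(p_bs, config.w, model, strand, rng)
                all_pos[strand].append(draws)
                counts[strand].append(len(draws))
    if config.background_rate > 0:
        for strand in (FORWARD, REVERSE):
            n_bg = rng.poisson(config.background_rate * config.genome_len)
            all_pos[strand].append(
                rng.integers(0, config.genome_len, size=n_bg).astype(np.int64)
            )
    track = TagTrack(
        {
            config.chrom: {
                strand: np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
                for strand, chunks in all_pos.items()
            }
        }
    )
    return track, TruthSet(sites=true_sites, counts=counts, seed=config.seed)
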