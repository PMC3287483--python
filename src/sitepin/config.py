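"""Run-time configuration shared across the detection pipeline."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class RunConfig:
    """Parameters of the two-step binding-site detection pipeline.

    Attributes
    ----------
    gap:
        Maximum distance (bp) between successive tag 5' positions that still
        joins them into one tag cluster.
    min_tags, min_len:
        Clusters with fewer tags or a shorter span (bp) are discarded before
        enrichment testing; such clusters are typically artifacts and too
        noisy for site-level deconvolution.
    fdr:
        Benjamini-Hochberg false discovery rate at which enriched regions
        are retained.
    top_fraction:
        Fraction of densest regions used for fragment-length estimation.
    alpha:
        Gamma shape of the fragment-length distribution.
    smooth_b:
        Width (bp) of the moving-average window applied to per-base tag
        start counts before template fitting.
    window_frac:
        Sliding-window width as a fraction of the mean fragment length L.
        Kept below 1 so the template approximation (valid for offsets
        smaller than L) holds throughout the window.
    max_frag:
        Maximum fragment length D (bp) allowed by size selection.
    effective_genome:
        Mappable genome size (bp) used for the background Poisson rate.
    merge_dist:
        Sites closer than this (bp) are merged; also the minimum separation
        between peaks extracted from one goodness-of-fit curve.
    slope_frac:
        A fit-curve peak is reported only if its regression slope is at
        least this fraction of the maximum slope in the region (per strand).
    fragment_length:
        Mean fragment length L in bp; ``None`` requests estimation from the
        densest regions.
    seed:
        Seed for any stochastic component (simulation subcommand).
    """

    gap: int = 30
    min_tags: int = 10
    min_len: int = 100
    fdr: float = 0.10
    top_fraction: float = 0.05
    alpha: float = 10.0
    smooth_b: int = 20
    window_frac: float = 0.8
    max_frag: int = 300
    effective_genome: float = 2.4e9
    merge_dist: int = 20
    slope_frac: float = 0.5
    fragment_length: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.window_frac < 1):
            raise ValueError("window_frac must be in (0, 1)")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.merge_dist < 0:
            raise ValueError("merge_dist must be >= 0")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.effective_genome <= 0:
            raise ValueError("effective_genome must be positive")
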