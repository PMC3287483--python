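"""Scoring detections against truth or reference centers.

For cross-method comparison each detected site is expanded to a 200-bp
standardized binding region (SBR); resolution is summarized by the
distance from every detected site to its nearest reference center (true
simulated site, or a motif-center BED on real data) and the fraction of
sites within a set of distance thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SBR:
    """A fixed-width standardized binding region centered on a detected site."""

    chrom: str
    start: int
    end: int


@dataclass
class ResolutionReport:
    """Distances from detected sites to nearest reference centers."""

    distances: np.ndarray = field(repr=False)
    fractions: dict[int, float] = field(default_factory=dict)
    n_sites: int = 0
    n_truth: int = 0

    def to_tsv(self) -> str:
        lines = ["threshold_bp\tfraction_within"]
        for thr in sorted(self.fractions):
            lines.append(f"{thr}\t{self.fractions[thr]:.4f}")
        lines.append(f"# n_sites={self.n_sites} n_reference={self.n_truth}")
        return "\n".join(lines) + "\n"


def make_sbrs(sites, width: int = 200) -> list[SBR]:
    """Expand site calls to width-bp standardized regions, clipped at 0.

    ``sites`` may be BindingSite objects or (chrom, pos) pairs.
    """
    if width % 2:
        raise ValueError("SBR width must be even")
    out = []
    for s in sites:
        chrom, pos = (s.chrom, s.pos) if hasattr(s, "pos") else (s[0], int(s[1]))
        out.append(SBR(chrom, max(0, pos - width // 2), pos + width // 2))
    return out


def nearest_distances(site_pos: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Distance from each site to the nearest reference center."""
    reference = np.sort(np.asarray(reference, dtype=np.int64))
    site_pos = np.asarray(site_pos, dtype=np.int64)
    if reference.size == 0:
        raise ValueError("reference center list is empty")
    if site_pos.size == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.searchsorted(reference, site_pos)
    left = np.abs(site_pos - reference[np.clip(idx - 1, 0, reference.size - 1)])
    right = np.abs(site_pos - reference[np.clip(idx, 0, reference.size - 1)])
    return np.minimum(left, right)


def resolution_metrics(
    site_pos: np.ndarray,
    reference: np.ndarray,
    thresholds: tuple[int, ...] = (5, 10, 20),
) -> ResolutionReport:
    """Per-site nearest-reference distances and within-threshold fractions.

    Matching is unconstrained: a reference center may be the nearest to
    several detected sites.
    """
    dists = nearest_distances(site_pos, reference)
    n = dists.size
    fractions = {
        int(thr): (float(np.mean(dists <= thr)) if n else 0.0) for thr in thresholds
    }
    return ResolutionReport(
        distances=dists,
        fractions=fractions,
        n_sites=int(n),
        n_truth=int(np.asarray(reference).size),
    )
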