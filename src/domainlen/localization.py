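"""Length-stratified localization of chromatin-interaction anchors, and
feature-length vs domain-length correlation.

Domains are split into equal-frequency length bins (quintiles by default).
Each interaction anchor overlapping a domain is clipped to it and mapped to
relative coordinates 0 (domain start) to 1 (domain end); per-base anchor
coverage is accumulated on a fixed relative-position grid with fractional
cell occupancy at the edges, then averaged over the domains of each bin.
Edge-clustered interactions show up as U-shaped profiles; uniformly placed
ones as flat profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import AnchorPair, GenomicInterval, IntervalTrack

__all__ = [
    "LengthBinAssignment",
    "CoverageProfile",
    "feature_length_vs_domain_length",
    "length_bins",
    "relative_anchor_coverage",
    "profile_report",
    "read_profile_report",
]


@dataclass
class LengthBinAssignment:
    """Domain -> length-bin index (1..k); equal-frequency bins.

    Bin index increases with domain length; bin sizes differ by at most one
    domain, with the larger bins at the lower (shorter-domain) ranks.
    ``boundaries`` holds each bin's (min length, max length) in bp.
    """

    k: int
    assignment: dict[str, int]
    boundaries: list[tuple[int, int]]

    def domains_in_bin(self, b: int) -> list[str]:
        return [d for d, i in self.assignment.items() if i == b]


@dataclass
class CoverageProfile:
    """Per length-bin mean anchor coverage over a relative-position grid.

    ``profiles[b]`` (b = 1..k) is a length-G vector; cell g spans relative
    positions [g/G, (g+1)/G). Values are mean per-base anchor counts,
    averaged over the domains of the bin (dimensionless).
    """

    grid: int
    profiles: dict[int, np.ndarray]

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.grid) + 0.5) / self.grid


def _domain_id(iv: GenomicInterval) -> str:
    return iv.name if iv.name is not None else f"{iv.chrom}:{iv.start}-{iv.end}"


def feature_length_vs_domain_length(
    domains: IntervalTrack, track: IntervalTrack
) -> tuple[list[tuple[int, int]], float]:
    """Pair each domain's length with the summed length of the overlapping
    track instances; return the pairs and their Spearman correlation.

    Only domains overlapping at least one instance contribute a pair. An
    instance's full length counts (not just the overlapping part), and
    instances are summed when several overlap one domain. Raises when fewer
    than 3 pairs exist or either side has zero variance.
    """
    by_chrom = track.by_chrom()
    pairs: list[tuple[int, int]] = []
    for d in domains:
        total = 0
        hit = False
        for iv in by_chrom.get(d.chrom, ()):
            if iv.start < d.end and iv.end > d.start:
                total += iv.length
                hit = True
        if hit:
            pairs.append((d.length, total))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 overlapping domains for a correlation, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero-variance lengths")
    rho, _ = stats.spearmanr(x, y)
    return pairs, float(rho)


def length_bins(domains: IntervalTrack, k: int = 5) -> LengthBinAssignment:
    """Rank domains by length (ties by start coordinate) and split the ranks
    into k contiguous equal-frequency bins, larger bins at the lower ranks."""
    n = len(domains)
    if n < k:
        raise ValueError(f"need at least k={k} domains, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(range(n), key=lambda i: (domains[i].length, domains[i].start))
    base, extra = divmod(n, k)
    sizes = [base + (1 if b < extra else 0) for b in range(k)]
    assignment: dict[str, int] = {}
    boundaries: list[tuple[int, int]] = []
    pos = 0
    for b, size in enumerate(sizes, start=1):
        members = order[pos:pos + size]
        pos += size
        lens = [domains[i].length for i in members]
        boundaries.append((min(lens), max(lens)))
        for i in members:
            assignment[_domain_id(domains[i])] = b
    return LengthBinAssignment(k=k, assignment=assignment, boundaries=boundaries)


def _domain_cell_coverage(domain: GenomicInterval, anchors: Sequence[GenomicInterval],
                          grid: int) -> np.ndarray:
    """Per-cell mean per-base coverage of one domain by clipped anchors.

    Cell g spans [start + g*L/G, start + (g+1)*L/G); an anchor contributes
    to each cell the overlapped fraction of that cell (fractional occupancy
    at its edges), i.e. overlap-bp / cell-width-bp.
    """
    L = domain.length
    cov = np.zeros(grid)
    for a in anchors:
        lo = max(a.start, domain.start)
        hi = min(a.end, domain.end)
        if hi <= lo:
            continue
        # relative anchor span scaled to grid units
        g_lo = (lo - domain.start) * grid / L
        g_hi = (hi - domain.start) * grid / L
        first, last = int(np.floor(g_lo)), min(int(np.ceil(g_hi)), grid)
        for g in range(first, last):
            cov[g] += max(0.0, min(g_hi, g + 1) - max(g_lo, g))
    return cov


def relative_anchor_coverage(
    domains: IntervalTrack,
    bins: LengthBinAssignment,
    anchors: Sequence[AnchorPair],
    grid: int = 100,
) -> CoverageProfile:
    """Mean relative-position anchor coverage per length bin.

    Both anchors of every pair are tested for domain overlap independently;
    an anchor overlapping several domains contributes to each. Each domain's
    per-cell coverage counts anchors per bp (a single anchor spanning the
    whole domain contributes 1.0 everywhere); the bin profile is the mean
    over all of the bin's domains, including anchor-free ones.
    """
    if grid < 2:
        raise ValueError("grid must be >= 2")
    # flatten pairs to single anchors, bucketed by chromosome and sorted
    flat: dict[str, list[GenomicInterval]] = {}
    for p in anchors:
        for a in (p.anchor1, p.anchor2):
            flat.setdefault(a.chrom, []).append(a)
    coords: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, v in flat.items():
        v.sort(key=lambda iv: (iv.start, iv.end))
        coords[chrom] = (
            np.array([a.start for a in v]),
            np.array([a.end for a in v]),
        )

    sums = {b: np.zeros(grid) for b in range(1, bins.k + 1)}
    counts = {b: 0 for b in range(1, bins.k + 1)}
    for d in domains:
        b = bins.assignment.get(_domain_id(d))
        if b is None:
            continue
        if d.chrom in coords:
            starts, ends = coords[d.chrom]
            idx = np.nonzero((starts < d.end) & (ends > d.start))[0]
            hits = [flat[d.chrom][i] for i in idx]
        else:
            hits = []
        sums[b] += _domain_cell_coverage(d, hits, grid)
        counts[b] += 1
    profiles = {
        b: (sums[b] / counts[b] if counts[b] else sums[b]) for b in sums
    }
    return CoverageProfile(grid=grid, profiles=profiles)


def profile_report(profile: CoverageProfile, path) -> None:
    """Write a TSV: bin, cell index, relative-position midpoint, coverage."""
    rows = []
    mids = profile.midpoints
    for b in sorted(profile.profiles):
        for g, v in enumerate(profile.profiles[b]):
            rows.append((b, g, mids[g], v))
    pd.DataFrame(rows, columns=["bin", "cell", "rel_pos", "mean_coverage"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_profile_report(path) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t")
    grid = int(df["cell"].max()) + 1
    profiles = {
        int(b): g.sort_values("cell")["mean_coverage"].to_numpy()
        for b, g in df.groupby("bin")
    }
    return CoverageProfile(grid=grid, profiles=profiles)
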