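"""Synthetic domains, predictor tracks and interaction anchors.

The generator emulates the data regime of broad histone-mark domain
analysis: domain lengths are right-skewed over roughly hundreds of bp to
tens of kb (log-normal in log10 space, default log10-mean 3.2, sd 0.4, i.e.
median ~1.6 kb), a subset of predictor tracks carries a planted monotone
link between domain length and overlap fraction, the rest are decoys whose
fractions are independent of length, and interaction anchors are planted
either uniformly along each domain or concentrated at the domain edges.
Every generated object records its ground truth so downstream recovery can
be tested.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .intervals import AnchorPair, GenomicInterval, IntervalTrack

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_domains",
    "simulate_feature_tracks",
    "simulate_anchors",
    "simulate_all",
]

CHROM = "chrSim"


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``effect_slopes`` gives one signed slope per informative track: the
    expected overlap fraction of track *k* on a domain with standardized
    log10 length *z* is ``sigmoid(slope_k * z)`` before noise. Defaults
    plant 6 informative tracks with alternating slopes +/-2 among 14 decoys
    on 2000 domains — the benchmark configuration used throughout the test
    suite.
    """

    n_domains: int = 2000
    length_log10_mean: float = 3.2
    length_log10_sd: float = 0.4
    n_informative: int = 6
    n_decoy: int = 14
    effect_slopes: tuple[float, ...] | None = None
    noise_sd: float = 0.05
    anchor_mode: Literal["uniform", "edge"] = "uniform"
    anchor_width: int = 500
    genome_span: int = 100_000_000
    min_gap: int = 100
    max_gap: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 0:
            raise ValueError("n_domains must be >= 0")
        if self.n_informative + self.n_decoy < 1:
            raise ValueError("need at least one track")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.anchor_mode not in ("uniform", "edge"):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")
        if self.effect_slopes is None:
            # alternating +/- slopes of magnitude 2
            self.effect_slopes = tuple(
                2.0 if k % 2 == 0 else -2.0 for k in range(self.n_informative)
            )
        self.effect_slopes = tuple(float(s) for s in self.effect_slopes)
        if len(self.effect_slopes) != self.n_informative:
            raise ValueError(
                f"effect_slopes has {len(self.effect_slopes)} entries "
                f"for {self.n_informative} informative tracks"
            )


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run, for recovery tests."""

    informative: dict[str, float]  # label -> slope
    decoys: list[str]
    anchor_mode: str
    domain_lengths: list[int]
    planted_fractions: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


class CapacityError(ValueError):
    """The simulated chromosome is too short to place all domains."""


def _rng(cfg: SimulationConfig, stage: str) -> np.random.Generator:
    # independent, reproducible stream per stage (crc32 is run-stable,
    # unlike Python's salted str hash)
    tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def simulate_domains(cfg: SimulationConfig) -> IntervalTrack:
    """Place ``n_domains`` non-overlapping domains on one synthetic chromosome.

    Lengths are 10**Normal(length_log10_mean, length_log10_sd), rounded to
    >=1 bp; domains are laid left to right separated by uniform random gaps.
    """
    rng = _rng(cfg, "domains")
    lengths = np.maximum(
        1, np.round(10 ** rng.normal(cfg.length_log10_mean, cfg.length_log10_sd, cfg.n_domains))
    ).astype(np.int64)
    gaps = rng.integers(cfg.min_gap, cfg.max_gap + 1, cfg.n_domains)
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    ends = starts + lengths
    if cfg.n_domains and ends[-1] > cfg.genome_span:
        raise CapacityError(
            f"genome_span {cfg.genome_span} bp cannot hold {cfg.n_domains} domains "
            f"(needed {int(ends[-1])} bp)"
        )
    intervals = [
        GenomicInterval(CHROM, int(s), int(e), name=f"domain{i}")
        for i, (s, e) in enumerate(zip(starts, ends))
    ]
    return IntervalTrack(label="domains", intervals=intervals)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_feature_tracks(
    domains: IntervalTrack, cfg: SimulationConfig
) -> tuple[list[IntervalTrack], SimulationTruth]:
    """Plant informative and decoy predictor tracks over the domains.

    Informative track *k*: each domain gets one instance covering a
    contiguous fraction ``f = clamp01(sigmoid(slope_k * z) + eps)`` of it at
    a random offset, where ``z`` is the standardized log10 domain length and
    ``eps ~ Normal(0, noise_sd)``. Decoy tracks draw the pre-noise term from
    an independent standard normal, so their fractions carry no length
    signal. Fractions of exactly 0 yield no instance.
    """
    if len(domains) == 0:
        raise ValueError("domains must be non-empty")
    rng = _rng(cfg, "tracks")
    lengths = np.array([iv.length for iv in domains], dtype=float)
    log_len = np.log10(lengths)
    sd = log_len.std()
    z = (log_len - log_len.mean()) / (sd if sd > 0 else 1.0)

    tracks: list[IntervalTrack] = []
    truth = SimulationTruth(
        informative={}, decoys=[], anchor_mode=cfg.anchor_mode,
        domain_lengths=[int(x) for x in lengths],
    )

    def build(label: str, fractions: np.ndarray) -> IntervalTrack:
        instances = []
        widths = np.round(fractions * lengths).astype(np.int64)
        offsets = rng.integers(0, np.maximum(1, lengths.astype(np.int64) - widths + 1))
        for iv, w, off in zip(domains, widths, offsets):
            if w >= 1:
                instances.append(GenomicInterval(iv.chrom, iv.start + int(off), iv.start + int(off) + int(w)))
        truth.planted_fractions[label] = [float(f) for f in fractions]
        return IntervalTrack(label=label, intervals=instances)

    for k, slope in enumerate(cfg.effect_slopes or ()):
        f = np.clip(_sigmoid(slope * z) + rng.normal(0, cfg.noise_sd, len(domains)), 0.0, 1.0)
        label = f"informative{k}"
        truth.informative[label] = float(slope)
        tracks.append(build(label, f))
    for k in range(cfg.n_decoy):
        f = np.clip(_sigmoid(rng.standard_normal(len(domains))) + rng.normal(0, cfg.noise_sd, len(domains)), 0.0, 1.0)
        label = f"decoy{k}"
        truth.decoys.append(label)
        tracks.append(build(label, f))
    return tracks, truth


def simulate_anchors(domains: IntervalTrack, cfg: SimulationConfig) -> list[AnchorPair]:
    """Plant one interaction anchor per domain, plus an outside partner.

    uniform mode: the anchor center is uniform over the domain span extended
    by half the anchor width at each end, so that after clipping to the
    domain the expected per-base coverage is flat across the whole domain
    (a center confined to the domain would depress the outermost bins).

    edge mode: the center lands within the outer 10% of the domain at either
    end (fair coin), and the band tightens with the domain's length rank so
    longer domains are more edge-concentrated. Anchors are ``anchor_width``
    bp wide (>=1 after clipping to positive coordinates); the partner anchor
    sits outside the domain.
    """
    if len(domains) == 0:
        raise ValueError("domains must be non-empty")
    rng = _rng(cfg, "anchors")
    w = max(1, cfg.anchor_width)
    half = w / 2.0

    lengths = np.array([iv.length for iv in domains], dtype=float)
    # percentile rank in [0, 1] of each domain's length
    order = lengths.argsort(kind="stable")
    rank = np.empty(len(lengths))
    rank[order] = np.arange(len(lengths))
    pct = rank / max(1, len(lengths) - 1)

    pairs: list[AnchorPair] = []
    for i, iv in enumerate(domains):
        L = iv.length
        if cfg.anchor_mode == "uniform":
            center = iv.start + rng.uniform(-half, L + half)
        else:
            band = 0.10 * (1.0 - 0.5 * pct[i])  # tighter band for longer domains
            rel = rng.uniform(0, band)
            if rng.random() < 0.5:
                rel = 1.0 - rel
            center = iv.start + rel * L
        a_start = int(round(center - half))
        a_end = max(a_start + 1, a_start + w)
        a_start = max(0, a_start)
        anchor = GenomicInterval(iv.chrom, a_start, a_end)
        partner_start = iv.end + int(rng.integers(10_000, 50_000))
        partner = GenomicInterval(iv.chrom, partner_start, partner_start + w)
        pairs.append(AnchorPair(anchor, partner, interaction_id=f"int{i}"))
    return pairs


def simulate_all(cfg: SimulationConfig):
    """Run all three generators; returns (domains, tracks, anchors, truth)."""
    domains = simulate_domains(cfg)
    tracks, truth = simulate_feature_tracks(domains, cfg)
    anchors = simulate_anchors(domains, cfg)
    return domains, tracks, anchors, truth
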