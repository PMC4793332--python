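"""Per-domain fraction-of-overlap feature matrix construction.

Each feature value is (summed overlap bp of the domain with all instances
of a track) / (domain length). The sum rule is applied literally: a domain
overlapping two mutually overlapping instances counts both, so fractions
may exceed 1. The regression target is the raw domain length in bp
(log10 transform available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalTrack, merge_instances, total_overlap_bp

__all__ = [
    "FeatureMatrix",
    "fraction_of_overlap",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]


@dataclass
class FeatureMatrix:
    """Domains x tracks table of overlap fractions plus the length target.

    ``values`` has shape ``(n_domains, n_features)``; ``target`` holds the
    domain lengths in bp, aligned with ``domain_ids``.
    """

    domain_ids: list[str]
    feature_labels: list[str]
    values: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        n, m = len(self.domain_ids), len(self.feature_labels)
        if self.values.shape != (n, m):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {m})")
        if self.target.shape != (n,):
            raise ValueError(f"target shape {self.target.shape} != ({n},)")
        if np.isnan(self.values).any() or np.isnan(self.target).any():
            raise ValueError("feature matrix must not contain NaN")
        if (self.values < 0).any():
            raise ValueError("overlap fractions must be >= 0")
        if n and (self.target < 1).any():
            raise ValueError("domain lengths must be >= 1 bp")

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_labels)
        df.insert(0, "length", self.target)
        df.insert(0, "domain_id", self.domain_ids)
        return df


def fraction_of_overlap(domain: GenomicInterval, track: IntervalTrack) -> float:
    """Summed overlap bp with every track instance, divided by domain length.

    May exceed 1 when instances overlap each other inside the domain.
    """
    return total_overlap_bp(domain, track) / domain.length


def _track_overlap_column(domains: IntervalTrack, track: IntervalTrack) -> np.ndarray:
    """Vectorized summed-overlap numerators for one track over all domains."""
    n = len(domains)
    out = np.zeros(n, dtype=np.int64)
    dom_by_chrom: dict[str, list[int]] = {}
    for i, d in enumerate(domains):
        dom_by_chrom.setdefault(d.chrom, []).append(i)
    for chrom, instances in track.by_chrom().items():
        idx = dom_by_chrom.get(chrom)
        if not idx:
            continue
        ds = np.array([domains[i].start for i in idx])[:, None]
        de = np.array([domains[i].end for i in idx])[:, None]
        ts = np.array([iv.start for iv in instances])[None, :]
        te = np.array([iv.end for iv in instances])[None, :]
        ov = np.clip(np.minimum(de, te) - np.maximum(ds, ts), 0, None)
        out[idx] = ov.sum(axis=1)
    return out


def build_feature_matrix(
    domains: IntervalTrack,
    tracks: Sequence[IntervalTrack],
    merge: bool = False,
) -> FeatureMatrix:
    """Assemble the fraction-of-overlap matrix in input order.

    Row i, column j is ``fraction_of_overlap(domain_i, track_j)``; the
    target is the domain length. ``merge=True`` union-merges each track's
    instances first (sensitivity-check variant; the default is the literal
    sum rule).
    """
    if len(domains) == 0:
        raise ValueError("domains must be non-empty")
    labels = [t.label for t in tracks]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate track labels: {dupes}")

    lengths = np.array([d.length for d in domains], dtype=float)
    cols = []
    for t in tracks:
        if merge:
            t = merge_instances(t)
        cols.append(_track_overlap_column(domains, t) / lengths)
    values = np.column_stack(cols) if cols else np.empty((len(domains), 0))
    ids = [d.name if d.name is not None else f"{d.chrom}:{d.start}-{d.end}" for d in domains]
    return FeatureMatrix(ids, labels, values, lengths)


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write as TSV: domain_id, length, then one column per feature."""
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str})
    for col in ("domain_id", "length"):
        if col not in df.columns:
            raise ValueError(f"feature matrix file {path} lacks required column {col!r}")
    labels = [c for c in df.columns if c not in ("domain_id", "length")]
    values = df[labels].to_numpy(dtype=float) if labels else np.empty((len(df), 0))
    if np.isnan(values).any() or df["length"].isna().any():
        raise ValueError(f"feature matrix file {path} contains NaN values")
    return FeatureMatrix(
        df["domain_id"].tolist(), labels, values, df["length"].to_numpy(dtype=float)
    )
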