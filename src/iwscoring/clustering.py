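"""Detection of recurrently mutated regions enriched for functional mutations.

A functional-mutation cluster is a maximal run of significant mutations
(integrated-score p strictly below the threshold, 0.05 by default) on one
chromosome in which every consecutive pair lies strictly less than
``max_gap`` (10 kb) apart, containing at least ``min_size`` (3) members. The
gap is the inter-distance between consecutive member positions, not the span
of the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import RegionSet, ValidationError, VariantKey
from .scoring import ScoredVariant

DEFAULT_ALPHA = 0.05
DEFAULT_MAX_GAP = 10_000
DEFAULT_MIN_SIZE = 3


@dataclass
class ClusterReport:
    """One cluster: its span (1-based inclusive), members and summary stats."""

    chrom: str
    start: int
    end: int
    members: list[VariantKey]
    size: int
    min_p: float
    mean_iw: float
    region_labels: tuple[str, ...] = ()


def significant_variants(scored: Sequence[ScoredVariant],
                         alpha: float = DEFAULT_ALPHA) -> list[ScoredVariant]:
    """Variants with p-value strictly below ``alpha``, input order preserved."""
    if not scored:
        raise ValidationError("empty scored-variant set")
    return [sv for sv in scored if sv.p_value < alpha]


def detect_clusters(significant: Sequence[ScoredVariant],
                    max_gap: int = DEFAULT_MAX_GAP,
                    min_size: int = DEFAULT_MIN_SIZE) -> list[ClusterReport]:
    """Greedily chain significant mutations into clusters per chromosome.

    Positions are sorted within each chromosome; a chain extends while the
    gap to the previous member is strictly below ``max_gap``, and is emitted
    when it holds at least ``min_size`` members. Output is deterministic and
    independent of input row order.
    """
    by_chrom: dict[str, list[ScoredVariant]] = {}
    for sv in significant:
        by_chrom.setdefault(sv.key.chrom, []).append(sv)

    reports: list[ClusterReport] = []
    for chrom in sorted(by_chrom):
        svs = sorted(by_chrom[chrom], key=lambda sv: (sv.key.pos, sv.key.ref, sv.key.alt))
        chain: list[ScoredVariant] = []
        for sv in svs + [None]:  # sentinel flushes the final chain
            if chain and (sv is None or sv.key.pos - chain[-1].key.pos >= max_gap):
                if len(chain) >= min_size:
                    reports.append(_report(chrom, chain))
                chain = []
            if sv is not None:
                chain.append(sv)
    return reports


def _report(chrom: str, chain: list[ScoredVariant]) -> ClusterReport:
    positions = [sv.key.pos for sv in chain]
    return ClusterReport(
        chrom=chrom,
        start=min(positions),
        end=max(positions),
        members=[sv.key for sv in chain],
        size=len(chain),
        min_p=float(min(sv.p_value for sv in chain)),
        mean_iw=float(np.mean([sv.iw_score for sv in chain])),
    )


def cluster_overlap(reports: Sequence[ClusterReport], region_set: RegionSet
                    ) -> list[ClusterReport]:
    """Annotate each cluster with every region its 1-based span intersects."""
    out = []
    for rep in reports:
        hits = region_set.tree(rep.chrom).overlap(rep.start - 1, rep.end)
        labels = tuple(iv.data for iv in sorted(hits, key=lambda iv: (iv.begin, iv.end, str(iv.data))))
        out.append(ClusterReport(rep.chrom, rep.start, rep.end, list(rep.members),
                                 rep.size, rep.min_p, rep.mean_iw, labels))
    return out
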