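"""Operating-point allele assignment and cross-predictor overlap analyses.

Presentation probabilities become (peptide, allele) assignments at fixed
operating points: probability >= 0.5 for ordinary comparisons, a stricter
>= 0.95 when an unambiguous single-allele (monoallelic) assignment is
needed, and %Rank <= 2 for external predictors whose scores are percentile
ranks (smaller is better).  The overlap analysis partitions the pairs
called by two predictors into shared/unique sets and reports, for each
partition, how many pairs are confirmed by an allele-matched single-allelic
reference set — optionally restricted to references from a minimum
publication year for a stricter benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import PredictionRecord

logger = logging.getLogger(__name__)

Pair = tuple[str, str]  # (peptide, allele)


@dataclass(frozen=True)
class AssignmentPolicy:
    """Operating points for turning scores into assignments."""

    threshold: float = 0.5
    strict_threshold: float = 0.95
    external_rank_cutoff: float = 2.0
    external_rank_inclusive: bool = True

    def __post_init__(self):
        if self.strict_threshold < self.threshold:
            raise ValueError("strict_threshold must be >= threshold")


@dataclass
class PartitionReport:
    size: int
    confirmed: int
    fraction: float
    degenerate: bool = False  # True when the partition is empty
    by_source: dict[str, int] = field(default_factory=dict)


@dataclass
class OverlapReport:
    """Shared/unique partition of two predictors' pair sets with confirmations."""

    shared: set[Pair]
    unique_a: set[Pair]
    unique_b: set[Pair]
    confirmed_shared: PartitionReport
    confirmed_unique_a: PartitionReport
    confirmed_unique_b: PartitionReport
    min_year: int | None = None

    def to_dict(self) -> dict:
        def part(pairs: set[Pair], rep: PartitionReport) -> dict:
            return {
                "size": rep.size,
                "confirmed": rep.confirmed,
                "fraction_confirmed": rep.fraction,
                "degenerate": rep.degenerate,
                "confirmed_by_source": rep.by_source,
            }

        return {
            "shared": part(self.shared, self.confirmed_shared),
            "unique_a": part(self.unique_a, self.confirmed_unique_a),
            "unique_b": part(self.unique_b, self.confirmed_unique_b),
            "min_year": self.min_year,
        }


def assign(
    records: Iterable[PredictionRecord],
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> set[Pair]:
    """Pairs whose instance probability reaches the threshold (inclusive).

    Filtered instances (NaN probability) are never assigned.
    """
    out = set()
    for rec in records:
        if rec.filtered or np.isnan(rec.instance_probability):
            continue
        if not 0.0 <= rec.instance_probability <= 1.0:
            raise ValueError(
                f"probability {rec.instance_probability} outside [0,1] "
                f"for {rec.peptide}/{rec.allele}"
            )
        if rec.instance_probability >= policy.threshold:
            out.add((rec.peptide, rec.allele))
    return out


def assign_external(
    records: Iterable[tuple[str, str, float]],
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> set[Pair]:
    """Binder calls from an external predictor's %Rank scores.

    %Rank is a percentile among random peptides, so *smaller* is better;
    the conventional cutoff is <=2.  Strict variants (e.g. <0.05) use an
    exclusive boundary via ``external_rank_inclusive=False``.
    """
    cutoff = policy.external_rank_cutoff
    out = set()
    for peptide, allele, rank in records:
        if rank < 0:
            raise ValueError(f"negative %Rank {rank} for {peptide}/{allele}")
        if (rank <= cutoff) if policy.external_rank_inclusive else (rank < cutoff):
            out.add((peptide, allele))
    return out


def monoallelic_assign(
    records: Iterable[PredictionRecord],
    policy: AssignmentPolicy = AssignmentPolicy(),
) -> dict[str, str]:
    """Unambiguous single-allele assignments at the strict threshold.

    A peptide is assigned iff *exactly one* of its candidate alleles passes
    ``strict_threshold``; ambiguous peptides (two or more passing) and
    peptides with none passing are excluded.
    """
    passing: dict[str, set[str]] = {}
    for rec in records:
        if rec.filtered or np.isnan(rec.instance_probability):
            continue
        if rec.instance_probability >= policy.strict_threshold:
            passing.setdefault(rec.peptide, set()).add(rec.allele)
    return {pep: next(iter(al)) for pep, al in passing.items() if len(al) == 1}


def quantile_matched_threshold(scores: Iterable[float], target_count: int) -> float:
    """Threshold such that exactly ``target_count`` scores are >= it.

    Supports matching an external predictor's assignment count when its
    native operating point is a score quantile.
    """
    ranked = sorted(scores, reverse=True)
    if not 1 <= target_count <= len(ranked):
        raise ValueError(f"target_count {target_count} outside 1..{len(ranked)}")
    return ranked[target_count - 1]


def _confirm(
    pairs: set[Pair], reference_pairs: set[Pair], source_of: Mapping[Pair, str]
) -> PartitionReport:
    confirmed = pairs & reference_pairs
    by_source: dict[str, int] = {}
    for pair in confirmed:
        src = source_of.get(pair, "")
        by_source[src] = by_source.get(src, 0) + 1
    if not pairs:
        return PartitionReport(size=0, confirmed=0, fraction=0.0, degenerate=True)
    return PartitionReport(
        size=len(pairs), confirmed=len(confirmed),
        fraction=len(confirmed) / len(pairs), by_source=by_source,
    )


def overlap_and_confirm(
    pairs_a: set[Pair],
    pairs_b: set[Pair],
    reference: pd.DataFrame,
    min_year: int | None = None,
) -> OverlapReport:
    """Partition two predictors' calls and confirm against a reference set.

    The reference is a single-allelic pHLA table (columns peptide, allele,
    optional source and year).  A pair is confirmed iff its exact (peptide,
    normalized allele) combination occurs in the reference; there is no
    peptide-only fallback.  With ``min_year`` set, reference records from
    earlier years are dropped first (the stricter benchmark restricts the
    references, not the predictions).
    """
    ref = reference
    if min_year is not None:
        if "year" not in ref.columns:
            raise ValueError("reference table has no 'year' column but min_year is set")
        ref = ref[ref["year"].notna() & (ref["year"] >= min_year)]
    ref_pairs = set(zip(ref["peptide"], ref["allele"]))
    source_of = (
        dict(zip(zip(ref["peptide"], ref["allele"]), ref["source"]))
        if "source" in ref.columns
        else {}
    )
    shared = pairs_a & pairs_b
    unique_a = pairs_a - pairs_b
    unique_b = pairs_b - pairs_a
    if not unique_a and not unique_b:
        logger.info("predictor calls identical; unique partitions empty")
    return OverlapReport(
        shared=shared,
        unique_a=unique_a,
        unique_b=unique_b,
        confirmed_shared=_confirm(shared, ref_pairs, source_of),
        confirmed_unique_a=_confirm(unique_a, ref_pairs, source_of),
        confirmed_unique_b=_confirm(unique_b, ref_pairs, source_of),
        min_year=min_year,
    )
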