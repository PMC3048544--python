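"""Descriptive summaries: novelty vs a known-variant set, per-chromosome
counts, SNP density tracks, indel-length histograms, coverage fractions,
and additive partition reports with printed-precision percentages.

All summaries are conservative: aggregation never creates or loses a count.
``partition_report`` is the single arithmetic path for every partition-style
figure the pipeline reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import VariantCall, VariantType


def round_half_up(value: float, decimals: int) -> float:
    """Decimal half-up rounding (what printed percentages use), not banker's."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Novelty


@dataclass(frozen=True)
class NoveltyResult:
    n_known: int
    n_novel: int
    pct_novel: Optional[float]  # None when there are no calls


def novelty_check(
    calls: Sequence[VariantCall], known: set[tuple[str, int]]
) -> NoveltyResult:
    """Position-key membership against a known-variant set.

    Chromosome naming must be consistent: if the two sets share no chromosome
    name while both are non-empty, that is treated as a naming mismatch.
    """
    if calls and known:
        call_chroms = {c.chromosome for c in calls}
        known_chroms = {chrom for chrom, _ in known}
        if not call_chroms & known_chroms:
            raise ValueError(
                f"chromosome naming mismatch: calls use {sorted(call_chroms)[:3]}..., "
                f"known set uses {sorted(known_chroms)[:3]}..."
            )
    n_known = sum(1 for c in calls if (c.chromosome, c.position) in known)
    n_novel = len(calls) - n_known
    if not calls:
        return NoveltyResult(0, 0, None)
    return NoveltyResult(
        n_known, n_novel, round_half_up(100.0 * n_novel / len(calls), 1)
    )


# ---------------------------------------------------------------------------
# Density


def snp_density(
    calls: Sequence[VariantCall],
    chromosome_lengths: Mapping[str, int],
    window_bp: int = 1000,
) -> pd.DataFrame:
    """Counts of calls per tiling window [k*w+1, (k+1)*w]; last window truncated.

    Returns a DataFrame with chromosome, window_start, window_end, count.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    frames = []
    by_chrom: dict[str, list[int]] = {}
    for c in calls:
        if c.chromosome not in chromosome_lengths:
            raise ValueError(f"call on unknown chromosome {c.chromosome}")
        if c.position > chromosome_lengths[c.chromosome]:
            raise ValueError(
                f"call at {c.chromosome}:{c.position} beyond chromosome end "
                f"{chromosome_lengths[c.chromosome]}"
            )
        by_chrom.setdefault(c.chromosome, []).append(c.position)
    for chrom, length in chromosome_lengths.items():
        n_windows = (length + window_bp - 1) // window_bp
        counts = np.zeros(n_windows, dtype=int)
        for pos in by_chrom.get(chrom, []):
            counts[(pos - 1) // window_bp] += 1
        starts = np.arange(n_windows) * window_bp + 1
        ends = np.minimum(starts + window_bp - 1, length)
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "window_start": starts,
                    "window_end": ends,
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def per_chromosome_counts(calls: Sequence[VariantCall]) -> pd.DataFrame:
    """SNP and indel counts per chromosome."""
    rows: dict[str, dict[str, int]] = {}
    for c in calls:
        row = rows.setdefault(c.chromosome, {"snps": 0, "indels": 0})
        row["snps" if c.variant_type is VariantType.SNP else "indels"] += 1
    df = pd.DataFrame(
        [{"chromosome": k, **v} for k, v in sorted(rows.items())]
    )
    return df


# ---------------------------------------------------------------------------
# Indel length histogram


def indel_length_histogram(calls: Sequence[VariantCall]) -> dict[int, int]:
    """Map signed indel length -> count (insertions positive, deletions negative)."""
    hist: dict[int, int] = {}
    for c in calls:
        if c.variant_type is VariantType.SNP:
            raise ValueError(
                f"SNP at {c.chromosome}:{c.position} passed to indel histogram"
            )
        length = len(c.alt_allele) - len(c.ref_allele)
        hist[length] = hist.get(length, 0) + 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# Coverage


@dataclass(frozen=True)
class CoverageResult:
    per_chromosome: pd.DataFrame  # chromosome, length, covered, pct_covered
    genome_pct_covered: float
    mean_fold_coverage: Optional[float]  # over covered positions; None if none


def coverage_fraction(
    depth_tracks: Mapping[str, Sequence[int]],
    chromosome_lengths: Optional[Mapping[str, int]] = None,
    min_depth: int = 1,
) -> CoverageResult:
    """Covered fraction (depth >= min_depth) and mean fold-coverage over
    covered positions only."""
    rows = []
    covered_total = 0
    length_total = 0
    depth_sum = 0
    for chrom, track in depth_tracks.items():
        arr = np.asarray(track)
        if (arr < 0).any():
            raise ValueError(f"{chrom}: negative depth values")
        if chromosome_lengths is not None and len(arr) != chromosome_lengths[chrom]:
            raise ValueError(
                f"{chrom}: depth track length {len(arr)} != chromosome length "
                f"{chromosome_lengths[chrom]}"
            )
        covered = int((arr >= min_depth).sum())
        rows.append(
            {
                "chromosome": chrom,
                "length": len(arr),
                "covered": covered,
                "pct_covered": round_half_up(100.0 * covered / len(arr), 1),
            }
        )
        covered_total += covered
        length_total += len(arr)
        depth_sum += int(arr[arr >= min_depth].sum())
    fold = depth_sum / covered_total if covered_total else None
    return CoverageResult(
        per_chromosome=pd.DataFrame(rows),
        genome_pct_covered=round_half_up(100.0 * covered_total / length_total, 1),
        mean_fold_coverage=fold,
    )


# ---------------------------------------------------------------------------
# Partition reports


#: Schemas: node -> (parent or None). Percentages are taken against the
#: root total; precision 0 for read partitions, 1 for variant partitions.
PARTITION_SCHEMAS: dict[str, dict] = {
    "read_mapping": {
        "children": {
            "total_reads": None,
            "mapped": "total_reads",
            "unmapped": "total_reads",
            "multi_mapped": "mapped",
            "uniquely_mapped": "mapped",
        },
        "precision": 0,
    },
    "snp_partition": {
        "children": {
            "total_snps": None,
            "heterozygous": "total_snps",
            "homozygous": "total_snps",
        },
        "precision": 1,
    },
    "snp_location": {
        "children": {
            "total_snps": None,
            "intergenic": "total_snps",
            "flank_5kb": "total_snps",
            "genic": "total_snps",
            "intron": "genic",
            "utr": "genic",
            "splice_site": "genic",
            "synonymous": "genic",
            "nonsynonymous": "genic",
        },
        "precision": 1,
    },
    "indel_partition": {
        "children": {
            "total_indels": None,
            "insertions": "total_indels",
            "deletions": "total_indels",
        },
        "precision": 1,
    },
    "indel_location": {
        "children": {
            "total_indels": None,
            "intergenic": "total_indels",
            "flank_5kb": "total_indels",
            "genic": "total_indels",
            "intron": "genic",
            "exon": "genic",
            "splice_site": "genic",
        },
        "precision": 1,
    },
    "coding_snps": {
        "children": {
            "coding": None,
            "synonymous": "coding",
            "nonsynonymous": "coding",
        },
        "precision": 1,
    },
}


@dataclass(frozen=True)
class PartitionReport:
    schema: str
    counts: dict[str, int]
    percentages: dict[str, float]
    totals: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(self.counts),
                "count": list(self.counts.values()),
                "percentage": [self.percentages[k] for k in self.counts],
            }
        )


def partition_report(
    component_counts: Mapping[str, int], schema: str
) -> PartitionReport:
    """Totals by summation over children; percentages at printed precision.

    Leaf counts are given; any internal node (including the root) missing
    from ``component_counts`` is computed as the sum of its children.
    Percentages are relative to each node's parent total (the root's
    percentage is 100). A child exceeding its parent is an error.
    """
    if schema not in PARTITION_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; have {sorted(PARTITION_SCHEMAS)}")
    spec = PARTITION_SCHEMAS[schema]
    parent_of: dict[str, Optional[str]] = spec["children"]
    precision: int = spec["precision"]
    if any(v < 0 for v in component_counts.values()):
        raise ValueError("negative counts")
    unknown = set(component_counts) - set(parent_of)
    if unknown:
        raise ValueError(f"counts {sorted(unknown)} not in schema {schema!r}")

    counts: dict[str, int] = {
        k: int(v) for k, v in component_counts.items()
    }
    children_of: dict[Optional[str], list[str]] = {}
    for node, parent in parent_of.items():
        children_of.setdefault(parent, []).append(node)

    def resolve(node: str) -> Optional[int]:
        """Count for node: given directly, else the sum of its resolvable
        children; None when neither exists (node omitted from the report)."""
        if node in counts:
            return counts[node]
        kid_values = [
            v for k in children_of.get(node, []) if (v := resolve(k)) is not None
        ]
        if not kid_values:
            return None
        counts[node] = sum(kid_values)
        return counts[node]

    for node in parent_of:
        resolve(node)
    missing = [n for n in parent_of if n not in counts]
    parent_of = {n: p for n, p in parent_of.items() if n not in missing}
    # consistency: children must sum to their parent's total
    for parent, kids in children_of.items():
        if parent is None:
            continue
        if parent not in counts:
            continue
        total = counts[parent]
        ksum = sum(counts[k] for k in kids if k in counts)
        if ksum > total:
            raise ValueError(
                f"children of {parent!r} sum to {ksum} > parent total {total}"
            )

    percentages = {}
    totals = {}
    for node, parent in parent_of.items():
        base = counts[_root_of(parent_of, node)]
        totals[node] = base
        percentages[node] = (
            100.0 if counts[node] == base and base > 0
            else round_half_up(100.0 * counts[node] / base, precision) if base
            else 0.0
        )
    return PartitionReport(schema=schema, counts=counts, percentages=percentages,
                           totals=totals)


def _root_of(parent_of: Mapping[str, Optional[str]], node: str) -> str:
    while parent_of[node] is not None:
        node = parent_of[node]  # type: ignore[assignment]
    return node
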