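"""Threshold-based SNP/indel calling from per-site pileup counts.

A pileup site becomes a call when three inclusive thresholds hold
simultaneously: total depth >= min_depth, reads supporting the alternate
allele >= min_alt_reads, and alternate fraction (alt reads / total depth)
>= min_alt_fraction. Calls at or above the hom_fraction cutoff are
homozygous, the rest heterozygous. No genotype-likelihood model is applied;
any site whose pileup contains a non-reference allele is a candidate.
"""

from __future__ import annotations

import logging
from typing import Iterable, Union

import pandas as pd

from .models import (
    FilterParams,
    NoCall,
    NoCallReason,
    PileupSite,
    VariantCall,
    VariantType,
    Zygosity,
)

logger = logging.getLogger(__name__)


def _candidate_alt(site: PileupSite) -> tuple[str, int] | None:
    """Highest-count allele differing from ref; lexicographic tie-break."""
    alts = [
        (allele, n)
        for allele, n in site.base_counts.items()
        if allele != site.ref_base and n > 0
    ]
    if not alts:
        return None
    top = max(n for _, n in alts)
    ties = sorted(a for a, n in alts if n == top)
    if len(ties) > 1:
        logger.warning(
            "%s:%d: tie between alternate alleles %s; keeping %s",
            site.chromosome,
            site.position,
            ties,
            ties[0],
        )
    return ties[0], top


def _allele_pair(site: PileupSite, alt_token: str) -> tuple[str, str, VariantType]:
    """Expand a pileup allele token into VCF-style ref/alt alleles."""
    if alt_token.startswith("+"):
        return site.ref_base, site.ref_base + alt_token[1:], VariantType.INS
    if alt_token.startswith("-"):
        return site.ref_base + alt_token[1:], site.ref_base, VariantType.DEL
    return site.ref_base, alt_token, VariantType.SNP


def classify_zygosity(alt_fraction: float, params: FilterParams) -> Zygosity:
    """HOM at or above the hom_fraction cutoff (inclusive), else HET."""
    return Zygosity.HOM if alt_fraction >= params.hom_fraction else Zygosity.HET


def call_variant(
    site: PileupSite, params: FilterParams = FilterParams()
) -> Union[VariantCall, NoCall]:
    """Apply the three filters to one site; return a call or a reasoned no-call.

    Reason codes: LOW_DEPTH (depth below min_depth), NO_ALT (no non-reference
    allele observed), LOW_ALT (alternate reads below min_alt_reads),
    LOW_FRACTION (alternate fraction below min_alt_fraction).
    """
    if site.depth < params.min_depth:
        return NoCall(site.chromosome, site.position, NoCallReason.LOW_DEPTH)
    cand = _candidate_alt(site)
    if cand is None:
        return NoCall(site.chromosome, site.position, NoCallReason.NO_ALT)
    alt_token, alt_count = cand
    if alt_count < params.min_alt_reads:
        return NoCall(site.chromosome, site.position, NoCallReason.LOW_ALT)
    fraction = alt_count / site.depth
    if fraction < params.min_alt_fraction:
        return NoCall(site.chromosome, site.position, NoCallReason.LOW_FRACTION)
    ref, alt, vtype = _allele_pair(site, alt_token)
    return VariantCall(
        chromosome=site.chromosome,
        position=site.position,
        variant_type=vtype,
        ref_allele=ref,
        alt_allele=alt,
        depth=site.depth,
        alt_reads=alt_count,
        zygosity=classify_zygosity(fraction, params),
    )


def call_variants(
    sites: Iterable[PileupSite], params: FilterParams = FilterParams()
) -> tuple[list[VariantCall], list[NoCall]]:
    """Call every site; return (calls, no-calls)."""
    calls: list[VariantCall] = []
    rejects: list[NoCall] = []
    for site in sites:
        result = call_variant(site, params)
        if isinstance(result, VariantCall):
            calls.append(result)
        else:
            rejects.append(result)
    return calls, rejects


def stringency_sweep(
    sites: list[PileupSite], param_sets: list[FilterParams]
) -> pd.DataFrame:
    """Re-call the same sites under each parameter set and tabulate.

    Returns one row per parameter set with HET/HOM SNP and indel counts, the
    shape of the study's filter-stringency comparison table.
    """
    if not param_sets:
        raise ValueError("at least one parameter set required")
    rows = []
    for p in param_sets:
        calls, _ = call_variants(sites, p)
        row = {
            "min_depth": p.min_depth,
            "min_alt_reads": p.min_alt_reads,
            "min_alt_fraction": p.min_alt_fraction,
            "snp_het": 0,
            "snp_hom": 0,
            "indel_het": 0,
            "indel_hom": 0,
        }
        for c in calls:
            kind = "snp" if c.variant_type is VariantType.SNP else "indel"
            row[f"{kind}_{c.zygosity.value.lower()}"] += 1
        row["snp_total"] = row["snp_het"] + row["snp_hom"]
        row["indel_total"] = row["indel_het"] + row["indel_hom"]
        rows.append(row)
    return pd.DataFrame(rows)


#: The study's three filter settings, lenient to strict.
SWEEP_PARAM_SETS = [
    FilterParams(min_depth=3, min_alt_reads=2, min_alt_fraction=0.30),
    FilterParams(min_depth=4, min_alt_reads=2, min_alt_fraction=0.30),
    FilterParams(min_depth=5, min_alt_reads=3, min_alt_fraction=0.30),
]
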