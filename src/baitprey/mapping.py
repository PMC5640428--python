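"""Partitioning of interactome members by synapse proteome and by age.

Synapse categories (excitatory-only / inhibitory-only / both / neither) come
either from precomputed per-member flags (as in a published hit table) or by
resolving each member against named excitatory- and inhibitory-enriched
proteome sets; both paths share the same categoriser. The developmental
partition splits screen members into those detected only in developing (P5)
brain, only in mature (P50) brain, or both.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    DevelopmentalCategory,
    InteractomeMember,
    Provenance,
    SynapseCategory,
    SynapseProteomeCollection,
    Table1Row,
    ValidationError,
)

logger = logging.getLogger(__name__)


def categorize(in_excitatory: bool, in_inhibitory: bool) -> SynapseCategory:
    """Shared four-way categoriser."""
    if in_excitatory and in_inhibitory:
        return SynapseCategory.BOTH
    if in_excitatory:
        return SynapseCategory.EXCITATORY_ONLY
    if in_inhibitory:
        return SynapseCategory.INHIBITORY_ONLY
    return SynapseCategory.NEITHER


def map_synapse_category(
    member: InteractomeMember, proteomes: SynapseProteomeCollection
) -> SynapseCategory:
    """Resolve a member against the proteome sets (accession first, then
    case-insensitive gene symbol); unresolved members are NEITHER."""
    hit_e = hit_i = False
    for ident in (member.prey_id, member.gene_symbol):
        if not ident:
            continue
        hit_e = hit_e or proteomes.in_excitatory(ident)
        hit_i = hit_i or proteomes.in_inhibitory(ident)
    if not (hit_e or hit_i):
        logger.debug("member %s unresolved against proteome sets", member.prey_id)
    return categorize(hit_e, hit_i)


def map_synapse_category_from_flags(member: InteractomeMember) -> SynapseCategory:
    return categorize(member.flags.es, member.flags.is_flag)


def partition_synapse(
    members: Sequence[InteractomeMember],
    proteomes: SynapseProteomeCollection | None = None,
) -> dict[SynapseCategory, set[str]]:
    """Four disjoint sets covering every member. With ``proteomes`` the
    membership is recomputed; without, the stored ES/IS flags are used."""
    out: dict[SynapseCategory, set[str]] = {c: set() for c in SynapseCategory}
    for m in members:
        cat = (
            map_synapse_category(m, proteomes)
            if proteomes is not None
            else map_synapse_category_from_flags(m)
        )
        out[cat].add(m.identity)
    return out


def partition_developmental(
    members: Iterable[InteractomeMember],
) -> dict[DevelopmentalCategory, set[str]]:
    """Three disjoint sets over screen members with at least one age flag;
    literature-only members are excluded (they carry no detection ages)."""
    out: dict[DevelopmentalCategory, set[str]] = {
        c: set() for c in DevelopmentalCategory
    }
    for m in members:
        if m.provenance is not Provenance.SCREEN:
            continue
        p5, p50 = m.flags.p5, m.flags.p50
        if p5 and p50:
            out[DevelopmentalCategory.SHARED].add(m.identity)
        elif p5:
            out[DevelopmentalCategory.P5_ONLY].add(m.identity)
        elif p50:
            out[DevelopmentalCategory.P50_ONLY].add(m.identity)
        # members without any age flag are not part of the partition
    return out


def partition_developmental_table1(
    rows: Iterable[Table1Row],
) -> dict[DevelopmentalCategory, set[str]]:
    """Developmental partition straight from fixture rows (bait excluded)."""
    out: dict[DevelopmentalCategory, set[str]] = {
        c: set() for c in DevelopmentalCategory
    }
    for r in rows:
        if r.is_bait:
            continue
        if r.p5 and r.p50:
            out[DevelopmentalCategory.SHARED].add(r.gene_symbol)
        elif r.p5:
            out[DevelopmentalCategory.P5_ONLY].add(r.gene_symbol)
        elif r.p50:
            out[DevelopmentalCategory.P50_ONLY].add(r.gene_symbol)
    return out


def summarize_partitions(
    partition: Mapping[object, set[str]], total: int, precision: int = 1
) -> pd.DataFrame:
    """Tabulate (category, count, percent) with percent = 100 * count / total."""
    counts = {k: len(v) for k, v in partition.items()}
    if total <= 0:
        raise ValidationError("total must be positive to define percentages")
    if total < sum(counts.values()):
        raise ValidationError(
            f"total ({total}) smaller than the partition sum ({sum(counts.values())})"
        )
    rows = [
        {
            "category": getattr(k, "value", str(k)),
            "count": n,
            "percent": round(100.0 * n / total, precision),
        }
        for k, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
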