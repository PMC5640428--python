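"""Two-pass candidate filtering, contaminant removal, tiering and merging.

The admission procedure mirrors standard AP-MS practice: a first pass keeps
preys with at least two unique peptides and a minimum bait/control fold
enrichment; a second pass rescues near-misses that are (a) previously
validated partners, (b) members of a protein family already admitted, or
(c) single-peptide preys recurring across independent experiments; preys
recurrently observed in negative-control purifications (contaminant
repository frequency above a threshold) are then removed; survivors are
tiered Platinum/Gold/Silver/Bronze from replicate presence, fold enrichment
and MaxP; finally a curated literature list is merged in without
duplicating proteins already found by the screen.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import (
    AnnotationFlags,
    EnrichmentProfile,
    FilterConfig,
    InteractomeMember,
    ProteinList,
    Provenance,
    RescueReason,
    Tier,
    _norm,
)

logger = logging.getLogger(__name__)

_TRAILING_DIGITS = re.compile(r"\d+$")


def first_pass_filter(
    profiles: Sequence[EnrichmentProfile], cfg: FilterConfig
) -> set[str]:
    """Preys with >= ``min_unique_peptides`` unique peptides AND fold
    enrichment >= ``first_pass_fold``."""
    return {
        p.prey_id
        for p in profiles
        if p.unique_peptides_max >= cfg.min_unique_peptides
        and p.fold_ratio >= cfg.first_pass_fold
    }


def family_of(
    prey: EnrichmentProfile, family_map: Optional[Mapping[str, str]]
) -> Optional[str]:
    """Family id for rescue criterion (b).

    With an explicit ``family_map`` (keyed by prey id or gene symbol) the
    mapped id is used; a prey missing from the map has no family. Without a
    map, a heuristic strips trailing digits from the gene symbol
    (ATP1A2 -> ATP1A); this approximation is logged once per call site.
    """
    if family_map is not None:
        fam = family_map.get(prey.prey_id)
        if fam is None:
            fam = family_map.get(prey.gene_symbol)
        if fam is None:
            logger.debug("prey %s absent from family map", prey.prey_id)
        return fam
    stem = _TRAILING_DIGITS.sub("", prey.gene_symbol)
    if stem and stem != prey.gene_symbol:
        logger.debug(
            "family heuristic (approximate): %s -> %s", prey.gene_symbol, stem
        )
        return _norm(stem)
    return None


def second_pass_rescue(
    candidate: EnrichmentProfile,
    first_pass_profiles: Sequence[EnrichmentProfile],
    first_pass_ids: set[str],
    literature: ProteinList,
    family_map: Optional[Mapping[str, str]] = None,
) -> tuple[bool, RescueReason]:
    """Evaluate the rescue criteria, in order (a) -> (b) -> (c), for a prey
    that failed the first pass; the first matching criterion is reported.

    (a) previously validated partner (literature list membership);
    (b) the candidate's protein family already appears in the first pass;
    (c) the candidate is a single-peptide prey recurring across experiments
        (seen in >= 2 antibody/age conditions or >= 2 replicates).
    """
    if candidate.prey_id in literature or candidate.gene_symbol in literature:
        return True, RescueReason.LITERATURE_VALIDATED

    fam = family_of(candidate, family_map)
    if fam is not None:
        fp_families = {
            family_of(p, family_map)
            for p in first_pass_profiles
            if p.prey_id in first_pass_ids
        }
        fp_families.discard(None)
        if fam in fp_families:
            return True, RescueReason.FAMILY_IN_FIRST_PASS

    if candidate.unique_peptides_max == 1 and (
        len(candidate.conditions_seen) >= 2 or candidate.replicate_presence >= 2
    ):
        return True, RescueReason.MULTI_EXPERIMENT

    return False, RescueReason.NONE


def remove_contaminants(
    ids: set[str], contaminants: ProteinList, threshold: float
) -> set[str]:
    """Drop members whose contaminant observation frequency >= ``threshold``.

    A listed contaminant without a stated frequency is treated as frequency
    1.0 (always removed at any threshold <= 1). Identity comparison is
    case-insensitive.
    """
    freq = {
        _norm(m): (contaminants.frequency or {}).get(m, 1.0)
        for m in contaminants.members
    }
    return {i for i in ids if freq.get(_norm(i), -1.0) < threshold}


def assign_confidence_tier(profile: EnrichmentProfile, cfg: FilterConfig) -> Tier:
    """Total classification into Platinum/Gold/Silver/Bronze.

    Platinum: present in >= ``platinum_min_replicates`` replicates with fold
    >= ``high_fold`` and MaxP >= ``high_maxp``; Gold: same enrichment and
    score in fewer replicates; Silver: fold in [``silver_fold_low``,
    ``high_fold``) with MaxP in [``silver_maxp_low``, ``high_maxp``); Bronze:
    everything else. The rules are deliberately non-monotone in (fold, MaxP):
    a high-fold prey with a weak score falls through to Bronze.
    """
    high = profile.fold_ratio >= cfg.high_fold and profile.maxp >= cfg.high_maxp
    if high and profile.replicate_presence >= cfg.platinum_min_replicates:
        return Tier.PLATINUM
    if high:
        return Tier.GOLD
    if (
        cfg.silver_fold_low <= profile.fold_ratio < cfg.high_fold
        and cfg.silver_maxp_low <= profile.maxp < cfg.high_maxp
    ):
        return Tier.SILVER
    return Tier.BRONZE


@dataclass(frozen=True)
class Interactome:
    """The finished member list with screen/literature bookkeeping."""

    members: tuple[InteractomeMember, ...]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def screen_members(self) -> tuple[InteractomeMember, ...]:
        return tuple(m for m in self.members if m.provenance is Provenance.SCREEN)

    @property
    def literature_members(self) -> tuple[InteractomeMember, ...]:
        return tuple(
            m for m in self.members if m.provenance is Provenance.LITERATURE
        )


def merge_literature_partners(
    screen_members: Sequence[InteractomeMember], literature: ProteinList
) -> Interactome:
    """Union keyed by protein identity; a literature protein already found by
    the screen keeps its SCREEN provenance and is not duplicated."""
    seen = {m.identity for m in screen_members}
    seen |= {_norm(m.gene_symbol) for m in screen_members if m.gene_symbol}
    merged = list(screen_members)
    for name in sorted(literature.members):
        if _norm(name) in seen:
            continue
        seen.add(_norm(name))
        merged.append(
            InteractomeMember(
                prey_id=name,
                gene_symbol=name,
                provenance=Provenance.LITERATURE,
                tier=Tier.NA_LITERATURE,
            )
        )
    return Interactome(members=tuple(merged))


def build_screen_members(
    profiles: Sequence[EnrichmentProfile],
    admitted_ids: set[str],
    cfg: FilterConfig,
    rescue_reasons: Optional[Mapping[str, RescueReason]] = None,
    flags: Optional[Mapping[str, AnnotationFlags]] = None,
) -> list[InteractomeMember]:
    """Materialise admitted preys as tiered screen members."""
    rescue_reasons = rescue_reasons or {}
    flags = flags or {}
    members = []
    for p in sorted(profiles, key=lambda q: q.prey_id):
        if p.prey_id not in admitted_ids:
            continue
        members.append(
            InteractomeMember(
                prey_id=p.prey_id,
                gene_symbol=p.gene_symbol,
                provenance=Provenance.SCREEN,
                tier=assign_confidence_tier(p, cfg),
                fold_ratio=p.fold_ratio,
                maxp=p.maxp,
                replicate_presence=p.replicate_presence,
                rescue_reason=rescue_reasons.get(p.prey_id, RescueReason.NONE),
                flags=flags.get(p.prey_id, AnnotationFlags()),
            )
        )
    return members
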