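"""Per-prey enrichment statistics and a simplified SAINT-style score.

Fold enrichment is the pseudocount-stabilised ratio of total bait-channel to
total control-channel spectral counts. NSAF (Normalized Spectral Abundance
Factor) is the length-normalised spectral count rescaled to sum to one per
sample. The MaxP score is the maximum, over replicate purifications, of the
posterior probability of a true bait-prey interaction under a two-component
Poisson mixture: counts are Poisson(lambda_bg) for background preys and
Poisson(enrichment_factor * lambda_bg) for true interactors. This is a
deliberately small count model, not a reimplementation of the full
empirical-Bayes SAINT machinery; curated MaxP values from a published table
always take precedence over recomputed ones when both are available.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .model import (
    Age,
    Antibody,
    Channel,
    EnrichmentProfile,
    PreyObservation,
    ScoreModelParams,
    ValidationError,
)

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_LAMBDA_BG_FLOOR = 0.1


def compute_fold_enrichment(
    bait_total: int, control_total: int, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """(bait + pseudocount) / (control + pseudocount).

    Strictly increasing in ``bait_total`` and strictly decreasing in
    ``control_total``. With pseudocount 0 and both totals 0 the ratio is
    undefined and a :class:`ValidationError` is raised.
    """
    if bait_total < 0 or control_total < 0:
        raise ValidationError("spectral totals must be non-negative")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    num = bait_total + pseudocount
    den = control_total + pseudocount
    if den == 0:
        if num == 0:
            raise ValidationError(
                "fold enrichment undefined: both totals zero with pseudocount 0"
            )
        raise ValidationError(
            "fold enrichment undefined: zero control total with pseudocount 0"
        )
    return num / den


def compute_nsaf(
    spectral_counts: Mapping[str, int], lengths: Mapping[str, int]
) -> dict[str, float]:
    """NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j); values sum to 1."""
    saf: dict[str, float] = {}
    for prey, count in spectral_counts.items():
        if prey not in lengths:
            raise ValidationError(f"no protein length for prey {prey!r}")
        if lengths[prey] <= 0:
            raise ValidationError(f"non-positive length for prey {prey!r}")
        saf[prey] = count / lengths[prey]
    total = sum(saf.values())
    if total <= 0:
        raise ValidationError("all spectral counts are zero: no abundance mass")
    return {prey: v / total for prey, v in saf.items()}


def replicate_presence(
    observations: Iterable[PreyObservation], prey_id: str
) -> int:
    """Number of distinct replicates in which the prey has at least one
    bait-channel PSM. A prey absent from the table scores 0."""
    reps = {
        o.replicate
        for o in observations
        if o.prey_id == prey_id and o.channel is Channel.BAIT and o.spectral_count > 0
    }
    return len(reps)


def _log_poisson(x: int, lam: float) -> float:
    return x * math.log(lam) - lam - math.lgamma(x + 1)


def posterior_true(count: int, params: ScoreModelParams) -> float:
    """Posterior probability of a true interaction given one replicate count."""
    lt = _log_poisson(count, params.lambda_true) + math.log(params.prior_true)
    lb = _log_poisson(count, params.lambda_bg) + math.log(1.0 - params.prior_true)
    m = max(lt, lb)
    return math.exp(lt - m) / (math.exp(lt - m) + math.exp(lb - m))


def score_prey_maxp(
    per_replicate_bait_counts: Sequence[int], params: ScoreModelParams
) -> float:
    """Maximum per-replicate posterior; non-decreasing in every count."""
    if not per_replicate_bait_counts:
        raise ValidationError("need at least one replicate count")
    return max(posterior_true(int(x), params) for x in per_replicate_bait_counts)


def build_profiles(
    observations: Sequence[PreyObservation],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_true: float = 0.5,
    enrichment_factor: float = 10.0,
    lambda_bg_floor: float = DEFAULT_LAMBDA_BG_FLOOR,
) -> dict[str, EnrichmentProfile]:
    """Aggregate raw observations into one :class:`EnrichmentProfile` per prey.

    The background Poisson mean for the MaxP score is estimated per prey as
    the mean control-channel count over all control purifications, floored at
    ``lambda_bg_floor`` to avoid degenerate posteriors for preys never seen
    in controls.
    """
    bait_total: dict[str, int] = defaultdict(int)
    ctrl_total: dict[str, int] = defaultdict(int)
    uniq_max: dict[str, int] = defaultdict(int)
    reps: dict[str, set[int]] = defaultdict(set)
    conds: dict[str, set[tuple[Antibody, Age]]] = defaultdict(set)
    per_rep_bait: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    symbols: dict[str, str] = {}
    n_control_purifs = len(
        {o.purification_id for o in observations if o.channel is Channel.CONTROL}
    )
    all_reps = {o.replicate for o in observations}

    for o in observations:
        symbols.setdefault(o.prey_id, o.gene_symbol)
        uniq_max[o.prey_id] = max(uniq_max[o.prey_id], o.unique_peptides)
        if o.channel is Channel.BAIT:
            bait_total[o.prey_id] += o.spectral_count
            per_rep_bait[o.prey_id][o.replicate] += o.spectral_count
            if o.spectral_count > 0:
                reps[o.prey_id].add(o.replicate)
                conds[o.prey_id].add((o.antibody, o.age))
        else:
            ctrl_total[o.prey_id] += o.spectral_count

    profiles: dict[str, EnrichmentProfile] = {}
    for prey in symbols:
        fold = compute_fold_enrichment(
            bait_total[prey], ctrl_total[prey], pseudocount
        )
        lam_bg = (
            ctrl_total[prey] / n_control_purifs if n_control_purifs else 0.0
        )
        params = ScoreModelParams(
            prior_true=prior_true,
            lambda_bg=max(lam_bg, lambda_bg_floor),
            enrichment_factor=enrichment_factor,
        )
        counts = [per_rep_bait[prey].get(r, 0) for r in sorted(all_reps)] or [0]
        profiles[prey] = EnrichmentProfile(
            prey_id=prey,
            gene_symbol=symbols[prey],
            fold_ratio=fold,
            unique_peptides_max=uniq_max[prey],
            psm_total_bait=bait_total[prey],
            psm_total_control=ctrl_total[prey],
            replicate_presence=len(reps[prey]),
            conditions_seen=frozenset(conds[prey]),
            maxp=score_prey_maxp(counts, params),
        )
    return profiles
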