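"""End-to-end orchestration: enrichment -> first pass -> rescue ->
contaminant removal -> tiering -> literature merge -> partition reports.

A run is driven by a :class:`PipelineConfig` (loadable from YAML with
unknown keys rejected) and produces a report bundle: the interactome table,
per-stage candidate counts, partition summaries and a plain-text log. The
same stages can also be replayed on the packaged screen-hit fixture, whose
stored fold ratios, MaxP scores and annotation flags stand in for
recomputed ones.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import io as bio
from .filtering import (
    Interactome,
    build_screen_members,
    first_pass_filter,
    merge_literature_partners,
    remove_contaminants,
    second_pass_rescue,
)
from .mapping import (
    partition_developmental,
    partition_synapse,
    summarize_partitions,
)
from .model import (
    AnnotationFlags,
    ConfigurationError,
    EnrichmentProfile,
    FilterConfig,
    InteractomeMember,
    ProteinList,
    Provenance,
    RescueReason,
    Table1Row,
    Tier,
)
from .scoring import DEFAULT_LAMBDA_BG_FLOOR, DEFAULT_PSEUDOCOUNT, build_profiles
from .simulate import SimulationConfig, simulate_apms_experiment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreConfig:
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    prior_true: float = 0.5
    enrichment_factor: float = 10.0
    lambda_bg_floor: float = DEFAULT_LAMBDA_BG_FLOOR


@dataclass(frozen=True)
class PipelineConfig:
    """Composition of file paths, scoring and filter settings for one run."""

    counts: Optional[str] = None
    literature: Optional[str] = None
    crapome: Optional[str] = None
    family_map: Optional[str] = None
    out_dir: str = "pipeline_out"
    report_precision: int = 1
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    score: ScoreConfig = field(default_factory=ScoreConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.counts is None and self.simulate is None:
            raise ConfigurationError(
                "config must name a field: provide `counts` (path) or `simulate`"
            )


def _build_section(cls, data: Mapping, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in `{section}`: {sorted(unknown)}"
        )
    return cls(**data)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    if "simulate" in kwargs and kwargs["simulate"] is not None:
        sim = dict(kwargs["simulate"])
        from .model import Age, Antibody  # enum coercion for YAML strings

        if "antibodies" in sim:
            sim["antibodies"] = tuple(Antibody(a) for a in sim["antibodies"])
        if "ages" in sim:
            sim["ages"] = tuple(Age(a) for a in sim["ages"])
        kwargs["simulate"] = _build_section(SimulationConfig, sim, "simulate")
    if "score" in kwargs and kwargs["score"] is not None:
        kwargs["score"] = _build_section(ScoreConfig, kwargs["score"], "score")
    if "filter" in kwargs and kwargs["filter"] is not None:
        kwargs["filter"] = _build_section(FilterConfig, kwargs["filter"], "filter")
    return PipelineConfig(**kwargs)


@dataclass
class ReportBundle:
    interactome: Interactome
    stage_counts: pd.DataFrame
    developmental_summary: pd.DataFrame
    synapse_summary: pd.DataFrame
    tier_counts: pd.DataFrame
    log_lines: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bio.write_interactome(list(self.interactome.members), out / "interactome.tsv")
        self.stage_counts.to_csv(out / "stage_counts.tsv", sep="\t", index=False)
        self.developmental_summary.to_csv(
            out / "developmental_partition.tsv", sep="\t", index=False
        )
        self.synapse_summary.to_csv(
            out / "synapse_partition.tsv", sep="\t", index=False
        )
        self.tier_counts.to_csv(out / "tier_counts.tsv", sep="\t", index=False)
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")


def _log(lines: list[str], msg: str) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    lines.append(f"{stamp} {msg}")
    logger.info(msg)


def filter_profiles(
    profiles: Sequence[EnrichmentProfile],
    cfg: FilterConfig,
    literature: ProteinList,
    contaminants: Optional[ProteinList] = None,
    family_map: Optional[Mapping[str, str]] = None,
) -> tuple[set[str], dict[str, RescueReason], list[tuple[str, int, int]]]:
    """Run first pass, rescue and contaminant removal; returns the admitted
    id set, rescue provenance, and chained per-stage (stage, n_in, n_out)."""
    stages: list[tuple[str, int, int]] = []
    n0 = len(profiles)
    stages.append(("enrichment", n0, n0))

    fp = first_pass_filter(profiles, cfg)
    stages.append(("first_pass", n0, len(fp)))

    rescue_reasons: dict[str, RescueReason] = {}
    admitted = set(fp)
    for p in profiles:
        if p.prey_id in fp:
            continue
        ok, reason = second_pass_rescue(p, profiles, fp, literature, family_map)
        if ok:
            admitted.add(p.prey_id)
            rescue_reasons[p.prey_id] = reason
    stages.append(("second_pass", len(fp), len(admitted)))

    if contaminants is not None:
        kept = remove_contaminants(
            admitted, contaminants, cfg.contaminant_frequency_threshold
        )
    else:
        kept = set(admitted)
    stages.append(("contaminant_removal", len(admitted), len(kept)))
    return kept, rescue_reasons, stages


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full filtering pipeline and assemble the report bundle."""
    lines: list[str] = []
    _log(lines, f"config: {config}")
    _log(lines, f"seed: {config.seed}")

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        observations, truth = simulate_apms_experiment(sim_cfg)
        family_map: Optional[Mapping[str, str]] = truth.family_map
        _log(lines, f"simulated {len(observations)} observations")
    else:
        observations = bio.read_count_table(config.counts)
        family_map = None
        _log(lines, f"read {len(observations)} observations from {config.counts}")
        if config.family_map:
            family_map = bio.read_family_map(config.family_map)

    profiles = list(
        build_profiles(
            observations,
            pseudocount=config.score.pseudocount,
            prior_true=config.score.prior_true,
            enrichment_factor=config.score.enrichment_factor,
            lambda_bg_floor=config.score.lambda_bg_floor,
        ).values()
    )

    literature = (
        bio.read_protein_list(config.literature)
        if config.literature
        else bio.read_literature_partners()
    )
    contaminants = (
        bio.read_protein_list(config.crapome) if config.crapome else None
    )
    if config.simulate is not None and contaminants is None:
        truth_freq = truth.contaminant_frequency
        contaminants = ProteinList(
            name="planted_contaminants",
            members=frozenset(truth.contaminant_ids),
            frequency=truth_freq,
        )

    admitted, rescue_reasons, stages = filter_profiles(
        profiles, config.filter, literature, contaminants, family_map
    )
    screen = build_screen_members(
        profiles, admitted, config.filter, rescue_reasons
    )
    interactome = merge_literature_partners(screen, literature)
    stages.append(("literature_merge", len(screen), len(interactome)))
    for name, n_in, n_out in stages:
        _log(lines, f"stage {name}: {n_in} -> {n_out}")

    stage_counts = pd.DataFrame(stages, columns=["stage", "n_in", "n_out"])
    dev = partition_developmental(interactome.members)
    n_dev = sum(len(v) for v in dev.values())
    dev_summary = (
        summarize_partitions(dev, n_dev, config.report_precision)
        if n_dev
        else pd.DataFrame(columns=["category", "count", "percent"])
    )
    syn = partition_synapse(list(interactome.members))
    syn_summary = (
        summarize_partitions(syn, len(interactome), config.report_precision)
        if len(interactome)
        else pd.DataFrame(columns=["category", "count", "percent"])
    )
    tiers = (
        pd.Series([m.tier.value for m in interactome.members])
        .value_counts()
        .rename_axis("tier")
        .reset_index(name="count")
        .sort_values("tier", kind="mergesort")
        .reset_index(drop=True)
    )
    return ReportBundle(
        interactome=interactome,
        stage_counts=stage_counts,
        developmental_summary=dev_summary,
        synapse_summary=syn_summary,
        tier_counts=tiers,
        log_lines=lines,
    )


def stage_count_report(bundle: ReportBundle) -> pd.DataFrame:
    """The per-stage (stage, n_in, n_out) table; chained so that each stage's
    n_out equals the next stage's n_in (the literature merge, which only adds
    members, closes the chain)."""
    return bundle.stage_counts.copy()


def members_from_table1(
    rows: Sequence[Table1Row], cfg: Optional[FilterConfig] = None
) -> list[InteractomeMember]:
    """Materialise fixture rows as screen members, bait rows excluded.

    Stored fold ratios and MaxP scores drive the tier rules; the fixture does
    not record replicate presence, so the replicate-gated Platinum rule is
    not applied (high-confidence rows classify as Gold).
    """
    cfg = cfg or FilterConfig()
    members = []
    for r in rows:
        if r.is_bait:
            continue
        high = r.spectral_ratio >= cfg.high_fold and r.maxp >= cfg.high_maxp
        if high:
            tier = Tier.GOLD
        elif (
            cfg.silver_fold_low <= r.spectral_ratio < cfg.high_fold
            and cfg.silver_maxp_low <= r.maxp < cfg.high_maxp
        ):
            tier = Tier.SILVER
        else:
            tier = Tier.BRONZE
        members.append(
            InteractomeMember(
                prey_id=r.uniprot_id,
                gene_symbol=r.gene_symbol,
                provenance=Provenance.SCREEN,
                tier=tier,
                fold_ratio=r.spectral_ratio,
                maxp=r.maxp,
                flags=AnnotationFlags(
                    es=r.es, is_flag=r.is_flag, p5=r.p5, p50=r.p50, ps940=r.ps940
                ),
            )
        )
    return members
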