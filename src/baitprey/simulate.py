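"""Synthetic AP-MS count tables and IV curves with planted ground truth.

The generator emulates the statistical structure the analysis assumes: in
each antibody x age condition and replicate, a bait purification and a
matched IgG/IgY control purification are run. True interactors draw
bait-channel counts from Poisson(enrichment_factor * lambda_bg) (subject to
a per-purification detection probability) and control counts from
Poisson(lambda_bg); background preys draw both channels from
Poisson(lambda_bg); frequent contaminants appear in both channels at high
counts. A configurable fraction of true interactors is forced down to a
single unique peptide so that the second-pass rescue logic is exercised.
Everything is reproducible from the config seed.

Defaults mirror the multi-epitope screen design that the pipeline targets:
three antibody epitopes x two ages x three replicates, with a background
mean of 3 PSM per purification and ten-fold enrichment for true partners.
An ``overdispersion`` parameter switches counts from Poisson to negative
binomial (gamma-mixed Poisson) for robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    Age,
    Antibody,
    Channel,
    IVPoint,
    PreyObservation,
    ValidationError,
)

DEFAULT_ANTIBODIES = (Antibody.C_TERM, Antibody.N_TERM_KCC2B, Antibody.PS940)
DEFAULT_AGES = (Age.P5, Age.P50)


@dataclass(frozen=True)
class SimulationConfig:
    n_true_interactors: int = 50
    n_background: int = 200
    n_contaminants: int = 10
    replicates_per_condition: int = 3
    antibodies: tuple[Antibody, ...] = DEFAULT_ANTIBODIES
    ages: tuple[Age, ...] = DEFAULT_AGES
    lambda_bg: float = 3.0
    enrichment_factor: float = 10.0
    true_detection_prob: float = 0.95
    contaminant_frequency: float = 0.8
    contaminant_lambda_factor: float = 5.0
    single_peptide_fraction: float = 0.1
    overdispersion: Optional[float] = None  # NB shape; None = pure Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_true_interactors", "n_background", "n_contaminants"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.replicates_per_condition < 1:
            raise ValidationError("need at least one replicate")
        if not self.antibodies or not self.ages:
            raise ValidationError("need at least one antibody and one age")
        if self.lambda_bg <= 0:
            raise ValidationError("lambda_bg must be > 0")
        if self.enrichment_factor <= 1:
            raise ValidationError("enrichment_factor must exceed 1")
        if not (0.0 < self.true_detection_prob <= 1.0):
            if self.n_true_interactors > 0:
                raise ValidationError(
                    "true_detection_prob must lie in (0, 1] when true "
                    "interactors are requested"
                )
        if not (0.0 < self.contaminant_frequency <= 1.0):
            raise ValidationError("contaminant_frequency must lie in (0, 1]")
        if not (0.0 <= self.single_peptide_fraction <= 1.0):
            raise ValidationError("single_peptide_fraction must lie in [0, 1]")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValidationError("overdispersion must be > 0 when set")


@dataclass(frozen=True)
class GroundTruth:
    true_ids: frozenset[str]
    background_ids: frozenset[str]
    contaminant_ids: frozenset[str]
    bait_lambda: dict[str, float] = field(default_factory=dict)
    single_peptide_ids: frozenset[str] = frozenset()
    contaminant_frequency: dict[str, float] = field(default_factory=dict)
    family_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.true_ids & self.background_ids
            or self.true_ids & self.contaminant_ids
            or self.background_ids & self.contaminant_ids
        ):
            raise ValidationError("ground-truth id sets must be disjoint")


def _draw_counts(rng: np.random.Generator, lam: float, cfg: SimulationConfig) -> int:
    if cfg.overdispersion is None:
        return int(rng.poisson(lam))
    shape = cfg.overdispersion
    return int(rng.poisson(rng.gamma(shape, lam / shape)))


def _unique_peptides(rng: np.random.Generator, spectral_count: int) -> int:
    """Sub-model: 1 + Binomial(count - 1, 0.5), capped at the count itself."""
    if spectral_count == 0:
        return 0
    return int(min(spectral_count, 1 + rng.binomial(spectral_count - 1, 0.5)))


def simulate_apms_experiment(
    cfg: SimulationConfig,
) -> tuple[list[PreyObservation], GroundTruth]:
    """Generate the full observation table plus its ground truth.

    Prey ids are TRU####, BG#### and CONT####; each gets its own singleton
    family id (paralog families are not modelled) and a protein length drawn
    uniformly from 200-1200 residues for NSAF use.
    """
    rng = np.random.default_rng(cfg.seed)
    true_ids = [f"TRU{i:04d}" for i in range(cfg.n_true_interactors)]
    bg_ids = [f"BG{i:04d}" for i in range(cfg.n_background)]
    cont_ids = [f"CONT{i:04d}" for i in range(cfg.n_contaminants)]
    all_ids = true_ids + bg_ids + cont_ids

    lengths = {p: int(rng.integers(200, 1201)) for p in all_ids}
    n_single = int(round(cfg.single_peptide_fraction * len(true_ids)))
    single_ids = frozenset(true_ids[:n_single])

    lam_true = cfg.enrichment_factor * cfg.lambda_bg
    lam_cont = cfg.contaminant_lambda_factor * cfg.lambda_bg
    bait_lambda = {p: lam_true for p in true_ids}
    bait_lambda.update({p: cfg.lambda_bg for p in bg_ids})
    bait_lambda.update({p: lam_cont for p in cont_ids})

    observations: list[PreyObservation] = []

    def emit(prey: str, purif: str, ab: Antibody, age: Age, rep: int,
             channel: Channel, count: int) -> None:
        if count <= 0:
            return
        uniq = 1 if prey in single_ids else _unique_peptides(rng, count)
        observations.append(
            PreyObservation(
                prey_id=prey,
                gene_symbol=prey,
                purification_id=purif,
                antibody=ab,
                age=age,
                replicate=rep,
                channel=channel,
                spectral_count=count,
                unique_peptides=uniq,
                protein_length=lengths[prey],
            )
        )

    for ab in cfg.antibodies:
        for age in cfg.ages:
            for rep in range(1, cfg.replicates_per_condition + 1):
                bait_purif = f"{ab.value}_{age.value}_r{rep}_BAIT"
                ctrl_purif = f"{ab.value}_{age.value}_r{rep}_CTRL"
                for prey in true_ids:
                    detected = rng.random() < cfg.true_detection_prob
                    b = _draw_counts(rng, lam_true, cfg) if detected else 0
                    c = _draw_counts(rng, cfg.lambda_bg, cfg)
                    emit(prey, bait_purif, ab, age, rep, Channel.BAIT, b)
                    emit(prey, ctrl_purif, ab, age, rep, Channel.CONTROL, c)
                for prey in bg_ids:
                    b = _draw_counts(rng, cfg.lambda_bg, cfg)
                    c = _draw_counts(rng, cfg.lambda_bg, cfg)
                    emit(prey, bait_purif, ab, age, rep, Channel.BAIT, b)
                    emit(prey, ctrl_purif, ab, age, rep, Channel.CONTROL, c)
                for prey in cont_ids:
                    if rng.random() < cfg.contaminant_frequency:
                        b = _draw_counts(rng, lam_cont, cfg)
                        c = _draw_counts(rng, lam_cont, cfg)
                        emit(prey, bait_purif, ab, age, rep, Channel.BAIT, b)
                        emit(prey, ctrl_purif, ab, age, rep, Channel.CONTROL, c)

    truth = GroundTruth(
        true_ids=frozenset(true_ids),
        background_ids=frozenset(bg_ids),
        contaminant_ids=frozenset(cont_ids),
        bait_lambda=bait_lambda,
        single_peptide_ids=single_ids,
        contaminant_frequency={p: cfg.contaminant_frequency for p in cont_ids},
        family_map={p: p for p in all_ids},
    )
    return observations, truth


def simulate_iv_curve(
    e_gaba: float,
    conductance: float,
    potentials: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[IVPoint]:
    """amplitude = conductance * (V - e_gaba) + Gaussian(0, noise_sd)."""
    if len(potentials) < 3:
        raise ValidationError("need at least 3 holding potentials")
    rng = np.random.default_rng(seed)
    points = []
    for v in potentials:
        amp = conductance * (v - e_gaba)
        if noise_sd > 0:
            amp += rng.normal(0.0, noise_sd)
        points.append(IVPoint(holding_potential=float(v), peak_amplitude=float(amp)))
    return points
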