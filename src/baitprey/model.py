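"""Domain types for bait-prey AP-MS interactome construction.

The pipeline operates on spectral-count observations from affinity
purifications of a bait protein (here the neuronal K+/Cl- cotransporter
KCC2) against matched IgG/IgY controls, across multiple antibody epitopes,
developmental ages and replicates. Types are plain frozen dataclasses; all
validation happens in ``__post_init__`` so that an instance, once built, is
known to satisfy its invariants.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Antibody(enum.Enum):
    """Epitope used for the affinity purification."""

    C_TERM = "C_TERM"
    N_TERM_KCC2B = "N_TERM_KCC2B"
    PS940 = "PS940"


class Age(enum.Enum):
    """Developmental age of the brain lysate."""

    P5 = "P5"
    P50 = "P50"


class Channel(enum.Enum):
    """Purification channel: bait antibody vs. pre-immune IgG/IgY control."""

    BAIT = "BAIT"
    CONTROL = "CONTROL"


class Provenance(enum.Enum):
    SCREEN = "SCREEN"
    LITERATURE = "LITERATURE"


class Tier(enum.Enum):
    PLATINUM = "PLATINUM"
    GOLD = "GOLD"
    SILVER = "SILVER"
    BRONZE = "BRONZE"
    NA_LITERATURE = "NA_LITERATURE"


class RescueReason(enum.Enum):
    NONE = "NONE"
    LITERATURE_VALIDATED = "LITERATURE_VALIDATED"
    FAMILY_IN_FIRST_PASS = "FAMILY_IN_FIRST_PASS"
    MULTI_EXPERIMENT = "MULTI_EXPERIMENT"


class SynapseCategory(enum.Enum):
    EXCITATORY_ONLY = "EXCITATORY_ONLY"
    INHIBITORY_ONLY = "INHIBITORY_ONLY"
    BOTH = "BOTH"
    NEITHER = "NEITHER"


class DevelopmentalCategory(enum.Enum):
    P5_ONLY = "P5_ONLY"
    P50_ONLY = "P50_ONLY"
    SHARED = "SHARED"


class ValidationError(ValueError):
    """A record or configuration violates a documented invariant."""


class ConfigurationError(ValueError):
    """An input file or config is structurally unusable (e.g. missing column)."""


class IntegrityError(ValueError):
    """A packaged fixture fails its structural invariants."""


# UniProt accessions of the two bait isoform rows (KCC2a, KCC2b).
BAIT_ACCESSIONS = frozenset({"Q91V14-1", "Q91V14-2"})


@dataclass(frozen=True)
class PreyObservation:
    """One prey protein's counts within one purification (bait or control)."""

    prey_id: str
    gene_symbol: str
    purification_id: str
    antibody: Antibody
    age: Age
    replicate: int
    channel: Channel
    spectral_count: int
    unique_peptides: int
    protein_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.unique_peptides < 0 or self.spectral_count < 0:
            raise ValidationError(
                f"negative count for prey {self.prey_id!r}: "
                f"spectral_count={self.spectral_count}, "
                f"unique_peptides={self.unique_peptides}"
            )
        if self.spectral_count < self.unique_peptides:
            raise ValidationError(
                f"prey {self.prey_id!r}: spectral_count ({self.spectral_count}) "
                f"< unique_peptides ({self.unique_peptides})"
            )
        if self.protein_length is not None and self.protein_length < 1:
            raise ValidationError(
                f"prey {self.prey_id!r}: protein_length must be positive"
            )


@dataclass(frozen=True)
class Table1Row:
    """A row of the packaged screen-hit fixture.

    ``spectral_ratio`` is the printed bait/control fold enrichment; ``maxp``
    the SAINT-style maximum posterior across replicate purifications; the
    boolean flags record excitatory/inhibitory synapse-proteome membership,
    presence at each developmental age, and recovery with the
    phospho-Ser940-directed antibody.
    """

    gene_symbol: str
    uniprot_id: str
    spectral_ratio: float
    maxp: float
    es: bool
    is_flag: bool
    p5: bool
    p50: bool
    ps940: bool
    starred: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.maxp <= 1.0):
            raise ValidationError(
                f"{self.gene_symbol}: maxp {self.maxp} outside [0, 1]"
            )
        if self.spectral_ratio <= 0:
            raise ValidationError(
                f"{self.gene_symbol}: spectral_ratio must be > 0"
            )

    @property
    def is_bait(self) -> bool:
        return self.uniprot_id in BAIT_ACCESSIONS


@dataclass(frozen=True)
class ProteinList:
    """A named protein set, optionally with per-member observation frequency
    (as in contaminant-repository exports)."""

    name: str
    members: frozenset[str]
    frequency: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.frequency is not None:
            extra = set(self.frequency) - set(self.members)
            if extra:
                raise ValidationError(
                    f"list {self.name!r}: frequency keys not in members: "
                    f"{sorted(extra)}"
                )
            for m, f in self.frequency.items():
                if not (0.0 <= f <= 1.0):
                    raise ValidationError(
                        f"list {self.name!r}: frequency[{m!r}]={f} outside [0, 1]"
                    )

    def __contains__(self, item: str) -> bool:
        return _norm(item) in {_norm(m) for m in self.members}


def _norm(identifier: str) -> str:
    """Case-insensitive identity key for symbol/accession comparisons."""
    return identifier.strip().upper()


@dataclass(frozen=True)
class SynapseProteomeCollection:
    """Named excitatory- and inhibitory-synapse-enriched protein sets."""

    excitatory_sets: Mapping[str, ProteinList]
    inhibitory_sets: Mapping[str, ProteinList]

    def __post_init__(self) -> None:
        dup = set(self.excitatory_sets) & set(self.inhibitory_sets)
        if dup:
            raise ValidationError(f"set names used on both sides: {sorted(dup)}")

    def in_excitatory(self, identifier: str) -> bool:
        return any(identifier in s for s in self.excitatory_sets.values())

    def in_inhibitory(self, identifier: str) -> bool:
        return any(identifier in s for s in self.inhibitory_sets.values())


@dataclass(frozen=True)
class EnrichmentProfile:
    """Per-prey aggregate over all purifications of one experiment."""

    prey_id: str
    gene_symbol: str
    fold_ratio: float
    unique_peptides_max: int
    psm_total_bait: int
    psm_total_control: int
    replicate_presence: int
    conditions_seen: frozenset[tuple[Antibody, Age]]
    maxp: float

    def __post_init__(self) -> None:
        if self.fold_ratio <= 0:
            raise ValidationError(f"{self.prey_id}: fold_ratio must be > 0")
        if not (0.0 <= self.maxp <= 1.0):
            raise ValidationError(f"{self.prey_id}: maxp outside [0, 1]")

    @property
    def ages_seen(self) -> frozenset[Age]:
        return frozenset(age for _, age in self.conditions_seen)


@dataclass(frozen=True)
class ScoreModelParams:
    """Two-component Poisson mixture behind the simplified MaxP score.

    A replicate bait count is modelled as Poisson(lambda_bg) under the
    background hypothesis and Poisson(enrichment_factor * lambda_bg) under
    the true-interaction hypothesis, mixed with prior weight ``prior_true``.
    """

    prior_true: float = 0.5
    lambda_bg: float = 1.0
    enrichment_factor: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_true < 1.0):
            raise ValidationError("prior_true must lie in (0, 1)")
        if self.lambda_bg <= 0:
            raise ValidationError(
                "lambda_bg must be > 0 (estimate the background with a floor)"
            )
        if self.enrichment_factor <= 1:
            raise ValidationError("enrichment_factor must exceed 1")

    @property
    def lambda_true(self) -> float:
        return self.enrichment_factor * self.lambda_bg


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for candidate filtering and confidence tiering."""

    min_unique_peptides: int = 2
    first_pass_fold: float = 1.5
    contaminant_frequency_threshold: float = 0.5
    platinum_min_replicates: int = 2
    high_fold: float = 5.0
    high_maxp: float = 0.89
    silver_fold_low: float = 3.0
    silver_maxp_low: float = 0.7
    bronze_fold_low: float = 1.5

    def __post_init__(self) -> None:
        if not (self.bronze_fold_low <= self.silver_fold_low <= self.high_fold):
            raise ValidationError(
                "require bronze_fold_low <= silver_fold_low <= high_fold"
            )
        if self.silver_maxp_low > self.high_maxp:
            raise ValidationError("require silver_maxp_low <= high_maxp")


@dataclass(frozen=True)
class AnnotationFlags:
    es: bool = False
    is_flag: bool = False
    p5: bool = False
    p50: bool = False
    ps940: bool = False


@dataclass(frozen=True)
class InteractomeMember:
    """A protein admitted to the interactome, with provenance and tier."""

    prey_id: str
    gene_symbol: str
    provenance: Provenance
    tier: Tier
    fold_ratio: Optional[float] = None
    maxp: Optional[float] = None
    replicate_presence: Optional[int] = None
    rescue_reason: RescueReason = RescueReason.NONE
    flags: AnnotationFlags = field(default_factory=AnnotationFlags)

    def __post_init__(self) -> None:
        if self.provenance is Provenance.LITERATURE:
            if self.tier is not Tier.NA_LITERATURE:
                raise ValidationError(
                    f"{self.prey_id}: literature members carry tier NA_LITERATURE"
                )
        elif self.tier is Tier.NA_LITERATURE:
            raise ValidationError(
                f"{self.prey_id}: screen members need a real confidence tier"
            )

    @property
    def identity(self) -> str:
        """Resolution key: accession when available, else gene symbol."""
        return _norm(self.prey_id or self.gene_symbol)


@dataclass(frozen=True)
class GroupSummary:
    """(mean, SEM, n) triple as printed in a results text or figure legend."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValidationError("sem must be > 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValidationError("p must lie in (0, 1]")


@dataclass(frozen=True)
class IVPoint:
    """One point of a current-voltage curve: holding potential (mV) vs.
    signed peak IPSC amplitude (pA)."""

    holding_potential: float
    peak_amplitude: float
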