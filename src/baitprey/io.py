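"""Readers and writers for every external table the pipeline touches.

All formats are delimited text (TSV by default, CSV via ``dialect="csv"``)
with mandatory headers. The screen-hit fixture and the synthetic
literature-partner list ship inside the package under ``baitprey/data``.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import (
    Age,
    Antibody,
    BAIT_ACCESSIONS,
    Channel,
    ConfigurationError,
    IntegrityError,
    InteractomeMember,
    PreyObservation,
    ProteinList,
    Table1Row,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_COUNT_COLUMNS = [
    "prey_id",
    "gene_symbol",
    "purification_id",
    "antibody",
    "age",
    "replicate",
    "channel",
    "spectral_count",
    "unique_peptides",
]

TABLE1_RESOURCE = "table1_kcc2_partners.tsv"
LITERATURE_RESOURCE = "literature_partners_synthetic.tsv"


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ConfigurationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def read_count_table(path: PathLike, dialect: str = "tsv") -> list[PreyObservation]:
    """Read a long-format bait/control spectral-count table.

    One row per prey x purification. Raises :class:`ConfigurationError`
    naming any missing required column, and :class:`ValidationError` with the
    offending row number for malformed rows.
    """
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, comment="#")
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    observations: list[PreyObservation] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            length = getattr(row, "protein_length", None)
            if length is not None and pd.isna(length):
                length = None
            obs = PreyObservation(
                prey_id=str(row.prey_id),
                gene_symbol=str(row.gene_symbol),
                purification_id=str(row.purification_id),
                antibody=Antibody(row.antibody),
                age=Age(row.age),
                replicate=int(row.replicate),
                channel=Channel(row.channel),
                spectral_count=int(row.spectral_count),
                unique_peptides=int(row.unique_peptides),
                protein_length=None if length is None else int(length),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        key = (obs.purification_id, obs.prey_id)
        if key in seen:
            raise ValidationError(
                f"{path}: row {i}: duplicate (purification_id, prey_id) pair {key}"
            )
        seen.add(key)
        observations.append(obs)
    return observations


def write_count_table(
    observations: Iterable[PreyObservation], path: PathLike, dialect: str = "tsv"
) -> None:
    """Round-trippable inverse of :func:`read_count_table`."""
    rows = []
    for o in observations:
        rows.append(
            {
                "prey_id": o.prey_id,
                "gene_symbol": o.gene_symbol,
                "purification_id": o.purification_id,
                "antibody": o.antibody.value,
                "age": o.age.value,
                "replicate": o.replicate,
                "channel": o.channel.value,
                "spectral_count": o.spectral_count,
                "unique_peptides": o.unique_peptides,
                "protein_length": o.protein_length,
            }
        )
    df = pd.DataFrame(rows, columns=_COUNT_COLUMNS + ["protein_length"])
    df["protein_length"] = df["protein_length"].astype("Int64")
    df.to_csv(path, sep=_sep(dialect), index=False)


def _parse_table1_frame(df: pd.DataFrame) -> list[Table1Row]:
    # "is" is a keyword, which itertuples would mangle
    df = df.rename(columns={"is": "is_"})
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            Table1Row(
                gene_symbol=str(r.gene_symbol),
                uniprot_id=str(r.uniprot_id),
                spectral_ratio=float(r.spectral_ratio),
                maxp=float(r.maxp),
                es=str(r.es) == "X",
                is_flag=str(r.is_) == "X",
                p5=str(r.p5) == "X",
                p50=str(r.p50) == "X",
                ps940=str(r.ps940) == "X",
                starred=str(r.starred) == "X",
            )
        )
    return rows


def read_table1_fixture() -> list[Table1Row]:
    """Load the packaged screen-hit table (bait rows included, flagged).

    Enforces the structural invariants of the transcription: exactly two bait
    rows (the KCC2a/KCC2b isoform accessions), valid score/ratio ranges, and
    at least one age flag on every prey row. Raises :class:`IntegrityError`
    if the shipped fixture is damaged.
    """
    ref = resources.files("baitprey.data") / TABLE1_RESOURCE
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    try:
        rows = _parse_table1_frame(df)
    except ValidationError as exc:
        raise IntegrityError(f"fixture row invalid: {exc}") from exc
    n_bait = sum(r.is_bait for r in rows)
    if n_bait != 2:
        raise IntegrityError(f"fixture must contain exactly 2 bait rows, got {n_bait}")
    if {r.uniprot_id for r in rows if r.is_bait} != set(BAIT_ACCESSIONS):
        raise IntegrityError("bait accessions must be Q91V14-1 and Q91V14-2")
    ageless = [r.gene_symbol for r in rows if not r.is_bait and not (r.p5 or r.p50)]
    if ageless:
        raise IntegrityError(f"prey rows without an age flag: {ageless}")
    return rows


def read_protein_list(path: PathLike, name: Optional[str] = None) -> ProteinList:
    """Read a protein list: one member per line, or member<TAB>frequency.

    Lines starting with ``#`` are comments. Members are deduplicated (an
    identical member keeps the last frequency seen). An empty file yields an
    empty list with a logged warning.
    """
    path = Path(path)
    members: set[str] = set()
    frequency: dict[str, float] = {}
    any_freq = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split(",")
            member = parts[0].strip()
            members.add(member)
            if len(parts) > 1 and parts[1].strip():
                try:
                    f = float(parts[1])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}: line {lineno}: bad frequency {parts[1]!r}"
                    ) from exc
                if not (0.0 <= f <= 1.0):
                    raise ValidationError(
                        f"{path}: line {lineno}: frequency {f} outside [0, 1]"
                    )
                frequency[member] = f
                any_freq = True
    if not members:
        logger.warning("protein list %s is empty", path)
    return ProteinList(
        name=name or path.stem,
        members=frozenset(members),
        frequency=frequency if any_freq else None,
    )


def read_literature_partners() -> ProteinList:
    """Packaged synthetic stand-in for the 31 previously established bait
    partners absent from the screen (see the file header for provenance)."""
    ref = resources.files("baitprey.data") / LITERATURE_RESOURCE
    with resources.as_file(ref) as p:
        return read_protein_list(p, name="literature_partners")


def read_family_map(path: PathLike) -> dict[str, str]:
    """Read a two-column member<TAB>family table into a plain dict."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}: line {lineno}: expected member<TAB>family"
                )
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def read_edge_list(path: PathLike, dialect: str = "tsv") -> list[tuple[str, str, Optional[str]]]:
    """Read an undirected edge list: node_a, node_b and optional provenance."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, comment="#")
    for col in ("node_a", "node_b"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing required column(s): {col}")
    has_prov = "provenance" in df.columns
    edges = []
    for r in df.itertuples(index=False):
        prov = getattr(r, "provenance", None) if has_prov else None
        if prov is not None and pd.isna(prov):
            prov = None
        edges.append((str(r.node_a), str(r.node_b), prov))
    return edges


def interactome_to_frame(members: Sequence[InteractomeMember]) -> pd.DataFrame:
    """Flatten members into the pipeline's canonical output table, sorted by
    tier, then descending fold enrichment, then identity."""
    tier_order = {"PLATINUM": 0, "GOLD": 1, "SILVER": 2, "BRONZE": 3, "NA_LITERATURE": 4}
    rows = []
    for m in members:
        rows.append(
            {
                "prey_id": m.prey_id,
                "gene_symbol": m.gene_symbol,
                "provenance": m.provenance.value,
                "tier": m.tier.value,
                "fold_ratio": m.fold_ratio,
                "maxp": m.maxp,
                "replicate_presence": m.replicate_presence,
                "rescue_reason": m.rescue_reason.value,
                "es": m.flags.es,
                "is": m.flags.is_flag,
                "p5": m.flags.p5,
                "p50": m.flags.p50,
                "ps940": m.flags.ps940,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["_tier"] = df["tier"].map(tier_order)
    df["_fold"] = -df["fold_ratio"].fillna(-1.0)
    df = df.sort_values(["_tier", "_fold", "prey_id"], kind="mergesort")
    return df.drop(columns=["_tier", "_fold"]).reset_index(drop=True)


def write_interactome(
    members: Sequence[InteractomeMember], path: PathLike, dialect: str = "tsv"
) -> None:
    interactome_to_frame(members).to_csv(path, sep=_sep(dialect), index=False)
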