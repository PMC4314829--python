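"""Homolog screening, filtering, classification and library summary.

The screen emulates, at toy scale, a genome data-mining campaign for
dehydroquinate dehydratase (DHQase, EC 4.2.1.10) genes: each proteome is
scored against a type I and a type II seed sequence by local alignment,
candidate hits are kept at an E-value threshold (default 1e-10), genomes
from redundant species are removed, genomes lacking a complete seven-step
shikimate pathway are removed, and each retained protein is classified to
the seed type with the smaller E-value.  The summary mirrors the standard
"distribution of type I and type II" table: bacterial genomes partitioned
into type-I-only / type-II-only / both, archaeal genomes counted apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import DEFAULT_SCHEME, ScoringScheme, estimate_evalue, global_alignment_map, score_local_alignment
from .errors import ConfigurationError, InputError
from .records import GenomeFixture, ProteinRecord

DEFAULT_EVALUE_THRESHOLD = 1e-10


@dataclass(frozen=True)
class ScreenHit:
    """One protein passing the seed screen."""

    record_id: str
    seed_type: str  # "I" or "II"
    score: int
    evalue: float

    def __post_init__(self) -> None:
        if self.score < 0 or self.evalue < 0:
            raise InputError("hit score and E-value must be non-negative")


def screen_proteome(
    genome: GenomeFixture,
    seeds: Mapping[str, ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[ScreenHit]:
    """Score every protein of *genome* against each seed; keep E <= threshold.

    E-values use m = seed length and n = total residue count of the proteome
    (the searched database).  Each record is reported at most once per seed
    type.
    """
    if not seeds:
        raise ConfigurationError("empty seed set")
    if threshold <= 0:
        raise ConfigurationError("E-value threshold must be positive")
    n_database = sum(len(r) for r in genome.records)
    hits: list[ScreenHit] = []
    for record in genome.records:
        for seed_type in sorted(seeds):
            seed = seeds[seed_type]
            score = score_local_alignment(seed.sequence, record.sequence, scheme)
            evalue = estimate_evalue(score, len(seed), n_database, scheme)
            if evalue <= threshold:
                hits.append(ScreenHit(record.id, seed_type, score, evalue))
    return hits


def filter_pathway_complete(genomes: Iterable[GenomeFixture]) -> list[GenomeFixture]:
    """Keep only genomes annotated with all seven shikimate-pathway steps."""
    return [g for g in genomes if g.pathway_complete]


def dedupe_species(
    hits: Sequence[tuple[GenomeFixture, ScreenHit]],
) -> list[tuple[GenomeFixture, ScreenHit]]:
    """Drop hits from redundant genomes of the same species.

    For each species string, the genome with the lexicographically smallest
    ``genome_id`` survives (deterministic tie-break); all hits from other
    genomes of that species are removed.
    """
    keeper: dict[str, str] = {}
    for genome, _hit in hits:
        cur = keeper.get(genome.species)
        if cur is None or genome.genome_id < cur:
            keeper[genome.species] = genome.genome_id
    return [
        (genome, hit)
        for genome, hit in hits
        if keeper[genome.species] == genome.genome_id
    ]


def dedupe_genomes(genomes: Iterable[GenomeFixture]) -> list[GenomeFixture]:
    """Species-level de-duplication of whole genomes (same rule as above)."""
    best: dict[str, GenomeFixture] = {}
    for genome in genomes:
        cur = best.get(genome.species)
        if cur is None or genome.genome_id < cur.genome_id:
            best[genome.species] = genome
    return sorted(best.values(), key=lambda g: g.genome_id)


def classify_type(
    record: ProteinRecord,
    seeds: Mapping[str, ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> str:
    """Assign "I", "II" or "none" by the seed with the smaller E-value.

    Ties resolve to type II, the dominant class among prokaryotic DHQases;
    "none" when neither seed passes the threshold.
    """
    if not seeds:
        raise ConfigurationError("empty seed set")
    evalues: dict[str, float] = {}
    for seed_type, seed in seeds.items():
        score = score_local_alignment(seed.sequence, record.sequence, scheme)
        evalues[seed_type] = estimate_evalue(score, len(seed), len(record), scheme)
    passing = {t: e for t, e in evalues.items() if e <= threshold}
    if not passing:
        return "none"
    best = min(passing.values())
    winners = sorted(t for t, e in passing.items() if e == best)
    return "II" if "II" in winners else winners[0]


@dataclass(frozen=True)
class DistributionSummary:
    """Type I/II counts and the percentages derived from them.

    Genome percentages are taken over the bacterial genome total; sequence
    percentages over the bacterial sequence total (total minus archaeal).
    All percentages are reported to one decimal.
    """

    n_genomes_typeI_only: int
    n_genomes_typeII_only: int
    n_genomes_both: int
    n_genomes_archaeal: int
    n_sequences_total: int
    n_type_I: int
    n_type_II: int
    n_archaeal_type_I: int

    def __post_init__(self) -> None:
        if self.n_type_I + self.n_type_II != self.n_sequences_total:
            raise InputError(
                "type I + type II sequence counts must equal the total"
            )

    @property
    def n_genomes_bacterial(self) -> int:
        return (
            self.n_genomes_typeI_only
            + self.n_genomes_typeII_only
            + self.n_genomes_both
        )

    @property
    def pct_genomes_typeI_only(self) -> float:
        return round(100.0 * self.n_genomes_typeI_only / self.n_genomes_bacterial, 1)

    @property
    def pct_genomes_typeII_only(self) -> float:
        return round(100.0 * self.n_genomes_typeII_only / self.n_genomes_bacterial, 1)

    @property
    def pct_genomes_both(self) -> float:
        return round(100.0 * self.n_genomes_both / self.n_genomes_bacterial, 1)

    @property
    def n_bacterial_sequences(self) -> int:
        return self.n_sequences_total - self.n_archaeal_type_I

    @property
    def pct_bacterial_type_II(self) -> float:
        return round(100.0 * self.n_type_II / self.n_bacterial_sequences, 1)

    @property
    def pct_bacterial_type_I(self) -> float:
        n_bact_I = self.n_type_I - self.n_archaeal_type_I
        return round(100.0 * n_bact_I / self.n_bacterial_sequences, 1)

    def to_dict(self) -> dict[str, float]:
        return {
            "n_genomes_typeI_only": self.n_genomes_typeI_only,
            "n_genomes_typeII_only": self.n_genomes_typeII_only,
            "n_genomes_both": self.n_genomes_both,
            "n_genomes_archaeal": self.n_genomes_archaeal,
            "n_sequences_total": self.n_sequences_total,
            "n_type_I": self.n_type_I,
            "n_type_II": self.n_type_II,
            "n_archaeal_type_I": self.n_archaeal_type_I,
            "pct_genomes_typeI_only": self.pct_genomes_typeI_only,
            "pct_genomes_typeII_only": self.pct_genomes_typeII_only,
            "pct_genomes_both": self.pct_genomes_both,
            "pct_bacterial_type_I": self.pct_bacterial_type_I,
            "pct_bacterial_type_II": self.pct_bacterial_type_II,
        }


def summary_from_counts(
    typeI_only: int,
    typeII_only: int,
    both: int,
    archaeal: int,
    n_sequences_total: int | None = None,
    n_type_I: int | None = None,
    n_type_II: int | None = None,
    n_archaeal_type_I: int | None = None,
) -> DistributionSummary:
    """Build a :class:`DistributionSummary` directly from tabulated counts.

    When sequence counts are omitted they default to one type I sequence per
    type-I-carrying genome and one type II per type-II-carrying genome.
    """
    if n_type_I is None:
        n_type_I = typeI_only + both + archaeal
    if n_type_II is None:
        n_type_II = typeII_only + both
    if n_sequences_total is None:
        n_sequences_total = n_type_I + n_type_II
    if n_archaeal_type_I is None:
        n_archaeal_type_I = archaeal
    return DistributionSummary(
        n_genomes_typeI_only=typeI_only,
        n_genomes_typeII_only=typeII_only,
        n_genomes_both=both,
        n_genomes_archaeal=archaeal,
        n_sequences_total=n_sequences_total,
        n_type_I=n_type_I,
        n_type_II=n_type_II,
        n_archaeal_type_I=n_archaeal_type_I,
    )


def summarize_distribution(
    classified: Sequence[tuple[GenomeFixture, Mapping[str, str] | Iterable[str]]],
) -> DistributionSummary:
    """Tabulate per-genome classifications into a distribution summary.

    *classified* pairs each genome with the classifications of its records,
    either as a mapping ``record_id -> type`` or as a plain iterable of
    types ("I", "II", "none").  Genomes without any classified DHQase are
    ignored; archaeal genomes are tallied separately.
    """
    if not classified:
        raise InputError("cannot summarize an empty classification set")
    typeI_only = typeII_only = both = archaeal_genomes = 0
    n_type_I = n_type_II = n_archaeal_type_I = 0
    for genome, types in classified:
        if isinstance(types, Mapping):
            types = list(types.values())
        else:
            types = list(types)
        n_I = sum(1 for t in types if t == "I")
        n_II = sum(1 for t in types if t == "II")
        if n_I + n_II == 0:
            continue
        n_type_I += n_I
        n_type_II += n_II
        if genome.domain == "Archaea":
            archaeal_genomes += 1
            n_archaeal_type_I += n_I
        elif n_I and n_II:
            both += 1
        elif n_I:
            typeI_only += 1
        else:
            typeII_only += 1
    return DistributionSummary(
        n_genomes_typeI_only=typeI_only,
        n_genomes_typeII_only=typeII_only,
        n_genomes_both=both,
        n_genomes_archaeal=archaeal_genomes,
        n_sequences_total=n_type_I + n_type_II,
        n_type_I=n_type_I,
        n_type_II=n_type_II,
        n_archaeal_type_I=n_archaeal_type_I,
    )


def residue_audit(
    records: Iterable[ProteinRecord],
    reference: ProteinRecord,
    positions: Sequence[int],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict[str, dict[int, str]]:
    """Report the residue of each record aligned to reference positions.

    Positions are 1-based indices into the reference sequence (the
    convention of active-site annotations such as Tyr24/His101 of type II
    DHQases).  Each record is globally aligned to the reference; a position
    aligned to a gap reports ``"-"``.
    """
    for pos in positions:
        if not 1 <= pos <= len(reference.sequence):
            raise InputError(
                f"position {pos} outside reference of length {len(reference.sequence)}"
            )
    audit: dict[str, dict[int, str]] = {}
    for record in records:
        mapping = global_alignment_map(reference.sequence, record.sequence, scheme)
        audit[record.id] = {pos: mapping[pos - 1] for pos in positions}
    return audit


def mine_cohort(
    genomes: Iterable[GenomeFixture],
    seeds: Mapping[str, ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> tuple[pd.DataFrame, DistributionSummary]:
    """Full pipeline: pathway filter -> species dedupe -> screen -> classify.

    Returns the per-hit table (record_id, species, seed_type, score, evalue,
    classification) and the distribution summary over genomes with hits.
    """
    kept = dedupe_genomes(filter_pathway_complete(genomes))
    rows: list[dict] = []
    classified: list[tuple[GenomeFixture, dict[str, str]]] = []
    for genome in kept:
        hits = screen_proteome(genome, seeds, scheme, threshold)
        by_record: dict[str, dict[str, ScreenHit]] = {}
        for hit in hits:
            by_record.setdefault(hit.record_id, {})[hit.seed_type] = hit
        genome_classes: dict[str, str] = {}
        for record_id, seed_hits in sorted(by_record.items()):
            best_type = min(
                seed_hits, key=lambda t: (seed_hits[t].evalue, t != "II")
            )
            genome_classes[record_id] = best_type
            for seed_type, hit in sorted(seed_hits.items()):
                rows.append(
                    {
                        "record_id": record_id,
                        "species": genome.species,
                        "seed_type": seed_type,
                        "score": hit.score,
                        "evalue": hit.evalue,
                        "classification": best_type,
                    }
                )
        if genome_classes:
            classified.append((genome, genome_classes))
    table = pd.DataFrame(
        rows,
        columns=["record_id", "species", "seed_type", "score", "evalue", "classification"],
    )
    summary = summarize_distribution(classified) if classified else None
    return table, summary


def write_hits_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
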