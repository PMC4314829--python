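"""Protein records, genome fixtures and their FASTA serialization.

A proteome FASTA header carries structured metadata as ``key=value`` tokens
after the record id, e.g.::

    >WP_000001 species=Escherichia_coli domain=Bacteria phylum=Proteobacteria pathway=1-7

Spaces inside a value are written as underscores; the ``pathway`` token lists
the shikimate-pathway steps annotated in the source genome as comma-separated
numbers or ranges (``1-7``, ``1,2,5``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

#: The 20 standard residues plus X (unknown).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: The seven catalytic steps of the shikimate pathway.
PATHWAY_STEPS = frozenset(f"step{i}" for i in range(1, 8))


def validate_protein_sequence(sequence: str, context: str = "sequence") -> None:
    """Raise :class:`InputError` if *sequence* is empty or has a bad residue."""
    if not sequence:
        raise InputError(f"{context}: empty protein sequence")
    for i, ch in enumerate(sequence):
        if ch not in PROTEIN_ALPHABET:
            raise InputError(
                f"{context}: invalid residue {ch!r} at position {i + 1}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with taxonomy metadata, the unit of screening."""

    id: str
    species: str
    domain: str  # "Bacteria" or "Archaea"
    phylum: str
    sequence: str

    def __post_init__(self) -> None:
        validate_protein_sequence(self.sequence, context=self.id or "record")
        if self.domain not in ("Bacteria", "Archaea"):
            raise InputError(
                f"{self.id}: domain must be Bacteria or Archaea, got {self.domain!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeFixture:
    """A toy genome: its proteins plus the annotated shikimate-pathway steps."""

    species: str
    records: list[ProteinRecord] = field(default_factory=list)
    pathway_genes: frozenset[str] = frozenset()
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.pathway_genes = frozenset(self.pathway_genes)
        bad = self.pathway_genes - PATHWAY_STEPS
        if bad:
            raise InputError(f"unknown pathway step labels: {sorted(bad)}")
        if not self.genome_id:
            self.genome_id = self.species.replace(" ", "_")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise InputError(f"{self.genome_id}: duplicate record ids")

    @property
    def pathway_complete(self) -> bool:
        return self.pathway_genes == PATHWAY_STEPS

    @property
    def domain(self) -> str:
        return self.records[0].domain if self.records else "Bacteria"


def _format_pathway(steps: frozenset[str]) -> str:
    nums = sorted(int(s[4:]) for s in steps)
    # collapse runs into ranges for readability
    parts: list[str] = []
    i = 0
    while i < len(nums):
        j = i
        while j + 1 < len(nums) and nums[j + 1] == nums[j] + 1:
            j += 1
        parts.append(str(nums[i]) if i == j else f"{nums[i]}-{nums[j]}")
        i = j + 1
    return ",".join(parts)


def _parse_pathway(token: str) -> frozenset[str]:
    steps: set[str] = set()
    if not token:
        return frozenset()
    for part in token.split(","):
        if "-" in part:
            lo, hi = part.split("-")
            steps.update(f"step{i}" for i in range(int(lo), int(hi) + 1))
        else:
            steps.add(f"step{int(part)}")
    return frozenset(steps)


def write_proteome_fasta(genome: GenomeFixture, path: str | Path) -> None:
    """Write one genome's proteins to FASTA with metadata header tokens."""
    records = []
    pathway = _format_pathway(genome.pathway_genes)
    for rec in genome.records:
        desc = (
            f"species={rec.species.replace(' ', '_')} "
            f"domain={rec.domain} phylum={rec.phylum.replace(' ', '_')}"
        )
        if pathway:
            desc += f" pathway={pathway}"
        records.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_proteome_fasta(path: str | Path) -> GenomeFixture:
    """Read one genome written by :func:`write_proteome_fasta`."""
    records: list[ProteinRecord] = []
    pathway: frozenset[str] = frozenset()
    species = ""
    for sr in SeqIO.parse(str(path), "fasta"):
        meta = {}
        for token in sr.description.split()[1:]:
            if "=" in token:
                key, _, val = token.partition("=")
                meta[key] = val
        rec_species = meta.get("species", "").replace("_", " ")
        records.append(
            ProteinRecord(
                id=sr.id,
                species=rec_species,
                domain=meta.get("domain", "Bacteria"),
                phylum=meta.get("phylum", "").replace("_", " "),
                sequence=str(sr.seq).upper(),
            )
        )
        if "pathway" in meta:
            pathway = _parse_pathway(meta["pathway"])
        species = species or rec_species
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return GenomeFixture(
        species=species,
        records=records,
        pathway_genes=pathway,
        genome_id=Path(path).stem,
    )


def read_seed_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read seed sequences keyed by DHQase type.

    The header must carry a ``type=I`` or ``type=II`` token; other metadata
    tokens are optional.
    """
    seeds: dict[str, ProteinRecord] = {}
    for sr in SeqIO.parse(str(path), "fasta"):
        meta = {}
        for token in sr.description.split()[1:]:
            if "=" in token:
                key, _, val = token.partition("=")
                meta[key] = val
        seed_type = meta.get("type")
        if seed_type not in ("I", "II"):
            raise InputError(
                f"{path}: seed {sr.id} must carry a type=I or type=II token"
            )
        seeds[seed_type] = ProteinRecord(
            id=sr.id,
            species=meta.get("species", "").replace("_", " "),
            domain=meta.get("domain", "Bacteria"),
            phylum=meta.get("phylum", "").replace("_", " "),
            sequence=str(sr.seq).upper(),
        )
    if not seeds:
        raise InputError(f"{path}: no seed records found")
    return seeds


def write_seed_fasta(seeds: dict[str, ProteinRecord], path: str | Path) -> None:
    records = []
    for seed_type, rec in sorted(seeds.items()):
        desc = f"type={seed_type} species={rec.species.replace(' ', '_')} domain={rec.domain}"
        records.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def iter_proteomes(directory: str | Path) -> Iterator[GenomeFixture]:
    """Yield genomes from every ``.fasta``/``.fa`` file in *directory*."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".fasta", ".fa", ".faa")
    )
    for p in paths:
        yield read_proteome_fasta(p)
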