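"""Synthetic inputs: toy proteomes with planted homologs, mock usage
tables, simulated plate reads, and the packaged library tables.

Every generator is a pure function of its seed and spec, so outputs are
byte-identical across runs.  The toy cohort emulates the composition of a
prokaryote-wide DHQase survey: bacterial genomes carrying a type I
homolog, a type II homolog or both, plus archaeal genomes (type I only),
diluted with unrelated random decoy proteins.  Sequence realism is
deliberately minimal — decoys are i.i.d. uniform over residues and
homologs differ from the seeds by point substitution only.

The seed sequences shipped here are synthetic stand-ins (random sequences
with the canonical type II active-site residues Tyr24 and His101 planted),
not database entries.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .codon import CodonUsageTable
from .errors import ConfigurationError, InputError, PackagingError
from .kinetics import AssayConfig, ProgressCurve, michaelis_menten_rate
from .records import PATHWAY_STEPS, GenomeFixture, ProteinRecord

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: sha256 of every packaged CSV, checked on load.
_FIXTURE_CHECKSUMS = {
    "table1_genome_counts.csv": "471f74c93437f831bdbdd5e6db352de7baed121777540b096a97deaea1b554bb",
    "table1_sequence_counts.csv": "5dbc7a91cadbad08e7b58c007ac0e423c5cdf2abc6c8591051df6205481f49d3",
    "table2_library.csv": "b9bc0cf8acd186e7ea8d78f5d26abaff9737afe96ef9b73a5b08173340557ba6",
    "table3_kinetics.csv": "b6c8246d330ef6bff7d1f3097abb9c91b1cf3b777be5970b6c41a4b0b6a303ab",
    "usage_ecoli_synthetic.csv": "7e4e4f527910817c61e65558aa32bf31a600d422de947b5e03258ec3965275e8",
    "usage_cglutamicum_synthetic.csv": "b8bd95b66c2c19df15cc2b831f558f0d4471acf46458cd244428ea8c64423d5e",
}


def _fixture_path(name: str) -> Path:
    path = resources.files("dhqforge").joinpath("data", name)
    with resources.as_file(path) as p:
        data = p.read_bytes()
        digest = hashlib.sha256(data).hexdigest()
        if digest != _FIXTURE_CHECKSUMS[name]:
            raise PackagingError(f"fixture {name} failed its checksum")
        return Path(p)


# ---------------------------------------------------------------------------
# synthetic seed proteins
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_RESIDUES), size=length))


def synthetic_seeds() -> dict[str, ProteinRecord]:
    """Deterministic synthetic seed pair for the homolog screen.

    Type II: 150 aa with Tyr at position 24 and His at position 101
    (1-based), mirroring the conserved catalytic pair of type II DHQases.
    Type I: 252 aa.  Both are random sequences, not database entries.
    """
    rng = np.random.default_rng(20150201)
    type2 = list(_random_protein(rng, 150))
    type2[23] = "Y"
    type2[100] = "H"
    type1 = _random_protein(rng, 252)
    return {
        "I": ProteinRecord(
            id="SYN_DHQ1_SEED",
            species="Escherichia coli",
            domain="Bacteria",
            phylum="Proteobacteria",
            sequence=type1,
        ),
        "II": ProteinRecord(
            id="SYN_DHQ2_SEED",
            species="Corynebacterium glutamicum",
            domain="Bacteria",
            phylum="Actinobacteria",
            sequence="".join(type2),
        ),
    }


def mutate_homolog(
    seed: ProteinRecord, identity: float, rng_seed: int
) -> ProteinRecord:
    """Plant a homolog: substitute floor((1-identity)*len) random positions.

    Each chosen position receives a random residue different from the
    original, so the realized identity equals the target within 1/len.
    """
    if not 0 < identity <= 1:
        raise InputError(f"identity must be in (0, 1], got {identity}")
    rng = np.random.default_rng(rng_seed)
    n_sub = math.floor((1.0 - identity) * len(seed.sequence))
    seq = list(seed.sequence)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for pos in positions:
        alternatives = [r for r in _RESIDUES if r != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return ProteinRecord(
        id=f"{seed.id}_mut{rng_seed}",
        species=seed.species,
        domain=seed.domain,
        phylum=seed.phylum,
        sequence="".join(seq),
    )


# ---------------------------------------------------------------------------
# toy cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a toy genome cohort.

    The four class fractions (bacterial type-I-only / type-II-only / both,
    plus archaeal) must sum to 1; counts are apportioned by largest
    remainder so the planted composition is exact for any cohort size.
    The default homolog identity (0.6) sits inside the 42-72% identity
    band typical of cross-species DHQase homologs.
    """

    n_genomes: int
    homolog_identity: float = 0.6
    fraction_typeI_only: float = 0.153
    fraction_typeII_only: float = 0.783
    fraction_both: float = 0.064
    fraction_archaeal: float = 0.0
    fraction_pathway_complete: float = 1.0
    n_decoys_per_genome: int = 4
    decoy_length: tuple[int, int] = (120, 260)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.fraction_typeI_only
            + self.fraction_typeII_only
            + self.fraction_both
            + self.fraction_archaeal
        )
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class fractions sum to {total}, not 1")
        if not 0 < self.homolog_identity <= 1:
            raise ConfigurationError("homolog_identity must be in (0, 1]")


def _apportion(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n among the given fractions."""
    raw = [n * f for f in fractions]
    counts = [math.floor(x) for x in raw]
    short = n - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


_BACTERIAL_PHYLA = ["Proteobacteria", "Actinobacteria", "Firmicutes"]
_ARCHAEAL_PHYLA = ["Euryarchaeota", "Crenarchaeota", "Thaumarchaeota"]


def gen_cohort(
    spec: CohortSpec, seeds: dict[str, ProteinRecord] | None = None
) -> tuple[list[GenomeFixture], pd.DataFrame]:
    """Generate a toy cohort plus its ground-truth table.

    Each genome carries the planted homolog(s) of its class diluted with
    random decoy proteins; ``fraction_pathway_complete`` of the genomes in
    each class are annotated with all seven shikimate-pathway steps, the
    rest lack a random subset.  The ground-truth table records one row per
    genome: its class, pathway completeness, and planted record ids.
    """
    if seeds is None:
        seeds = synthetic_seeds()
    rng = np.random.default_rng(spec.rng_seed)
    classes = ["typeI_only", "typeII_only", "both", "archaeal"]
    counts = _apportion(
        spec.n_genomes,
        [
            spec.fraction_typeI_only,
            spec.fraction_typeII_only,
            spec.fraction_both,
            spec.fraction_archaeal,
        ],
    )
    genomes: list[GenomeFixture] = []
    truth_rows: list[dict] = []
    idx = 0
    for cls, n_cls in zip(classes, counts):
        n_complete = round(n_cls * spec.fraction_pathway_complete)
        for j in range(n_cls):
            idx += 1
            gid = f"G{idx:04d}"
            domain = "Archaea" if cls == "archaeal" else "Bacteria"
            phyla = _ARCHAEAL_PHYLA if domain == "Archaea" else _BACTERIAL_PHYLA
            phylum = phyla[idx % len(phyla)]
            species = f"Genus{idx:04d} species{idx:04d}"
            complete = j < n_complete
            if complete:
                pathway = PATHWAY_STEPS
            else:
                dropped = rng.choice(sorted(PATHWAY_STEPS), size=1 + rng.integers(3))
                pathway = PATHWAY_STEPS - set(dropped)
            records: list[ProteinRecord] = []
            planted: list[str] = []
            plant_types = {
                "typeI_only": ["I"],
                "typeII_only": ["II"],
                "both": ["I", "II"],
                "archaeal": ["I"],
            }[cls]
            for seed_type in plant_types:
                homolog = mutate_homolog(
                    seeds[seed_type],
                    spec.homolog_identity,
                    rng_seed=int(rng.integers(2**31)),
                )
                rec = ProteinRecord(
                    id=f"{gid}_DHQ{seed_type}",
                    species=species,
                    domain=domain,
                    phylum=phylum,
                    sequence=homolog.sequence,
                )
                records.append(rec)
                planted.append(f"{rec.id}:{seed_type}")
            for d in range(spec.n_decoys_per_genome):
                lo, hi = spec.decoy_length
                length = int(rng.integers(lo, hi + 1))
                records.append(
                    ProteinRecord(
                        id=f"{gid}_P{d:03d}",
                        species=species,
                        domain=domain,
                        phylum=phylum,
                        sequence=_random_protein(rng, length),
                    )
                )
            genomes.append(
                GenomeFixture(
                    species=species,
                    records=records,
                    pathway_genes=pathway,
                    genome_id=gid,
                )
            )
            truth_rows.append(
                {
                    "genome_id": gid,
                    "species": species,
                    "domain": domain,
                    "category": cls,
                    "pathway_complete": complete,
                    "planted": ";".join(planted),
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["genome_id", "species", "domain", "category", "pathway_complete", "planted"],
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# simulated plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateSimSpec:
    """Ground truth and design for a simulated kinetic plate.

    The default 8-point substrate design spans 80-1000 umol/L, the range
    used for dehydratase plate assays.  Substrate depletion is integrated
    explicitly (fixed-step Euler, duration/2000 per step) so the
    initial-rate window rule is genuinely exercised; a design far above
    10*Km adds nothing and triggers a warning.
    """

    Km: float = 300.0
    Vmax: float = 10.0
    substrate_design: tuple[float, ...] = (80, 125, 250, 375, 500, 625, 750, 1000)
    noise_cv: float = 0.01
    n_timepoints: int = 301  # 0.2 s interval: a fast kinetic plate read
    duration: float = 60.0  # seconds
    rng_seed: int = 0
    n_steps: int = 2000

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.Vmax < 0:
            raise ConfigurationError("Km must be positive and Vmax non-negative")
        if min(self.substrate_design) <= 0:
            raise ConfigurationError("substrate concentrations must be positive")
        if self.n_timepoints < 4:
            raise ConfigurationError("need at least 4 time points")


def simulate_plate(spec: PlateSimSpec, cfg: AssayConfig) -> list[ProgressCurve]:
    """Simulate A234 progress curves for every substrate in the design.

    Product P(t) integrates dP/dt = Vmax*(S0-P)/(Km+S0-P); absorbance is
    A = epsilon*l*P/1e6 with multiplicative Gaussian noise of coefficient
    of variation ``noise_cv``.  Deterministic per seed.
    """
    if max(spec.substrate_design) > 10 * spec.Km:
        warnings.warn(
            "substrate design extends beyond 10*Km; the upper points add "
            "no curvature information",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.rng_seed)
    S0 = np.asarray(spec.substrate_design, dtype=float)
    dt = spec.duration / spec.n_steps
    step_times = np.linspace(0.0, spec.duration, spec.n_steps + 1)
    P = np.zeros((spec.n_steps + 1, S0.size))
    for i in range(spec.n_steps):
        S = np.maximum(S0 - P[i], 0.0)
        P[i + 1] = P[i] + spec.Vmax * S / (spec.Km + S) * dt
    sample_times = np.linspace(0.0, spec.duration, spec.n_timepoints)
    curves = []
    scale = cfg.epsilon * cfg.path_length / 1e6
    for j, s0 in enumerate(S0):
        p_sampled = np.interp(sample_times, step_times, P[:, j])
        absorbance = p_sampled * scale
        if spec.noise_cv > 0:
            absorbance = absorbance * (
                1.0 + spec.noise_cv * rng.standard_normal(absorbance.size)
            )
        curves.append(
            ProgressCurve(
                well=f"W{j + 1:02d}",
                times=sample_times,
                absorbance=absorbance,
                substrate=float(s0),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def table_fixtures() -> dict[str, object]:
    """Load the packaged library tables, verifying checksums.

    Returns ``table1_genomes`` (genome counts by category),
    ``table1_sequences`` (sequence totals as a dict), ``table2`` (selected
    enzymes: origins, accessions, masses, identities) and ``table3``
    (kinetic constants; the four enzymes without detectable activity carry
    missing values).
    """
    t1g = pd.read_csv(_fixture_path("table1_genome_counts.csv"))
    t1s_df = pd.read_csv(_fixture_path("table1_sequence_counts.csv"))
    t1s = dict(zip(t1s_df["quantity"], t1s_df["count"].astype(int)))
    t2 = pd.read_csv(_fixture_path("table2_library.csv"), dtype={"code": str})
    t3 = pd.read_csv(_fixture_path("table3_kinetics.csv"), dtype={"code": str})
    return {
        "table1_genomes": t1g,
        "table1_sequences": t1s,
        "table2": t2,
        "table3": t3,
    }


def load_usage_tables() -> tuple[CodonUsageTable, CodonUsageTable]:
    """The packaged synthetic two-host usage tables (E. coli-style,
    C. glutamicum-style)."""
    ecoli = CodonUsageTable.from_csv(
        _fixture_path("usage_ecoli_synthetic.csv"), host="ecoli"
    )
    cglut = CodonUsageTable.from_csv(
        _fixture_path("usage_cglutamicum_synthetic.csv"), host="cglutamicum"
    )
    return ecoli, cglut
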