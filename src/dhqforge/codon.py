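"""Codon engineering: dual-host recoding, site curing, hairpin removal,
BioBrick adapters and design QC.

A protein is reverse-translated under weights that harmonize the codon
usage bias of two expression hosts (by default *E. coli* and
*C. glutamicum* style tables): a codon's weight is the geometric mean of
its per-host relative adaptiveness (its family-relative frequency divided
by the family maximum).  The resulting ORF is then cured of the seven
restriction sites whose recognition sequences the BioBrick RFC10 standard
and common expression cloning reserve (NdeI, XhoI, EcoRI, NotI, XbaI,
SpeI, PstI), screened for stable 5'-end hairpins, and wrapped in the RFC10
prefix/suffix adapters.  All edits are synonymous, so the translation
(bacterial table 11) is preserved exactly.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from Bio.SeqUtils import gc_fraction, molecular_weight

from .errors import ConfigurationError, DesignError, InputError

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> amino acid (61 sense codons, bacterial translation table 11)
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE11.stop_codons))

#: amino acid -> sorted synonymous codons
FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, []).append(_codon)

#: Appended stop codon: TAA, the majority stop in both reference hosts.
DEFAULT_STOP = "TAA"

#: Restriction sites cured from every designed gene.
ENZYME_MOTIFS: dict[str, str] = {
    "NdeI": "CATATG",
    "XhoI": "CTCGAG",
    "EcoRI": "GAATTC",
    "NotI": "GCGGCCGC",
    "XbaI": "TCTAGA",
    "SpeI": "ACTAGT",
    "PstI": "CTGCAG",
}

#: BioBrick RFC10 adapters as printed for the synthesized parts.
BIOBRICK_PREFIX = "GCAGAATTCGCGGCCGCTTCTAGA"
BIOBRICK_SUFFIX = "ACTAGTAGCGGCCGCCTGCAG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, context: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise InputError(f"{context}: non-ACGT character {ch!r} at position {i}")


def translate_orf(orf: str, allow_trailing_stop: bool = True) -> str:
    """Translate an ORF with table 11; a single trailing stop is dropped."""
    if len(orf) % 3:
        raise InputError(f"ORF length {len(orf)} is not a multiple of 3")
    _validate_dna(orf, "ORF")
    protein = []
    n_codons = len(orf) // 3
    for i in range(n_codons):
        codon = orf[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if allow_trailing_stop and i == n_codons - 1:
                break
            raise InputError(f"internal stop codon {codon} at codon {i}")
        protein.append(CODON_TO_AA[codon])
    return "".join(protein)


# ---------------------------------------------------------------------------
# usage tables and harmonized weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-host codon usage as family-relative frequencies.

    ``usage`` maps each of the 61 sense codons to its relative frequency
    within its synonymous family; each family sums to 1.  Kazusa-style raw
    counts or per-thousand frequencies are accepted by the constructors and
    normalized within families.
    """

    host: str
    usage: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CODON_TO_AA) - set(self.usage)
        if missing:
            raise ConfigurationError(
                f"{self.host}: usage table missing codons {sorted(missing)[:4]}..."
                if len(missing) > 4
                else f"{self.host}: usage table missing codons {sorted(missing)}"
            )
        for aa, codons in FAMILIES.items():
            total = sum(self.usage[c] for c in codons)
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"{self.host}: family {aa} frequencies sum to {total}, not 1"
                )
            if max(self.usage[c] for c in codons) <= 0:
                raise ConfigurationError(f"{self.host}: family {aa} has no used codon")

    @classmethod
    def from_counts(cls, host: str, counts: Mapping[str, float]) -> "CodonUsageTable":
        """Normalize raw codon counts (or frequencies) within each family."""
        usage: dict[str, float] = {}
        for aa, codons in FAMILIES.items():
            total = sum(float(counts.get(c, 0.0)) for c in codons)
            if total <= 0:
                raise ConfigurationError(f"{host}: family {aa} has zero total count")
            for c in codons:
                usage[c] = float(counts.get(c, 0.0)) / total
        return cls(host=host, usage=usage)

    @classmethod
    def from_csv(cls, path: str | Path, host: str | None = None) -> "CodonUsageTable":
        """Read a ``codon,amino_acid,fraction`` CSV (counts also accepted)."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        codon_col = cols.get("codon")
        value_col = cols.get("fraction") or cols.get("count") or cols.get("frequency")
        if codon_col is None or value_col is None:
            raise ConfigurationError(f"{path}: need 'codon' and 'fraction' columns")
        counts = {
            str(row[codon_col]).upper().replace("U", "T"): float(row[value_col])
            for _, row in df.iterrows()
        }
        counts = {c: v for c, v in counts.items() if c in CODON_TO_AA}
        return cls.from_counts(host or Path(path).stem, counts)

    def relative_adaptiveness(self) -> dict[str, float]:
        """codon -> usage / max usage within its synonymous family."""
        rel: dict[str, float] = {}
        for aa, codons in FAMILIES.items():
            fmax = max(self.usage[c] for c in codons)
            for c in codons:
                rel[c] = self.usage[c] / fmax
        return rel


@dataclass(frozen=True)
class HarmonizedWeights:
    """Joint selection weights: geometric mean of per-host adaptiveness.

    Codons with weight below ``floor`` are inadmissible for reverse
    translation unless their whole family falls below the floor, in which
    case the family's best codon stays admissible.
    """

    weight: Mapping[str, float]
    floor: float
    hosts: tuple[str, ...] = ()

    def admissible_codons(self, aa: str) -> list[str]:
        codons = FAMILIES[aa]
        ok = [c for c in codons if self.weight[c] >= self.floor]
        if not ok:
            best = max(self.weight[c] for c in codons)
            ok = [c for c in codons if self.weight[c] == best]
        return ok

    def best_codon(self, aa: str) -> str:
        """Highest-weight admissible codon; lexicographic tie-break."""
        return min(
            self.admissible_codons(aa), key=lambda c: (-self.weight[c], c)
        )


def build_weights(
    tables: Sequence[CodonUsageTable], floor: float = 0.10
) -> HarmonizedWeights:
    """Combine per-host relative adaptiveness by geometric mean."""
    if not tables:
        raise ConfigurationError("at least one usage table is required")
    if not 0 <= floor < 1:
        raise ConfigurationError(f"floor must be in [0, 1), got {floor}")
    rels = [t.relative_adaptiveness() for t in tables]
    weight: dict[str, float] = {}
    for codon in CODON_TO_AA:
        product = 1.0
        for rel in rels:
            product *= rel[codon]
        weight[codon] = product ** (1.0 / len(rels))
    return HarmonizedWeights(
        weight=weight, floor=floor, hosts=tuple(t.host for t in tables)
    )


def reverse_translate(protein: str, weights: HarmonizedWeights) -> str:
    """Deterministic argmax reverse translation under harmonized weights."""
    if not protein:
        raise InputError("empty protein")
    codons = []
    for i, aa in enumerate(protein):
        if aa not in FAMILIES:
            raise InputError(f"residue {aa!r} at position {i + 1} cannot be encoded")
        codons.append(weights.best_codon(aa))
    return "".join(codons)


# ---------------------------------------------------------------------------
# design spec, motif scanning and curing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HairpinSpec:
    """Inverted-repeat scan parameters for the 5' region of the ORF."""

    scan_window: int = 120  # nt from the 5' end
    min_stem: int = 8  # perfect Watson-Crick pairs
    loop_range: tuple[int, int] = (3, 9)  # nt


@dataclass(frozen=True)
class DesignSpec:
    """Forbidden motifs, adapters and structure-scan settings."""

    forbidden_motifs: tuple[str, ...] = tuple(ENZYME_MOTIFS.values())
    prefix: str = BIOBRICK_PREFIX
    suffix: str = BIOBRICK_SUFFIX
    hairpin: HairpinSpec = field(default_factory=HairpinSpec)
    max_scrub_iterations: int = 200

    def __post_init__(self) -> None:
        for motif in self.forbidden_motifs:
            _validate_dna(motif, f"motif {motif}")
        if not self.prefix or not self.suffix:
            raise ConfigurationError("prefix and suffix must be non-empty")
        _validate_dna(self.prefix, "prefix")
        _validate_dna(self.suffix, "suffix")

    @property
    def nonpalindromic_motifs(self) -> tuple[str, ...]:
        """Motifs that are not their own reverse complement (the seven
        defaults all are, so single-strand scanning is complete for them)."""
        return tuple(
            m for m in self.forbidden_motifs if reverse_complement(m) != m
        )


DEFAULT_SPEC = DesignSpec()


def scan_motifs(
    seq: str, motifs: Sequence[str] | DesignSpec = DEFAULT_SPEC
) -> list[tuple[str, int]]:
    """All (motif, 0-based start) occurrences, overlapping ones included.

    Non-palindromic motifs are additionally searched on the reverse
    complement strand; such matches are reported at their forward-strand
    start coordinate.
    """
    if isinstance(motifs, DesignSpec):
        motif_list: Sequence[str] = motifs.forbidden_motifs
    else:
        motif_list = motifs
    _validate_dna(seq, "sequence")
    found: list[tuple[str, int]] = []
    for motif in motif_list:
        patterns = {motif}
        if reverse_complement(motif) != motif:
            patterns.add(reverse_complement(motif))
        for pattern in patterns:
            start = seq.find(pattern)
            while start != -1:
                found.append((motif, start))
                start = seq.find(pattern, start + 1)
    return sorted(set(found), key=lambda x: (x[1], x[0]))


@dataclass(frozen=True)
class CodonEdit:
    """One synonymous substitution, in application order."""

    codon_index: int
    old: str
    new: str
    reason: str  # "usage" | "motif" | "structure"


def apply_edits(orf: str, edits: Iterable[CodonEdit]) -> str:
    """Replay an edit log onto an ORF (used to audit design provenance)."""
    codons = [orf[i : i + 3] for i in range(0, len(orf), 3)]
    for edit in edits:
        if codons[edit.codon_index] != edit.old:
            raise DesignError(
                f"edit replay mismatch at codon {edit.codon_index}: "
                f"expected {edit.old}, found {codons[edit.codon_index]}"
            )
        codons[edit.codon_index] = edit.new
    return "".join(codons)


def _codon_list(orf: str) -> list[str]:
    return [orf[i : i + 3] for i in range(0, len(orf), 3)]


def _editable_alternatives(
    codon: str, weights: HarmonizedWeights
) -> list[tuple[float, str]]:
    """Synonymous replacements sorted by ascending weight loss then codon."""
    aa = CODON_TO_AA.get(codon)
    if aa is None:  # stop codon: synonymous stops, no weight preference
        return [(0.0, c) for c in STOP_CODONS if c != codon]
    w0 = weights.weight[codon]
    alts = [
        (w0 - weights.weight[c], c) for c in FAMILIES[aa] if c != codon
    ]
    return sorted(alts)


def _count_hits(seq: str, spec: DesignSpec) -> list[tuple[str, int]]:
    return scan_motifs(seq, spec)


def _exhaustive_window(
    codons: list[str],
    indices: list[int],
    weights: HarmonizedWeights,
    spec: DesignSpec,
    cap: int = 250_000,
) -> list[str] | None:
    """Try every synonymous assignment of the window codons; return the
    motif-fewest, then highest-weight assignment that improves on the
    current motif count, or None."""
    choices: list[list[str]] = []
    for i in indices:
        aa = CODON_TO_AA.get(codons[i])
        if aa is None:
            choices.append([codons[i]])
        else:
            choices.append(sorted(FAMILIES[aa], key=lambda c: (-weights.weight[c], c)))
    n_combo = math.prod(len(c) for c in choices)
    if n_combo > cap:
        return None
    base_hits = len(_count_hits("".join(codons), spec))
    best: tuple[int, float, list[str]] | None = None
    for combo in itertools.product(*choices):
        trial = list(codons)
        for idx, codon in zip(indices, combo):
            trial[idx] = codon
        n_hits = len(_count_hits("".join(trial), spec))
        gain = sum(
            weights.weight.get(c, 0.0) for c in combo
        )
        key = (n_hits, -gain)
        if best is None or key < (best[0], -best[1]):
            best = (n_hits, gain, trial)
    if best is not None and best[0] < base_hits:
        return best[2]
    return None


def scrub_motifs(
    orf: str,
    protein: str,
    weights: HarmonizedWeights,
    spec: DesignSpec = DEFAULT_SPEC,
) -> tuple[str, list[CodonEdit]]:
    """Remove every forbidden motif by synonymous substitution.

    Greedy strategy: take the leftmost motif; among codons overlapping it,
    try replacements in order of least harmonized-weight loss, accepting the
    first that removes the occurrence without creating a new site.  When no
    single substitution helps, a bounded exhaustive search over the motif
    window (extended by one codon each side) runs; for short peptides the
    whole synonymous space is searched, which proves unsatisfiability when
    it fails.
    """
    if translate_orf(orf) != protein:
        raise InputError("ORF does not translate to the given protein")
    codons = _codon_list(orf)
    protected = {
        i for i, c in enumerate(codons) if c in STOP_CODONS
    }  # keep an appended stop codon fixed
    edits: list[CodonEdit] = []
    for _ in range(spec.max_scrub_iterations):
        seq = "".join(codons)
        hits = _count_hits(seq, spec)
        if not hits:
            return seq, edits
        motif, start = hits[0]
        end = start + len(motif)
        overlap = [
            i for i in range(start // 3, (end - 1) // 3 + 1) if i not in protected
        ]
        candidates: list[tuple[float, int, str]] = []
        for ci in overlap:
            for loss, alt in _editable_alternatives(codons[ci], weights):
                candidates.append((loss, ci, alt))
        candidates.sort()
        applied = False
        for _loss, ci, alt in candidates:
            trial = list(codons)
            trial[ci] = alt
            trial_hits = _count_hits("".join(trial), spec)
            if (motif, start) not in trial_hits and len(trial_hits) < len(hits):
                edits.append(CodonEdit(ci, codons[ci], alt, "motif"))
                codons = trial
                applied = True
                break
        if applied:
            continue
        # single substitutions cannot clear this site: search the window
        lo = max(0, start // 3 - 1)
        hi = min(len(codons) - 1, (end - 1) // 3 + 1)
        window = [i for i in range(lo, hi + 1) if i not in protected]
        solution = _exhaustive_window(codons, window, weights, spec)
        if solution is None and len(codons) <= 10:
            # short peptide: search the entire synonymous space
            solution = _exhaustive_window(
                codons,
                [i for i in range(len(codons)) if i not in protected],
                weights,
                spec,
                cap=2_000_000,
            )
        if solution is None:
            n_editable = len(window)
            proof = (
                " (unsatisfiable: proven by exhaustive enumeration of the window)"
                if n_editable <= 5
                else ""
            )
            raise DesignError(
                f"cannot cure {motif} at {start} by synonymous substitution{proof}"
            )
        for i, (old, new) in enumerate(zip(codons, solution)):
            if old != new:
                edits.append(CodonEdit(i, old, new, "motif"))
        codons = solution
    raise DesignError(
        f"motif scrub did not converge within {spec.max_scrub_iterations} iterations"
    )


# ---------------------------------------------------------------------------
# hairpin detection and elimination
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def detect_hairpins(
    seq: str, spec: DesignSpec = DEFAULT_SPEC
) -> list[tuple[int, int, int]]:
    """Maximal perfect-stem inverted repeats near the 5' end.

    Returns (stem_start, stem_len, loop_len) for every hairpin lying
    entirely within the first ``scan_window`` nt whose perfect Watson-Crick
    stem is at least ``min_stem`` bp with a loop inside ``loop_range``.
    Hairpins nested inside a longer-stemmed one are suppressed.
    """
    hp = spec.hairpin
    region = seq[: hp.scan_window]
    loop_min, loop_max = hp.loop_range
    raw: set[tuple[int, int, int]] = set()
    for s in range(len(region)):
        for loop in range(loop_min, loop_max + 1):
            e = s + loop
            if e > len(region):
                break
            k = 0
            while (
                s - 1 - k >= 0
                and e + k < len(region)
                and (region[s - 1 - k], region[e + k]) in _PAIRS
            ):
                k += 1
            if k >= hp.min_stem:
                raw.add((s - k, k, loop))
    # drop hairpins contained in a longer-stemmed one
    results = []
    for h in raw:
        h_start, h_stem, h_loop = h
        h_end = h_start + 2 * h_stem + h_loop
        contained = any(
            o != h
            and o[0] <= h_start
            and o[0] + 2 * o[1] + o[2] >= h_end
            and o[1] > h_stem
            for o in raw
        )
        if not contained:
            results.append(h)
    return sorted(results)


def eliminate_structures(
    orf: str,
    protein: str,
    weights: HarmonizedWeights,
    spec: DesignSpec = DEFAULT_SPEC,
) -> tuple[str, list[CodonEdit], list[tuple[int, int, int]]]:
    """Break 5'-end hairpins by synonymous substitutions inside their stems.

    Each iteration targets the first remaining hairpin and applies the
    least-weight-loss stem substitution that reduces the hairpin count
    without re-introducing a forbidden motif.  Returns the edited ORF, the
    edit log and the list of residual hairpins (empty on success; a
    non-empty residue is a warning, not an error, since synthesis may still
    proceed).
    """
    if translate_orf(orf) != protein:
        raise InputError("ORF does not translate to the given protein")
    motif_free_input = not scan_motifs(orf, spec)
    codons = _codon_list(orf)
    protected = {i for i, c in enumerate(codons) if c in STOP_CODONS}
    edits: list[CodonEdit] = []
    for _ in range(spec.max_scrub_iterations):
        seq = "".join(codons)
        hairpins = detect_hairpins(seq, spec)
        if not hairpins:
            return seq, edits, []
        stem_start, stem_len, loop_len = hairpins[0]
        arm1 = range(stem_start, stem_start + stem_len)
        arm2_start = stem_start + stem_len + loop_len
        arm2 = range(arm2_start, arm2_start + stem_len)
        stem_codons = sorted(
            {p // 3 for p in arm1} | {p // 3 for p in arm2}
        )
        stem_codons = [i for i in stem_codons if i not in protected and i < len(codons)]
        candidates: list[tuple[float, int, str]] = []
        for ci in stem_codons:
            for loss, alt in _editable_alternatives(codons[ci], weights):
                candidates.append((loss, ci, alt))
        candidates.sort()
        applied = False
        for _loss, ci, alt in candidates:
            trial = list(codons)
            trial[ci] = alt
            trial_seq = "".join(trial)
            if motif_free_input and scan_motifs(trial_seq, spec):
                continue
            if len(detect_hairpins(trial_seq, spec)) < len(hairpins):
                edits.append(CodonEdit(ci, codons[ci], alt, "structure"))
                codons = trial
                applied = True
                break
        if not applied:
            return seq, edits, hairpins
    seq = "".join(codons)
    return seq, edits, detect_hairpins(seq, spec)


# ---------------------------------------------------------------------------
# BioBrick assembly and validation
# ---------------------------------------------------------------------------


def customize_biobrick(orf: str, spec: DesignSpec = DEFAULT_SPEC) -> str:
    """Attach the RFC10 prefix and suffix around a motif-free ORF."""
    _validate_dna(orf, "ORF")
    if scan_motifs(orf, spec):
        raise InputError("ORF still contains forbidden motifs; scrub first")
    return spec.prefix + orf + spec.suffix


@dataclass(frozen=True)
class ConstructReport:
    """Restriction-site audit of a full construct."""

    expected_sites: tuple[tuple[str, int], ...]
    violations: tuple[tuple[str, int, str], ...]  # (motif, start, region)
    adapters_present: bool
    passed: bool

    def to_dict(self) -> dict:
        return {
            "expected_sites": [list(x) for x in self.expected_sites],
            "violations": [list(x) for x in self.violations],
            "adapters_present": self.adapters_present,
            "passed": self.passed,
        }


def validate_construct(
    construct: str, spec: DesignSpec = DEFAULT_SPEC
) -> ConstructReport:
    """Check that restriction sites occur only inside the adapters.

    Sites lying entirely within the prefix or suffix coordinates are the
    standard's own (EcoRI/NotI/XbaI in the prefix, SpeI/NotI/PstI in the
    suffix for the defaults); any occurrence overlapping the ORF region or
    an adapter junction is a violation.
    """
    _validate_dna(construct, "construct")
    n_pre, n_suf = len(spec.prefix), len(spec.suffix)
    if len(construct) < n_pre + n_suf:
        raise InputError("construct shorter than prefix + suffix")
    orf_start, orf_end = n_pre, len(construct) - n_suf
    expected: list[tuple[str, int]] = []
    violations: list[tuple[str, int, str]] = []
    for motif, start in scan_motifs(construct, spec):
        end = start + len(motif)
        if end <= orf_start or start >= orf_end:
            expected.append((motif, start))
        elif start >= orf_start and end <= orf_end:
            violations.append((motif, start, "orf"))
        else:
            violations.append((motif, start, "junction"))
    adapters_present = construct.startswith(spec.prefix) and construct.endswith(
        spec.suffix
    )
    return ConstructReport(
        expected_sites=tuple(expected),
        violations=tuple(violations),
        adapters_present=adapters_present,
        passed=not violations and adapters_present,
    )


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------


def cai(seq: str, table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Single-codon families (Met, Trp) contribute 1 by construction; a
    trailing stop codon is ignored, an internal one is an error.
    """
    if len(seq) % 3:
        raise InputError(f"sequence length {len(seq)} is not a multiple of 3")
    _validate_dna(seq, "sequence")
    rel = table.relative_adaptiveness()
    log_sum = 0.0
    n = 0
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise InputError(f"internal stop codon {codon} at codon {i}")
        log_sum += math.log(rel[codon])
        n += 1
    if n == 0:
        raise InputError("no sense codons in sequence")
    return math.exp(log_sum / n)


def theoretical_mass(protein: str) -> float:
    """Average-isotope molecular mass of the translated protein, in kDa."""
    if not protein:
        raise InputError("empty protein")
    for i, aa in enumerate(protein):
        if aa not in FAMILIES:
            raise InputError(f"unknown residue {aa!r} at position {i + 1}")
    return molecular_weight(protein, seq_type="protein") / 1000.0


# ---------------------------------------------------------------------------
# full design pipeline
# ---------------------------------------------------------------------------


@dataclass
class GeneDesign:
    """A synthesis-ready part: ORF, construct, edit provenance and QC."""

    protein_id: str
    protein: str
    orf: str
    construct: str
    edits: list[CodonEdit]
    qc: dict
    report: ConstructReport
    residual_hairpins: list[tuple[int, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "protein": self.protein,
            "orf": self.orf,
            "construct": self.construct,
            "edits": [
                {
                    "codon_index": e.codon_index,
                    "old": e.old,
                    "new": e.new,
                    "reason": e.reason,
                }
                for e in self.edits
            ],
            "qc": self.qc,
            "construct_report": self.report.to_dict(),
            "residual_hairpins": [list(h) for h in self.residual_hairpins],
        }


def design_gene(
    protein_id: str,
    protein: str,
    tables: Sequence[CodonUsageTable],
    spec: DesignSpec = DEFAULT_SPEC,
    floor: float = 0.10,
    add_stop: bool = True,
) -> GeneDesign:
    """Full pipeline: recode, cure sites, break hairpins, add adapters, QC.

    When ``add_stop`` is true a TAA stop codon is appended to the ORF (it is
    never edited during curing).
    """
    weights = build_weights(tables, floor=floor)
    orf0 = reverse_translate(protein, weights)
    if add_stop:
        orf0 += DEFAULT_STOP
    orf1, motif_edits = scrub_motifs(orf0, protein, weights, spec)
    orf2, structure_edits, residual = eliminate_structures(orf1, protein, weights, spec)
    construct = customize_biobrick(orf2, spec)
    report = validate_construct(construct, spec)
    qc = {
        "cai": {t.host: round(cai(orf2, t), 4) for t in tables},
        "gc_fraction": round(gc_fraction(orf2), 4),
        "motif_free": not scan_motifs(orf2, spec),
        "hairpin_free": not residual,
        "theoretical_mass_kda": round(theoretical_mass(protein), 1),
        "orf_length_nt": len(orf2),
        "construct_length_nt": len(construct),
        "n_edits": len(motif_edits) + len(structure_edits),
    }
    return GeneDesign(
        protein_id=protein_id,
        protein=protein,
        orf=orf2,
        construct=construct,
        edits=motif_edits + structure_edits,
        qc=qc,
        report=report,
        residual_hairpins=residual,
    )


def write_design_outputs(design: GeneDesign, out_dir: str | Path) -> None:
    """Write FASTA (ORF + construct), a JSON design report, and an annotated
    GenBank flat file for one design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = design.protein_id
    SeqIO.write(
        [
            SeqRecord(Seq(design.orf), id=f"{stem}_orf", description="codon-optimized ORF"),
            SeqRecord(
                Seq(design.construct),
                id=f"{stem}_construct",
                description="BioBrick construct (prefix+ORF+suffix)",
            ),
        ],
        str(out_dir / f"{stem}.fasta"),
        "fasta",
    )
    with open(out_dir / f"{stem}.design.json", "w") as fh:
        json.dump(design.to_dict(), fh, indent=2)
    record = SeqRecord(
        Seq(design.construct),
        id=stem[:16],
        name=stem[:16],
        description="BioBrick part",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    prefix_len = design.construct.find(design.orf)
    record.features = [
        SeqFeature(
            FeatureLocation(0, prefix_len), type="misc_feature",
            qualifiers={"label": "biobrick_prefix"},
        ),
        SeqFeature(
            FeatureLocation(prefix_len, prefix_len + len(design.orf)), type="CDS",
            qualifiers={"label": design.protein_id, "translation": design.protein},
        ),
        SeqFeature(
            FeatureLocation(prefix_len + len(design.orf), len(design.construct)),
            type="misc_feature", qualifiers={"label": "biobrick_suffix"},
        ),
    ]
    SeqIO.write([record], str(out_dir / f"{stem}.gb"), "genbank")
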