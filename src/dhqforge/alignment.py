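"""Local/global protein alignment scoring and Karlin–Altschul E-values.

The homolog screen scores candidate proteins against seed sequences by
optimal local alignment (Smith–Waterman with affine gaps) and converts raw
scores to E-values with the Karlin–Altschul formula

    E = K * m * n * exp(-lambda * S)

where ``m`` and ``n`` are query and database lengths and ``S`` the alignment
score.  A gap of length L costs ``gap_open + gap_extend * L`` (the BLAST
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import ConfigurationError, InputError
from .records import validate_protein_sequence


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value parameters.

    Defaults: BLOSUM62, gap open 11 / extend 1, ungapped Karlin–Altschul
    parameters K = 0.041, lambda = 0.267 (nats per score unit) applied to the
    gapped score.  All four are configurable.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_K: float = 0.041
    karlin_lambda: float = 0.267

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ConfigurationError("gap penalties must be positive")
        if self.karlin_K <= 0 or self.karlin_lambda <= 0:
            raise ConfigurationError("Karlin-Altschul K and lambda must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def _aligner(self, mode: str) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.substitution_matrix = self.matrix
        aligner.mode = mode
        # Biopython charges open_gap_score on the first gap position only,
        # so open + extend reproduces the BLAST cost gap_open + gap_extend*L.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


def score_local_alignment(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Optimal Smith–Waterman score of *a* vs *b* under *scheme* (>= 0)."""
    validate_protein_sequence(a, context="sequence a")
    validate_protein_sequence(b, context="sequence b")
    score = scheme._aligner("local").score(a, b)
    return int(round(max(score, 0.0)))


def estimate_evalue(
    score: float, m: int, n: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Karlin–Altschul E-value for a single query of length *m* against *n*
    residues of database.

    Strictly decreasing in *score*, linear in *m* and in *n*.  The product
    uses the single-query m*n search space, not a database-wide sum.
    """
    if m < 1 or n < 1:
        raise InputError(f"sequence lengths must be >= 1, got m={m}, n={n}")
    return scheme.karlin_K * m * n * math.exp(-scheme.karlin_lambda * score)


def global_alignment_map(
    reference: str, query: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> dict[int, str]:
    """Map each 0-based reference position to the aligned query residue.

    Uses Needleman–Wunsch with the scheme's matrix and gap costs; positions
    aligned to a gap map to ``"-"``.
    """
    validate_protein_sequence(reference, context="reference")
    validate_protein_sequence(query, context="query")
    alignment = scheme._aligner("global").align(reference, query)[0]
    mapping = {i: "-" for i in range(len(reference))}
    ref_blocks, query_blocks = alignment.aligned
    for (rs, re), (qs, _qe) in zip(ref_blocks, query_blocks):
        for offset in range(re - rs):
            mapping[rs + offset] = query[qs + offset]
    return mapping
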