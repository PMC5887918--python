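"""Global pairwise alignment identity.

Identity between two nucleotide sequences is defined as the number of
matching columns divided by the total number of alignment columns
(gap columns included) in an optimal global alignment under a simple
match/mismatch/gap scoring scheme.  This single definition underpins
both MOTU clustering thresholds and taxonomic assignment, so it is
pinned down here once.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    *,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
    mode: str = "global",
) -> float:
    """Fraction of identical columns in an optimal pairwise alignment.

    Parameters
    ----------
    a, b:
        Nucleotide sequences (non-empty).
    match, mismatch, gap:
        Scoring used to pick the optimal alignment; gap open and extend
        cost the same.
    mode:
        ``"global"`` (Needleman-Wunsch, the default) or ``"local"``
        (Smith-Waterman; used for half-read chimera screening).

    Returns
    -------
    float
        matches / alignment length, in [0, 1].  Symmetric in its
        arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    if (match, mismatch, gap, mode) == (DEFAULT_MATCH, DEFAULT_MISMATCH, DEFAULT_GAP, "global"):
        # symmetric, so normalize the pair ordering for the cache
        return _default_identity(*sorted((a, b)))
    aligner = _aligner(match, mismatch, gap, mode)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    if total == 0:
        return 0.0
    return counts.identities / total


@lru_cache(maxsize=1 << 20)
def _default_identity(a: str, b: str) -> float:
    """Default-scoring global identity, cached across repeated pairs
    (MOTU clustering revisits the same haplotype/centroid pairs at every
    grid threshold)."""
    aligner = _aligner(DEFAULT_MATCH, DEFAULT_MISMATCH, DEFAULT_GAP, "global")
    if len(a) == len(b):
        # when a gapless alignment attains the optimal score it is an
        # optimal alignment, and identity reduces to Hamming identity
        mismatches = sum(x != y for x, y in zip(a, b))
        if aligner.score(a, b) == len(a) - 2 * mismatches:
            return (len(a) - mismatches) / len(a)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    if total == 0:
        return 0.0
    return counts.identities / total
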