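"""Pairwise protein alignment and duplicate-pair calling.

Duplicate gene pairs are called from local protein alignments: a pair is
a duplicate when both percent identity and the aligned coverage of *each*
partner exceed a threshold (default 80%, strict inequality).  Alignment is
Smith-Waterman with affine gaps and BLOSUM62 scoring — the identity and
coverage evidence this produces is what the duplicate rule consumes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .io import FamilyTable

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0  # BLASTP-like affine costs
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Identity/coverage evidence for one aligned protein pair.

    ``identity`` is the percentage of identical positions over all aligned
    columns of the local region (internal gap columns count as mismatches);
    ``coverage_a``/``coverage_b`` are the percentage of each sequence's
    length covered by the locally aligned span.
    """

    id_a: str
    id_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    aligned_length: int
    score: float

    def passes(self, threshold: float = 80.0) -> bool:
        """Duplicate rule: identity and both coverages strictly above threshold."""
        return (
            self.identity > threshold
            and min(self.coverage_a, self.coverage_b) > threshold
        )


def align_pair(
    protein_a: str, protein_b: str, id_a: str = "a", id_b: str = "b"
) -> AlignmentResult:
    """Locally align two protein sequences and summarize the evidence."""
    if not protein_a or not protein_b:
        raise ValidationError("align_pair requires non-empty sequences")
    aligner = _make_aligner()
    aln = aligner.align(protein_a, protein_b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    columns = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        columns += ea - sa
        matches += sum(
            1 for x, y in zip(protein_a[sa:ea], protein_b[sb:eb]) if x == y
        )
    # internal gaps between consecutive blocks count as mismatch columns
    for k in range(1, len(blocks_a)):
        columns += blocks_a[k][0] - blocks_a[k - 1][1]
        columns += blocks_b[k][0] - blocks_b[k - 1][1]
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return AlignmentResult(
        id_a=id_a,
        id_b=id_b,
        identity=100.0 * matches / columns,
        coverage_a=100.0 * span_a / len(protein_a),
        coverage_b=100.0 * span_b / len(protein_b),
        aligned_length=columns,
        score=float(aln.score),
    )


def all_pairs(family: FamilyTable) -> list[AlignmentResult]:
    """Align every unordered pair of family members (sorted id order)."""
    if len(family) < 2:
        raise ValidationError("need at least two family members to compare")
    results = []
    for id_a, id_b in itertools.combinations(sorted(family.ids), 2):
        a, b = family[id_a], family[id_b]
        if a.protein is None or b.protein is None:
            raise ValidationError(f"protein missing for {id_a!r} or {id_b!r}")
        results.append(align_pair(a.protein, b.protein, id_a, id_b))
    return results


def call_duplicates(
    family: FamilyTable, threshold: float = 80.0
) -> list[AlignmentResult]:
    """Return the duplicate pairs of a family.

    A pair is called iff identity > ``threshold`` and the coverage of both
    partners > ``threshold`` (strict, in percent).  Each unordered pair is
    reported once; the output is independent of family input order.
    """
    return [r for r in all_pairs(family) if r.passes(threshold)]


def similarity_report(
    family: FamilyTable, threshold: float = 80.0
) -> pd.DataFrame:
    """All-pairs TSV-ready report with the called flag per pair."""
    rows = [
        {
            "id_a": r.id_a,
            "id_b": r.id_b,
            "identity": round(r.identity, 2),
            "coverage_a": round(r.coverage_a, 2),
            "coverage_b": round(r.coverage_b, 2),
            "called": r.passes(threshold),
        }
        for r in all_pairs(family)
    ]
    return pd.DataFrame(rows)
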