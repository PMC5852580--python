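"""Codon-level evolutionary analysis of duplicate gene pairs.

Implements the Nei-Gojobori (1986) unweighted-pathway method:

* **site counting** — each codon position contributes one site, split into
  a synonymous fraction (the fraction of its single-nucleotide changes
  that preserve the encoded amino acid) and a nonsynonymous remainder;
  changes that would create a stop codon are excluded and the fraction is
  renormalized over the remaining alternatives, so S + N == 3 per codon;
* **difference counting** — for a codon pair differing at k positions,
  synonymous/nonsynonymous step counts are averaged over all k! mutational
  pathways, skipping pathways that pass through a stop codon (if *every*
  pathway is illegal the differences are counted as all-nonsynonymous and
  a warning is emitted);
* **distance correction** — the observed proportions pS = Sd/S and
  pN = Nd/N are converted to per-site substitution estimates with the
  Jukes-Cantor formula d = -(3/4)·ln(1 - (4/3)p), giving Ks and Ka;
* **selection mode** — Ka/Ks > 1 positive, < 1 purifying, == 1 neutral;
* **dating** — T(Mya) = Ks / (2r) with r = 1.5e-8 synonymous
  substitutions per site per year (dicotyledon clock).

Site totals are averaged over the two sequences before forming pS/pN, and
codon columns containing a gap in either sequence are excluded pairwise
(complete deletion at the codon level).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Data import CodonTable

from .errors import SequenceError, ValidationError

SYNONYMOUS_RATE_PER_YEAR = 1.5e-8  # r, dicot synonymous clock

_standard = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
_BASES = "ACGT"


def _require_sense(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise SequenceError(f"stop codon {codon!r} not allowed")
    if codon not in GENETIC_CODE:
        raise SequenceError(f"{codon!r} is not an unambiguous sense codon")
    return codon


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    Returns ``(S, N)`` with ``S + N == 3``.  For each of the nine
    single-nucleotide neighbors, neighbors that are stop codons are
    excluded and the synonymous fraction at that position is renormalized
    over the remaining alternatives.
    """
    codon = _require_sense(codon)
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_legal = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_legal += 1
            if GENETIC_CODE[alt] == aa:
                n_syn += 1
        if n_legal:
            syn += n_syn / n_legal
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 pathway-averaged synonymous/nonsynonymous differences.

    Averages the per-step synonymous/nonsynonymous tallies over every
    order of introducing the mismatched positions, excluding pathways
    whose intermediate codons are stops.  If no pathway is legal the k
    steps are all counted as nonsynonymous (with a warning).
    """
    codon_a = _require_sense(codon_a)
    codon_b = _require_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_legal_paths = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        legal = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                legal = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if legal:
            n_legal_paths += 1
            syn_total += syn
            nonsyn_total += nonsyn
    if n_legal_paths == 0:
        warnings.warn(
            f"all mutational pathways {codon_a}->{codon_b} pass through stop "
            "codons; counting all steps as nonsynonymous",
            stacklevel=2,
        )
        return 0.0, float(k)
    return syn_total / n_legal_paths, nonsyn_total / n_legal_paths


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4)·ln(1 - (4/3)p)."""
    if p < 0:
        raise ValidationError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise ValidationError(
            f"p = {p:.4f} >= 3/4: Jukes-Cantor correction undefined (saturated)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def divergence_time(ks: float, r: float = SYNONYMOUS_RATE_PER_YEAR) -> float:
    """Duplication age in million years: T = Ks / (2r) / 1e6."""
    if ks < 0:
        raise ValidationError("Ks must be non-negative")
    return ks / (2.0 * r) / 1e6


def classify_selection(ratio: float | None, tol: float = 1e-9) -> str:
    """Selection mode from omega: >1 positive, <1 purifying, ==1 neutral."""
    if ratio is None:
        return "undefined"
    if ratio < 0:
        raise ValidationError("Ka/Ks cannot be negative")
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


# ---------------------------------------------------------------------------
# Codon alignment


@dataclass
class CodonAlignment:
    """Pairwise codon alignment: per-column codons or None for a gap codon."""

    id_a: str
    id_b: str
    columns: list[tuple[str | None, str | None]]

    @property
    def comparable_columns(self) -> list[tuple[str, str]]:
        """Columns with a sense codon in both sequences (complete deletion)."""
        return [
            (a, b)
            for a, b in self.columns
            if a is not None
            and b is not None
            and a not in STOP_CODONS
            and b not in STOP_CODONS
        ]


def back_translate(
    aln_a: str,
    aln_b: str,
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Thread CDS codons onto a gapped pairwise protein alignment.

    Each amino-acid column maps back to its source codon; a gap character
    becomes a whole-codon gap.  The ungapped protein of each row must
    translate from its CDS (terminal stop tolerated); a mismatch raises
    naming the first offending residue position.
    """
    if len(aln_a) != len(aln_b):
        raise ValidationError("aligned rows must have equal length")

    def codons_of(aln: str, cds: str, name: str) -> list[str | None]:
        cds = cds.upper()
        if len(cds) % 3:
            raise SequenceError(f"{name}: CDS length not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = [c for c in aln if c != "-"]
        if len(residues) != len(codons):
            raise SequenceError(
                f"{name}: protein has {len(residues)} residues but CDS has "
                f"{len(codons)} (non-stop) codons"
            )
        for i, (aa, codon) in enumerate(zip(residues, codons)):
            if GENETIC_CODE.get(codon) != aa:
                raise SequenceError(
                    f"{name}: residue {i + 1} ({aa}) does not match codon "
                    f"{codon} ({GENETIC_CODE.get(codon, '*')})"
                )
        out: list[str | None] = []
        it = iter(codons)
        for c in aln:
            out.append(None if c == "-" else next(it))
        return out

    col_a = codons_of(aln_a, cds_a, id_a)
    col_b = codons_of(aln_b, cds_b, id_b)
    return CodonAlignment(id_a=id_a, id_b=id_b, columns=list(zip(col_a, col_b)))


# ---------------------------------------------------------------------------
# Ka/Ks


@dataclass
class KaKsResult:
    """NG86 counts plus corrected rates for one gene pair."""

    id_a: str
    id_b: str
    n_codons: int  # comparable codon columns
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float | None  # None when Ks == 0
    selection: str
    divergence_mya: float
    saturated: bool = False  # True when JC correction was undefined


def compute_kaks(
    aln: CodonAlignment, r: float = SYNONYMOUS_RATE_PER_YEAR
) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction for a codon alignment.

    Site totals are averaged over the two sequences; gapped columns are
    excluded pairwise.  When pS or pN reaches the JC saturation bound the
    result is flagged ``saturated`` with NaN rates rather than raising.
    """
    cols = aln.comparable_columns
    if not cols:
        raise ValidationError("no comparable (ungapped, sense) codon columns")
    S_a = N_a = S_b = N_b = Sd = Nd = 0.0
    for ca, cb in cols:
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = count_differences(ca, cb)
        Sd += sd
        Nd += nd
    S = (S_a + S_b) / 2.0
    N = (N_a + N_b) / 2.0
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    saturated = pS >= 0.75 or pN >= 0.75
    if saturated:
        Ks = Ka = float("nan")
        ratio: float | None = None
        selection = "undefined"
        mya = float("nan")
    else:
        Ks = jukes_cantor(pS)
        Ka = jukes_cantor(pN)
        ratio = Ka / Ks if Ks > 0 else None
        selection = classify_selection(ratio)
        mya = divergence_time(Ks, r)
    return KaKsResult(
        id_a=aln.id_a,
        id_b=aln.id_b,
        n_codons=len(cols),
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        selection=selection,
        divergence_mya=mya,
        saturated=saturated,
    )


def kaks_for_pair(
    gene_a, gene_b, r: float = SYNONYMOUS_RATE_PER_YEAR
) -> KaKsResult:
    """Align two gene models' proteins globally, back-translate, and score.

    Convenience wrapper for :func:`compute_kaks` starting from two
    :class:`~genefam.io.GeneModel` objects carrying CDS and protein.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    for g in (gene_a, gene_b):
        if g.cds is None or g.protein is None:
            raise ValidationError(f"{g.gene_id!r} lacks CDS or protein sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(gene_a.protein, gene_b.protein)[0]
    gapped_a, gapped_b = _gapped_rows(aln, gene_a.protein, gene_b.protein)
    codon_aln = back_translate(
        gapped_a, gapped_b, gene_a.cds, gene_b.cds, gene_a.gene_id, gene_b.gene_id
    )
    return compute_kaks(codon_aln, r=r)


def _gapped_rows(aln, seq_a: str, seq_b: str) -> tuple[str, str]:
    """Reconstruct the two gapped alignment rows from block coordinates."""
    blocks_a, blocks_b = aln.aligned
    out_a: list[str] = []
    out_b: list[str] = []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        out_a.append(seq_a[pa:sa] + "-" * (sb - pb))
        out_b.append("-" * (sa - pa) + seq_b[pb:sb])
        out_a.append(seq_a[sa:ea])
        out_b.append(seq_b[sb:eb])
        pa, pb = ea, eb
    out_a.append(seq_a[pa:] + "-" * (len(seq_b) - pb))
    out_b.append("-" * (len(seq_a) - pa) + seq_b[pb:])
    return "".join(out_a), "".join(out_b)


def kaks_report(results: list[KaKsResult], dup_types: dict | None = None) -> pd.DataFrame:
    """Per-pair report: Ks, Ka, ratio, duplication type, selection, age."""
    rows = []
    for res in results:
        key = (res.id_a, res.id_b)
        rows.append(
            {
                "id_a": res.id_a,
                "id_b": res.id_b,
                "Ks": round(res.Ks, 4),
                "Ka": round(res.Ka, 4),
                "Ka_Ks": "" if res.ratio is None else round(res.ratio, 4),
                "dup_type": (dup_types or {}).get(key, ""),
                "selection": res.selection,
                "divergence_mya": round(res.divergence_mya, 2),
            }
        )
    return pd.DataFrame(rows)
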