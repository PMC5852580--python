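"""Physicochemical protein properties: residue count, molecular weight,
isoelectric point.

Molecular weight is the sum of average-isotopic residue masses plus one
water, reported in kDa.  The isoelectric point solves net charge = 0 by
bisection over pH using Henderson-Hasselbalch terms for the termini and
the ionizable side chains (D, E, C, Y, K, R, H) with the Bjellqvist pKa
set used by the Expasy Compute pI tool, including the residue-specific
terminal pKa adjustments.  Because the terminal pKa depends on which
residue carries each terminus, pI is invariant under permutations of the
internal residues but may shift slightly when the terminal residues
change.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import SequenceError, ValidationError

# Average isotopic residue masses (Da), Expasy convention
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

# Bjellqvist pKa values (as embedded in the Expasy pI computation);
# the terminal pKa depends on which residue carries the terminus
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_RESIDUE = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
}
PKA_CTERM_RESIDUE = {"D": 4.55, "E": 4.75}


@dataclass(frozen=True)
class ProteinProperties:
    gene_id: str
    length: int
    mw_kda: float
    pi: float


def _check(protein: str) -> str:
    protein = protein.upper()
    if not protein:
        raise ValidationError("empty protein sequence")
    bad = set(protein) - set(RESIDUE_MASS)
    if bad:
        raise SequenceError(f"unknown residue(s) {sorted(bad)}")
    return protein


def residue_count(protein: str) -> int:
    return len(_check(protein))


def molecular_weight(protein: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    protein = _check(protein)
    return (sum(RESIDUE_MASS[a] for a in protein) + WATER_MASS) / 1000.0


def net_charge(protein: str, ph: float) -> float:
    """Net charge at a given pH (Henderson-Hasselbalch over ionizable groups)."""
    protein = _check(protein)
    counts = Counter(protein)
    pka_n = PKA_NTERM_RESIDUE.get(protein[0], PKA_POSITIVE["Nterm"])
    pka_c = PKA_CTERM_RESIDUE.get(protein[-1], PKA_NEGATIVE["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - pka_n))
    charge -= 1.0 / (1.0 + 10 ** (pka_c - ph))
    for aa in ("K", "R", "H"):
        charge += counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    for aa in ("D", "E", "C", "Y"):
        charge -= counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-3) -> float:
    """pH at which the net charge crosses zero, by bisection.

    The charge is strictly decreasing in pH and is positive at pH 0 and
    negative at pH 14 for any sequence, so the bracket is always valid.
    """
    protein = _check(protein)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def properties_report(proteins: dict[str, str]) -> pd.DataFrame:
    """Per-gene table of length (aa), MW (kDa), and pI."""
    rows = [
        {
            "gene_id": gid,
            "aa": residue_count(seq),
            "mw_kda": round(molecular_weight(seq), 2),
            "pi": round(isoelectric_point(seq), 2),
        }
        for gid, seq in proteins.items()
    ]
    return pd.DataFrame(rows)
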