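"""Synthetic gene families and qPCR tables with planted ground truth.

The family generator emulates the inputs of a gene-family study: CDS /
protein gene models laid out on several chromosomes, with duplicate
pairs planted either in tandem (same chromosome, nearest-edge offset
below 100 kb) or segmentally (different chromosomes), and each pair
diverged to a chosen synonymous distance (target Ks) and selection
intensity (target omega = Ka/Ks).  Divergence is realized by drawing the
implied numbers of synonymous and nonsynonymous point substitutions from
the Nei-Gojobori site counts of the ancestral sequence and placing them
at randomly chosen eligible codon positions, rejecting any change that
would create a stop codon.

The Cq generator emulates a qPCR plate: per-replicate target Cq is
baseline - planted log2 fold + Gaussian noise, the reference gene sits
at a constant Cq with the same noise model.

Both generators are deterministic for a fixed seed and write the same
FASTA/TSV/CSV dialects the package's readers accept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CqTable, FamilyTable, GeneModel, write_fasta, write_gene_table
from .molevol import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, count_sites

_BASES = "ACGT"


@dataclass
class DuplicatePlan:
    """One planted duplicate pair and its divergence targets."""

    id_a: str
    id_b: str
    dup_type: str  # "tandem" | "segmental"
    target_omega: float = 0.3
    target_ks: float = 0.2
    tandem_offset_bp: int = 5_000  # nearest-edge gap for tandem pairs

    def __post_init__(self) -> None:
        if self.dup_type not in ("tandem", "segmental"):
            raise ValidationError(f"unknown duplication type {self.dup_type!r}")
        if not (0.0 < self.target_ks < 0.7):
            raise ValidationError("target_ks must lie in (0, 0.7)")
        if self.target_omega <= 0:
            raise ValidationError("target_omega must be positive")
        if self.dup_type == "tandem" and not (0 < self.tandem_offset_bp < 100_000):
            raise ValidationError("tandem offset must be < 100 kb")


@dataclass
class FamilySimConfig:
    """Layout and divergence plan for one synthetic gene family."""

    n_chromosomes: int = 5
    n_singletons: int = 4  # unrelated background genes
    codon_length: int = 300  # codons per gene (excl. stop)
    duplicate_plan: list[DuplicatePlan] = field(default_factory=list)
    intergenic_bp: int = 500_000  # spacing between unrelated gene starts
    seed: int = 0


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Uniform sense codons; ATG start for realism, no internal stops."""
    codons = ["ATG"] + [
        SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))] for _ in range(n_codons - 1)
    ]
    return "".join(codons)


def _inverse_jc(d: float) -> float:
    """Observed proportion p implied by a JC-corrected distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _eligible_changes(cds: str, synonymous: bool) -> list[tuple[int, str]]:
    """All (nucleotide position, new base) single changes of the wanted kind.

    A change is eligible when it does not create a stop codon and its
    effect on the encoded amino acid matches ``synonymous``.
    """
    out = []
    for codon_idx in range(len(cds) // 3):
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        aa = GENETIC_CODE[codon]
        for off in range(3):
            for base in _BASES:
                if base == codon[off]:
                    continue
                alt = codon[:off] + base + codon[off + 1 :]
                if alt in STOP_CODONS:
                    continue
                if (GENETIC_CODE[alt] == aa) == synonymous:
                    out.append((codon_idx * 3 + off, base))
    return out


def diverge_cds(
    cds: str, target_ks: float, target_omega: float, rng: np.random.Generator
) -> str:
    """Apply the substitution budget implied by (target Ks, target omega).

    The synonymous/nonsynonymous substitution counts are ``round(p * sites)``
    with p the inverse-JC observed proportion and sites the NG86 totals of
    the ancestral sequence.  Changes are placed one at a time at uniformly
    chosen eligible positions of the *current* sequence (so multiple hits
    at one codon are possible, as in real divergence).
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    S = sum(count_sites(c)[0] for c in codons)
    N = sum(count_sites(c)[1] for c in codons)
    n_syn = round(_inverse_jc(target_ks) * S)
    n_nonsyn = round(_inverse_jc(target_ks * target_omega) * N)
    seq = list(cds)
    for synonymous, budget in ((True, n_syn), (False, n_nonsyn)):
        for _ in range(budget):
            choices = _eligible_changes("".join(seq), synonymous)
            if not choices:
                raise ValidationError(
                    "substitution budget exceeds eligible sites"
                )
            pos, base = choices[rng.integers(0, len(choices))]
            seq[pos] = base
    return "".join(seq)


def _translate(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def simulate_family(cfg: FamilySimConfig) -> FamilyTable:
    """Generate a synthetic family honoring the planted duplication plan.

    Tandem pairs are placed adjacently on one chromosome with the planned
    nearest-edge offset; segmental pairs go on two different chromosomes;
    singletons are scattered with large spacing.  Deterministic under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    chrom_cursor: dict[str, int] = {}
    chrom_names = [f"Chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    if cfg.duplicate_plan and cfg.n_chromosomes < 2:
        raise ValidationError("segmental placement needs >= 2 chromosomes")

    def place(chrom: str, length_bp: int, gap: int) -> tuple[int, int]:
        start = chrom_cursor.get(chrom, 1) + gap
        end = start + length_bp - 1
        chrom_cursor[chrom] = end
        return start, end

    next_chrom = 0

    def take_chrom() -> str:
        nonlocal next_chrom
        chrom = chrom_names[next_chrom % len(chrom_names)]
        next_chrom += 1
        return chrom

    for plan in cfg.duplicate_plan:
        ancestor = _random_cds(rng, cfg.codon_length)
        derived = diverge_cds(ancestor, plan.target_ks, plan.target_omega, rng)
        length_bp = len(ancestor)
        if plan.dup_type == "tandem":
            chrom = take_chrom()
            sa, ea = place(chrom, length_bp, cfg.intergenic_bp)
            sb, eb = place(chrom, length_bp, plan.tandem_offset_bp)
            coords = [(chrom, sa, ea), (chrom, sb, eb)]
        else:
            ca, cb = take_chrom(), take_chrom()
            if ca == cb:  # happens only when n_chromosomes == 1, guarded above
                raise ValidationError("cannot place segmental pair on one chromosome")
            coords = [
                (ca, *place(ca, length_bp, cfg.intergenic_bp)),
                (cb, *place(cb, length_bp, cfg.intergenic_bp)),
            ]
        for gid, cds, (chrom, start, end) in zip(
            (plan.id_a, plan.id_b), (ancestor, derived), coords
        ):
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.integers(0, 2) else "-",
                    cds=cds,
                    protein=_translate(cds),
                )
            )

    for i in range(cfg.n_singletons):
        cds = _random_cds(rng, cfg.codon_length)
        chrom = take_chrom()
        start, end = place(chrom, len(cds), cfg.intergenic_bp)
        genes.append(
            GeneModel(
                gene_id=f"bg{i + 1:02d}",
                chromosome=chrom,
                start=start,
                end=end,
                strand="+" if rng.integers(0, 2) else "-",
                cds=cds,
                protein=_translate(cds),
            )
        )
    return FamilyTable(genes)


def write_family(family: FamilyTable, out_dir: str | Path) -> dict[str, Path]:
    """Write coordinate TSV plus CDS and protein FASTA for a family."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out_dir / "genes.tsv",
        "cds": out_dir / "cds.fasta",
        "protein": out_dir / "protein.fasta",
    }
    write_gene_table(family, paths["table"])
    write_fasta({g.gene_id: g.cds for g in family}, paths["cds"])
    write_fasta({g.gene_id: g.protein for g in family}, paths["protein"])
    return paths


# ---------------------------------------------------------------------------
# Cq simulation


@dataclass
class CqSimConfig:
    """Planted qPCR experiment: per-gene x group log2 fold-changes.

    ``planted_log2_fold`` maps (gene_id, line, temperature, time) to the
    true log2 fold against that series' 0 h calibrator; unlisted cells
    default to 0 (no change).
    """

    genes: list[str] = field(default_factory=lambda: ["g1"])
    lines: list[str] = field(default_factory=lambda: ["tolerant"])
    temperatures: list[float] = field(default_factory=lambda: [5.0])
    times: list[float] = field(default_factory=lambda: [0.0, 6.0, 24.0])
    planted_log2_fold: dict = field(default_factory=dict)
    n_replicates: int = 3
    noise_sd: float = 0.2  # cycles
    baseline_cq: float = 24.0
    reference_cq: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        if 0.0 not in self.times:
            raise ValidationError("times must include the 0 h calibrator")


def simulate_cq(cfg: CqSimConfig) -> CqTable:
    """Generate a replicate Cq table with the planted fold-changes.

    Target Cq per replicate = baseline - log2fold + N(0, sd); the
    reference gene sits at a constant Cq with the same noise.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for gene in cfg.genes:
        for line in cfg.lines:
            for temp in cfg.temperatures:
                for t in cfg.times:
                    lf = cfg.planted_log2_fold.get((gene, line, temp, t), 0.0)
                    for rep in range(1, cfg.n_replicates + 1):
                        rows.append(
                            {
                                "gene_id": gene,
                                "line": line,
                                "temperature": temp,
                                "time": t,
                                "replicate": rep,
                                "cq_target": cfg.baseline_cq
                                - lf
                                + rng.normal(0.0, cfg.noise_sd),
                                "cq_reference": cfg.reference_cq
                                + rng.normal(0.0, cfg.noise_sd),
                            }
                        )
    return CqTable(pd.DataFrame(rows))
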