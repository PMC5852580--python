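"""Tandem/segmental classification of duplicate pairs and gene-cluster calling.

Conventions (recorded here because the distance convention changes calls):

* distance between two genes is the nearest-edge gap between their genomic
  spans (0 for overlapping genes), not start-to-start;
* a pair is *tandem* iff it lies on one chromosome within the tandem
  window (default 100 kb, boundary inclusive), otherwise *segmental* —
  cross-chromosome pairs are always segmental;
* a *gene cluster* is a maximal left-to-right run of more than two genes
  whose starts lie within the cluster window (default 200 kb) of the
  run's first gene, all on one chromosome.

Scaffold pseudo-chromosomes (e.g. "00") are ordinary labels for the
same/different-chromosome test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io import FamilyTable, GeneModel

TANDEM_WINDOW_BP = 100_000
CLUSTER_WINDOW_BP = 200_000


@dataclass(frozen=True)
class DuplicatePair:
    id_a: str
    id_b: str
    same_chromosome: bool
    genomic_distance: int | None  # bp nearest-edge; None across chromosomes
    dup_type: str  # "tandem" | "segmental"


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    members: tuple[str, ...]
    span: int  # bp from first start to last end, inclusive


def genomic_distance(a: GeneModel, b: GeneModel) -> int | None:
    """Nearest-edge gap in bp between two gene spans; None across chromosomes."""
    if a.chromosome != b.chromosome:
        return None
    if a.start > b.start:
        a, b = b, a
    return b.start - a.end if b.start > a.end else 0


def classify_pair(
    a: GeneModel, b: GeneModel, tandem_window: int = TANDEM_WINDOW_BP
) -> DuplicatePair:
    """Classify one duplicate pair as tandem or segmental.

    Symmetric in argument order; tandem iff same chromosome and
    nearest-edge distance <= ``tandem_window``.
    """
    if a.gene_id == b.gene_id:
        raise ValidationError(f"cannot classify {a.gene_id!r} against itself")
    dist = genomic_distance(a, b)
    same = dist is not None
    tandem = same and dist <= tandem_window
    id_a, id_b = sorted((a.gene_id, b.gene_id))
    return DuplicatePair(
        id_a=id_a,
        id_b=id_b,
        same_chromosome=same,
        genomic_distance=dist,
        dup_type="tandem" if tandem else "segmental",
    )


def find_clusters(
    family: FamilyTable,
    cluster_window: int = CLUSTER_WINDOW_BP,
    min_genes: int = 3,
) -> list[GeneCluster]:
    """Greedy left-to-right sweep for gene clusters on each chromosome.

    Genes are sorted by start; a run is anchored at its first (leftmost
    unassigned) gene and extends over consecutive genes whose start lies
    within ``cluster_window`` of the anchor's start.  Runs with at least
    ``min_genes`` members are reported; no gene belongs to two clusters.
    """
    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in family:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        i = 0
        while i < len(genes):
            anchor = genes[i]
            j = i + 1
            while j < len(genes) and genes[j].start - anchor.start <= cluster_window:
                j += 1
            run = genes[i:j]
            if len(run) >= min_genes:
                clusters.append(
                    GeneCluster(
                        chromosome=chrom,
                        members=tuple(g.gene_id for g in run),
                        span=run[-1].end - run[0].start + 1,
                    )
                )
            i = j
    return clusters


def classify_family_pairs(
    family: FamilyTable,
    pairs: list[tuple[str, str]],
    tandem_window: int = TANDEM_WINDOW_BP,
) -> list[DuplicatePair]:
    """Classify a list of (id_a, id_b) duplicate pairs against the family."""
    return [
        classify_pair(family[a], family[b], tandem_window) for a, b in pairs
    ]


def duplication_report(pairs: list[DuplicatePair]) -> tuple[Counter, pd.DataFrame]:
    """Counts by duplication type plus the per-pair TSV-ready table."""
    counts = Counter(p.dup_type for p in pairs)
    df = pd.DataFrame(
        [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "same_chromosome": p.same_chromosome,
                "distance_bp": "" if p.genomic_distance is None else p.genomic_distance,
                "dup_type": p.dup_type,
            }
            for p in pairs
        ]
    )
    return counts, df


def cluster_report(clusters: list[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": c.chromosome,
                "n_genes": len(c.members),
                "members": ",".join(c.members),
                "span_bp": c.span,
            }
            for c in clusters
        ]
    )
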