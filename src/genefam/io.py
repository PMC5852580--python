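"""Readers and writers for the pipeline's external data.

Three input dialects are supported: FASTA for CDS/protein sequences,
a delimited gene-coordinate table (comma or tab, sniffed from the header
line), and a CSV table of qPCR quantification cycles (Cq).  All report
outputs are TSV with a header row.

Coordinates are 1-based inclusive throughout, matching how gene models
are printed in genome-database tables; distance arithmetic converts
internally but reports in bp.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    ReferenceError_,
    SchemaError,
    SequenceError,
    ValidationError,
)

NUCLEOTIDES = set("ACGT")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}  # unicode minus tolerated


@dataclass
class GeneModel:
    """One member of a gene family: coordinates plus optional sequences.

    ``start``/``end`` are 1-based inclusive base positions; ``end >= start``.
    A CDS, when attached, must be in frame (length divisible by 3) with no
    internal stop codon; a single terminal stop codon is tolerated and the
    translation check trims it.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        self.strand = _STRAND_ALIASES.get(self.strand, self.strand)
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.gene_id}: unknown strand symbol {self.strand!r}"
            )
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise ValidationError(f"{self.gene_id}: coordinates must be integers")
        if self.start < 1:
            raise ValidationError(
                f"{self.gene_id}: start {self.start} < 1 (coordinates are 1-based)"
            )
        if self.end < self.start:
            raise ValidationError(
                f"{self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.cds is not None:
            self._check_cds()
        if self.protein is not None:
            self._check_protein()

    def _check_cds(self) -> None:
        cds = self.cds.upper()
        bad = set(cds) - NUCLEOTIDES
        if bad:
            raise SequenceError(
                f"{self.gene_id}: illegal CDS characters {sorted(bad)}"
            )
        if len(cds) % 3 != 0:
            raise SequenceError(
                f"{self.gene_id}: CDS length {len(cds)} not divisible by 3"
            )
        aa = str(Seq(cds).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            pos = aa.index("*")
            raise SequenceError(
                f"{self.gene_id}: internal stop codon at codon {pos + 1}"
            )
        self.cds = cds

    def _check_protein(self) -> None:
        protein = self.protein.upper().rstrip("*")
        bad = set(protein) - AMINO_ACIDS
        if bad:
            raise SequenceError(
                f"{self.gene_id}: illegal protein characters {sorted(bad)}"
            )
        if self.cds is not None:
            n_codons = len(self.cds) // 3
            if len(protein) not in (n_codons, n_codons - 1):
                raise SequenceError(
                    f"{self.gene_id}: protein length {len(protein)} inconsistent "
                    f"with CDS of {n_codons} codons"
                )
        self.protein = protein

    @property
    def span_bp(self) -> int:
        """Genomic footprint in bp (inclusive span)."""
        return self.end - self.start + 1


class FamilyTable:
    """Ordered collection of :class:`GeneModel` with lookup by gene_id."""

    def __init__(self, genes: list[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise DuplicateIdError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise ReferenceError_(f"gene_id {gene_id!r} not in family") from None

    @property
    def ids(self) -> list[str]:
        return list(self._genes)

    def attach_sequences(
        self,
        cds: Mapping[str, str] | None = None,
        protein: Mapping[str, str] | None = None,
    ) -> None:
        """Join CDS/protein FASTA mappings onto the table by gene_id.

        Every family member must be present in each supplied mapping;
        a missing id raises naming the offender.
        """
        for kind, mapping in (("cds", cds), ("protein", protein)):
            if mapping is None:
                continue
            for g in self:
                if g.gene_id not in mapping:
                    raise ReferenceError_(
                        f"{kind} FASTA is missing family member {g.gene_id!r}"
                    )
                setattr(g, kind, mapping[g.gene_id])
                g._check_cds() if kind == "cds" else g._check_protein()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chromosome": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                }
                for g in self
            ]
        )


@dataclass
class CqTable:
    """Replicate qPCR quantification cycles for target and reference genes.

    One row per (gene, line, temperature, time, replicate); ``cq_target``
    and ``cq_reference`` are the cycles at which the target and the
    reference-gene reactions crossed threshold in that well.
    """

    data: pd.DataFrame
    calibrator_time: float = 0.0

    GROUP_COLS = ["line", "temperature", "time"]

    def __post_init__(self) -> None:
        required = ["gene_id", *self.GROUP_COLS, "replicate", "cq_target", "cq_reference"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise SchemaError(
                f"Cq table lacks column(s) {missing}; expected schema: {required} "
                "(optional: organ)"
            )
        for col in ("cq_target", "cq_reference"):
            vals = self.data[col]
            if vals.isna().any():
                raise ValidationError(f"empty cells in {col}")
            if not ((vals > 0) & vals.apply(math.isfinite)).all():
                raise ValidationError(f"{col} values must be finite and > 0")
        times = set(self.data["time"])
        if self.calibrator_time not in times:
            raise ValidationError(
                f"calibrator time point {self.calibrator_time} h absent from table"
            )

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene_id"]))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: str = "nucleotide") -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Ids are the first whitespace-delimited token of each header; sequences
    are uppercased and, for proteins, a single trailing ``*`` is trimmed.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"unknown kind {kind!r}")
    alphabet = NUCLEOTIDES if kind == "nucleotide" else AMINO_ACIDS
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if kind == "protein" and seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in out:
            raise DuplicateIdError(f"{path}: duplicate FASTA id {rec.id!r}")
        bad = set(seq) - alphabet
        if bad:
            raise SequenceError(
                f"{path}: record {rec.id!r} has illegal {kind} characters {sorted(bad)}"
            )
        out[rec.id] = seq
    if not out:
        raise SchemaError(f"{path}: empty or non-FASTA file")
    return out


def write_fasta(mapping: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in mapping.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene-coordinate table


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_gene_table(path: str | Path) -> FamilyTable:
    """Read a delimited gene-coordinate table into a :class:`FamilyTable`.

    Required header columns: gene_id, chromosome, start, end, strand.
    Comma and tab delimiters are both accepted (sniffed from the header).
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["gene_id", "chromosome", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: gene table lacks column(s) {missing}")
    genes = []
    for _, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: non-integer coordinates for {row['gene_id']!r}"
            ) from None
        genes.append(
            GeneModel(
                gene_id=str(row["gene_id"]).strip(),
                chromosome=str(row["chromosome"]).strip(),
                start=start,
                end=end,
                strand=str(row["strand"]).strip(),
            )
        )
    return FamilyTable(genes)


def write_gene_table(family: FamilyTable, path: str | Path) -> None:
    family.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cq table


def read_cq_table(path: str | Path, calibrator_time: float = 0.0) -> CqTable:
    """Read a CSV of replicate Cq measurements.

    The calibrator group defaults to the 0 h time point of each gene's
    own (line, temperature) series unless ``calibrator_time`` overrides it.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    return CqTable(df, calibrator_time=calibrator_time)


def write_cq_table(cq: CqTable, path: str | Path) -> None:
    cq.data.to_csv(path, index=False)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular report as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


def fasta_roundtrip_equal(mapping: Mapping[str, str]) -> bool:
    """True iff write→read is the identity on ``mapping`` (used by tests)."""
    buf = _io.StringIO()
    records = [
        SeqRecord(Seq(s), id=n, description="") for n, s in mapping.items()
    ]
    SeqIO.write(records, buf, "fasta")
    buf.seek(0)
    back = {r.id: str(r.seq) for r in SeqIO.parse(buf, "fasta")}
    return back == dict(mapping)
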