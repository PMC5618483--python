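"""Gene models: exon/intron organisation, intron phases and structure summaries.

Coordinates follow the GFF3 convention throughout: 1-based, closed intervals
on the forward genomic strand.  Within a :class:`GeneModel`, exon/CDS/UTR
segment lists are ordered in *transcript* orientation (5'->3' of the mRNA),
so for minus-strand genes the first exon is the one with the largest genomic
coordinates.

The intron *phase* is the position of the intron relative to codon
boundaries: phase 0 falls between codons, phase 1 after the first base of a
codon, phase 2 after the second.  Equivalently, phase_i = (cumulative CDS
length upstream of intron i) mod 3.  Introns that do not interrupt the CDS
(fully within a UTR) carry no phase and are flagged non-coding.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

Segment = tuple[int, int]  # 1-based closed genomic interval


class GffParseError(ValueError):
    """Raised for structurally invalid gene annotations."""


@dataclass
class Intron:
    start: int          # genomic, 1-based closed
    end: int
    size: int
    phase: int | None   # 0/1/2, or None for non-coding introns
    coding: bool


@dataclass
class GeneModel:
    gene_id: str
    mrna_id: str
    chrom: str
    strand: str
    exons: list[Segment]          # transcript orientation
    cds: list[Segment] = field(default_factory=list)
    utr5: list[Segment] = field(default_factory=list)
    utr3: list[Segment] = field(default_factory=list)
    cds_incomplete: bool = False  # set when summed CDS length % 3 != 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GffParseError(f"{self.mrna_id}: bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise GffParseError(f"{self.mrna_id}: overlapping exons")

    # -- basic geometry -------------------------------------------------

    @property
    def span(self) -> Segment:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def location(self) -> str:
        s, e = self.span
        return f"{self.chrom}:{s}-{e}:{self.strand}"

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site (+1)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[0][1]

    @property
    def introns(self) -> list[Intron]:
        phases = intron_phases(self, require_cds=False)
        out = []
        for (a, b), ph in zip(_intron_segments(self), phases):
            out.append(Intron(a, b, b - a + 1, ph, ph is not None))
        return out

    def transcript_sequence(self, genome: dict[str, str]) -> str:
        return _splice(genome[self.chrom], self.exons, self.strand)

    def cds_sequence(self, genome: dict[str, str]) -> str:
        return _splice(genome[self.chrom], self.cds, self.strand)


def _splice(chrom_seq: str, segments: Sequence[Segment], strand: str) -> str:
    parts = [chrom_seq[s - 1:e] for s, e in sorted(segments)]
    seq = "".join(parts)
    if strand == "-":
        seq = _revcomp(seq)
    return seq


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _intron_segments(model: GeneModel) -> list[Segment]:
    """Genomic gaps between transcript-adjacent exons, transcript order."""
    out = []
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        if model.strand == "+":
            out.append((e1 + 1, s2 - 1))
        else:
            out.append((e2 + 1, s1 - 1))
    return out


def intron_phases(model: GeneModel, require_cds: bool = True) -> list[int | None]:
    """Phase of each intron, in transcript order.

    Raises if the model has no CDS (unless ``require_cds`` is false, in which
    case all introns are reported as non-coding ``None``).
    """
    if not model.cds:
        if require_cds:
            raise GffParseError(f"{model.mrna_id}: no CDS annotated")
        return [None] * max(len(model.exons) - 1, 0)
    total = model.cds_length
    phases: list[int | None] = []
    # cumulative CDS bases in exons 1..i (transcript orientation)
    cum = 0
    cds_genomic = sorted(model.cds)
    for exon in model.exons[:-1]:
        s, e = exon
        for cs, ce in cds_genomic:
            lo, hi = max(s, cs), min(e, ce)
            if lo <= hi:
                cum += hi - lo + 1
        if cum == 0 or cum == total:
            phases.append(None)  # intron sits entirely in a UTR
        else:
            phases.append(cum % 3)
    return phases


# -- GFF3 I/O -----------------------------------------------------------


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS/UTR features into one GeneModel per mRNA."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        parent = list(db.parents(mrna, featuretype="gene"))
        gene_id = parent[0].id if parent else mrna.id
        segs: dict[str, list[Segment]] = {
            "exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []
        }
        for child in db.children(mrna.id):
            if child.featuretype in segs:
                segs[child.featuretype].append((child.start, child.end))
        order = (lambda xs: sorted(xs)) if mrna.strand == "+" else (
            lambda xs: sorted(xs, reverse=True))
        model = GeneModel(
            gene_id=gene_id,
            mrna_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=order(segs["exon"]),
            cds=order(segs["CDS"]),
            utr5=order(segs["five_prime_UTR"]),
            utr3=order(segs["three_prime_UTR"]),
        )
        if model.cds and model.cds_length % 3 != 0:
            model.cds_incomplete = True
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        gs, ge = m.span
        lines.append("\t".join([
            m.chrom, "snrkfam", "gene", str(gs), str(ge), ".", m.strand, ".",
            f"ID={m.gene_id}"]))
        lines.append("\t".join([
            m.chrom, "snrkfam", "mRNA", str(gs), str(ge), ".", m.strand, ".",
            f"ID={m.mrna_id};Parent={m.gene_id}"]))
        for s, e in sorted(m.exons):
            lines.append("\t".join([
                m.chrom, "snrkfam", "exon", str(s), str(e), ".", m.strand, ".",
                f"Parent={m.mrna_id}"]))
        # GFF3 CDS phase column: bases to skip to reach the next codon start
        cds_tx = m.cds  # transcript orientation
        cum = 0
        phased = []
        for s, e in cds_tx:
            phased.append((s, e, (3 - cum % 3) % 3))
            cum += e - s + 1
        for s, e, frame in sorted(phased):
            lines.append("\t".join([
                m.chrom, "snrkfam", "CDS", str(s), str(e), ".", m.strand,
                str(frame), f"Parent={m.mrna_id}"]))
        for ftype, seglist in (("five_prime_UTR", m.utr5),
                               ("three_prime_UTR", m.utr3)):
            for s, e in sorted(seglist):
                lines.append("\t".join([
                    m.chrom, "snrkfam", ftype, str(s), str(e), ".", m.strand,
                    ".", f"Parent={m.mrna_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- summaries ----------------------------------------------------------


_NA = "NA"


def structure_summary(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene exon/intron statistics plus a family-level rollup row."""
    if not models:
        raise ValueError("structure_summary needs at least one model")
    rows = []
    all_sizes: list[int] = []
    for m in models:
        sizes = [i.size for i in m.introns]
        all_sizes.extend(sizes)
        rows.append({
            "gene": m.gene_id,
            "location": m.location,
            "exon_count": len(m.exons),
            "intron_count": len(m.exons) - 1,
            "min_intron_bp": min(sizes) if sizes else _NA,
            "max_intron_bp": max(sizes) if sizes else _NA,
            "transcript_length_bp": m.transcript_length,
            "intron_phases": ",".join(
                "nc" if p is None else str(p)
                for p in intron_phases(m, require_cds=False)),
        })
    rows.append({
        "gene": "FAMILY",
        "location": _NA,
        "exon_count": _NA,
        "intron_count": _NA,
        "min_intron_bp": min(all_sizes) if all_sizes else _NA,
        "max_intron_bp": max(all_sizes) if all_sizes else _NA,
        "transcript_length_bp": _NA,
        "intron_phases": _NA,
    })
    return pd.DataFrame(rows)
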