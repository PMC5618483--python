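"""Promoter extraction and cis-regulatory element scanning.

Promoters are the 2-kb windows upstream of the transcription start site
(TSS, +1), taken on the gene's coding strand with the window's 3' end
abutting the TSS.  Hits are reported PlantCARE-style: the 1-based index of
the match from the window's 5' end, displayed as a negative upstream offset
(index 516 -> "-516"), plus the strand of the matching pattern.  A
minus-strand hit means the forward window holds the pattern's reverse
complement at that index; it is reported at the leftmost forward-strand
position of the span.

All overlapping and nested occurrences are reported.  Palindromic patterns
(equal to their own reverse complement) would otherwise yield a mirrored
duplicate at every site and are deduplicated to a single forward-strand hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .structure import GeneModel, _revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class CatalogError(ValueError):
    """Raised for malformed cis-element catalogs or patterns."""


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    return pattern.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class CisElement:
    name: str
    pattern: str      # 5'->3', IUPAC codes allowed
    function: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise CatalogError(f"{self.name}: empty pattern")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise CatalogError(f"{self.name}: invalid IUPAC code(s) {bad}")

    @property
    def palindromic(self) -> bool:
        return self.pattern == revcomp_pattern(self.pattern)


@dataclass(frozen=True)
class ElementHit:
    gene: str
    element: str
    pattern: str      # catalog pattern as written 5'->3'
    index: int        # 1-based from the window's 5' end (leftmost of span)
    strand: str       # '+' or '-'

    @property
    def display_position(self) -> int:
        return -self.index

    @property
    def span(self) -> tuple[int, int]:
        """Forward-strand 1-based closed span of the matched bases."""
        return (self.index, self.index + len(self.pattern) - 1)


def load_catalog(path: str | Path | None = None) -> list[CisElement]:
    """Load a cis-element catalog TSV (element, pattern, function).

    With no path, loads the bundled catalog of hormone-response elements
    reported for the soybean SnRK2 promoters.
    """
    if path is None:
        src = resources.files("snrkfam.data") / "cis_elements.tsv"
        with src.open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out = [CisElement(r.element, r.pattern, getattr(r, "function", ""))
           for r in df.itertuples(index=False)]
    return out


@lru_cache(maxsize=4096)
def _compile(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    body = "".join(f"[{IUPAC[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def scan(window: str, catalog: Sequence[CisElement], gene: str = "") -> list[ElementHit]:
    """Report every catalog-pattern occurrence in ``window`` on both strands.

    ``window`` is the promoter on the gene's coding strand, over A/C/G/T/N
    (N never matches).  Hits are sorted by index, then element name, then
    strand ('+' before '-').
    """
    window = window.upper()
    hits: list[ElementHit] = []
    for el in catalog:
        for m in _compile(el.pattern).finditer(window):
            hits.append(ElementHit(gene, el.name, el.pattern, m.start() + 1, "+"))
        if not el.palindromic:
            rc = revcomp_pattern(el.pattern)
            for m in _compile(rc).finditer(window):
                hits.append(ElementHit(gene, el.name, el.pattern, m.start() + 1, "-"))
    hits.sort(key=lambda h: (h.index, h.element, h.strand))
    return hits


def extract_promoter(genome: Mapping[str, str], model: GeneModel,
                     length: int = 2000) -> str:
    """2-kb (by default) window upstream of the TSS, on the coding strand.

    Truncated windows (gene near a chromosome edge) are returned shorter; a
    gene with zero upstream sequence is an error.
    """
    chrom = genome[model.chrom]
    tss = model.tss
    if model.strand == "+":
        start = max(tss - length, 1)
        window = chrom[start - 1:tss - 1]
    else:
        end = min(tss + length, len(chrom))
        window = _revcomp(chrom[tss:end])
    if not window:
        raise ValueError(f"{model.gene_id}: no upstream sequence before TSS")
    return window


def hits_to_frame(hits: Iterable[ElementHit]) -> pd.DataFrame:
    rows = [{
        "gene": h.gene, "element": h.element, "pattern": h.pattern,
        "position": h.display_position, "strand": h.strand,
        "span_start": h.span[0], "span_end": h.span[1],
    } for h in hits]
    cols = ["gene", "element", "pattern", "position", "strand",
            "span_start", "span_end"]
    return pd.DataFrame(rows, columns=cols)


def hits_to_bed(hits: Iterable[ElementHit], window_length: int = 2000) -> pd.DataFrame:
    """BED-like 0-based half-open forward-strand intervals within the window."""
    rows = [{
        "chrom": h.gene, "start": h.span[0] - 1, "end": h.span[1],
        "name": h.element, "score": 0, "strand": h.strand,
    } for h in hits]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def summarize(hits: Iterable[ElementHit],
              group_map: Mapping[str, int | str]) -> pd.DataFrame:
    """Per-gene element counts, ABRE presence, and group labels.

    Every gene in ``group_map`` appears in the output even with zero hits,
    so family-level rollups (e.g. ABRE-free groups) are explicit.
    """
    hits = list(hits)
    unknown = {h.gene for h in hits} - set(group_map)
    if unknown:
        raise KeyError(f"hits for genes missing from group map: {sorted(unknown)}")
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        counts[(h.gene, h.element)] = counts.get((h.gene, h.element), 0) + 1
    elements = sorted({el for _, el in counts})
    rows = []
    for gene, group in group_map.items():
        row: dict[str, object] = {"gene": gene, "group": group}
        for el in elements:
            row[el] = counts.get((gene, el), 0)
        row["has_ABRE"] = counts.get((gene, "ABRE"), 0) > 0
        rows.append(row)
    return pd.DataFrame(rows)
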