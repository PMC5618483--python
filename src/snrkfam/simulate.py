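"""Synthetic study inputs with known ground truth.

This module fabricates every input the pipeline consumes, at desk scale:

* a toy genome carrying a planted multi-exon kinase family in four groups
  (plus signature-defective and unrelated decoy genes), with GFF3 gene
  models, reverse-translated coding sequences and 2-kb promoters;
* promoter windows reconstructed from the published cis-element placements
  (pattern, upstream position, strand), planted on otherwise catalog-clean
  background;
* tissue count matrices with block-correlated expression;
* qRT-PCR Ct tables with configurable true fold changes and noise.

Every planted feature is recorded in a :class:`TruthTable`, so downstream
stages can be scored without external information.  All randomness flows
from one seed; identical configurations give byte-identical outputs.

The defaults mirror the study design this package emulates: a 22-member
family split 6/4/8/4 over four groups, nine exons/eight introns per gene
except one designated shorter analog, 2-kb promoters, 28 tissues, three
biological replicates and treatment sampling at 0/8/16/24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .promoter import IUPAC, CisElement, load_catalog, scan
from .structure import GeneModel, _revcomp

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# planted kinase signature instances (valid under the bundled PROSITE
# patterns; verified by the generator)
ATP_SIG = "LGSGNFGVARLTDKETGELVVAMK"       # ATP-binding region, residues 10-33
ACT_SIG = "LVHRDLKLENTLL"                  # Ser/Thr active site, residues 119-131
_ATP_AT = 9      # 0-based start offsets in the 340-aa scaffold
_ACT_AT = 118
CORE_LEN = 290
TAIL_LEN = 50
PROT_LEN = CORE_LEN + TAIL_LEN

# cumulative CDS phase after each intron (the family's conserved phasing)
PHASES_9EXON = (0, 2, 0, 0, 1, 2, 0, 0)
PHASES_8EXON = (0, 2, 0, 0, 1, 2, 0)

UTR5_LEN = 120
UTR3_LEN = 150

# standard genetic code, one row per codon (synonymous choice is random)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "*": ["TAA", "TAG", "TGA"],
}


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    seed: int = 42
    family_size: int = 22
    group_sizes: tuple[int, int, int, int] = (6, 4, 8, 4)
    decoy_near: int = 2           # signature-defective near-kinases
    decoy_unrelated: int = 3      # unrelated random genes
    promoter_length: int = 2000
    tissue_count: int = 28
    replicate_count: int = 3
    time_points_h: tuple[float, ...] = (0.0, 8.0, 16.0, 24.0)
    treatments: tuple[str, ...] = ("NaCl", "ABA", "rac-GR24")
    noise_sd_ct: float = 0.2      # cycles; typical qPCR replicate scatter
    background_gc: float = 0.35
    plant_promoter_elements: bool = True
    intron_size_range: tuple[int, int] = (78, 600)
    chromosome_count: int = 5

    def validate(self, catalog: Sequence[CisElement] | None = None) -> None:
        if sum(self.group_sizes) != self.family_size:
            raise ConfigError(
                f"group sizes {self.group_sizes} do not sum to family size "
                f"{self.family_size}")
        if catalog:
            longest = max(len(el.pattern) for el in catalog)
            if self.promoter_length < longest:
                raise ConfigError("promoter shorter than a catalog pattern")
        if self.intron_size_range[0] < 10:
            raise ConfigError("introns need room for splice sites")


@dataclass
class PlantedGene:
    gene_id: str
    group: int
    exon_count: int
    intron_phases: tuple[int, ...]


@dataclass
class TruthTable:
    planted_genes: list[PlantedGene] = field(default_factory=list)
    snrk26_analog: str | None = None         # the designated fewer-intron gene
    planted_elements: list[tuple[str, str, str, int, str]] = field(
        default_factory=list)                # gene, element, pattern, index, strand
    dropped_placements: list[tuple[str, str, str, int, str]] = field(
        default_factory=list)
    expression_blocks: list[tuple[tuple[str, ...], float]] = field(
        default_factory=list)
    qpcr_effects: list[tuple[str, str, float, float]] = field(
        default_factory=list)                # gene, treatment, time_h, true FC
    decoys: dict[str, str] = field(default_factory=dict)  # id -> kind

    @property
    def family_ids(self) -> list[str]:
        return [g.gene_id for g in self.planted_genes]

    def group_of(self) -> dict[str, int]:
        return {g.gene_id: g.group for g in self.planted_genes}


# ---------------------------------------------------------------------------
# bundled study tables


def load_placements() -> pd.DataFrame:
    """Published promoter element placements (gene, group, element, pattern,
    upstream position, strand)."""
    src = resources.files("snrkfam.data") / "promoter_placements.tsv"
    with src.open() as fh:
        return pd.read_csv(fh, sep="\t")


def family_group_map() -> dict[str, int]:
    src = resources.files("snrkfam.data") / "family_groups.tsv"
    with src.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df.gene, df.group))


# ---------------------------------------------------------------------------
# promoter reconstruction


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def gen_promoters(catalog: Sequence[CisElement],
                  placements: pd.DataFrame,
                  genes: Sequence[str] | None = None,
                  length: int = 2000,
                  gc: float = 0.35,
                  seed: int | np.random.Generator = 0,
                  on_conflict: str = "error",
                  ) -> tuple[dict[str, str], TruthTable]:
    """Plant each placement row into an otherwise catalog-clean window.

    A placement (pattern, position N, strand) puts the pattern (its reverse
    complement for minus-strand rows) on the forward window strand with its
    leftmost base at 1-based index N from the window's 5' end, i.e. at
    display position -N.  Overlapping placements must agree base-by-base;
    ``on_conflict`` 'error' raises, 'skip' drops the later row and records
    it.  Background bases are resampled until no catalog match touches them,
    so scanning reproduces exactly the planted occurrences (plus nested /
    mirrored / palindromic consequences of the planted bases themselves).

    ``genes`` may add genes with no placements (clean background windows).
    Returns the windows and a truth table of planted elements.
    """
    if on_conflict not in ("error", "skip"):
        raise ValueError("on_conflict must be 'error' or 'skip'")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    truth = TruthTable()
    windows: dict[str, str] = {}
    all_genes = list(dict.fromkeys(
        list(placements.gene) + list(genes or [])))
    for gene in all_genes:
        rows = placements[placements.gene == gene]
        planted = np.full(length, b"", dtype="S1")
        for row in rows.itertuples(index=False):
            pat = str(row.pattern).upper()
            if set(pat) - set("ACGT"):
                raise GenerationError(
                    f"{gene}: cannot plant ambiguous pattern {pat!r}")
            seq = pat if row.strand == "+" else _revcomp(pat)
            idx = int(row.position)
            if idx < 1 or idx + len(seq) - 1 > length:
                raise ConfigError(
                    f"{gene}: placement at {idx} outside 1..{length}")
            lo = idx - 1
            old = planted[lo:lo + len(seq)]
            new = np.frombuffer(seq.encode(), dtype="S1")
            clash = (old != b"") & (old != new)
            if clash.any():
                if on_conflict == "error":
                    raise GenerationError(
                        f"{gene}: placement {row.element} {pat} at -{idx} "
                        f"({row.strand}) conflicts with earlier planted bases")
                truth.dropped_placements.append(
                    (gene, row.element, pat, idx, row.strand))
                continue
            planted[lo:lo + len(seq)] = new
            truth.planted_elements.append(
                (gene, row.element, pat, idx, row.strand))
        windows[gene] = _fill_background(planted, catalog, rng, gc)
    return windows, truth


def _fill_background(planted: np.ndarray, catalog: Sequence[CisElement],
                     rng: np.random.Generator, gc: float,
                     max_iter: int = 20000) -> str:
    """Fill unplanted positions so that no catalog hit touches background."""
    length = planted.size
    is_planted = planted != b""
    chars = planted.copy()
    bg = ~is_planted
    chars[bg] = _random_dna(rng, int(bg.sum()), gc)
    for _ in range(max_iter):
        window = chars.tobytes().decode()
        offending: list[int] = []
        for h in scan(window, catalog):
            span = np.arange(h.span[0] - 1, h.span[1])
            if not is_planted[span].all():
                offending.extend(int(k) for k in span if not is_planted[k])
        if not offending:
            return window
        pos = sorted(set(offending))
        chars[pos] = _random_dna(rng, len(pos), gc)
    raise GenerationError("background resampling failed to converge")


# ---------------------------------------------------------------------------
# protein scaffolds


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protect: tuple[tuple[int, int], ...] = ()) -> str:
    """Point substitutions at the given per-site rate, sparing protected
    0-based [start, end) windows."""
    chars = list(seq)
    shielded = set()
    for a, b in protect:
        shielded.update(range(a, b))
    for i in range(len(chars)):
        if i in shielded:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != chars[i]]
            chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


_SIG_WINDOWS = ((_ATP_AT, _ATP_AT + len(ATP_SIG)),
                (_ACT_AT, _ACT_AT + len(ACT_SIG)))

_TAIL_COMPOSITION = {
    1: {"E": 0.30},    # Glu-rich C-terminal (group 1)
    2: {"D": 0.30},    # Asp-rich (groups 2 and 3)
    3: {"D": 0.30},
    4: {},             # no D/E enrichment (group 4)
}


def _group_tail(group: int, rng: np.random.Generator) -> str:
    enrich = _TAIL_COMPOSITION[group]
    if enrich:
        (aa, frac), = enrich.items()
        others = [a for a in AA20 if a != aa]
        p_other = (1 - frac) / len(others)
        letters = [aa] + others
        probs = [frac] + [p_other] * len(others)
    else:
        letters = [a for a in AA20 if a not in "DE"]
        probs = [1 / len(letters)] * len(letters)
    return "".join(rng.choice(letters, size=TAIL_LEN, p=probs))


def _family_scaffold(rng: np.random.Generator) -> str:
    core = list(_random_protein(rng, PROT_LEN))
    core[_ATP_AT:_ATP_AT + len(ATP_SIG)] = ATP_SIG
    core[_ACT_AT:_ACT_AT + len(ACT_SIG)] = ACT_SIG
    return "".join(core)


@dataclass
class ReferenceSet:
    """Reference proteomes (family plus non-family kinases) with labels."""
    proteomes: dict[str, dict[str, str]]      # species -> id -> sequence
    family_labels: dict[str, bool]
    groups: dict[str, int]                    # family references only

    @property
    def queries(self) -> dict[str, str]:
        """The labelled family reference peptides (the screen queries)."""
        out = {}
        for proteome in self.proteomes.values():
            for pid, seq in proteome.items():
                if self.family_labels.get(pid):
                    out[pid] = seq
        return out


# reference family composition: first species spans groups 1-3 only, the
# second contributes the sole group-4 anchor, mirroring the study's
# reference species
_REF_PLAN = {
    "Athaliana": {1: 3, 2: 3, 3: 4, 4: 0},
    "Osativa": {1: 2, 2: 3, 3: 4, 4: 1},
}
_REF_PREFIX = {"Athaliana": "AtSnRK2.", "Osativa": "OsSAPK"}
_NONFAM = {"Athaliana": ("AtCIPK1", "AtCDPK3"),
           "Osativa": ("OsCIPK2", "OsCDPK7")}

# per-site substitution rates of the sequence hierarchy
_RATE_GROUP = 0.10      # family ancestor -> group ancestor
_RATE_GENE = 0.05       # group ancestor -> family gene
_RATE_REF = 0.08        # group ancestor -> reference family protein
_RATE_NONFAM = 0.40     # family ancestor -> non-family kinase ancestor
_RATE_NEAR = 0.15       # family ancestor -> near-kinase decoy


def _check_signatures(seq: str, want_atp: bool, want_act: bool) -> bool:
    from .identify import load_signatures
    sigs = {s.name: s for s in load_signatures()}
    has_atp = sigs["IPR017441"].search(seq) is not None
    has_act = sigs["IPR008271"].search(seq) is not None
    return has_atp == want_atp and has_act == want_act


def make_family_proteins(config: GeneratorConfig, rng: np.random.Generator,
                         gene_ids: Mapping[str, int],
                         ) -> tuple[dict[str, str], ReferenceSet, dict[str, str]]:
    """Family peptides, reference proteomes and decoy peptides.

    ``gene_ids`` maps family gene id -> group.  Returns (family proteins,
    references, decoy proteins).
    """
    ancestor = _family_scaffold(rng)
    group_anc = {}
    for g in (1, 2, 3, 4):
        anc = _mutate(ancestor, _RATE_GROUP, rng, _SIG_WINDOWS)
        anc = anc[:CORE_LEN] + _group_tail(g, rng)
        group_anc[g] = anc

    family: dict[str, str] = {}
    for gid, g in gene_ids.items():
        seq = _mutate(group_anc[g], _RATE_GENE, rng, _SIG_WINDOWS)
        seq = seq[:CORE_LEN] + _group_tail(g, rng)
        if not _check_signatures(seq, True, True):   # pragma: no cover
            raise GenerationError(f"{gid}: signature lost during mutation")
        family[gid] = seq

    proteomes: dict[str, dict[str, str]] = {}
    labels: dict[str, bool] = {}
    ref_groups: dict[str, int] = {}
    nonfam_anc = _mutate(ancestor, _RATE_NONFAM, rng)
    for species, plan in _REF_PLAN.items():
        proteome: dict[str, str] = {}
        k = 1
        for g, count in plan.items():
            for _ in range(count):
                rid = f"{_REF_PREFIX[species]}{k}"
                seq = _mutate(group_anc[g], _RATE_REF, rng, _SIG_WINDOWS)
                seq = seq[:CORE_LEN] + _group_tail(g, rng)
                proteome[rid] = seq
                labels[rid] = True
                ref_groups[rid] = g
                k += 1
        for rid in _NONFAM[species]:
            proteome[rid] = _mutate(nonfam_anc, 0.05, rng)
            labels[rid] = False
        proteomes[species] = proteome

    decoys: dict[str, str] = {}
    for i in range(config.decoy_near):
        seq = _mutate(ancestor, _RATE_NEAR, rng, _SIG_WINDOWS[:1])
        # destroy the active-site signature, keep the ATP-binding one
        for _ in range(50):
            repl = _random_protein(rng, len(ACT_SIG))
            cand = seq[:_ACT_AT] + repl + seq[_ACT_AT + len(ACT_SIG):]
            if _check_signatures(cand, True, False):
                seq = cand
                break
        else:   # pragma: no cover
            raise GenerationError("could not build a signature-defective decoy")
        decoys[f"NearKinase.{i + 1}"] = seq
    for i in range(config.decoy_unrelated):
        decoys[f"Unrelated.{i + 1}"] = _random_protein(rng, 330)
    return family, ReferenceSet(proteomes, labels, ref_groups), decoys


# ---------------------------------------------------------------------------
# genome assembly


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))]
              for aa in protein + "*"]
    return "".join(codons)


def _cds_cuts(cds_len: int, phases: Sequence[int]) -> list[int]:
    """Cumulative CDS lengths at each intron, realising the phase pattern."""
    n_exons = len(phases) + 1
    cuts = []
    for i, ph in enumerate(phases, start=1):
        c = round(cds_len * i / n_exons)
        c += (ph - c) % 3
        cuts.append(c)
    if any(b <= a for a, b in zip(cuts, cuts[1:])) or cuts[-1] >= cds_len:
        raise GenerationError("exon plan failed")   # pragma: no cover
    return cuts


@dataclass
class _Cassette:
    """A gene on its coding strand: promoter, exons, introns, UTRs."""
    seq: str
    exons: list[tuple[int, int]]      # cassette coords, 1-based closed
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]
    promoter: str
    phases: tuple[int, ...]


def _build_cassette(protein: str, promoter: str, phases: Sequence[int],
                    config: GeneratorConfig,
                    rng: np.random.Generator) -> _Cassette:
    cds = _reverse_translate(protein, rng)
    cuts = _cds_cuts(len(cds), phases)
    bounds = [0] + cuts + [len(cds)]
    cds_parts = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    utr5 = _random_dna(rng, UTR5_LEN, config.background_gc).tobytes().decode()
    utr3 = _random_dna(rng, UTR3_LEN, config.background_gc).tobytes().decode()
    lo, hi = config.intron_size_range
    introns = []
    for _ in range(len(cds_parts) - 1):
        size = int(rng.integers(lo, hi + 1))
        inner = _random_dna(rng, size - 4, config.background_gc).tobytes().decode()
        introns.append("GT" + inner + "AG")

    pos = len(promoter)          # last filled position (1-based count)
    seq_parts = [promoter]
    exons, cds_iv, utr5_iv, utr3_iv = [], [], [], []
    for i, part in enumerate(cds_parts):
        exon_seq = part
        if i == 0:
            exon_seq = utr5 + exon_seq
        if i == len(cds_parts) - 1:
            exon_seq = exon_seq + utr3
        start = pos + 1
        end = pos + len(exon_seq)
        exons.append((start, end))
        if i == 0:
            utr5_iv.append((start, start + UTR5_LEN - 1))
            cds_iv.append((start + UTR5_LEN, start + UTR5_LEN + len(part) - 1))
        elif i == len(cds_parts) - 1:
            cds_iv.append((start, start + len(part) - 1))
            utr3_iv.append((start + len(part), end))
        else:
            cds_iv.append((start, end))
        seq_parts.append(exon_seq)
        pos = end
        if i < len(introns):
            seq_parts.append(introns[i])
            pos += len(introns[i])
    return _Cassette("".join(seq_parts), exons, cds_iv, utr5_iv, utr3_iv,
                     promoter, tuple(phases))


def _place(cassette: _Cassette, gene_id: str, chrom: str, offset: int,
           strand: str) -> GeneModel:
    """Genomic GeneModel for a cassette inserted at 1-based ``offset``."""
    L = len(cassette.seq)

    def map_iv(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        if strand == "+":
            return (offset + a - 1, offset + b - 1)
        return (offset + L - b, offset + L - a)

    order = (lambda xs: sorted(xs)) if strand == "+" else (
        lambda xs: sorted(xs, reverse=True))
    return GeneModel(
        gene_id=gene_id, mrna_id=f"{gene_id}.t1", chrom=chrom, strand=strand,
        exons=order([map_iv(iv) for iv in cassette.exons]),
        cds=order([map_iv(iv) for iv in cassette.cds]),
        utr5=order([map_iv(iv) for iv in cassette.utr5]),
        utr3=order([map_iv(iv) for iv in cassette.utr3]),
    )


@dataclass
class SyntheticGenome:
    genome: dict[str, str]
    models: list[GeneModel]
    proteins: dict[str, str]          # ground-truth peptides, family + decoys
    references: ReferenceSet
    truth: TruthTable
    promoters: dict[str, str]         # planted windows, by gene id


def _family_gene_ids(config: GeneratorConfig) -> dict[str, int]:
    """Family gene ids by group.  With the study's 6/4/8/4 layout the
    published gene names are reused so the bundled promoter placements apply
    directly; otherwise neutral synthetic ids are minted."""
    published = family_group_map()
    if tuple(config.group_sizes) == (6, 4, 8, 4) and config.family_size == 22:
        return published
    ids: dict[str, int] = {}
    for g, size in enumerate(config.group_sizes, start=1):
        for k in range(size):
            ids[f"SynSnRK2.G{g}.{k + 1}"] = g
    return ids


def gen_genome(config: GeneratorConfig | None = None) -> SyntheticGenome:
    """Generate the toy genome, gene models, peptides and truth table."""
    config = config or GeneratorConfig()
    catalog = load_catalog()
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)

    gene_ids = _family_gene_ids(config)
    family, references, decoys = make_family_proteins(config, rng, gene_ids)

    # promoters: family genes get the published placements when applicable
    placements = load_placements()
    if not set(gene_ids) >= set(placements.gene.unique()):
        placements = placements.iloc[0:0]
    windows, ptruth = gen_promoters(
        catalog, placements if config.plant_promoter_elements
        else placements.iloc[0:0],
        genes=list(gene_ids) + list(decoys),
        length=config.promoter_length, gc=config.background_gc,
        seed=rng, on_conflict="skip")

    truth = TruthTable(
        planted_elements=ptruth.planted_elements,
        dropped_placements=ptruth.dropped_placements,
        decoys={d: ("near_kinase" if d.startswith("NearKinase") else "unrelated")
                for d in decoys},
    )

    # the designated shorter analog: the first group-2 gene (the published
    # name GmSnRK2.6 under the study layout)
    group2 = [gid for gid, g in gene_ids.items() if g == 2]
    analog = "GmSnRK2.6" if "GmSnRK2.6" in gene_ids else (
        group2[0] if group2 else None)
    truth.snrk26_analog = analog

    chrom_names = [f"Chr{c + 1:02d}" for c in range(config.chromosome_count)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_pos: dict[str, int] = {c: 0 for c in chrom_names}
    models: list[GeneModel] = []
    all_prots = {**family, **decoys}

    for k, (gid, prot) in enumerate(all_prots.items()):
        phases = PHASES_8EXON if gid == analog else PHASES_9EXON
        cassette = _build_cassette(prot, windows[gid], phases, config, rng)
        chrom = chrom_names[k % len(chrom_names)]
        strand = "+" if (k // len(chrom_names)) % 2 == 0 else "-"
        pad = _random_dna(rng, 200, config.background_gc).tobytes().decode()
        chrom_parts[chrom].append(pad)
        chrom_pos[chrom] += len(pad)
        insert = cassette.seq if strand == "+" else _revcomp(cassette.seq)
        offset = chrom_pos[chrom] + 1
        chrom_parts[chrom].append(insert)
        chrom_pos[chrom] += len(insert)
        models.append(_place(cassette, gid, chrom, offset, strand))
        if gid in family:
            truth.planted_genes.append(PlantedGene(
                gid, gene_ids[gid], len(cassette.exons), cassette.phases))

    for c in chrom_names:
        tail = _random_dna(rng, 200, config.background_gc).tobytes().decode()
        chrom_parts[c].append(tail)
    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}

    truth.expression_blocks = default_expression_blocks(truth)
    truth.qpcr_effects = default_qpcr_effects(truth, config)
    return SyntheticGenome(genome, models, all_prots, references, truth,
                           windows)


# ---------------------------------------------------------------------------
# expression counts


def default_expression_blocks(truth: TruthTable,
                              block_size: int = 4, n_blocks: int = 3,
                              target: float = 0.9
                              ) -> list[tuple[tuple[str, ...], float]]:
    fam = truth.family_ids
    blocks = []
    for b in range(n_blocks):
        members = tuple(fam[b * block_size:(b + 1) * block_size])
        if len(members) == block_size:
            blocks.append((members, target))
    return blocks


def gen_expression(config: GeneratorConfig, truth: TruthTable,
                   lengths: Mapping[str, int] | None = None,
                   seed: int | np.random.Generator | None = None,
                   ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Block-correlated tissue count matrix.

    Genes inside a block share a latent log-scale profile with the block's
    target correlation; other genes are independent.  Returns (counts,
    gene lengths in bp, per-tissue library totals).
    """
    if config.tissue_count < 2:
        raise ConfigError("need at least two tissues for correlations")
    for _, rho in truth.expression_blocks:
        if not -1 < rho < 1:
            raise ConfigError(f"correlation target {rho} outside (-1, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed + 1 if seed is None else seed))
    genes = truth.family_ids
    tissues = [f"tissue_{t + 1:02d}" for t in range(config.tissue_count)]
    block_of: dict[str, int] = {}
    rho_of: dict[str, float] = {}
    for b, (members, rho) in enumerate(truth.expression_blocks):
        for g in members:
            block_of[g] = b
            rho_of[g] = rho
    latents = rng.standard_normal((len(truth.expression_blocks),
                                   config.tissue_count))
    log2fpkm = np.zeros((len(genes), config.tissue_count))
    for i, g in enumerate(genes):
        noise = rng.standard_normal(config.tissue_count)
        mu = rng.uniform(3.0, 8.0)
        if g in block_of:
            rho = rho_of[g]
            x = np.sqrt(rho) * latents[block_of[g]] + np.sqrt(1 - rho) * noise
        else:
            x = noise
        log2fpkm[i] = mu + x
    if lengths is None:
        lengths = {g: 1500 for g in genes}
    L = pd.Series({g: lengths[g] for g in genes}, name="length_bp")
    totals = pd.Series(
        np.round(2e7 * rng.uniform(0.8, 1.2, size=config.tissue_count)),
        index=tissues, name="mapped_fragments")
    fpkm_true = 2.0 ** log2fpkm
    counts = np.floor(fpkm_true * L.to_numpy()[:, None]
                      * totals.to_numpy()[None, :] / 1e9).astype(int)
    return (pd.DataFrame(counts, index=genes, columns=tissues), L, totals)


# ---------------------------------------------------------------------------
# qRT-PCR Ct tables


REFERENCE_GENE = "GmSKIP"


def default_qpcr_effects(truth: TruthTable, config: GeneratorConfig
                         ) -> list[tuple[str, str, float, float]]:
    """Deterministic true fold changes emulating the study's salient
    responses: two strong salt inductions (~13- and ~18-fold at 8 h), a
    late-rising and a falling hormone response, an SL-induced and an
    SL-repressed gene; everything else flat (FC 1)."""
    by_group: dict[int, list[str]] = {}
    for g in truth.planted_genes:
        by_group.setdefault(g.group, []).append(g.gene_id)
    effects: list[tuple[str, str, float, float]] = []

    def add(gene: str, trt: str, series: dict[float, float]) -> None:
        for t, fc in series.items():
            effects.append((gene, trt, t, fc))

    g1, g3, g4 = by_group.get(1, []), by_group.get(3, []), by_group.get(4, [])
    g2 = by_group.get(2, [])
    if g1:
        add(g1[0], "NaCl", {8.0: 13.0, 16.0: 4.0, 24.0: 1.5})
    if g4:
        add(g4[0], "NaCl", {8.0: 18.0, 16.0: 6.0, 24.0: 2.5})
    if g2:
        add(g2[0], "ABA", {8.0: 1.5, 16.0: 3.0, 24.0: 7.1})
    if g3:
        add(g3[0], "ABA", {8.0: 3.9, 16.0: 0.4, 24.0: 0.5})
    if len(g1) > 1:
        add(g1[1], "rac-GR24", {8.0: 2.5, 16.0: 4.0, 24.0: 5.0})
    if len(g3) > 1:
        add(g3[1], "rac-GR24", {8.0: 0.8, 16.0: 0.3, 24.0: 0.1})
    return effects


def gen_qpcr(config: GeneratorConfig, truth: TruthTable,
             effects: Sequence[tuple[str, str, float, float]] | None = None,
             seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Ct table (gene, treatment, time_h, replicate, ct).

    The reference gene is constant up to noise; a target with true fold
    change FC at (treatment, time) has its Ct shifted by -log2(FC) relative
    to the untreated control.  Three replicates per condition by default.
    """
    effects = truth.qpcr_effects if effects is None else list(effects)
    fc_map: dict[tuple[str, str, float], float] = {}
    for gene, trt, t, fc in effects:
        if fc <= 0:
            raise ConfigError(f"fold change must be positive ({gene}, {trt})")
        fc_map[(gene, trt, t)] = fc
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(config.seed + 2 if seed is None else seed))
    genes = truth.family_ids
    baselines = {g: 24.0 + 0.7 * (i % 5) for i, g in enumerate(genes)}
    rows = []
    conditions = ["control"] + list(config.treatments)
    for trt in conditions:
        for t in config.time_points_h:
            for rep in range(1, config.replicate_count + 1):
                noise = rng.normal(0.0, config.noise_sd_ct)
                rows.append({"gene": REFERENCE_GENE, "treatment": trt,
                             "time_h": t, "replicate": rep,
                             "ct": 20.0 + noise})
                for g in genes:
                    fc = 1.0 if trt == "control" else fc_map.get((g, trt, t), 1.0)
                    noise = rng.normal(0.0, config.noise_sd_ct)
                    rows.append({"gene": g, "treatment": trt, "time_h": t,
                                 "replicate": rep,
                                 "ct": baselines[g] - np.log2(fc) + noise})
    return pd.DataFrame(rows, columns=["gene", "treatment", "time_h",
                                       "replicate", "ct"])


# ---------------------------------------------------------------------------
# file output


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fixture_set(syn: SyntheticGenome, config: GeneratorConfig,
                      outdir: str | Path) -> dict[str, Path]:
    """Write the complete synthetic input bundle as plain-text files."""
    from .structure import write_gff3
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fasta"
    write_fasta(syn.genome, paths["genome"])
    paths["gff3"] = outdir / "genes.gff3"
    write_gff3(syn.models, paths["gff3"])
    paths["proteins"] = outdir / "proteins.faa"
    write_fasta(syn.proteins, paths["proteins"])
    paths["promoters"] = outdir / "promoters.fasta"
    write_fasta(syn.promoters, paths["promoters"])

    for species, proteome in syn.references.proteomes.items():
        paths[f"ref_{species}"] = outdir / f"reference_{species}.faa"
        write_fasta(proteome, paths[f"ref_{species}"])
    labels = pd.DataFrame(
        [{"protein": pid, "family": int(flag),
          "group": syn.references.groups.get(pid, 0)}
         for proteome in syn.references.proteomes.values()
         for pid, flag in ((p, syn.references.family_labels[p])
                           for p in proteome)])
    paths["ref_labels"] = outdir / "reference_labels.tsv"
    labels.to_csv(paths["ref_labels"], sep="\t", index=False)

    counts, lengths, totals = gen_expression(config, syn.truth)
    paths["counts"] = outdir / "counts.tsv"
    counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    paths["lengths"] = outdir / "gene_lengths.tsv"
    lengths.rename_axis("gene").to_csv(paths["lengths"], sep="\t")
    paths["totals"] = outdir / "library_totals.tsv"
    totals.rename_axis("sample").to_csv(paths["totals"], sep="\t")

    ct = gen_qpcr(config, syn.truth)
    paths["ct"] = outdir / "ct_values.tsv"
    ct.to_csv(paths["ct"], sep="\t", index=False)

    tt = pd.DataFrame([{
        "gene": g.gene_id, "group": g.group, "exon_count": g.exon_count,
        "intron_phases": ",".join(map(str, g.intron_phases)),
    } for g in syn.truth.planted_genes])
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    tt.to_csv(paths["truth_genes"], sep="\t", index=False)
    pe = pd.DataFrame(syn.truth.planted_elements,
                      columns=["gene", "element", "pattern", "index", "strand"])
    paths["truth_elements"] = outdir / "truth_elements.tsv"
    pe.to_csv(paths["truth_elements"], sep="\t", index=False)
    return paths
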