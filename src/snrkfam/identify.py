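"""Family identification: homology screen, reciprocal best hit, domain check.

The identification procedure mirrors the classic gene-family workflow:

1. *screen* - every reference SnRK2 peptide is aligned locally against every
   translated candidate gene model; candidates with at least one hit at
   E <= 1e-5 (database-style search space) are retained.
2. *reciprocal best hit* - a retained candidate is kept only if its best hit
   within each full reference proteome (family plus non-family proteins) is
   itself a labelled SnRK2.
3. *domain check* - the candidate peptide must carry both protein-kinase
   signatures (ATP-binding region and Ser/Thr active site), written in
   PROSITE syntax, in its N-terminal half.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentHit, ScoringScheme, local_align

log = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class PrositeError(ValueError):
    """Raised for malformed PROSITE-syntax patterns."""


_TOKEN = re.compile(
    r"^(?:(?P<any>x)|\[(?P<inc>[A-Z]+)\]|\{(?P<exc>[A-Z]+)\}|(?P<lit>[A-Z]))"
    r"(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)


def prosite_to_regex(pattern: str) -> str:
    """Translate a PROSITE-syntax pattern into a Python regex string.

    Supports residue literals, ``x`` wildcards, ``[...]`` inclusion,
    ``{...}`` exclusion and ``(n)`` / ``(n,m)`` repetition; the terminal
    ``.`` and ``<``/``>`` anchors are accepted.
    """
    pat = pattern.strip().rstrip(".")
    anchored_start = pat.startswith("<")
    anchored_end = pat.endswith(">")
    pat = pat.lstrip("<").rstrip(">")
    parts = []
    for tok in pat.split("-"):
        m = _TOKEN.match(tok)
        if not m:
            raise PrositeError(f"bad PROSITE token {tok!r} in {pattern!r}")
        if m["any"]:
            body = f"[{AA20}X]"      # the wildcard also accepts unknown X
        elif m["inc"]:
            bad = set(m["inc"]) - set(AA20)
            if bad:
                raise PrositeError(f"non-residue {bad} in {tok!r}")
            body = f"[{m['inc']}]"
        elif m["exc"]:
            bad = set(m["exc"]) - set(AA20)
            if bad:
                raise PrositeError(f"non-residue {bad} in {tok!r}")
            allowed = "".join(c for c in AA20 if c not in set(m["exc"]))
            body = f"[{allowed}X]"
        else:
            if m["lit"] not in AA20:
                raise PrositeError(f"non-residue literal {tok!r}")
            body = m["lit"]
        if m["lo"]:
            # ranged repetitions match as few residues as possible, so the
            # reported span is the leftmost-shortest match
            rep = f"{{{m['lo']},{m['hi']}}}?" if m["hi"] else f"{{{m['lo']}}}"
            body += rep
        parts.append(body)
    regex = "".join(parts)
    if anchored_start:
        regex = "^" + regex
    if anchored_end:
        regex += "$"
    return regex


@dataclass(frozen=True)
class DomainSignature:
    name: str
    pattern: str
    description: str = ""

    def compiled(self) -> re.Pattern:
        return re.compile(prosite_to_regex(self.pattern))

    def search(self, seq: str) -> tuple[int, int] | None:
        """1-based inclusive span of the first (leftmost) match, or None."""
        m = self.compiled().search(seq.upper())
        if m is None:
            return None
        return (m.start() + 1, m.end())


def load_signatures(path: str | Path | None = None) -> list[DomainSignature]:
    """Bundled kinase signatures: ATP-binding region and Ser/Thr active site."""
    if path is None:
        src = resources.files("snrkfam.data") / "domain_signatures.tsv"
        with src.open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [DomainSignature(r.name, r.pattern, getattr(r, "description", ""))
            for r in df.itertuples(index=False)]


@dataclass
class DomainAnnotation:
    spans: dict[str, tuple[int, int] | None]
    passed: bool

    def table_style(self) -> str:
        """Render matched spans like ``IPR017441 (10-33); IPR008271 (119-131)``."""
        parts = []
        for name, span in self.spans.items():
            if span is not None:
                parts.append(f"{name} ({span[0]}-{span[1]})")
        return "; ".join(parts)


def domain_check(protein: str, signatures: Sequence[DomainSignature] | None = None
                 ) -> DomainAnnotation:
    """Pass iff every signature matches; spans are 1-based inclusive."""
    signatures = signatures if signatures is not None else load_signatures()
    spans = {sig.name: sig.search(protein) for sig in signatures}
    return DomainAnnotation(spans, all(v is not None for v in spans.values()))


# -- homology screen ----------------------------------------------------


@dataclass
class ScreenResult:
    hits: pd.DataFrame                    # outfmt6-like columns
    retained: dict[str, str]              # candidate -> best query
    threshold: float


def screen(queries: Mapping[str, str], candidates: Mapping[str, str],
           scheme: ScoringScheme | None = None,
           threshold: float = 1e-5) -> ScreenResult:
    """Retain candidates with >=1 local-alignment hit at E <= threshold.

    E-values use the database-style search space: query length times the
    summed length of all candidate peptides.
    """
    if not queries:
        raise ValueError("screen requires at least one query")
    if threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    scheme = scheme or ScoringScheme()
    db_size = sum(len(s) for s in candidates.values())
    rows = []
    best: dict[str, AlignmentHit] = {}
    for cid, cseq in candidates.items():
        for qid, qseq in queries.items():
            hit = local_align(qseq, cseq, scheme, qid, cid,
                              search_space=db_size)
            rows.append({
                "query": qid, "target": cid, "score": hit.score,
                "bitscore": round(hit.bitscore, 2), "evalue": hit.evalue,
                "qstart": hit.query_span[0], "qend": hit.query_span[1],
                "tstart": hit.target_span[0], "tend": hit.target_span[1],
            })
            if hit.evalue <= threshold:
                prev = best.get(cid)
                if prev is None or hit.score > prev.score:
                    best[cid] = hit
    hits = pd.DataFrame(rows, columns=["query", "target", "score", "bitscore",
                                       "evalue", "qstart", "qend", "tstart",
                                       "tend"])
    retained = {cid: h.query for cid, h in best.items()}
    return ScreenResult(hits, retained, threshold)


@dataclass
class RBHResult:
    retained: list[str]
    best_hits: pd.DataFrame   # candidate, species, best_target, family_flag
    dropped: list[str] = field(default_factory=list)


def reciprocal_best_hit(candidates: Mapping[str, str],
                        reference_proteomes: Mapping[str, Mapping[str, str]],
                        family_labels: Mapping[str, bool],
                        scheme: ScoringScheme | None = None,
                        mode: str = "each") -> RBHResult:
    """Keep candidates whose best reference hit is a labelled family member.

    ``reference_proteomes`` maps species -> {protein id -> sequence} and must
    include non-family proteins; ``family_labels`` flags the family members.
    ``mode`` 'each' requires the best hit in every species to be family;
    'any' requires it in at least one species.  Ties on raw score break
    toward the lexicographically smallest target id.
    """
    if mode not in ("each", "any"):
        raise ValueError("mode must be 'each' or 'any'")
    scheme = scheme or ScoringScheme()
    retained, dropped, rows = [], [], []
    for cid, cseq in candidates.items():
        verdicts = []
        for species, proteome in reference_proteomes.items():
            best_id, best_score = None, -1.0
            for rid in sorted(proteome):
                hit = local_align(cseq, proteome[rid], scheme, cid, rid)
                if hit.score > best_score:
                    best_id, best_score = rid, hit.score
            if best_id is None:
                continue
            is_family = bool(family_labels.get(best_id, False))
            verdicts.append(is_family)
            rows.append({"candidate": cid, "species": species,
                         "best_target": best_id, "score": best_score,
                         "family": is_family})
        if not verdicts:
            dropped.append(cid)
            log.warning("candidate %s had no reference hits; excluded", cid)
            continue
        ok = all(verdicts) if mode == "each" else any(verdicts)
        (retained if ok else dropped).append(cid)
    table = pd.DataFrame(rows, columns=["candidate", "species", "best_target",
                                        "score", "family"])
    return RBHResult(retained, table, dropped)


@dataclass
class IdentificationResult:
    family: list[str]
    screen: ScreenResult
    rbh: RBHResult
    domain_annotations: dict[str, DomainAnnotation]

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "candidates": self.screen.hits["target"].nunique(),
            "screen_retained": len(self.screen.retained),
            "rbh_retained": len(self.rbh.retained),
            "family": len(self.family),
        }


def identify_family(queries: Mapping[str, str], candidates: Mapping[str, str],
                    reference_proteomes: Mapping[str, Mapping[str, str]],
                    family_labels: Mapping[str, bool],
                    scheme: ScoringScheme | None = None,
                    threshold: float = 1e-5,
                    signatures: Sequence[DomainSignature] | None = None,
                    rbh_mode: str = "each") -> IdentificationResult:
    """Run screen -> reciprocal best hit -> domain check, in order."""
    scr = screen(queries, candidates, scheme, threshold)
    survivors = {cid: candidates[cid] for cid in scr.retained}
    rbh = reciprocal_best_hit(survivors, reference_proteomes, family_labels,
                              scheme, rbh_mode)
    annotations = {}
    family = []
    for cid in rbh.retained:
        ann = domain_check(candidates[cid], signatures)
        annotations[cid] = ann
        if ann.passed:
            family.append(cid)
    return IdentificationResult(sorted(family), scr, rbh, annotations)
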