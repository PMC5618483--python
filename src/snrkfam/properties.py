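"""ProtParam-style physicochemical properties of peptides.

Molecular weight sums average (isotope-weighted) residue masses plus one
water; the isoelectric point solves Henderson-Hasselbalch net charge = 0 by
bisection with the Bjellqvist-style pKa set used by ProtParam (including the
residue-dependent terminal pKa values); GRAVY is the mean Kyte-Doolittle
hydropathy; the aliphatic index follows Ikai:
AI = X(Ala) + a*X(Val) + b*(X(Ile) + X(Leu)), a = 2.9, b = 3.9, with X in
mole percent.

The C-terminal Asp/Glu classification captures the family's group semantics:
group 1 members carry Glu-rich tails, groups 2-3 Asp-rich tails, group 4
neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

# average residue masses, Da (Expasy)
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa values (as used by ProtParam / Expasy)
PKA_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
             "V": 7.44, "E": 7.7}
PKA_NTERM_DEFAULT = 7.5
PKA_CTERM = {"D": 4.55, "E": 4.75}
PKA_CTERM_DEFAULT = 3.55

ALIPHATIC_A = 2.9
ALIPHATIC_B = 3.9


class ResidueError(ValueError):
    pass


def _check(seq: str) -> str:
    seq = seq.upper().rstrip("*")
    if not seq:
        raise ResidueError("empty sequence")
    bad = set(seq) - set(RESIDUE_MASS)
    if bad:
        raise ResidueError(f"unknown residue(s): {sorted(bad)}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da."""
    seq = _check(seq)
    return sum(RESIDUE_MASS[a] for a in seq) + WATER_MASS


def molecular_weight_kda(seq: str) -> float:
    return round(molecular_weight(seq) / 1000.0, 2)


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at ``ph``."""
    seq = _check(seq)
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM.get(seq[0], PKA_NTERM_DEFAULT)))
    for aa, pk in PKA_POSITIVE.items():
        charge += seq.count(aa) / (1.0 + 10.0 ** (ph - pk))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM.get(seq[-1], PKA_CTERM_DEFAULT) - ph))
    for aa, pk in PKA_NEGATIVE.items():
        charge -= seq.count(aa) / (1.0 + 10.0 ** (pk - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-3) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique.  The
    root is located to at least ``tol`` in pH (iterated well past it so the
    residual net charge at the returned pH is negligible).
    """
    seq = _check(seq)
    lo, hi = 0.0, 14.0
    tol = min(tol, 1e-7)
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gravy(seq: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle score)."""
    seq = _check(seq)
    return sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    seq = _check(seq)
    n = len(seq)
    x = lambda aa: 100.0 * seq.count(aa) / n
    return x("A") + ALIPHATIC_A * x("V") + ALIPHATIC_B * (x("I") + x("L"))


def cterm_de_class(seq: str, domain_end: int, tau: float = 0.12) -> str:
    """Classify the tail after ``domain_end`` (1-based) as E-rich / D-rich / neither.

    E-rich requires mole fraction f(E) >= tau and f(E) > f(D); D-rich is the
    mirror condition.  An empty tail is 'neither'.
    """
    seq = _check(seq)
    if domain_end >= len(seq):
        raise ValueError("domain_end must precede the end of the sequence")
    tail = seq[domain_end:]
    if not tail:
        return "neither"
    fe = tail.count("E") / len(tail)
    fd = tail.count("D") / len(tail)
    if fe >= tau and fe > fd:
        return "E-rich"
    if fd >= tau and fd > fe:
        return "D-rich"
    return "neither"


@dataclass
class PropertyRecord:
    protein_id: str
    length: int
    mw_kda: float
    pi: float
    gravy: float
    aliphatic_index: float
    cterm_class: str


def property_table(proteins: Mapping[str, str],
                   tail_length: int = 50,
                   domain_ends: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Property records for a set of peptides, in Table-style column order.

    The D/E tail is taken after ``domain_ends[id]`` when provided, otherwise
    as the last ``tail_length`` residues.
    """
    rows = []
    for pid, seq in proteins.items():
        seq = _check(seq)
        if domain_ends and pid in domain_ends:
            dend = domain_ends[pid]
        else:
            dend = max(len(seq) - tail_length, 1)
        rec = PropertyRecord(
            protein_id=pid,
            length=len(seq),
            mw_kda=molecular_weight_kda(seq),
            pi=round(isoelectric_point(seq), 2),
            gravy=round(gravy(seq), 3),
            aliphatic_index=round(aliphatic_index(seq), 2),
            cterm_class=cterm_de_class(seq, dend),
        )
        rows.append(vars(rec))
    return pd.DataFrame(rows)
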