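"""Expression quantification: FPKM, per-gene Z-scores, and 2^-ddCt fold changes.

FPKM = 1e9 * C / (N * L) for count C, per-sample mapped-fragment total N and
exon length L (bp).  Z-scores standardize each gene across samples with the
sample standard deviation (ddof=1); constant genes yield an all-zero row and
are flagged.

qRT-PCR quantification follows the 2^-ddCt convention with a reference gene
(internal control) and the untreated sample at the same time point as the
calibrator: dCt = Ct_target - Ct_reference per replicate,
ddCt = mean(dCt_treated) - mean(dCt_control), fold change = 2^-ddCt.
Significance is a two-sided Student's t-test on the replicate dCt values
(equal variance by default, Welch optional); amplification efficiency is
taken as 100% and p-values are reported raw (no multiple-testing
correction), matching standard practice for per-gene star annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    ``counts`` is genes x samples; ``lengths`` in bp indexed by gene;
    ``totals`` per-sample mapped fragments (defaults to column sums).
    """
    if totals is None:
        totals = counts.sum(axis=0)
    lengths = lengths.reindex(counts.index)
    totals = totals.reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("library totals must be positive for all samples")
    return 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)


def zscore_by_gene(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene Z-score across samples; returns (Z, constant-gene list).

    Constant genes (sd == 0) become all-zero rows and are flagged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-scores need at least two samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flagged = list(matrix.index[sd == 0])
    safe_sd = sd.replace(0, np.nan)
    z = matrix.sub(mean, axis=0).div(safe_sd, axis=0).fillna(0.0)
    return z, flagged


@dataclass
class FoldChange:
    gene: str
    treatment: str
    time_h: float
    ddct: float
    fold_change: float
    p_value: float
    stars: str

    @staticmethod
    def star(p: float) -> str:
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""


def _safe_ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def ddct(ct_table: pd.DataFrame, ref_gene: str,
         calibrator: str = "control", equal_var: bool = True) -> pd.DataFrame:
    """2^-ddCt fold changes with per-condition replicate t-tests.

    ``ct_table`` columns: gene, treatment, time_h, replicate, ct.  The
    reference gene must be measured in every (treatment, time, replicate)
    sample; the calibrator is the ``calibrator`` treatment at the same time
    point.  Returns one row per (gene, treatment != calibrator, time).
    """
    required = {"gene", "treatment", "time_h", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    ref = ct_table[ct_table.gene == ref_gene]
    if ref.empty:
        raise ValueError(f"reference gene {ref_gene!r} absent from Ct table")
    ref_idx = ref.set_index(["treatment", "time_h", "replicate"]).ct
    targets = ct_table[ct_table.gene != ref_gene].copy()
    key = pd.MultiIndex.from_frame(targets[["treatment", "time_h", "replicate"]])
    ref_ct = ref_idx.reindex(key)
    if ref_ct.isna().any():
        bad = key[np.asarray(ref_ct.isna())][0]
        raise ValueError(f"reference Ct missing for sample {tuple(bad)}")
    targets["dct"] = targets.ct.to_numpy() - ref_ct.to_numpy()

    if calibrator not in set(targets.treatment):
        raise ValueError(f"calibrator condition {calibrator!r} not present")
    ctrl = targets[targets.treatment == calibrator]
    ctrl_groups = {k: g.dct.to_numpy()
                   for k, g in ctrl.groupby(["gene", "time_h"])}
    rows = []
    treated = targets[targets.treatment != calibrator]
    for (gene, trt, t), grp in treated.groupby(["gene", "treatment", "time_h"]):
        if (gene, t) not in ctrl_groups:
            raise ValueError(f"no {calibrator!r} replicates for {gene} at {t} h")
        tr = grp.dct.to_numpy()
        co = ctrl_groups[(gene, t)]
        if len(tr) < 2 or len(co) < 2:
            raise ValueError(f"{gene}/{trt}/{t} h: need >=2 replicates")
        dd = tr.mean() - co.mean()
        p = _safe_ttest(tr, co, equal_var)
        rows.append({
            "gene": gene, "treatment": trt, "time_h": t, "ddct": dd,
            "fold_change": 2.0 ** (-dd), "p_value": p,
            "stars": FoldChange.star(p),
        })
    return pd.DataFrame(rows, columns=["gene", "treatment", "time_h", "ddct",
                                       "fold_change", "p_value", "stars"])


def induced_set(foldchanges: pd.DataFrame, fc_min: float = 2.0,
                alpha: float = 0.05) -> dict[str, set[str]]:
    """Genes induced (FC >= fc_min and p <= alpha, both boundaries inclusive)
    at >=1 time point, per treatment."""
    out: dict[str, set[str]] = {}
    hits = foldchanges[(foldchanges.fold_change >= fc_min)
                       & (foldchanges.p_value <= alpha)]
    for trt, grp in hits.groupby("treatment"):
        out[str(trt)] = set(grp.gene)
    return out


def foldchange_profiles(foldchanges: pd.DataFrame,
                        treatment: str) -> pd.DataFrame:
    """Genes x time-points fold-change matrix for one treatment (the profile
    fed to treatment-response co-expression networks)."""
    sub = foldchanges[foldchanges.treatment == treatment]
    return sub.pivot(index="gene", columns="time_h", values="fold_change")
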