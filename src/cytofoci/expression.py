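"""Relative qPCR quantification and FPKM differential-expression filtering.

``delta_delta_ct`` implements the 2^(-ddCt) method: per condition the
target gene's mean quantification cycle is normalised against the
geometric mean of two reference genes' mean Cq values (dCt), the
control condition's dCt is subtracted (ddCt), and the fold change is
2^(-ddCt).  ``de_filter`` applies the classic three-way screen used in
bulk RNA-seq reports -- fold-change cutoff, raw p-value cutoff, and a
minimum group-mean FPKM floor -- and ``zscore_matrix`` produces the
row-wise standardisation used for heat-map display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChangeResult",
    "delta_delta_ct",
    "reference_stability",
    "de_filter",
    "zscore_matrix",
]


@dataclass
class FoldChangeResult:
    gene: str
    condition: str
    control_condition: str
    fold_change: float
    delta_ct: float
    delta_ct_control: float
    delta_delta_ct: float
    replicate_sd: float


def _mean_cq(table: pd.DataFrame, gene: str, condition: str) -> float:
    """Mean Cq of one gene in one condition: technical replicates are
    averaged per sample first, then samples averaged."""
    sub = table[(table["gene"] == gene) & (table["condition"] == condition)]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not measured in condition {condition!r}")
    per_sample = sub.groupby("sample")["cq"].mean()
    return float(per_sample.mean())


def _reference_value(
    table: pd.DataFrame,
    condition: str,
    reference_genes,
    combine: str,
) -> float:
    means = np.array([_mean_cq(table, g, condition) for g in reference_genes])
    if combine == "geometric":
        if (means <= 0).any():
            raise ValueError("non-positive Cq cannot enter a geometric mean")
        return float(stats.gmean(means))
    if combine == "arithmetic":
        return float(means.mean())
    raise ValueError("combine must be 'geometric' or 'arithmetic'")


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    condition: str,
    control_condition: str,
    reference_genes=("Gapdh", "Rpl13a"),
    ref_combine: str = "geometric",
) -> FoldChangeResult:
    """Relative expression by the 2^(-ddCt) method.

    dCt(cond) = mean Cq(target, cond) - combined reference Cq(cond),
    where the reference combination is the geometric mean of the
    reference genes' mean Cq values (``ref_combine='arithmetic'``
    switches to the arithmetic mean of Cq, which equals the geometric
    mean on the expression scale).  ddCt = dCt(condition) -
    dCt(control); fold change = 2^(-ddCt).  A condition compared with
    itself has fold change exactly 1.
    """
    if len(reference_genes) < 2:
        raise ValueError("need at least 2 reference genes")
    for rg in reference_genes:
        for cond in (condition, control_condition):
            if table[(table["gene"] == rg) & (table["condition"] == cond)].empty:
                raise ValueError(f"reference gene {rg!r} missing in condition {cond!r}")

    d_ct = _mean_cq(table, gene, condition) - _reference_value(
        table, condition, reference_genes, ref_combine
    )
    d_ct_ctrl = _mean_cq(table, gene, control_condition) - _reference_value(
        table, control_condition, reference_genes, ref_combine
    )
    dd_ct = d_ct - d_ct_ctrl
    # per-sample spread of the target Cq in the test condition
    sub = table[(table["gene"] == gene) & (table["condition"] == condition)]
    rep_sd = float(sub.groupby("sample")["cq"].mean().std(ddof=1)) \
        if sub["sample"].nunique() > 1 else 0.0
    return FoldChangeResult(
        gene=gene,
        condition=condition,
        control_condition=control_condition,
        fold_change=float(2.0 ** (-dd_ct)),
        delta_ct=float(d_ct),
        delta_ct_control=float(d_ct_ctrl),
        delta_delta_ct=float(dd_ct),
        replicate_sd=rep_sd,
    )


def reference_stability(
    table: pd.DataFrame,
    reference_genes=("Gapdh", "Rpl13a"),
    sd_bound: float = 0.5,
) -> pd.DataFrame:
    """Descriptive stability report for the reference genes.

    Per reference gene: the SD of its mean Cq across conditions and the
    largest pairwise condition difference; a gene is flagged when the
    SD exceeds ``sd_bound`` cycles (default 0.5).  This is a simple
    descriptive screen, not a geNorm/NormFinder-style ranking.
    """
    conditions = sorted(table["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("stability needs >= 2 conditions")
    rows = []
    for gene in reference_genes:
        means = np.array([_mean_cq(table, gene, c) for c in conditions])
        sd = float(means.std(ddof=1))
        max_diff = float(means.max() - means.min())
        rows.append(
            dict(gene=gene, sd_across_conditions=sd,
                 max_pairwise_diff=max_diff, flagged=sd > sd_bound)
        )
    return pd.DataFrame(rows)


def de_filter(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    fpkm_floor: float = 0.5,
    pseudocount: float = 0.1,
    with_fdr: bool = True,
) -> pd.DataFrame:
    """Three-criterion differential-expression screen on an FPKM matrix.

    Per gene (B relative to A):

    * fold change = mean FPKM(B) / mean FPKM(A), on raw means (0/0 is
      treated as FC 1; x/0 as infinite); ``passes_fc`` iff FC >=
      ``fc_cutoff`` or FC <= 1/``fc_cutoff`` (cutoffs inclusive);
    * p from an unpaired two-tailed pooled-variance t-test on
      log2(FPKM + pseudocount); ``passes_p`` iff p <= ``p_cutoff``;
    * ``passes_fpkm`` iff mean FPKM >= ``fpkm_floor`` in at least one
      group.

    A gene is differentially expressed iff all three pass.  No
    multiple-testing correction enters the flag; a Benjamini-Hochberg
    ``fdr`` column is emitted for transparency when ``with_fdr``.
    """
    a_samples = groups.index[groups == group_a]
    b_samples = groups.index[groups == group_b]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = matrix[a_samples].to_numpy(dtype=float)
    B = matrix[b_samples].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(
            mean_a > 0, mean_b / mean_a, np.where(mean_b > 0, np.inf, 1.0)
        )
    logA = np.log2(A + pseudocount)
    logB = np.log2(B + pseudocount)
    t, p = stats.ttest_ind(logB, logA, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)

    passes_fc = (fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff)
    passes_p = p <= p_cutoff
    passes_fpkm = (mean_a >= fpkm_floor) | (mean_b >= fpkm_floor)
    de = passes_fc & passes_p & passes_fpkm

    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "log2_fc": np.log2(np.where(fc > 0, fc, np.nan)),
            "p": p,
            "passes_fc": passes_fc,
            "passes_p": passes_p,
            "passes_fpkm": passes_fpkm,
            "de": de,
            "direction": np.where(fc >= 1.0, "up", "down"),
        },
        index=matrix.index,
    )
    if with_fdr:
        from statsmodels.stats.multitest import multipletests

        out["fdr"] = multipletests(p, method="fdr_bh")[1]
    return out


def zscore_matrix(values: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores of a genes x conditions summary matrix.

    Each row is centred on its mean and scaled by its SD (sample SD,
    ``ddof=1``, the convention of R's ``scale``); constant rows cannot
    be scaled and come back as zeros with a flag.

    Returns (z, constant_flags).
    """
    if values.shape[1] < 2:
        raise ValueError("z-scores need >= 2 conditions per gene")
    x = values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / safe_sd
    z[constant, :] = 0.0
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns)
    flags = pd.Series(constant, index=values.index, name="constant_row")
    return zdf, flags
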