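"""Relative qPCR quantification by the 2^-ddCt method.

Per sample, replicate Ct values are collapsed by mean; dCt is the target
minus the reference gene (HMBS by default); ddCt centers dCt on the mean of
the baseline group (primary tumors), so the baseline geometric-mean fold
change is 1 by construction. Fold change = 2^(-ddCt). Group comparisons
use a two-sided rank-sum test on ddCt; co-expression between an intronic
transcript and its host mRNA is a Pearson correlation of log2 fold
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_GENE = "HMBS"


def _collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over replicate columns (rep*_ct) per (gene, sample)."""
    rep_cols = [c for c in table.columns if c.endswith("_ct")]
    if not rep_cols:
        raise ValueError("Ct table has no replicate columns (rep*_ct)")
    out = table[["gene", "sample", "group"]].copy()
    out["ct"] = table[rep_cols].mean(axis=1)
    return out


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    baseline_group: str = "primary",
) -> pd.DataFrame:
    """Fold-change records for every target gene and sample.

    Input columns: gene, sample, group, rep1_ct..repN_ct. Samples lacking a
    reference-gene measurement are excluded with a warning column rather than
    an error. Returns gene, sample, group, dct, ddct, fold.
    """
    ct = _collapse_replicates(table)
    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    targets = ct[ct["gene"] != reference_gene].copy()
    missing_ref = ~targets["sample"].isin(ref.index)
    if missing_ref.any():
        import warnings

        dropped = sorted(targets.loc[missing_ref, "sample"].unique())
        warnings.warn(
            f"samples without reference-gene Ct excluded: {dropped}",
            stacklevel=2,
        )
        targets = targets[~missing_ref]
    targets["dct"] = targets["ct"] - ref[targets["sample"]].to_numpy()

    out = []
    for gene, sub in targets.groupby("gene", sort=False):
        base = sub.loc[sub["group"] == baseline_group, "dct"]
        if base.empty:
            raise ValueError(
                f"gene {gene!r} has no samples in baseline group "
                f"{baseline_group!r}"
            )
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - base.mean()
        sub["fold"] = 2.0 ** -sub["ddct"]
        out.append(sub)
    records = pd.concat(out, ignore_index=True)
    return records[["gene", "sample", "group", "dct", "ddct", "fold"]]


@dataclass
class GroupComparison:
    gene: str
    p_value: float
    direction: str          # up / down / none, for the non-baseline group
    degenerate: bool = False


def compare_groups(
    records: pd.DataFrame,
    groups: tuple[str, str] = ("primary", "metastasis"),
    test: str = "rank_sum",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided per-gene test of ddCt between the two groups.

    `test` is "rank_sum" (default, Wilcoxon/Mann-Whitney) or "t" (Welch on
    dCt). All-tied data yields p = 1 with the degenerate flag. Direction is
    the sign of the second group's mean fold change relative to the first.
    """
    g1, g2 = groups
    rows = []
    for gene, sub in records.groupby("gene", sort=False):
        a = sub.loc[sub["group"] == g1, "ddct"].to_numpy()
        b = sub.loc[sub["group"] == g2, "ddct"].to_numpy()
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"gene {gene!r}: both groups need >= 3 samples")
        degenerate = np.ptp(np.concatenate([a, b])) == 0
        if degenerate:
            p = 1.0
        elif test == "rank_sum":
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        elif test == "t":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        # lower ddCt = higher expression
        if degenerate or np.mean(b) == np.mean(a):
            direction = "none"
        else:
            direction = "up" if np.mean(b) < np.mean(a) else "down"
        rows.append((gene, float(p), direction, p < alpha, degenerate))
    return pd.DataFrame(
        rows, columns=["gene", "p_value", "direction", "significant",
                       "degenerate"]
    ).set_index("gene")


def coding_noncoding_correlation(
    records: pd.DataFrame, intronic_gene: str, mrna_gene: str
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between the log2 fold profiles
    of an intronic transcript and its host mRNA over shared samples."""
    a = records[records["gene"] == intronic_gene].set_index("sample")["ddct"]
    b = records[records["gene"] == mrna_gene].set_index("sample")["ddct"]
    shared = a.index.intersection(b.index)
    if len(shared) < 5:
        raise ValueError(
            f"need >= 5 paired samples, got {len(shared)} for "
            f"({intronic_gene}, {mrna_gene})"
        )
    x = -a[shared].to_numpy()  # -ddCt == log2 fold
    y = -b[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
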