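"""Two-class permutation differential expression with FDR control.

Implements the significance-analysis-of-microarrays recipe: a moderated
two-sample statistic d_i = (mean1 - mean2) / (s_i + s0), with the fudge
factor s0 chosen by the coefficient-of-variation grid search over
percentiles of the pooled scatter s_i, a permutation null over group
labels, and a permutation FDR

    FDR(delta) = median permutation false-call count / observed call count.

The called set at a target FDR is the one at the smallest delta whose FDR
is at or below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


@dataclass
class SamResult:
    table: pd.DataFrame      # per probe: mean1, mean2, s, d, q, called, direction
    s0: float
    delta: float             # delta achieving the requested FDR (inf if none)
    fdr: float               # realized FDR at that delta (NaN if no calls)
    fdr_threshold: float
    n_perm: int
    groups: tuple[str, str]

    @property
    def called(self) -> pd.Index:
        return self.table.index[self.table["called"]]


def _group_stats(X, M, a):
    """Masked group means/SS for indicator matrix a (B x n). X has NaN->0,
    M is the validity mask. Returns means and pooled scatter s_i per probe
    per permutation (B x p)."""
    n1 = M @ a.T                      # p x B valid counts in group 1
    n2 = M @ (1 - a).T
    s1 = X @ a.T
    s2 = X @ (1 - a).T
    q1 = (X**2) @ a.T
    q2 = (X**2) @ (1 - a).T
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = s1 / n1
        m2 = s2 / n2
        ss = (q1 - n1 * m1**2) + (q2 - n2 * m2**2)
        dof = n1 + n2 - 2
        pooled = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / dof)
    return m1, m2, pooled


def _fudge_factor(diff: np.ndarray, s: np.ndarray) -> float:
    """Tusher-style s0: the percentile of s (grid 0,5,...,100) minimizing the
    coefficient of variation of window-wise MADs of d across the s range."""
    if len(s) == 0 or s.max() == 0:
        return 0.0
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    diff_sorted = diff[order]
    qs = np.percentile(s, np.arange(0, 101, 1))
    candidates = np.concatenate([[0.0], np.percentile(s, np.arange(0, 101, 5))])
    # 100 windows of s defined by its percentiles
    edges = np.unique(qs)
    best_s0, best_cv = 0.0, np.inf
    windows = np.searchsorted(s_sorted, edges[:-1], side="left")
    bounds = list(zip(windows, np.append(windows[1:], len(s_sorted))))
    for s0 in np.unique(candidates):
        denom = s_sorted + s0
        if denom.min() == 0:
            continue
        d = diff_sorted / denom
        mads = []
        for lo, hi in bounds:
            if hi - lo >= 3:
                w = d[lo:hi]
                mads.append(np.median(np.abs(w - np.median(w))) * 1.4826)
        mads = np.asarray(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads, ddof=1) / np.mean(mads)
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_indicators(labels01: np.ndarray, n_perm: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Distinct label assignments as a B x n indicator matrix. If fewer than
    `n_perm` distinct assignments exist they are enumerated exhaustively."""
    n = len(labels01)
    n1 = int(labels01.sum())
    total = comb(n, n1)
    if total < 2:
        raise ValueError("fewer than 2 distinct permutations possible")
    if total <= n_perm:
        A = np.zeros((total, n))
        for i, idx in enumerate(combinations(range(n), n1)):
            A[i, list(idx)] = 1.0
        return A
    A = np.zeros((n_perm, n))
    for i in range(n_perm):
        idx = rng.choice(n, size=n1, replace=False)
        A[i, idx] = 1.0
    return A


def sam_two_class(
    values: pd.DataFrame,
    labels: pd.Series,
    groups: tuple[str, str],
    n_perm: int = 1000,
    fdr_threshold: float = 0.10,
    seed: int = 0,
    n_delta: int = 200,
) -> SamResult:
    """SAM-style two-class analysis of a probes x samples matrix.

    `labels` maps sample id to group; samples outside `groups` are dropped.
    Missing values are excluded pairwise per probe. Probes with fewer than
    2 valid samples in either group get d = 0 and are never called.
    """
    g1, g2 = groups
    keep = labels[labels.isin(groups)].index
    if len(keep) == 0:
        raise ValueError(f"no samples in groups {groups}")
    V = values[list(keep)]
    lab = (labels[keep] == g1).to_numpy(dtype=float)
    for g in groups:
        if (labels[keep] == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")

    X = V.to_numpy(dtype=float)
    M = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X, nan=0.0)

    m1, m2, s = _group_stats(X0, M, lab[None, :])
    m1, m2, s = m1[:, 0], m2[:, 0], s[:, 0]
    n1 = (M @ lab) ; n2 = (M @ (1 - lab))
    usable = (n1 >= 2) & (n2 >= 2) & np.isfinite(s) & (s >= 0)
    diff = np.where(usable, m1 - m2, 0.0)
    s = np.where(usable, s, np.nanmedian(s[usable]) if usable.any() else 1.0)

    s0 = _fudge_factor(diff[usable], s[usable]) if usable.any() else 0.0
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    d[~usable] = 0.0

    rng = np.random.default_rng(seed)
    A = _permutation_indicators(lab, n_perm, rng)
    B = A.shape[0]
    pm1, pm2, ps = _group_stats(X0, M, A)
    with np.errstate(invalid="ignore"):
        d_perm = (pm1 - pm2) / (ps + s0)      # p x B
    d_perm = np.nan_to_num(d_perm, nan=0.0)
    d_perm[~usable, :] = 0.0

    # expected order statistics and delta grid
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    dbar = np.mean(np.sort(d_perm, axis=0), axis=1)
    dev = d_sorted - dbar
    grid = np.unique(np.abs(dev))
    if len(grid) > n_delta:
        grid = np.quantile(grid, np.linspace(0, 1, n_delta))
    grid = np.unique(np.concatenate([[0.0], grid]))

    d_perm_flat = np.sort(d_perm, axis=0)      # per permutation column sorted
    results = []
    p = len(d)
    for delta in grid:
        above = np.where(dev >= delta)[0]
        below = np.where(dev <= -delta)[0]
        cutup = d_sorted[above[0]] if len(above) else np.inf
        cutlow = d_sorted[below[-1]] if len(below) else -np.inf
        called = (d >= cutup) | (d <= cutlow)
        n_called = int(called.sum())
        if n_called == 0:
            results.append((delta, 0, np.nan, cutup, cutlow))
            continue
        up_counts = (
            (d_perm_flat >= cutup).sum(axis=0) if np.isfinite(cutup) else np.zeros(B)
        )
        low_counts = (
            (d_perm_flat <= cutlow).sum(axis=0) if np.isfinite(cutlow) else np.zeros(B)
        )
        false = np.median(up_counts + low_counts)
        results.append((delta, n_called, false / n_called, cutup, cutlow))

    res = pd.DataFrame(
        results, columns=["delta", "n_called", "fdr", "cutup", "cutlow"]
    )
    ok = res[(res["fdr"] <= fdr_threshold) & (res["n_called"] > 0)]
    if len(ok):
        chosen = ok.iloc[0]
        delta, fdr = float(chosen["delta"]), float(chosen["fdr"])
        called = (d >= chosen["cutup"]) | (d <= chosen["cutlow"])
    else:
        delta, fdr = np.inf, np.nan
        called = np.zeros(p, dtype=bool)

    # per-probe q: smallest FDR among deltas at which the probe is called
    q = np.full(p, np.nan)
    for row in res.itertuples():
        if row.n_called == 0 or not np.isfinite(row.fdr):
            continue
        in_set = (d >= row.cutup) | (d <= row.cutlow)
        q = np.where(in_set & (~(q <= row.fdr)), row.fdr, q)

    table = pd.DataFrame(
        {
            "mean1": m1, "mean2": m2, "s": s, "d": d, "q": q,
            "called": called,
            "direction": np.where(d > 0, "up", np.where(d < 0, "down", "none")),
        },
        index=values.index,
    )
    return SamResult(table, s0, delta, fdr, fdr_threshold, B, groups)


def called_at(result: SamResult, fdr_threshold: float) -> pd.Index:
    """Called set of an existing result re-thresholded at a (possibly
    tighter) FDR, via the per-probe q-values."""
    t = result.table
    return t.index[t["q"].notna() & (t["q"] <= fdr_threshold)]


# --------------------------------------------------------------- signature

@dataclass
class SignatureTable:
    table: pd.DataFrame          # probe_id, genomic_class, direction, d, q, host
    composition: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.table)


def assemble_signature(result: SamResult, probes) -> SignatureTable:
    """Join the called set with probe classifications and count composition.

    `probes` is an iterable of ProbeRecord. Composition counts partition the
    signature by genomic class.
    """
    by_id = {p.probe_id: p for p in probes}
    rows = []
    t = result.table
    for probe_id in result.called:
        p = by_id.get(probe_id)
        rows.append(
            (
                probe_id,
                p.genomic_class if p else "unknown",
                t.loc[probe_id, "direction"],
                t.loc[probe_id, "d"],
                t.loc[probe_id, "q"],
                p.host_gene_id if p else "",
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["probe_id", "genomic_class", "direction", "d", "q",
                 "host_gene_id"],
    )
    composition = table["genomic_class"].value_counts().to_dict() if len(table) else {}
    return SignatureTable(table, composition)


def order_samples_by_profile_correlation(
    values: pd.DataFrame,
    signature_probes,
    labels: pd.Series,
    reference_group: str,
) -> pd.DataFrame:
    """Rank samples by Pearson correlation to the reference-group mean
    profile over the signature probes (descending). Samples with an
    undefined correlation (constant profile) are placed last and flagged.
    """
    sig = values.loc[list(signature_probes)]
    ref_samples = labels.index[labels == reference_group]
    ref_profile = sig[list(ref_samples)].mean(axis=1)
    rows = []
    for sample in sig.columns:
        x = sig[sample]
        ok = x.notna() & ref_profile.notna()
        xs, rs = x[ok], ref_profile[ok]
        if len(xs) < 2 or xs.std(ddof=0) == 0 or rs.std(ddof=0) == 0:
            rows.append((sample, np.nan, True))
        else:
            r = np.corrcoef(xs, rs)[0, 1]
            rows.append((sample, r, False))
    df = pd.DataFrame(rows, columns=["sample_id", "correlation", "undefined"])
    df = df.sort_values(
        ["undefined", "correlation"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return df


def standardize_for_heatmap(
    values: pd.DataFrame, signature_probes
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores (population sd) of the signature submatrix.

    Zero-variance rows are zero-filled and flagged. Returns (z, flagged).
    """
    sub = values.loc[list(signature_probes)]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    flagged = sd == 0
    safe_sd = sd.mask(flagged, 1.0)
    z = sub.sub(mean, axis=0).div(safe_sd, axis=0)
    z[flagged] = 0.0
    return z, flagged
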