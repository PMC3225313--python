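"""Replicated-intensity preprocessing for the spotted cDNA array design.

The experimental unit is a sample hybridized on 2 slides with every probe
spotted in duplicate, giving 4 replicate measurements per probe per sample.
The pipeline order is fixed: quantile normalization across slides, per-slide
low-intensity filtering, replicate collapse (>= 3 of 4 valid), group
detection calls (>= 75% of samples in any histology group), then batch
adjustment. Missing/invalid entries are NaN and are ignored, never
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

HISTOLOGY_GROUPS = ("NT", "T", "M", "CP")

# the sample sheet of the source design uses "PA" for pancreatitis in one
# place; normalize it on input
_HISTOLOGY_SYNONYMS = {"PA": "CP"}


@dataclass
class ExpressionMatrix:
    """Probes x measurements grid with slide/sample metadata.

    At the replicate stage ``values`` has a (slide_id, spot) MultiIndex on
    columns and ``slides`` maps slide_id -> sample_id/histology/batch. After
    `collapse_replicates` columns are sample ids and ``slides`` is None.
    ``samples`` is indexed by sample_id with histology and batch columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    slides: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = self.samples.copy()
        self.samples["histology"] = (
            self.samples["histology"].replace(_HISTOLOGY_SYNONYMS)
        )
        if self.slides is not None:
            missing = set(self.slides["sample_id"]) - set(self.samples.index)
            if missing:
                raise ValueError(f"slides reference unknown samples: {missing}")

    @property
    def slide_ids(self) -> list:
        if self.slides is None:
            raise ValueError("matrix already collapsed to samples")
        return list(self.slides.index)

    def slide_vector(self, slide_id) -> pd.Series:
        """All measurements of one slide (both spots), stacked."""
        sub = self.values[slide_id]
        return sub.stack(future_stack=True)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.samples.copy(),
            None if self.slides is None else self.slides.copy(),
        )


def from_long(intensities: pd.DataFrame, sample_sheet: pd.DataFrame) -> ExpressionMatrix:
    """Build an ExpressionMatrix from long-format TSV tables.

    `intensities`: columns probe_id, slide_id, spot, intensity.
    `sample_sheet`: columns slide_id, sample_id, histology, batch.
    """
    wide = intensities.pivot_table(
        index="probe_id", columns=["slide_id", "spot"], values="intensity",
        aggfunc="first", dropna=False,
    )
    slides = sample_sheet.set_index("slide_id")
    samples = (
        sample_sheet.groupby("sample_id")[["histology", "batch"]].first()
    )
    wide = wide.loc[:, [c for c in wide.columns if c[0] in slides.index]]
    return ExpressionMatrix(wide, samples, slides)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every slide's intensity distribution onto the common quantile
    curve (the mean quantile function across slides).

    Each slide's vector is both spot columns stacked. Ties within a slide
    receive the mean of their pooled quantile values (average ranks); missing
    entries are ignored and preserved.
    """
    if matrix.slides is None:
        raise ValueError("quantile normalization runs on the replicate matrix")
    slide_ids = matrix.slide_ids
    if len(slide_ids) == 1:
        return matrix.copy()
    vectors = {sid: matrix.slide_vector(sid) for sid in slide_ids}
    counts = {sid: int(v.notna().sum()) for sid, v in vectors.items()}
    if min(counts.values()) == 0:
        bad = [sid for sid, c in counts.items() if c == 0]
        raise ValueError(f"slides with all-missing values: {bad}")

    m = max(counts.values())
    grid = (np.arange(m) + 0.5) / m
    ref = np.zeros(m)
    for sid in slide_ids:
        vals = np.sort(vectors[sid].dropna().to_numpy())
        ref += np.interp(grid, (np.arange(len(vals)) + 0.5) / len(vals), vals)
    ref /= len(slide_ids)

    out = matrix.copy()
    for sid in slide_ids:
        v = vectors[sid]
        valid = v.notna()
        n = counts[sid]
        ranks = stats.rankdata(v[valid].to_numpy())  # average ranks for ties
        newvals = np.interp((ranks - 0.5) / n, grid, ref)
        norm = v.copy()
        norm[valid] = newvals
        for spot in out.values[sid].columns:
            out.values[(sid, spot)] = norm.xs(spot, level=-1)
    return out


def filter_low_intensity(
    matrix: ExpressionMatrix, fraction: float = 0.5
) -> ExpressionMatrix:
    """Invalidate the lowest `fraction` of valid intensities per slide.

    Exactly floor(n_valid * fraction) entries are removed per slide; ties are
    broken by stable order for determinism.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if matrix.slides is None:
        raise ValueError("low-intensity filter runs on the replicate matrix")
    out = matrix.copy()
    for sid in matrix.slide_ids:
        v = matrix.slide_vector(sid)
        valid_idx = v.index[v.notna()]
        k = int(np.floor(len(valid_idx) * fraction))
        if k == 0:
            continue
        order = np.argsort(v[valid_idx].to_numpy(), kind="stable")
        drop = valid_idx[order[:k]]
        v.loc[drop] = np.nan
        block = v.unstack()
        for spot in block.columns:
            out.values[(sid, spot)] = block[spot]
    return out


def collapse_replicates(
    matrix: ExpressionMatrix, min_valid: int = 3, n_replicates: int = 4
) -> ExpressionMatrix:
    """Per-sample probe means over valid replicates; < `min_valid` of
    `n_replicates` valid measurements yields a missing value."""
    if matrix.slides is None:
        raise ValueError("matrix already collapsed")
    cols = {}
    for sample_id, grp in matrix.slides.groupby("sample_id", sort=False):
        block = matrix.values.loc[:, list(grp.index)]
        if block.shape[1] != n_replicates:
            raise ValueError(
                f"sample {sample_id!r} maps to {block.shape[1]} measurements, "
                f"expected {n_replicates}"
            )
        nvalid = block.notna().sum(axis=1)
        mean = block.mean(axis=1)
        mean[nvalid < min_valid] = np.nan
        cols[sample_id] = mean
    values = pd.DataFrame(cols)
    values = values[list(matrix.samples.index)]
    return ExpressionMatrix(values, matrix.samples, None)


@dataclass
class DetectionTable:
    """Per-probe detection flags per histology group plus the overall flag."""

    detected: pd.DataFrame  # probes x groups, bool
    expressed: pd.Series    # probes, bool (OR over groups)

    def class_counts(self, classes: pd.Series) -> pd.DataFrame:
        """Table-1-style accounting: per genomic class, per group detected
        counts plus the overall expressed count."""
        df = self.detected.copy()
        df["expressed"] = self.expressed
        df["genomic_class"] = classes.reindex(df.index)
        return df.groupby("genomic_class").sum()


def detection_calls(
    matrix: ExpressionMatrix, min_frac: float = 0.75
) -> DetectionTable:
    """Detected in group G iff the valid-sample fraction within G is >=
    `min_frac` (inclusive); expressed iff detected in >= 1 group."""
    if matrix.slides is not None:
        raise ValueError("detection runs on the collapsed per-sample matrix")
    groups = matrix.samples.groupby("histology").groups
    flags = {}
    for g, sample_ids in groups.items():
        if len(sample_ids) == 0:
            raise ValueError(f"empty histology group {g!r}")
        block = matrix.values[list(sample_ids)]
        flags[g] = block.notna().mean(axis=1) >= min_frac
    detected = pd.DataFrame(flags)
    return DetectionTable(detected, detected.any(axis=1))


def batch_adjust(matrix: ExpressionMatrix, shrink: bool = True) -> ExpressionMatrix:
    """Location/scale batch adjustment on the per-sample matrix.

    Per probe and batch, the batch mean and variance are adjusted to the
    pooled probe mean/variance. With `shrink`, batch parameters are shrunk
    toward their across-probe average (an empirical-Bayes moderation in the
    spirit of the canonical batch-correction tool, not a bit-compatible
    reimplementation). Works on log2 intensities.
    """
    if matrix.slides is not None:
        raise ValueError("batch adjustment runs on the collapsed matrix")
    batches = matrix.samples["batch"]
    if batches.nunique() < 2:
        return matrix.copy()
    cross = pd.crosstab(matrix.samples["histology"], batches)
    if ((cross > 0).sum(axis=1) == 1).all() and batches.nunique() > 1:
        raise ValueError(
            "batch is confounded 1:1 with histology; adjustment would erase "
            "the biological signal"
        )
    sizes = batches.value_counts()
    if (sizes < 2).any():
        raise ValueError("every batch needs >= 2 samples")

    X = matrix.values
    grand_mean = X.mean(axis=1)
    grand_sd = X.std(axis=1, ddof=1)
    out = X.copy()
    for b, sample_ids in matrix.samples.groupby("batch").groups.items():
        block = X[list(sample_ids)]
        gamma = block.mean(axis=1) - grand_mean          # batch location
        delta = block.std(axis=1, ddof=1) / grand_sd     # batch scale
        delta = delta.replace([np.inf, 0], np.nan).fillna(1.0)
        if shrink:
            n_b = len(sample_ids)
            gamma_bar = gamma.mean()
            tau2 = max(gamma.var(ddof=1), 1e-12)
            resid_var = block.var(axis=1, ddof=1).fillna(grand_sd**2)
            w = tau2 / (tau2 + resid_var / n_b)
            gamma = w * gamma + (1 - w) * gamma_bar
            # moderate scale toward the across-probe mean scale
            delta = (n_b * delta + delta.mean()) / (n_b + 1)
        adj = block.sub(grand_mean + gamma, axis=0).div(delta, axis=0)
        out[list(sample_ids)] = adj.add(grand_mean, axis=0)
    return ExpressionMatrix(out, matrix.samples, None)


def interslide_correlation(matrix: ExpressionMatrix, min_shared: int = 10) -> float:
    """Mean pairwise Pearson correlation over slide vectors.

    Each pair uses only entries valid in both slides; pairs sharing fewer
    than `min_shared` valid probes are skipped with a warning.
    """
    slide_ids = matrix.slide_ids
    if len(slide_ids) < 2:
        raise ValueError("need >= 2 slides")
    stacked = pd.DataFrame(
        {sid: matrix.slide_vector(sid) for sid in slide_ids}
    )
    # pairwise-complete Pearson; pairs sharing < min_shared probes are masked
    corr = stacked.corr(min_periods=min_shared)
    valid = stacked.notna().astype(float)
    shared = valid.T @ valid
    iu = np.triu_indices(len(slide_ids), k=1)
    skipped = int((shared.to_numpy()[iu] < min_shared).sum())
    if skipped:
        warnings.warn(
            f"{skipped} slide pair(s) share fewer than {min_shared} valid "
            "probes; skipped",
            stacklevel=2,
        )
    vals = corr.to_numpy()[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no slide pair had enough shared valid probes")
    return float(np.mean(vals))


def knn_impute(matrix: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Optional KNN imputation (Euclidean over shared samples) on the
    collapsed matrix; off by default in the pipeline."""
    if matrix.slides is not None:
        raise ValueError("imputation runs on the collapsed matrix")
    X = matrix.values.to_numpy(dtype=float)
    out = X.copy()
    missing_rows = np.where(np.isnan(X).any(axis=1))[0]
    complete = ~np.isnan(X).any(axis=1)
    for i in missing_rows:
        row = X[i]
        obs = ~np.isnan(row)
        if obs.sum() == 0:
            continue
        cand = X[complete][:, obs]
        d = np.sqrt(((cand - row[obs]) ** 2).mean(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        fill = X[complete][nn].mean(axis=0)
        out[i, ~obs] = fill[~obs]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples, None)


@dataclass
class PreprocessResult:
    normalized: ExpressionMatrix
    filtered: ExpressionMatrix
    collapsed: ExpressionMatrix
    detection: DetectionTable
    adjusted: ExpressionMatrix
    interslide_correlation_raw: float
    interslide_correlation_normalized: float


def run_pipeline(
    matrix: ExpressionMatrix,
    low_intensity_fraction: float = 0.5,
    min_valid: int = 3,
    n_replicates: int = 4,
    detect_frac: float = 0.75,
    adjust_batches: bool = True,
    log2: bool = True,
) -> PreprocessResult:
    """The fixed-order preprocessing driver.

    quantile_normalize -> filter_low_intensity -> collapse_replicates ->
    detection_calls -> batch_adjust. Intensities are log2-transformed after
    normalization (the scale on which downstream statistics operate).
    """
    raw_cor = interslide_correlation(matrix)
    normalized = quantile_normalize(matrix)
    norm_cor = interslide_correlation(normalized)
    filtered = filter_low_intensity(normalized, low_intensity_fraction)
    if log2:
        filtered = ExpressionMatrix(
            np.log2(filtered.values), filtered.samples, filtered.slides
        )
    collapsed = collapse_replicates(filtered, min_valid, n_replicates)
    detection = detection_calls(collapsed, detect_frac)
    expressed = collapsed.values.loc[detection.expressed[detection.expressed].index]
    expressed_matrix = ExpressionMatrix(expressed, collapsed.samples, None)
    if adjust_batches and matrix.samples["batch"].nunique() > 1:
        adjusted = batch_adjust(expressed_matrix)
    else:
        adjusted = expressed_matrix
    return PreprocessResult(
        normalized, filtered, collapsed, detection, adjusted, raw_cor, norm_cor
    )
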