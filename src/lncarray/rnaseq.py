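"""RPKM normalization and intron-vs-flanking-exon co-expression.

Each intronic lncRNA locus is a triplet (upstream exon, intron, downstream
exon) with read counts across libraries. A triplet is analyzed only if all
three features are detected in at least 4 of the 9 libraries; Pearson
correlations over per-library RPKM vectors classify the intron as
positively (r > 0.5), poorly (-0.5 <= r <= 0.5) or negatively (r < -0.5)
correlated with its flanks. Class boundaries are strict inequalities:
r = 0.5 is "poor".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ROLES = ("up_exon", "intron", "down_exon")


def rpkm(count, feature_length, library_size):
    """Reads per kilobase of feature per million mapped reads:
    count * 1e9 / (length * library_size). Vectorized."""
    feature_length = np.asarray(feature_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (feature_length <= 0).any() if feature_length.ndim else feature_length <= 0:
        raise ValueError("feature_length must be positive")
    if (library_size <= 0).any() if library_size.ndim else library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(count, dtype=float) * 1e9 / (feature_length * library_size)


def rpkm_table(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Apply `rpkm` to a long counts table (locus_id, feature_role,
    length_bp, lib columns); returns the same shape with RPKM values."""
    libs = [c for c in counts.columns if c in library_sizes.index]
    out = counts.copy()
    out[libs] = rpkm(
        counts[libs].to_numpy(),
        counts["length_bp"].to_numpy()[:, None],
        library_sizes[libs].to_numpy()[None, :],
    )
    return out


def detect_in_libraries(
    rpkms: pd.DataFrame,
    min_libs: int = 4,
    detect_threshold: float = 0.0,
) -> pd.Series:
    """Triplet eligibility: every one of its three features must be detected
    (RPKM strictly above `detect_threshold`) in >= `min_libs` libraries."""
    if detect_threshold < 0:
        raise ValueError("detect_threshold must be >= 0")
    libs = [c for c in rpkms.columns
            if c not in ("locus_id", "feature_role", "length_bp")]
    det = (rpkms[libs] > detect_threshold).sum(axis=1)
    per_locus = (
        rpkms.assign(n_detected=det)
        .pivot_table(index="locus_id", columns="feature_role",
                     values="n_detected", aggfunc="first")
    )
    for role in ROLES:
        if role not in per_locus:
            per_locus[role] = 0
    eligible = (per_locus[list(ROLES)] >= min_libs).all(axis=1)
    eligible.name = "eligible"
    return eligible


def _classify(r: float) -> str:
    if np.isnan(r):
        return "undefined"
    if r > 0.5:
        return "positive"
    if r < -0.5:
        return "negative"
    return "poor"


def flank_correlations(
    rpkms: pd.DataFrame, eligible: pd.Series
) -> pd.DataFrame:
    """Per eligible locus: Pearson r of the intron against each flanking
    exon and between the two exons, with classes.

    The intron's headline class comes from the flank with the larger |r|;
    both per-flank values are retained. Zero-variance vectors flag the
    record and exclude it from class tallies.
    """
    libs = [c for c in rpkms.columns
            if c not in ("locus_id", "feature_role", "length_bp")]
    rows = []
    for locus, sub in rpkms.groupby("locus_id"):
        if not eligible.get(locus, False):
            continue
        vecs = {
            r.feature_role: np.asarray([getattr(r, l) for l in libs], dtype=float)
            for r in sub.itertuples()
        }
        if set(ROLES) - set(vecs):
            continue

        def corr(a, b):
            if np.std(vecs[a]) == 0 or np.std(vecs[b]) == 0:
                return np.nan
            return stats.pearsonr(vecs[a], vecs[b]).statistic

        r_up = corr("intron", "up_exon")
        r_down = corr("intron", "down_exon")
        r_ee = corr("up_exon", "down_exon")
        flagged = any(np.isnan(v) for v in (r_up, r_down, r_ee))
        if np.isnan(r_up) and np.isnan(r_down):
            headline = np.nan
        elif np.isnan(r_down) or (
            not np.isnan(r_up) and abs(r_up) >= abs(r_down)
        ):
            headline = r_up
        else:
            headline = r_down
        rows.append(
            (
                locus, r_up, r_down, r_ee, headline,
                _classify(headline), _classify(r_ee), flagged, len(libs),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "r_up", "r_down", "r_exon_exon", "r_headline",
            "intron_class", "exon_exon_class", "flagged", "n_libraries",
        ],
    ).set_index("locus_id")


@dataclass
class ClassTallies:
    eligible: int
    exon_exon_high: int      # exon-exon r > 0.5
    positive: int
    poor: int
    negative: int
    flagged: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_classes(records: pd.DataFrame) -> ClassTallies:
    """Tallies over correlation records; the three intron classes partition
    the unflagged eligible loci, flagged records are counted separately."""
    ok = records.loc[~records["flagged"].astype(bool)]
    return ClassTallies(
        eligible=len(records),
        exon_exon_high=int((ok["r_exon_exon"] > 0.5).sum()),
        positive=int((ok["intron_class"] == "positive").sum()),
        poor=int((ok["intron_class"] == "poor").sum()),
        negative=int((ok["intron_class"] == "negative").sum()),
        flagged=int(records["flagged"].sum()),
    )
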