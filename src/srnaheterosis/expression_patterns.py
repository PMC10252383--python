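"""Hybrid expression-pattern analysis on trio count matrices.

The analysis runs: RPM normalisation, expression filtering, negative-binomial
differential tests for the three trio contrasts (female vs male, hybrid vs
female, hybrid vs male), candidate selection, and classification of each
candidate by its dominance/additivity (D/A) ratio into five patterns:

=====  =============================================  ==============
class  meaning                                        D/A interval
=====  =============================================  ==============
THPE   transgressive high-parent expression           (2, +inf)
DHPE   dominant high-parent expression                (0.5, 2]
AE     additive expression                            [-0.5, 0.5]
DLPE   dominant low-parent expression                 [-2, -0.5)
TLPE   transgressive low-parent expression            (-inf, -2)
=====  =============================================  ==============

with D = RPM_hybrid - RPM_midparent, A = RPM_highparent - RPM_midparent,
all on replicate-mean normalised expression.  Boundary values go to the
less extreme class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleSheet, TrioCountMatrix

PATTERNS = ("THPE", "DHPE", "AE", "DLPE", "TLPE")
SUPERCLASS = {"THPE": "HPE", "DHPE": "HPE", "AE": "AE",
              "DLPE": "LPE", "TLPE": "LPE"}
CONTRASTS = ("FvsM", "HvsF", "HvsM")
_CONTRAST_GROUPS = {"FvsM": ("female", "male"),
                    "HvsF": ("hybrid", "female"),
                    "HvsM": ("hybrid", "male")}

#: parents-equal tolerance for the additivity denominator
EPS_ADDITIVITY = 1e-9


# ---------------------------------------------------------------------------
# normalisation and filtering
# ---------------------------------------------------------------------------

def normalize_rpm(matrix: TrioCountMatrix) -> pd.DataFrame:
    """Reads-per-million over the features in the matrix, per sample.

    Each returned column sums to 1e6.  A sample with zero total counts is an
    error.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    return matrix.counts / totals * 1e6


def filter_expressed(normalized: pd.DataFrame, threshold: float,
                     min_samples: int) -> pd.DataFrame:
    """Keep features strictly above ``threshold`` in >= ``min_samples`` samples.

    Used with RPM > 2 in >= 2 samples for small RNA, and FPKM > 0.5 in >= 2
    samples for genes.
    """
    keep = (normalized > threshold).sum(axis=1) >= min_samples
    return normalized.loc[keep]


# ---------------------------------------------------------------------------
# differential expression (negative-binomial Wald test)
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over features positive in all samples."""
    logc = np.log(counts.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        logmeans = logc.mean(axis=1)
    usable = np.isfinite(logmeans)
    if not usable.any():
        raise ValueError("no feature is positive in every sample; "
                         "cannot estimate size factors")
    ratios = logc[usable] - logmeans[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def nb_differential_test(matrix: TrioCountMatrix, contrast: str,
                         all_size_factors: pd.Series | None = None,
                         fdr_threshold: float = 0.05,
                         lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Negative-binomial Wald test for one trio contrast.

    Per feature: counts are scaled by median-of-ratios size factors; the NB
    dispersion (``var = mu + alpha * mu^2``) is estimated by method of
    moments from the pooled within-group variance, floored at 1e-8; the Wald
    statistic for the log fold change is referred to a Student-t with the
    residual degrees of freedom (n1 + n2 - 2), which keeps the test
    calibrated at the small replicate numbers typical of these designs.
    Benjamini-Hochberg FDR is computed across all tested features.

    ``significant`` is ``fdr < fdr_threshold and |log2fc| > lfc_threshold``
    (the "FDR < 0.05 and fold change > 2" rule by default).

    Returns a DataFrame indexed by feature with columns
    ``contrast, log2fc, p, fdr, significant``.  The second-named genotype of
    the contrast is the baseline.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    g1, g2 = _CONTRAST_GROUPS[contrast]
    s1 = matrix.samples.samples_of(g1)
    s2 = matrix.samples.samples_of(g2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"contrast {contrast} needs >=2 replicates per group")
    sf = all_size_factors if all_size_factors is not None \
        else size_factors(matrix.counts)
    norm = matrix.counts / sf
    c1 = norm[s1].to_numpy(dtype=float)
    c2 = norm[s2].to_numpy(dtype=float)
    n1, n2 = c1.shape[1], c2.shape[1]
    m1, m2 = c1.mean(axis=1), c2.mean(axis=1)

    ss = ((c1 - m1[:, None]) ** 2).sum(axis=1) + ((c2 - m2[:, None]) ** 2).sum(axis=1)
    s2_pooled = ss / (n1 + n2 - 2)
    mu = (m1 * n1 + m2 * n2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2_pooled - mu) / np.where(mu > 0, mu, np.nan) ** 2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, 1e-8)

    eps = 0.5  # pseudo-mean keeps zero-count groups finite
    v1 = (m1 + alpha * m1 ** 2) / n1
    v2 = (m2 + alpha * m2 ** 2) / n2
    lfc_ln = np.log(m1 + eps) - np.log(m2 + eps)
    se_ln = np.sqrt(v1 / (m1 + eps) ** 2 + v2 / (m2 + eps) ** 2)
    both_flat = (v1 + v2) == 0
    z = np.zeros_like(lfc_ln)
    nz = ~both_flat
    z[nz] = lfc_ln[nz] / np.maximum(se_ln[nz], 1e-300)
    p = 2 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    log2fc = lfc_ln / math.log(2)
    out = pd.DataFrame(
        {
            "contrast": contrast,
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "significant": (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold),
        },
        index=matrix.counts.index,
    )
    return out


def select_heterosis_candidates(de_fm: pd.DataFrame, de_hf: pd.DataFrame,
                                de_hm: pd.DataFrame) -> set[str]:
    """Features differential between the parents, or consistently shifted in
    the hybrid against both parents.

    A feature is a candidate iff it is significant in F vs M, OR significant
    in both H vs F and H vs M with the same sign of log2fc (commonly up- or
    down-regulated against both parents).
    """
    for other in (de_hf, de_hm):
        if not de_fm.index.equals(other.index):
            raise ValueError("differential-test results cover different features")
    common = (de_hf["significant"] & de_hm["significant"]
              & (np.sign(de_hf["log2fc"]) == np.sign(de_hm["log2fc"]))
              & (np.sign(de_hf["log2fc"]) != 0))
    cand = de_fm.index[de_fm["significant"] | common]
    return set(cand)


# ---------------------------------------------------------------------------
# D/A classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionPatternCall:
    """Per-feature dominance/additivity summary and pattern label."""

    feature_id: str
    rpm_f: float
    rpm_m: float
    rpm_h: float
    mpv: float
    hp: float
    dominance_d: float
    additivity_a: float
    da_ratio: float
    pattern: str

    @property
    def superclass(self) -> str:
        return SUPERCLASS[self.pattern]


def classify_da(da_ratio: float) -> str:
    """Map a D/A ratio (possibly +/-inf) to one of the five patterns.

    Boundaries go to the less extreme class: exactly 2 is DHPE, exactly 0.5
    is AE, etc.
    """
    if math.isnan(da_ratio):
        raise ValueError("D/A ratio is NaN")
    if da_ratio > 2:
        return "THPE"
    if da_ratio > 0.5:
        return "DHPE"
    if da_ratio >= -0.5:
        return "AE"
    if da_ratio >= -2:
        return "DLPE"
    return "TLPE"


def classify_expression_pattern(rpm_f: float, rpm_m: float, rpm_h: float,
                                feature_id: str = "") -> ExpressionPatternCall:
    """Compute D, A and D/A from replicate-mean expression and classify.

    When the parents are (numerically) equal the additivity denominator
    vanishes; the call is then AE if the hybrid also equals the shared
    parental level, otherwise THPE/TLPE by the sign of D with D/A recorded
    as +/-inf.
    """
    if min(rpm_f, rpm_m, rpm_h) < 0:
        raise ValueError("expression means must be non-negative")
    mpv = (rpm_f + rpm_m) / 2
    hp = max(rpm_f, rpm_m)
    d = rpm_h - mpv
    a = hp - mpv
    if a < EPS_ADDITIVITY:
        if abs(d) < EPS_ADDITIVITY * max(1.0, mpv):
            da, pattern = 0.0, "AE"
        else:
            da = math.inf if d > 0 else -math.inf
            pattern = "THPE" if d > 0 else "TLPE"
    else:
        da = d / a
        pattern = classify_da(da)
    return ExpressionPatternCall(feature_id, rpm_f, rpm_m, rpm_h,
                                 mpv, hp, d, a, da, pattern)


def classify_matrix(rpm: pd.DataFrame, samples: SampleSheet,
                    feature_ids=None) -> pd.DataFrame:
    """Classify every (or the given) features of a normalised matrix.

    Replicate means per genotype feed :func:`classify_expression_pattern`.
    Returns a DataFrame indexed by feature with the call fields.
    """
    sub = rpm if feature_ids is None else rpm.loc[list(feature_ids)]
    means = {g: sub[samples.samples_of(g)].mean(axis=1) for g in
             ("female", "male", "hybrid")}
    rows = []
    for fid in sub.index:
        call = classify_expression_pattern(
            float(means["female"][fid]), float(means["male"][fid]),
            float(means["hybrid"][fid]), feature_id=str(fid))
        rows.append((call.feature_id, call.rpm_f, call.rpm_m, call.rpm_h,
                     call.mpv, call.hp, call.dominance_d, call.additivity_a,
                     call.da_ratio, call.pattern, call.superclass))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "rpm_f", "rpm_m", "rpm_h", "mpv", "hp",
                 "dominance_d", "additivity_a", "da_ratio", "pattern",
                 "superclass"],
    ).set_index("feature_id")


def summarize_patterns(calls: pd.DataFrame | list) -> dict[str, int]:
    """Tallies per pattern plus the HPE/LPE/AE superclass totals."""
    if isinstance(calls, pd.DataFrame):
        patterns = list(calls["pattern"])
    else:
        patterns = [c.pattern if isinstance(c, ExpressionPatternCall) else c
                    for c in calls]
    counts = {p: 0 for p in PATTERNS}
    for p in patterns:
        if p not in counts:
            raise ValueError(f"unknown pattern {p!r}")
        counts[p] += 1
    counts["HPE"] = counts["THPE"] + counts["DHPE"]
    counts["LPE"] = counts["TLPE"] + counts["DLPE"]
    counts["total"] = len(patterns)
    return counts


def run_expression_analysis(matrix: TrioCountMatrix,
                            expressed_threshold: float = 2.0,
                            min_samples: int = 2,
                            fdr_threshold: float = 0.05,
                            lfc_threshold: float = 1.0) -> dict:
    """Full expression stage: normalise, filter, test, select, classify.

    Returns a dict with the normalised matrix, the three differential-test
    tables, the candidate set and the classified calls (candidates only).
    """
    rpm = normalize_rpm(matrix)
    kept = filter_expressed(rpm, expressed_threshold, min_samples)
    filtered = TrioCountMatrix(matrix.counts.loc[kept.index], matrix.samples,
                               matrix.feature_kind)
    sf = size_factors(filtered.counts)
    de = {c: nb_differential_test(filtered, c, sf, fdr_threshold,
                                  lfc_threshold) for c in CONTRASTS}
    candidates = select_heterosis_candidates(de["FvsM"], de["HvsF"], de["HvsM"])
    calls = classify_matrix(kept, matrix.samples, sorted(candidates))
    return {"rpm": rpm, "expressed": kept, "de": de,
            "candidates": candidates, "calls": calls,
            "summary": summarize_patterns(calls)}
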