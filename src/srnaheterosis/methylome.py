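"""Weighted methylation levels, differential methylation and Met_d/a patterns.

Bisulfite cytosine calls for the trio (female, male, hybrid; two or more
replicates each) are pooled per genotype by summing reads per cytosine.
Region methylation is the weighted methylation level (WML): summed
methylated reads over summed total reads across the region's cytosines of
one context, counting only cytosines with pooled coverage >= 5 reads.

Hybrid methylation patterns are classified by the methylation
dominance/additivity statistic

    Met_d/a = (WML_H - WML_MPV) / max(|WML_F - WML_MPV|, |WML_M - WML_MPV|)

which, for distinct parents, equals 2 * (WML_H - MPV) / |WML_F - WML_M|.
Met_d/a > 0.5 is TCM (trans-chromosomal methylation), < -0.5 is TCdM
(trans-chromosomal demethylation), the rest is NIM (non-interactive
methylation); boundary values are NIM.

Differential methylation between two genotypes over predefined regions is a
two-sided Mann-Whitney U test between the groups' per-cytosine methylation
levels, BH-corrected across regions within a context.  A region is called
differentially methylated when it has >= 4 eligible cytosines, FDR < 0.05
and an absolute mean difference above the context threshold (0.1 for CG and
CHG, 0.05 for CHH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CONTEXTS, GenomicInterval

MIN_COVERAGE = 5
MIN_CYTOSINES = 4
DIFF_THRESHOLDS = {"CG": 0.1, "CHG": 0.1, "CHH": 0.05}
MET_DA_CUT = 0.5
METH_PATTERNS = ("TCM", "TCdM", "NIM")


# ---------------------------------------------------------------------------
# pooling and WML
# ---------------------------------------------------------------------------

def pool_replicates(calls_by_sample: dict[str, pd.DataFrame],
                    sample_ids: list[str]) -> pd.DataFrame:
    """Sum meth/total reads per cytosine over a genotype's replicates.

    Cytosines are keyed by (chrom, pos0, strand, context); replicates may
    cover different subsets — absent rows contribute zero reads.
    """
    frames = []
    for s in sample_ids:
        if s not in calls_by_sample:
            raise KeyError(f"no cytosine calls for sample {s!r}")
        frames.append(calls_by_sample[s])
    cat = pd.concat(frames, ignore_index=True)
    pooled = (cat.groupby(["chrom", "pos0", "strand", "context"],
                          sort=True, observed=True)[["meth_reads", "total_reads"]]
              .sum().reset_index())
    return pooled


def compute_wml(calls: pd.DataFrame, region: GenomicInterval, context: str,
                min_coverage: int = MIN_COVERAGE) -> tuple[float, int]:
    """Weighted methylation level of one region in one (pooled) genotype.

    ``calls`` is a pooled cytosine table.  Only cytosines of ``context``
    inside ``region`` with total_reads >= ``min_coverage`` count.  Returns
    ``(wml, n_cytosines)``; with no passing cytosine the WML is undefined
    and returned as NaN (never 0).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sel = calls[(calls["chrom"] == region.chrom)
                & (calls["pos0"] >= region.start)
                & (calls["pos0"] < region.end)
                & (calls["context"] == context)
                & (calls["total_reads"] >= min_coverage)]
    n = len(sel)
    if n == 0:
        return (math.nan, 0)
    return (float(sel["meth_reads"].sum() / sel["total_reads"].sum()), n)


def region_wml_table(pooled: dict[str, pd.DataFrame],
                     regions: list[GenomicInterval], context: str,
                     min_coverage: int = MIN_COVERAGE) -> pd.DataFrame:
    """WML of every region for each pooled genotype.

    ``pooled`` maps genotype -> pooled cytosine table.  Returns a DataFrame
    indexed by region id with columns ``wml_<genotype>``,
    ``n_cyt_<genotype>`` and ``mpv_wml``.
    """
    per_genotype: dict[str, dict] = {}
    for geno, calls in pooled.items():
        sub = calls[(calls["context"] == context)
                    & (calls["total_reads"] >= min_coverage)]
        sub = sub.sort_values(["chrom", "pos0"], kind="mergesort")
        grouped = {c: g for c, g in sub.groupby("chrom", observed=True)}
        per_genotype[geno] = grouped
    rows = []
    for region in regions:
        rec: dict = {"region_id": region.id}
        for geno, by_chrom in per_genotype.items():
            g = by_chrom.get(region.chrom)
            if g is None:
                rec[f"wml_{geno}"], rec[f"n_cyt_{geno}"] = math.nan, 0
                continue
            pos = g["pos0"].to_numpy()
            lo = np.searchsorted(pos, region.start, side="left")
            hi = np.searchsorted(pos, region.end, side="left")
            if hi <= lo:
                rec[f"wml_{geno}"], rec[f"n_cyt_{geno}"] = math.nan, 0
            else:
                meth = g["meth_reads"].to_numpy()[lo:hi].sum()
                tot = g["total_reads"].to_numpy()[lo:hi].sum()
                rec[f"wml_{geno}"] = float(meth / tot)
                rec[f"n_cyt_{geno}"] = int(hi - lo)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("region_id")
    if {"wml_female", "wml_male"} <= set(out.columns):
        out["mpv_wml"] = (out["wml_female"] + out["wml_male"]) / 2
    return out


def make_bins(chrom_sizes: dict[str, int], width: int = 100) -> list[GenomicInterval]:
    """Tile each chromosome with non-overlapping left-closed bins.

    The last partial bin is retained, so the bins conserve genome length.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    bins: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive size")
        for i, start in enumerate(range(0, size, width)):
            end = min(start + width, size)
            bins.append(GenomicInterval(chrom, start, end, ".", "dmr_bin",
                                        f"{chrom}:{start}-{end}"))
    return bins


# ---------------------------------------------------------------------------
# differential methylation
# ---------------------------------------------------------------------------

def region_dm_test(calls_by_sample: dict[str, pd.DataFrame],
                   regions: list[GenomicInterval], context: str,
                   group1: list[str], group2: list[str],
                   diff_threshold: float | None = None,
                   min_coverage: int = MIN_COVERAGE,
                   min_cytosines: int = MIN_CYTOSINES,
                   fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Rank-based differential methylation over predefined regions.

    Reads are pooled within each group; a cytosine is eligible when covered
    >= ``min_coverage`` in both groups.  Per region the two groups'
    per-cytosine methylation levels are compared with a two-sided
    Mann-Whitney U test (exact where SciPy permits, normal approximation
    with tie correction otherwise), BH-corrected across all tested regions.
    ``meth_diff`` is group1 minus group2 mean per-cytosine level.

    Regions with zero eligible cytosines are excluded from testing and
    reported with ``tested = False``.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs >=2 replicates")
    if diff_threshold is None:
        diff_threshold = DIFF_THRESHOLDS[context]
    p1 = pool_replicates(calls_by_sample, group1)
    p2 = pool_replicates(calls_by_sample, group2)
    key = ["chrom", "pos0", "strand", "context"]
    merged = p1.merge(p2, on=key, suffixes=("_1", "_2"))
    merged = merged[(merged["context"] == context)
                    & (merged["total_reads_1"] >= min_coverage)
                    & (merged["total_reads_2"] >= min_coverage)]
    merged = merged.sort_values(["chrom", "pos0"], kind="mergesort")
    merged["lv1"] = merged["meth_reads_1"] / merged["total_reads_1"]
    merged["lv2"] = merged["meth_reads_2"] / merged["total_reads_2"]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, g in merged.groupby("chrom", observed=True):
        by_chrom[str(chrom)] = (g["pos0"].to_numpy(),
                                g["lv1"].to_numpy(), g["lv2"].to_numpy())
    rows = []
    for region in regions:
        entry = by_chrom.get(region.chrom)
        if entry is None:
            rows.append((region.id, 0, math.nan, math.nan, False))
            continue
        pos, a, b = entry
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        n = hi - lo
        if n == 0:
            rows.append((region.id, 0, math.nan, math.nan, False))
            continue
        x, y = a[lo:hi], b[lo:hi]
        diff = float(x.mean() - y.mean())
        if np.all(x == y):
            p = 1.0
        else:
            # exact null distribution where cheap; normal approximation with
            # tie correction for larger regions
            method = "exact" if n <= 12 else "asymptotic"
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method=method).pvalue)
        rows.append((region.id, int(n), diff, p, True))
    out = pd.DataFrame(rows, columns=["region_id", "n_cytosines",
                                      "meth_diff", "p", "tested"]
                       ).set_index("region_id")
    out["context"] = context
    tested = out["tested"].to_numpy()
    fdr = np.full(len(out), math.nan)
    if tested.any():
        fdr[tested] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["significant"] = (tested
                          & (out["n_cytosines"] >= min_cytosines)
                          & (out["fdr"] < fdr_threshold)
                          & (out["meth_diff"].abs() >= diff_threshold))
    return out


def select_methylation_candidates(dm_fm: pd.DataFrame, dm_hf: pd.DataFrame,
                                  dm_hm: pd.DataFrame) -> set[str]:
    """Regions differentially methylated between parents, or consistently
    hyper-/hypo-methylated in the hybrid against both parents.

    Mirrors the expression candidate rule: significant in F vs M, OR
    significant in both hybrid contrasts with the same sign of meth_diff
    (hybrid is group1 in the hybrid contrasts).
    """
    for other in (dm_hf, dm_hm):
        if not dm_fm.index.equals(other.index):
            raise ValueError("differential-methylation tables cover "
                             "different regions")
    common = (dm_hf["significant"] & dm_hm["significant"]
              & (np.sign(dm_hf["meth_diff"]) == np.sign(dm_hm["meth_diff"]))
              & (np.sign(dm_hf["meth_diff"]) != 0))
    return set(dm_fm.index[dm_fm["significant"] | common])


# ---------------------------------------------------------------------------
# Met_d/a classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylationPatternCall:
    """Per-region Met_d/a and TCM/TCdM/NIM label for one context."""

    region_id: str
    context: str
    wml_f: float
    wml_m: float
    wml_h: float
    mpv: float
    met_da: float
    pattern: str


def classify_met_da_value(met_da: float, cut: float = MET_DA_CUT) -> str:
    """Map a Met_d/a value (possibly +/-inf) to TCM/TCdM/NIM.

    Boundaries +/-cut go to NIM (the strict inequalities of the defining
    rule leave them open; the conservative call is non-interactive).
    """
    if math.isnan(met_da):
        raise ValueError("Met_d/a is NaN")
    if met_da > cut:
        return "TCM"
    if met_da < -cut:
        return "TCdM"
    return "NIM"


def classify_met_da(wml_f: float, wml_m: float, wml_h: float,
                    region_id: str = "", context: str = "CG",
                    cut: float = MET_DA_CUT) -> MethylationPatternCall:
    """Classify a region's hybrid methylation pattern from trio WMLs.

    Met_d/a = (H - MPV) / max(|F - MPV|, |M - MPV|); TCM above ``cut``,
    TCdM below ``-cut``, NIM otherwise (boundaries inclusive to NIM).  With
    equal parents the denominator vanishes: NIM if the hybrid sits at the
    shared parental level, else TCM/TCdM by sign with Met_d/a +/-inf.
    """
    for v in (wml_f, wml_m, wml_h):
        if v is None or math.isnan(v):
            raise ValueError("all three WMLs must be defined")
    mpv = (wml_f + wml_m) / 2
    denom = max(abs(wml_f - mpv), abs(wml_m - mpv))
    num = wml_h - mpv
    if denom == 0:
        if num == 0:
            met_da, pattern = 0.0, "NIM"
        else:
            met_da = math.inf if num > 0 else -math.inf
            pattern = "TCM" if num > 0 else "TCdM"
    else:
        met_da = num / denom
        pattern = classify_met_da_value(met_da, cut)
    return MethylationPatternCall(region_id, context, wml_f, wml_m, wml_h,
                                  mpv, met_da, pattern)


def classify_met_da_table(wml: pd.DataFrame, context: str) -> pd.DataFrame:
    """Vectorised Met_d/a classification of a :func:`region_wml_table` result.

    Regions with any undefined WML are dropped (reported via the returned
    frame's ``attrs['n_undefined']``).
    """
    cols = ["wml_female", "wml_male", "wml_hybrid"]
    ok = wml[cols].notna().all(axis=1)
    sub = wml.loc[ok]
    rows = []
    for rid, f, m, h in zip(sub.index, sub["wml_female"], sub["wml_male"],
                            sub["wml_hybrid"]):
        call = classify_met_da(float(f), float(m), float(h),
                               region_id=str(rid), context=context)
        rows.append((call.region_id, call.context, call.wml_f, call.wml_m,
                     call.wml_h, call.mpv, call.met_da, call.pattern))
    out = pd.DataFrame(rows, columns=["region_id", "context", "wml_f",
                                      "wml_m", "wml_h", "mpv", "met_da",
                                      "pattern"]).set_index("region_id")
    out.attrs["n_undefined"] = int((~ok).sum())
    return out


def wml_shift_test(hybrid_wml, mpv_wml) -> tuple[int, float]:
    """Two-sided Wilcoxon rank-sum of hybrid WMLs against mid-parent WMLs.

    Returns ``(direction, p)`` where direction is the sign of the median
    paired difference (+1 hybrid above MPV, -1 below, 0 no shift).
    """
    h = np.asarray(hybrid_wml, dtype=float)
    m = np.asarray(mpv_wml, dtype=float)
    if h.shape != m.shape:
        raise ValueError("vectors must have equal length")
    if h.size == 0:
        raise ValueError("empty input")
    if np.array_equal(h, m):
        return (0, 1.0)
    p = float(stats.ranksums(h, m).pvalue)
    direction = int(np.sign(np.median(h - m)))
    return (direction, p)
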