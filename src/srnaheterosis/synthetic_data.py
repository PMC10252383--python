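"""Trio datasets with planted ground truth for end-to-end validation.

Three generators emulate the statistical structure of a maize
female/male/hybrid trio:

* :func:`simulate_trio_counts` — feature x sample count matrices with each
  feature planted in one of the five D/A expression classes.  Parental
  means differ by a configurable log2 fold change; the hybrid mean is
  planted on the D/A scale (midpoint of the finite class intervals, +/-3
  for the transgressive classes) so that truth aligns with the
  classifier's geometry; counts are negative-binomial.
* :func:`simulate_methylome` — per-sample cytosine calls over regions
  planted as TCM / TCdM / NIM.  Parental methylation targets are distinct;
  the hybrid target is planted on the Met_d/a scale (+1 / -1 / 0);
  coverage is Poisson and methylated reads are beta-binomial, replicate
  overdispersion being the realistic failure mode of the rank-based region
  test.
* :func:`simulate_annotation` — a toy genome with stranded genes, TEs and
  clusters placed in known feature categories.

Everything is deterministic given ``SimulationConfig.seed`` (a single
``numpy.random.default_rng`` stream per generator, consumed in a fixed
order).

A note on transgressive feasibility: a hybrid mean for D/A = -3 exists only
when the parental ratio is below 2 (otherwise the mean would be negative).
For features whose planted D/A would push the hybrid mean below a quarter
of the mid-parent value, the generator shrinks that feature's parental gap
just enough to restore the margin; the truth table records the D/A actually
planted, which is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, SampleSheet, TrioCountMatrix

EXPR_DA_TARGETS = {"THPE": 3.0, "DHPE": 1.25, "AE": 0.0,
                   "DLPE": -1.25, "TLPE": -3.0}
METH_DA_TARGETS = {"TCM": 1.0, "TCdM": -1.0, "NIM": 0.0}

#: minimum planted hybrid mean as a fraction of the mid-parent value
HYBRID_MEAN_FLOOR = 0.25


def _default_expr_props():
    return {"THPE": 0.10, "DHPE": 0.20, "AE": 0.40, "DLPE": 0.20, "TLPE": 0.10}


def _default_meth_props():
    return {"TCM": 1 / 3, "TCdM": 1 / 3, "NIM": 1 / 3}


@dataclass
class SimulationConfig:
    """Knobs for all three generators; defaults follow the trio design
    (3 expression replicates, 2 methylome replicates) and a strong-effect
    regime (4-fold parental expression difference, 0.4 parental WML gap)."""

    seed: int = 0
    # expression
    n_features: int = 2000
    class_proportions: dict = field(default_factory=_default_expr_props)
    base_mean_range: tuple = (100.0, 1000.0)
    nb_dispersion: float = 0.05
    parental_log2fc: float = 2.0
    n_reps_expr: int = 3
    # methylome
    n_regions: int = 1000
    meth_class_proportions: dict = field(default_factory=_default_meth_props)
    cytosines_per_region: tuple = (12, 30)
    coverage_mean: float = 50.0
    bb_overdispersion: float = 0.05
    parental_meth_levels: tuple = (0.7, 0.3)
    n_reps_meth: int = 2
    # annotation
    gene_length: int = 2000
    te_length: int = 500
    cluster_length: int = 200
    flank: int = 2000

    def validate(self) -> None:
        for name, props in (("class_proportions", self.class_proportions),
                            ("meth_class_proportions",
                             self.meth_class_proportions)):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(v < 0 for v in props.values()):
                raise ValueError(f"{name} must be non-negative")
        non_ae = sum(v for k, v in self.class_proportions.items() if k != "AE")
        if self.parental_log2fc == 0 and non_ae == 0:
            # equal parents make every D/A class degenerate (A = 0)
            raise ValueError("parental_log2fc = 0 leaves no additivity; "
                             "the planted classes are degenerate")
        if self.parental_meth_levels[0] == self.parental_meth_levels[1]:
            raise ValueError("parental methylation levels must differ "
                             "(Met_d/a denominator would vanish)")
        if not (0 < self.bb_overdispersion < 1):
            raise ValueError("bb_overdispersion must be in (0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


def _class_assignment(props: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic composition matching the proportions as closely as an
    integer split allows, then shuffled."""
    classes = sorted(props)
    counts = {c: int(np.floor(props[c] * n)) for c in classes}
    rest = n - sum(counts.values())
    frac = sorted(classes, key=lambda c: props[c] * n - counts[c], reverse=True)
    for c in frac[:rest]:
        counts[c] += 1
    labels = np.concatenate([np.full(counts[c], c, dtype=object)
                             for c in classes])
    rng.shuffle(labels)
    return labels


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
             size) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mean), size=size)


def trio_sample_sheet(n_reps: int, prefix: str = "") -> SampleSheet:
    ids, genos, reps = [], [], []
    for geno, tag in (("female", "F"), ("male", "M"), ("hybrid", "H")):
        for r in range(1, n_reps + 1):
            ids.append(f"{prefix}{tag}{r}")
            genos.append(geno)
            reps.append(r)
    return SampleSheet(tuple(ids), tuple(genos), tuple(reps))


def simulate_trio_counts(config: SimulationConfig
                         ) -> tuple[TrioCountMatrix, pd.DataFrame]:
    """Draw a trio count matrix with planted D/A classes.

    Returns the matrix and a truth table (feature_id, planted_class,
    planted_effect = the planted D/A, f_mean, m_mean, h_mean).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    labels = _class_assignment(config.class_proportions, n, rng)
    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    swap = rng.random(n) < 0.5  # which parent is the high one

    ratio_req = 2.0 ** config.parental_log2fc
    f_mean = np.empty(n)
    m_mean = np.empty(n)
    h_mean = np.empty(n)
    planted = np.empty(n)
    for i, cls in enumerate(labels):
        da = EXPR_DA_TARGETS[str(cls)]
        r = ratio_req
        if da < 0:
            # keep the hybrid mean above HYBRID_MEAN_FLOOR * MPV:
            # h/mpv = 1 + da (r-1)/(r+1) >= floor  =>  r <= (q - da)/(-da - q)
            q = 1.0 - HYBRID_MEAN_FLOOR
            if -da > q:
                r = min(r, (q - da) / (-da - q))
        low, high = base[i], base[i] * r
        mpv = (low + high) / 2
        a = (high - low) / 2
        h_mean[i] = mpv + da * a
        if swap[i]:
            f_mean[i], m_mean[i] = high, low
        else:
            f_mean[i], m_mean[i] = low, high
        planted[i] = da

    sheet = trio_sample_sheet(config.n_reps_expr)
    cols = {}
    for geno, means in (("female", f_mean), ("male", m_mean),
                        ("hybrid", h_mean)):
        for s in sheet.samples_of(geno):
            cols[s] = _nb_draw(rng, means, config.nb_dispersion, n)
    feature_ids = [f"feat_{i:05d}" for i in range(n)]
    counts = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"),
                          columns=list(sheet.sample_ids))
    truth = pd.DataFrame({
        "feature_id": feature_ids,
        "planted_class": labels.astype(str),
        "planted_effect": planted,
        "f_mean": f_mean, "m_mean": m_mean, "h_mean": h_mean,
    }).set_index("feature_id")
    return TrioCountMatrix(counts, sheet, "sirna_cluster"), truth


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

_REGION_SPACING = 1000
_CYT_SPACING = 6
_CONTEXT_CYCLE = ("CG", "CHG", "CHH")


def _beta_binomial(rng: np.random.Generator, level: np.ndarray,
                   coverage: np.ndarray, rho: float) -> np.ndarray:
    level = np.clip(level, 1e-6, 1 - 1e-6)
    conc = (1 - rho) / rho
    p = rng.beta(level * conc, (1 - level) * conc)
    return rng.binomial(coverage, p)


def simulate_methylome(config: SimulationConfig
                       ) -> tuple[dict[str, pd.DataFrame],
                                  list[GenomicInterval], pd.DataFrame]:
    """Draw per-sample cytosine calls over regions planted TCM/TCdM/NIM.

    Regions tile a single toy chromosome ("chrM") one per kilobase; each
    region's cytosines cycle through the CG/CHG/CHH contexts and share the
    region's methylation target, so the planted class is recoverable in
    every context.  Returns (calls per sample, regions, truth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_regions
    labels = _class_assignment(config.meth_class_proportions, n, rng)
    lv_a, lv_b = config.parental_meth_levels
    hi_lv, lo_lv = max(lv_a, lv_b), min(lv_a, lv_b)
    swap = rng.random(n) < 0.5
    n_cyt = rng.integers(config.cytosines_per_region[0],
                         config.cytosines_per_region[1] + 1, n)

    regions: list[GenomicInterval] = []
    rows_truth = []
    chrom = "chrM"
    f_t = np.where(swap, lo_lv, hi_lv)
    m_t = np.where(swap, hi_lv, lo_lv)
    mpv = (f_t + m_t) / 2
    dev = np.abs(f_t - mpv)
    targets = {"female": f_t, "male": m_t}
    h_t = np.array([mpv[i] + METH_DA_TARGETS[str(labels[i])] * dev[i]
                    for i in range(n)])
    targets["hybrid"] = np.clip(h_t, 0.0, 1.0)

    cyt_chrom, cyt_region, cyt_context = [], [], []
    for i in range(n):
        start = i * _REGION_SPACING
        end = start + int(n_cyt[i]) * _CYT_SPACING
        rid = f"region_{i:05d}"
        regions.append(GenomicInterval(chrom, start, end, ".",
                                       "sirna_cluster", rid))
        rows_truth.append((rid, str(labels[i]), METH_DA_TARGETS[str(labels[i])],
                           float(f_t[i]), float(m_t[i]),
                           float(targets["hybrid"][i])))
        for j in range(int(n_cyt[i])):
            cyt_region.append(i)
            cyt_context.append(_CONTEXT_CYCLE[j % 3])
    cyt_region = np.asarray(cyt_region)
    pos0 = np.concatenate([
        np.arange(int(n_cyt[i])) * _CYT_SPACING + i * _REGION_SPACING
        for i in range(n)])
    n_c = len(pos0)

    sheet = trio_sample_sheet(config.n_reps_meth)
    calls: dict[str, pd.DataFrame] = {}
    for geno in ("female", "male", "hybrid"):
        level = targets[geno][cyt_region]
        for s in sheet.samples_of(geno):
            cov = rng.poisson(config.coverage_mean, n_c)
            meth = _beta_binomial(rng, level, cov, config.bb_overdispersion)
            df = pd.DataFrame({
                "chrom": chrom, "pos0": pos0, "strand": "+",
                "context": cyt_context,
                "meth_reads": meth.astype(np.int64),
                "total_reads": cov.astype(np.int64),
            })
            df.attrs["sample_id"] = s
            calls[s] = df
    truth = pd.DataFrame(rows_truth,
                         columns=["region_id", "planted_class",
                                  "planted_effect", "f_wml", "m_wml",
                                  "h_wml"]).set_index("region_id")
    return calls, regions, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_SLOT = 20000  # one gene/TE/cluster neighbourhood per 20 kb


def simulate_annotation(config: SimulationConfig,
                        category_counts: dict[str, int] | None = None,
                        n_mirna_pairs: int = 0
                        ) -> dict:
    """Toy genome annotation with clusters placed in known categories.

    ``category_counts`` maps gene_body/up2kb/down2kb/TE/intergenic to the
    number of clusters wanted there (default 4 each).  One 20-kb slot per
    cluster holds a stranded gene (alternating strands), a TE and the
    cluster itself, so placements never interfere; a genome too small for
    the request is an error.

    Returns a dict with ``genes``, ``tes``, ``clusters`` (interval lists),
    ``truth`` (DataFrame cluster_id -> planted category/linked gene) and
    ``pairs`` (miRNA-target table pairing synthetic miRNA ids with gene
    ids, empty unless ``n_mirna_pairs`` is set).
    """
    config.validate()
    if category_counts is None:
        category_counts = {c: 4 for c in
                           ("gene_body", "up2kb", "down2kb", "TE", "intergenic")}
    bad = set(category_counts) - {"gene_body", "up2kb", "down2kb", "TE",
                                  "intergenic"}
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    rng = np.random.default_rng(config.seed + 2)
    glen, tlen, clen = config.gene_length, config.te_length, config.cluster_length
    if config.flank + glen + tlen + clen + 6000 > _SLOT:
        raise ValueError("overcrowded genome: feature sizes exceed slot")
    genes: list[GenomicInterval] = []
    tes: list[GenomicInterval] = []
    clusters: list[GenomicInterval] = []
    rows = []
    slot = 0
    chrom = "chr1"
    for category in ("gene_body", "up2kb", "down2kb", "TE", "intergenic"):
        for k in range(category_counts.get(category, 0)):
            base = slot * _SLOT
            strand = "+" if slot % 2 == 0 else "-"
            gene = GenomicInterval(chrom, base + 5000, base + 5000 + glen,
                                   strand, "gene", f"gene_{slot:04d}")
            te = GenomicInterval(chrom, base + 12000, base + 12000 + tlen,
                                 ".", "TE", f"te_{slot:04d}")
            cid = f"cluster_{slot:04d}"
            linked: str | None = gene.id
            if category == "gene_body":
                genes.append(gene)
                tes.append(te)
                off = int(rng.integers(0, glen - clen))
                c = GenomicInterval(chrom, gene.start + off,
                                    gene.start + off + clen, ".",
                                    "sirna_cluster", cid)
            elif category in ("up2kb", "down2kb"):
                genes.append(gene)
                tes.append(te)
                upstream = (category == "up2kb") == (strand == "+")
                if upstream:
                    win = (gene.start - config.flank, gene.start)
                else:
                    win = (gene.end, gene.end + config.flank)
                off = int(rng.integers(0, config.flank - clen))
                c = GenomicInterval(chrom, win[0] + off, win[0] + off + clen,
                                    ".", "sirna_cluster", cid)
            elif category == "TE":
                # no gene in this slot: keeps the TE out of any flank
                tes.append(te)
                off = int(rng.integers(0, tlen - clen)) if tlen > clen else 0
                c = GenomicInterval(chrom, te.start + off, te.start + off + clen,
                                    ".", "sirna_cluster", cid)
                linked = None
            else:  # intergenic: empty slot
                c = GenomicInterval(chrom, base + 16000, base + 16000 + clen,
                                    ".", "sirna_cluster", cid)
                linked = None
            clusters.append(c)
            rows.append((cid, category, linked))
            slot += 1
    truth = pd.DataFrame(rows, columns=["cluster_id", "planted_category",
                                        "linked_gene_id"]
                         ).set_index("cluster_id")
    pairs = pd.DataFrame(columns=["mirna_id", "target_gene_id", "source"])
    if n_mirna_pairs:
        if not genes:
            raise ValueError("cannot make miRNA-target pairs without genes")
        gids = [g.id for g in genes]
        pairs = pd.DataFrame({
            "mirna_id": [f"mir_{i:03d}" for i in range(n_mirna_pairs)],
            "target_gene_id": [gids[i % len(gids)]
                               for i in range(n_mirna_pairs)],
            "source": ["predicted"] * n_mirna_pairs,
        })
    return {"genes": genes, "tes": tes, "clusters": clusters,
            "truth": truth, "pairs": pairs}
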