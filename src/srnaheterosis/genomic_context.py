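"""Placement of siRNA clusters relative to genes, TEs and DMRs.

Clusters are annotated to one of five categories with a fixed precedence:
gene body > 5' upstream 2 kb > 3' downstream 2 kb > TE > intergenic.  Flank
windows are strand-aware and measured from the annotated gene start/end;
"any base overlap" on half-open intervals decides membership.  Within a
precedence tier the nearest gene (ties broken by lexicographic id) is
linked.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from intervaltree import IntervalTree

from .io_formats import GenomicInterval

CATEGORIES = ("gene_body", "up2kb", "down2kb", "TE", "intergenic")
FLANK = 2000
GENE_CATEGORIES = ("gene_body", "up2kb", "down2kb")
SIZE_CLASSES = tuple(range(18, 25))


@dataclass(frozen=True)
class ClusterAnnotation:
    cluster_id: str
    category: str
    linked_gene_id: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in GENE_CATEGORIES and not self.linked_gene_id:
            raise ValueError(f"{self.category} annotation needs a linked gene")


@dataclass(frozen=True)
class SizeClassCall:
    cluster_id: str
    length_histogram: dict
    dominant_class: int | None  # None = ambiguous tie


def _flanks(gene: GenomicInterval, flank: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(up2kb, down2kb) windows of a gene as half-open intervals."""
    if gene.strand == "+":
        up = (max(0, gene.start - flank), gene.start)
        down = (gene.end, gene.end + flank)
    elif gene.strand == "-":
        up = (gene.end, gene.end + flank)
        down = (max(0, gene.start - flank), gene.start)
    else:
        raise ValueError(f"gene {gene.id!r} must be stranded")
    return up, down


class FeatureIndex:
    """Interval-tree index over genes (body + flanks) and TEs for fast
    cluster annotation."""

    def __init__(self, genes: list[GenomicInterval], tes: list[GenomicInterval],
                 flank: int = FLANK):
        self.flank = flank
        self.genes = {g.id: g for g in genes}
        self._body: dict[str, IntervalTree] = {}
        self._up: dict[str, IntervalTree] = {}
        self._down: dict[str, IntervalTree] = {}
        self._te: dict[str, IntervalTree] = {}
        for g in genes:
            self._body.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
            up, down = _flanks(g, flank)
            if up[0] < up[1]:
                self._up.setdefault(g.chrom, IntervalTree()).addi(*up, g)
            if down[0] < down[1]:
                self._down.setdefault(g.chrom, IntervalTree()).addi(*down, g)
        for t in tes:
            self._te.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)

    def _hits(self, trees, cluster):
        tree = trees.get(cluster.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(cluster.start, cluster.end)]

    def annotate(self, cluster: GenomicInterval) -> ClusterAnnotation:
        for category, trees in (("gene_body", self._body),
                                ("up2kb", self._up),
                                ("down2kb", self._down)):
            hits = self._hits(trees, cluster)
            if hits:
                best = min(hits, key=lambda g: (_gene_distance(cluster, g), g.id))
                return ClusterAnnotation(cluster.id, category, best.id)
        if self._hits(self._te, cluster):
            return ClusterAnnotation(cluster.id, "TE")
        return ClusterAnnotation(cluster.id, "intergenic")


def _gene_distance(cluster: GenomicInterval, gene: GenomicInterval) -> int:
    """Gap between cluster and gene body (0 when they touch or overlap)."""
    if cluster.start < gene.end and gene.start < cluster.end:
        return 0
    return gene.start - cluster.end if gene.start >= cluster.end \
        else cluster.start - gene.end


def annotate_cluster(cluster: GenomicInterval, genes: list[GenomicInterval],
                     tes: list[GenomicInterval],
                     flank: int = FLANK) -> ClusterAnnotation:
    """Annotate a single cluster (convenience over :class:`FeatureIndex`)."""
    return FeatureIndex(genes, tes, flank).annotate(cluster)


def annotate_clusters(clusters: list[GenomicInterval],
                      genes: list[GenomicInterval],
                      tes: list[GenomicInterval],
                      flank: int = FLANK) -> list[ClusterAnnotation]:
    index = FeatureIndex(genes, tes, flank)
    return [index.annotate(c) for c in clusters]


def category_distribution(annotations: list[ClusterAnnotation]) -> dict[str, float]:
    """Fraction of clusters per category, plus the gene-associated total
    (gene body + both flanks)."""
    if not annotations:
        raise ValueError("no annotations")
    counts = Counter(a.category for a in annotations)
    n = len(annotations)
    out = {c: counts.get(c, 0) / n for c in CATEGORIES}
    out["gene_associated"] = sum(out[c] for c in GENE_CATEGORIES)
    return out


def dominant_size_class(length_histogram: dict, cluster_id: str = "") -> SizeClassCall:
    """Dominant read length (18-24 nt) of a cluster; exact ties are ambiguous.

    Ambiguous clusters carry ``dominant_class = None`` and are excluded from
    size-class summaries.
    """
    hist = {int(k): int(v) for k, v in length_histogram.items()}
    if not hist:
        raise ValueError("empty length histogram")
    bad = [k for k in hist if k not in SIZE_CLASSES]
    if bad:
        raise ValueError(f"length {bad[0]} outside 18..24")
    top = max(hist.values())
    winners = [k for k, v in hist.items() if v == top]
    dom = winners[0] if len(winners) == 1 else None
    return SizeClassCall(cluster_id, hist, dom)


def dmr_sirna_overlap(dmrs: list[GenomicInterval],
                      clusters: list[GenomicInterval]
                      ) -> tuple[float, dict[str, bool]]:
    """Fraction of DMRs sharing >= 1 base with any cluster, plus per-DMR flags.

    Half-open convention: abutting intervals do not overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for c in clusters:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end)
    flags: dict[str, bool] = {}
    for d in dmrs:
        tree = trees.get(d.chrom)
        flags[d.id] = bool(tree.overlap(d.start, d.end)) if tree else False
    frac = sum(flags.values()) / len(flags) if flags else 0.0
    return frac, flags
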