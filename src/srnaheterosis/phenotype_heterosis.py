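"""Mid-parent and better-parent heterosis for measured traits.

MPH = 100 * (F1 - MPV) / MPV with MPV the parental mean; BPH uses the
better parent instead.  For a positive trait BPH <= MPH always, since
(f1 - x)/x decreases in x.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd


@dataclass(frozen=True)
class TraitRecord:
    genotype: str  # female | male | hybrid
    environment: str
    replicate: int
    value: float

    def __post_init__(self):
        if self.genotype not in ("female", "male", "hybrid"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.value <= 0:
            raise ValueError("trait values must be positive")


def mph(f1: float, p1: float, p2: float) -> float:
    """Mid-parent heterosis in percent."""
    if p1 <= 0 or p2 <= 0:
        raise ValueError("parental values must be positive")
    mpv = (p1 + p2) / 2
    return 100.0 * (f1 - mpv) / mpv


def bph(f1: float, p1: float, p2: float) -> float:
    """Better-parent heterosis in percent."""
    if p1 <= 0 or p2 <= 0:
        raise ValueError("parental values must be positive")
    bpv = max(p1, p2)
    return 100.0 * (f1 - bpv) / bpv


def heterosis_by_environment(records: list[TraitRecord]) -> pd.DataFrame:
    """Per-environment MPH/BPH on genotype replicate means, plus the spread
    over all (female, male, hybrid) replicate pairings.

    Returns a DataFrame indexed by environment with columns mph, bph (point
    estimates on means) and mph_min/mph_max/bph_min/bph_max over pairings.
    Missing genotypes in an environment are an error.
    """
    if not records:
        raise ValueError("no trait records")
    df = pd.DataFrame([(r.genotype, r.environment, r.replicate, r.value)
                       for r in records],
                      columns=["genotype", "environment", "replicate", "value"])
    rows = []
    for env, g in df.groupby("environment"):
        vals = {geno: gg["value"].to_list()
                for geno, gg in g.groupby("genotype")}
        for geno in ("female", "male", "hybrid"):
            if not vals.get(geno):
                raise ValueError(f"environment {env!r} missing {geno}")
        f = sum(vals["female"]) / len(vals["female"])
        m = sum(vals["male"]) / len(vals["male"])
        h = sum(vals["hybrid"]) / len(vals["hybrid"])
        pair_mph = [mph(hh, ff, mm) for ff, mm, hh in
                    product(vals["female"], vals["male"], vals["hybrid"])]
        pair_bph = [bph(hh, ff, mm) for ff, mm, hh in
                    product(vals["female"], vals["male"], vals["hybrid"])]
        rows.append((env, mph(h, f, m), bph(h, f, m),
                     min(pair_mph), max(pair_mph),
                     min(pair_bph), max(pair_bph)))
    return pd.DataFrame(rows, columns=["environment", "mph", "bph",
                                       "mph_min", "mph_max",
                                       "bph_min", "bph_max"]
                        ).set_index("environment")
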