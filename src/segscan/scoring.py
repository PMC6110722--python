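"""Variant scoring: segregation LLR plus a coding-impact penalty.

The genome-scan score for a marker m is

    score(m) = LLR(m) - log P(coding effect of m)

so that, at equal segregation evidence, a loss-of-function variant
outranks a moderate-impact one by a fixed offset (2.96 log-likelihood
units, reflecting the relative frequencies of the two mutation classes).
Only the offset between the classes is identified by that calibration;
the absolute penalty level is configurable and cancels in ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOF",
    "MODERATE",
    "ImpactWeights",
    "VariantRecord",
    "score_variant",
    "rank_variants",
    "filter_by_carrier_count",
    "read_variant_vcf",
]

LOF = "LoF"
MODERATE = "moderate"

#: score offset of LoF over moderate-impact variants (log-likelihood units)
LOF_MODERATE_OFFSET = 2.96


def _default_p_coding():
    # moderate-impact prior 0.01 is the package default; only the
    # LoF/moderate offset of exp(-2.96) is externally calibrated
    p_mod = 0.01
    return {MODERATE: p_mod, LOF: p_mod * float(np.exp(-LOF_MODERATE_OFFSET))}


@dataclass
class ImpactWeights:
    """Per-impact-class coding-effect probabilities and -log penalties."""

    p_coding_effect: dict = field(default_factory=_default_p_coding)

    def __post_init__(self):
        for cls, p in self.p_coding_effect.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"p_coding_effect[{cls!r}] must be in (0,1)")

    def penalty(self, impact: str) -> float:
        """-log P(coding effect); positive, larger for rarer classes."""
        if impact not in self.p_coding_effect:
            raise KeyError(f"unknown impact class {impact!r}")
        return float(-np.log(self.p_coding_effect[impact]))


@dataclass
class VariantRecord:
    contig: str
    position: int
    ref: str
    alt: str
    impact: str
    carriers: list = field(default_factory=list)
    cohort_carrier_count: int = 0
    build: str = "GRCh38"

    @property
    def key(self):
        return (self.contig, self.position, self.alt)

    def __str__(self):
        return f"{self.contig}:{self.position}:{self.ref}>{self.alt}"


def score_variant(llr: float, impact: str, weights: ImpactWeights | None = None) -> float:
    """score = LLR + penalty(impact); higher means stronger evidence."""
    weights = weights or ImpactWeights()
    return float(llr) + weights.penalty(impact)


def rank_variants(
    records: Sequence[VariantRecord], scores: Sequence[float]
) -> list[tuple[VariantRecord, float]]:
    """Sort descending by score; ties break by (contig, position, alt)."""
    if len(records) != len(scores):
        raise ValueError("records and scores differ in length")
    paired = list(zip(records, [float(s) for s in scores]))
    paired.sort(key=lambda rs: (-rs[1], rs[0].key))
    return paired


def filter_by_carrier_count(
    records: Sequence[VariantRecord], max_carriers: int = 30
) -> list[VariantRecord]:
    """Pre-filter to rare variants carried by at most ``max_carriers``
    sequenced cohort members (high-penetrance search space)."""
    return [r for r in records if r.cohort_carrier_count <= max_carriers]


def scores_table(ranked) -> pd.DataFrame:
    rows = [
        {
            "variant": str(r),
            "contig": r.contig,
            "position": r.position,
            "impact": r.impact,
            "score": s,
            "rank": i + 1,
        }
        for i, (r, s) in enumerate(ranked)
    ]
    return pd.DataFrame(rows)


def read_variant_vcf(path, impact_tag: str = "IMPACT"):
    """Read variants and carrier lists from a VCF.

    A sample is a carrier when any ALT allele is called at the record.
    The impact class comes from the INFO field named ``impact_tag`` and
    must map (case-insensitively) onto {LoF, moderate}; VEP-style HIGH
    is accepted as LoF and MODERATE as moderate.
    """
    import pysam

    aliases = {
        "lof": LOF,
        "high": LOF,
        "moderate": MODERATE,
        "missense": MODERATE,
    }
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            raw = rec.info.get(impact_tag)
            if raw is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks INFO/{impact_tag}"
                )
            if isinstance(raw, tuple):
                raw = raw[0]
            impact = aliases.get(str(raw).lower())
            if impact is None:
                raise ValueError(f"unmappable impact class {raw!r}")
            carriers = [
                s
                for s in samples
                if any(a not in (None, 0) for a in (rec.samples[s].get("GT") or ()))
            ]
            out.append(
                VariantRecord(
                    contig=str(rec.chrom),
                    position=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(rec.alts[0]) if rec.alts else ".",
                    impact=impact,
                    carriers=carriers,
                    cohort_carrier_count=len(carriers),
                )
            )
    return out
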