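"""Marker-normalized trait quantification (the median-RPK estimator).

For each gene family, filtered best-hit read counts are normalized by the
family's average gene size to give RPK (reads per kilobase, using the mean
amino-acid length x 3 as the nucleotide-equivalent gene size).  The
"total-bacteria" score is the median RPK across the 25 universal
single-copy marker families; the phenazine score is the median RPK across
the five merged biosynthesis families; each degradation gene is scored by
its own RPK.  Using medians makes both scores robust to non-specific
signal concentrated in one or two families.  The trait fraction — the
estimated fraction of bacteria carrying the trait, under the single-copy
assumption — is the trait score divided by the marker score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ReferenceCatalog
from .search import HitTable

#: Sample classification thresholds, as fractions of total bacteria.
PHZ_RICH_THRESHOLD = 0.0025  # "phz+ rich": at least 0.25% phz+ bacteria
HIGH_THRESHOLD = 0.005       # "high": at least 0.5% phz+ bacteria


class QuantifyError(ValueError):
    pass


@dataclass
class FamilyCounts:
    """Per-family filtered read counts and size-normalized RPK values."""

    table: pd.DataFrame  # index: family; columns: category, read_count, rpk

    def rpk(self, family: str) -> float:
        return float(self.table.loc[family, "rpk"])

    def category_rpks(self, category: str) -> pd.Series:
        return self.table.loc[self.table["category"] == category, "rpk"]


@dataclass
class SampleQuantification:
    """Per-sample estimator output."""

    sample_id: str
    marker_score: float
    trait_scores: dict[str, float]
    trait_fractions: dict[str, float]
    taxon_breakdown: dict[str, float] = field(default_factory=dict)
    taxon_signal: dict[str, float] = field(default_factory=dict)
    phz_rich: bool = False
    high: bool = False


def count_by_family(hits: HitTable, catalog: ReferenceCatalog) -> FamilyCounts:
    """Pool filtered hits per gene family and normalize by mean gene size.

    Each hit increments exactly one family (the family of its target
    protein); RPK divides the pooled count by the family's mean amino-acid
    length expressed in kilobases of nucleotide-equivalent sequence
    (``mean_length_aa * 3 / 1000``).
    """
    fam_index = sorted(catalog.families)
    counts = dict.fromkeys(fam_index, 0)
    for target, n in hits.hits["target_protein_id"].value_counts().items():
        if target not in catalog:
            raise QuantifyError(f"hit targets protein {target!r} absent from catalog")
        counts[catalog.protein(target).family] += int(n)
    rows = []
    for fam in fam_index:
        f = catalog.families[fam]
        kb = f.mean_length_aa * 3.0 / 1000.0
        rows.append(
            {
                "family": fam,
                "category": f.category,
                "read_count": counts[fam],
                "rpk": counts[fam] / kb,
            }
        )
    return FamilyCounts(pd.DataFrame(rows).set_index("family"))


def marker_score(counts: FamilyCounts, n_markers: int = 25) -> float:
    """Median RPK over the universal single-copy marker families."""
    rpks = counts.category_rpks("marker")
    if len(rpks) < n_markers:
        raise QuantifyError(
            f"expected {n_markers} marker families, found {len(rpks)}"
        )
    return float(np.median(rpks.to_numpy()))


def trait_score(counts: FamilyCounts, trait: str) -> float:
    """Score a trait: median RPK over its families.

    ``trait`` is either the category name ``"trait_biosynthesis"`` (median
    over the merged phenazine families) or a single degradation gene name
    (``"phdA"``/``"podA"``; the median of one value is the value itself).
    """
    if trait == "trait_biosynthesis":
        rpks = counts.category_rpks("trait_biosynthesis")
        if rpks.empty:
            raise QuantifyError("no trait_biosynthesis families in counts")
        return float(np.median(rpks.to_numpy()))
    if trait in counts.table.index and counts.table.loc[trait, "category"] == "trait_degradation":
        return counts.rpk(trait)
    raise QuantifyError(f"unknown trait {trait!r}")


def trait_fraction(trait_score_value: float, marker_score_value: float) -> float:
    """Trait score divided by the total-bacteria score.

    Interpreted as the fraction of bacteria carrying the trait; not clamped
    at 1 — values above 1 indicate a catalog/sample pathology and trigger a
    warning.
    """
    if marker_score_value <= 0:
        raise QuantifyError("no bacterial signal: marker score is zero")
    frac = trait_score_value / marker_score_value
    if frac > 1:
        warnings.warn(
            f"trait fraction {frac:.3g} exceeds 1; check catalog and sample",
            stacklevel=2,
        )
    return frac


def taxon_breakdown(
    hits: HitTable,
    catalog: ReferenceCatalog,
    level: str = "order",
    trait: str = "trait_biosynthesis",
) -> dict[str, float]:
    """Relative abundance of each taxon among trait-positive signal.

    Per taxon, trait-family hit counts are divided by the family mean
    length (kb) before summing, so long and short genes contribute
    comparably; the result is normalized to sum to 1.  Taxa with no signal
    are omitted; with no trait hits at all an empty mapping is returned.
    """
    signal = taxon_signal(hits, catalog, level, trait)
    total = sum(signal.values())
    if total == 0:
        return {}
    return {taxon: v / total for taxon, v in signal.items()}


def taxon_signal(
    hits: HitTable,
    catalog: ReferenceCatalog,
    level: str = "order",
    trait: str = "trait_biosynthesis",
) -> dict[str, float]:
    """Unnormalized size-normalized trait signal per taxon (RPK units)."""
    if level not in ("species", "genus", "order"):
        raise QuantifyError(f"unknown taxonomy level {level!r}")
    if trait == "trait_biosynthesis":
        families = set(catalog.phz_families)
    elif trait == "trait_degradation":
        families = set(catalog.degradation_families)
    elif trait in catalog.families:
        families = {trait}
    else:
        raise QuantifyError(f"unknown trait {trait!r}")

    signal: dict[str, float] = {}
    for target, n in hits.hits["target_protein_id"].value_counts().items():
        prot = catalog.protein(target)
        if prot.family not in families:
            continue
        kb = catalog.families[prot.family].mean_length_aa * 3.0 / 1000.0
        taxon = getattr(prot, "species" if level == "species" else level)
        signal[taxon] = signal.get(taxon, 0.0) + int(n) / kb
    return signal


def classify_sample(fraction: float) -> dict[str, bool]:
    """Flag a sample as phz-rich (>=0.25%) and/or high (>=0.5%)."""
    if fraction < 0:
        raise QuantifyError(f"fraction must be non-negative, got {fraction}")
    return {
        "phz_rich": fraction >= PHZ_RICH_THRESHOLD,
        "high": fraction >= HIGH_THRESHOLD,
    }


def extrapolate_bacterial_load(cfu_per_gram: float, fraction: float) -> dict[str, float]:
    """Extrapolate total bacterial load from culturable counts.

    Dividing the cfu/g of a culturable trait-positive group by its
    metagenomically estimated fraction of all bacteria gives the total
    bacterial load per gram (e.g. 6.5e6 cfu/g at 0.4% implies ~1.6e9
    bacteria per gram, order of magnitude 9).
    """
    if fraction <= 0:
        raise QuantifyError("fraction must be positive to extrapolate load")
    load = cfu_per_gram / fraction
    return {"load": load, "order_of_magnitude": int(round(math.log10(load)))}


def quantify_sample(
    hits: HitTable,
    catalog: ReferenceCatalog,
    sample_id: str = "sample",
    n_markers: int = 25,
    taxonomy_level: str = "order",
) -> SampleQuantification:
    """Run the full estimator on one sample's filtered hit table."""
    counts = count_by_family(hits, catalog)
    marker = marker_score(counts, n_markers=n_markers)
    scores = {"phz": trait_score(counts, "trait_biosynthesis")}
    for gene in catalog.degradation_families:
        scores[gene] = trait_score(counts, gene)
    fractions = {name: trait_fraction(s, marker) if marker > 0 else 0.0 for name, s in scores.items()}
    flags = classify_sample(fractions["phz"])
    return SampleQuantification(
        sample_id=sample_id,
        marker_score=marker,
        trait_scores=scores,
        trait_fractions=fractions,
        taxon_breakdown=taxon_breakdown(hits, catalog, taxonomy_level),
        taxon_signal=taxon_signal(hits, catalog, taxonomy_level),
        phz_rich=flags["phz_rich"],
        high=flags["high"],
    )


def quantification_frame(quants: list[SampleQuantification]) -> pd.DataFrame:
    """Per-sample summary table (one row per sample)."""
    rows = []
    for q in quants:
        row = {
            "sample_id": q.sample_id,
            "marker_score": q.marker_score,
            "phz_score": q.trait_scores.get("phz", 0.0),
            "phz_fraction_pct": 100.0 * q.trait_fractions.get("phz", 0.0),
        }
        for gene in ("phdA", "podA"):
            if gene in q.trait_fractions:
                row[f"{gene}_fraction_pct"] = 100.0 * q.trait_fractions[gene]
        row["phz_rich"] = q.phz_rich
        row["high"] = q.high
        rows.append(row)
    return pd.DataFrame(rows)
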