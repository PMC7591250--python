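"""Habitat-level aggregation of per-sample quantifications.

Joins per-sample estimator output with sample metadata (habitat class:
``soil`` or ``rhizosphere``, plus a free-text sub-habitat), then compares
the two habitat classes: mean/median trait fractions, the fold difference
of means, a two-sided Wilcoxon rank-sum test, and the enrichment of
high-trait samples (fraction >= 0.5%) in rhizospheres relative to soils.
The taxon x habitat matrix pools hit-level, size-normalized trait signal
across all samples of a habitat before renormalizing, so deeply sequenced
samples weigh in proportionally (per-sample averaging is available as an
option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ReferenceCatalog
from .quantify import HIGH_THRESHOLD, SampleQuantification, quantify_sample
from .search import SearchParams, best_hit_search, filter_hits, parse_hit_table

logger = logging.getLogger(__name__)

HABITAT_CLASSES = ("soil", "rhizosphere")


class SurveyError(ValueError):
    pass


@dataclass
class SurveyTable:
    """Joined sample quantifications and metadata (one row per sample)."""

    frame: pd.DataFrame
    quantifications: dict[str, SampleQuantification]


@dataclass
class HabitatSummary:
    per_class: pd.DataFrame  # index: habitat_class
    fold_mean: float
    rank_sum_p: float
    enrichment_high: float  # NaN when undefined (no high-trait soil samples)
    enrichment_defined: bool


def quantify_batch(
    inputs: Mapping[str, str | Path] | Iterable[tuple[str, str | Path]],
    catalog: ReferenceCatalog,
    input_type: str = "hits",
    min_identity: float = 80.0,
    n_markers: int = 25,
    params: SearchParams = SearchParams(),
) -> tuple[list[SampleQuantification], dict[str, str]]:
    """Quantify many samples; failures are logged and reported, not dropped.

    ``input_type`` is ``"hits"`` for tabular best-hit files (outfmt 6) or
    ``"reads"`` for FASTA/FASTQ processed with the internal aligner.
    Returns the successful quantifications and a mapping of failed sample
    id -> error message; raises if no sample succeeds.
    """
    if input_type not in ("hits", "reads"):
        raise SurveyError(f"input_type must be 'hits' or 'reads', got {input_type!r}")
    pairs = inputs.items() if isinstance(inputs, Mapping) else inputs
    quants: list[SampleQuantification] = []
    failures: dict[str, str] = {}
    for sample_id, path in pairs:
        try:
            if input_type == "hits":
                hits = parse_hit_table(path)
            else:
                hits = best_hit_search(path, catalog, params)
            hits = filter_hits(hits, min_identity)
            quants.append(
                quantify_sample(hits, catalog, sample_id=sample_id, n_markers=n_markers)
            )
        except Exception as exc:
            logger.warning("sample %s failed: %s", sample_id, exc)
            failures[sample_id] = str(exc)
    if not quants:
        raise SurveyError(f"no sample quantified successfully ({len(failures)} failures)")
    return quants, failures


def build_survey_table(
    quants: list[SampleQuantification],
    metadata: pd.DataFrame | str | Path,
) -> SurveyTable:
    """Join quantifications with a metadata table.

    ``metadata`` needs columns ``sample_id``, ``habitat_class`` and
    ``sub_habitat``; every quantified sample must have a metadata row and a
    habitat class of ``soil`` or ``rhizosphere``.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, sep="\t", dtype=str)
    required = {"sample_id", "habitat_class", "sub_habitat"}
    missing = required - set(metadata.columns)
    if missing:
        raise SurveyError(f"metadata is missing columns: {sorted(missing)}")
    bad = set(metadata["habitat_class"]) - set(HABITAT_CLASSES)
    if bad:
        raise SurveyError(f"unknown habitat classes: {sorted(bad)}")
    meta = metadata.set_index("sample_id")
    rows = []
    for q in quants:
        if q.sample_id not in meta.index:
            raise SurveyError(f"sample {q.sample_id!r} has no metadata row")
        m = meta.loc[q.sample_id]
        rows.append(
            {
                "sample_id": q.sample_id,
                "habitat_class": m["habitat_class"],
                "sub_habitat": m["sub_habitat"],
                "marker_score": q.marker_score,
                "phz_fraction": q.trait_fractions.get("phz", 0.0),
                "phdA_fraction": q.trait_fractions.get("phdA", np.nan),
                "podA_fraction": q.trait_fractions.get("podA", np.nan),
                "phz_rich": q.phz_rich,
                "high": q.high,
            }
        )
    return SurveyTable(
        frame=pd.DataFrame(rows), quantifications={q.sample_id: q for q in quants}
    )


def aggregate_by_habitat(table: SurveyTable) -> HabitatSummary:
    """Compare trait-fraction distributions between soil and rhizosphere."""
    df = table.frame
    for cls in HABITAT_CLASSES:
        if (df["habitat_class"] == cls).sum() == 0:
            raise SurveyError(f"habitat class {cls!r} has no samples")
    per_class = (
        df.groupby("habitat_class")["phz_fraction"]
        .agg(n="count", mean="mean", median="median", std="std")
    )
    rhizo = df.loc[df["habitat_class"] == "rhizosphere", "phz_fraction"].to_numpy()
    soil = df.loc[df["habitat_class"] == "soil", "phz_fraction"].to_numpy()
    fold = float(rhizo.mean() / soil.mean()) if soil.mean() > 0 else float("nan")
    # two-sided Wilcoxon rank-sum (Mann-Whitney), normal approximation with
    # tie correction
    _, p = stats.mannwhitneyu(rhizo, soil, alternative="two-sided", method="asymptotic")
    prop_rhizo = float((rhizo >= HIGH_THRESHOLD).mean())
    prop_soil = float((soil >= HIGH_THRESHOLD).mean())
    defined = prop_soil > 0
    enrichment = prop_rhizo / prop_soil if defined else float("nan")
    return HabitatSummary(
        per_class=per_class,
        fold_mean=fold,
        rank_sum_p=float(p),
        enrichment_high=float(enrichment),
        enrichment_defined=defined,
    )


def taxon_habitat_matrix(
    table: SurveyTable, level: str = "order", per_sample_average: bool = False
) -> pd.DataFrame:
    """Taxon x habitat matrix of relative trait abundance.

    Columns are habitat classes; by default the hit-level size-normalized
    signal is pooled across all samples of a habitat before renormalizing
    each column to 1.  ``per_sample_average`` averages per-sample
    breakdowns instead.  A habitat without any trait signal yields a zero
    column (flagged via a log warning).

    Note: quantifications must have been computed at the requested
    taxonomy ``level``.
    """
    df = table.frame
    habitats = sorted(df["habitat_class"].unique())
    pooled: dict[str, dict[str, float]] = {h: {} for h in habitats}
    for _, row in df.iterrows():
        q = table.quantifications[row["sample_id"]]
        source = q.taxon_breakdown if per_sample_average else q.taxon_signal
        for taxon, v in source.items():
            pooled[row["habitat_class"]][taxon] = (
                pooled[row["habitat_class"]].get(taxon, 0.0) + v
            )
    taxa = sorted({t for h in pooled.values() for t in h})
    mat = pd.DataFrame(0.0, index=taxa, columns=habitats)
    for h in habitats:
        for t, v in pooled[h].items():
            mat.loc[t, h] = v
        total = mat[h].sum()
        if total > 0:
            mat[h] /= total
        else:
            logger.warning("habitat %s has zero trait signal", h)
    return mat
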