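"""In-silico validation on simulated spike-in communities.

Runs each community of a factorial design through the standard pipeline
(read sampling -> translated best-hit search -> identity filter ->
median-RPK quantification), pairs the estimates with the exact ground
truth, and computes the accuracy metrics: Pearson correlation between
known and estimated producer fractions, per-species error in mixed
communities, the maximum estimate across negative controls, and the
operational detection limit (the lowest designed abundance whose replicate
estimates all strictly exceed every negative-control estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ReferenceCatalog
from .quantify import quantify_sample
from .search import HitTable, SearchParams, _packed_catalog, search_encoded
from .simulate import CommunitySpec, SyntheticSpecies, draw_reads


class BenchmarkError(ValueError):
    pass


#: Raw-score prefilter matching an 80%-identity, 15-column floor (see
#: :class:`~phzquant.search.SearchParams`); used by the benchmark pipeline.
BENCHMARK_SEARCH_PARAMS = SearchParams(min_report_score=36)


@dataclass
class BenchmarkRecord:
    community_id: str
    coverage: int
    abundance: float
    combo: str
    replicate: int
    known_fraction: float
    estimated_fraction: float
    producer_known: dict[str, float] = field(default_factory=dict)
    producer_estimated: dict[str, float] = field(default_factory=dict)
    degrader_known: float = 0.0
    degrader_estimated: dict[str, float] = field(default_factory=dict)


@dataclass
class BenchmarkMetrics:
    pearson_r: float
    per_species_error: np.ndarray
    detection_limit: float | None
    negative_control_max: float


def _quantify_community(
    spec: CommunitySpec,
    catalog: ReferenceCatalog,
    species: list[SyntheticSpecies],
    min_identity: float,
    params: SearchParams,
    n_markers: int,
) -> BenchmarkRecord:
    mat, _, _ = draw_reads(spec, species)
    packed = _packed_catalog(catalog, params.kmer_size)
    lens = np.full(mat.shape[0], mat.shape[1], dtype=np.int64)
    prot, score, match, cols = search_encoded(mat, lens, packed, params)
    del mat
    hit = prot >= 0
    pident = np.zeros(prot.shape, dtype=float)
    pident[hit] = 100.0 * match[hit] / cols[hit]
    keep = hit & (pident >= min_identity)
    idx = np.nonzero(keep)[0]
    protein_ids = np.array(catalog.ordering, dtype=object)
    hits = HitTable(
        hits=pd.DataFrame(
            {
                "read_id": idx,
                "target_protein_id": protein_ids[prot[idx]],
                "percent_identity": pident[idx],
                "alignment_length": cols[idx],
                "score": score[idx].astype(float),
            }
        ),
        provenance="internal",
        identity_threshold_applied=min_identity,
    )
    q = quantify_sample(hits, catalog, sample_id=spec.community_id,
                        n_markers=n_markers, taxonomy_level="species")
    est_total = q.trait_fractions["phz"]
    producer_ids = [sp.species_id for sp in species if sp.role == "producer"]
    est_by_producer = {
        sid: est_total * q.taxon_breakdown.get(sid, 0.0) for sid in producer_ids
    }
    gt = spec.ground_truth
    return BenchmarkRecord(
        community_id=spec.community_id,
        coverage=spec.condition.get("coverage", spec.library_size),
        abundance=spec.condition.get("abundance", gt.total_producer_fraction),
        combo=spec.condition.get("combo", ""),
        replicate=spec.condition.get("replicate", 1),
        known_fraction=gt.total_producer_fraction,
        estimated_fraction=est_total,
        producer_known={sid: gt.producer_fractions.get(sid, 0.0) for sid in producer_ids},
        producer_estimated=est_by_producer,
        degrader_known=gt.degrader_fraction,
        degrader_estimated={
            gene: q.trait_fractions.get(gene, 0.0) for gene in catalog.degradation_families
        },
    )


def run_benchmark(
    design: list[CommunitySpec],
    catalog: ReferenceCatalog,
    species: list[SyntheticSpecies],
    min_identity: float = 80.0,
    params: SearchParams = BENCHMARK_SEARCH_PARAMS,
    n_markers: int = 25,
    progress: bool = False,
) -> list[BenchmarkRecord]:
    """Sample, search, filter and quantify every community of a design."""
    if not design:
        raise BenchmarkError("benchmark design is empty")
    records = []
    for i, spec in enumerate(design):
        try:
            records.append(
                _quantify_community(spec, catalog, species, min_identity, params, n_markers)
            )
        except Exception as exc:
            raise BenchmarkError(f"community {spec.community_id!r} failed: {exc}") from exc
        if progress:
            print(f"[{i + 1}/{len(design)}] {spec.community_id}", flush=True)
    return records


def records_frame(records: list[BenchmarkRecord]) -> pd.DataFrame:
    """Flat per-community results table (fractions in percent)."""
    rows = []
    for r in records:
        row = {
            "community_id": r.community_id,
            "coverage": r.coverage,
            "abundance_pct": 100.0 * r.abundance,
            "combo": r.combo,
            "replicate": r.replicate,
            "known_pct": 100.0 * r.known_fraction,
            "estimated_pct": 100.0 * r.estimated_fraction,
            "degrader_known_pct": 100.0 * r.degrader_known,
        }
        for gene, v in r.degrader_estimated.items():
            row[f"{gene}_estimated_pct"] = 100.0 * v
        rows.append(row)
    return pd.DataFrame(rows)


def accuracy_metrics(
    records: list[BenchmarkRecord], error_floor: float = 0.001
) -> BenchmarkMetrics:
    """Accuracy metrics over benchmark records.

    ``error_floor`` restricts the per-species error distribution to
    producers spiked above that known fraction (default 0.1%).
    """
    known = np.array([r.known_fraction for r in records])
    est = np.array([r.estimated_fraction for r in records])
    if len(np.unique(known)) < 3:
        raise BenchmarkError("need at least 3 distinct known values for correlation")
    if np.ptp(known) == 0:
        raise BenchmarkError("known fractions are constant; correlation undefined")
    r, _ = stats.pearsonr(known, est)

    errors = []
    for rec in records:
        for sid, k in rec.producer_known.items():
            if k > error_floor:
                errors.append(k - rec.producer_estimated.get(sid, 0.0))
    per_species_error = np.array(errors)

    neg = est[known == 0]
    negative_control_max = float(neg.max()) if neg.size else float("nan")

    detection_limit: float | None = None
    if neg.size:
        levels = sorted({r.abundance for r in records if r.abundance > 0})
        for level in levels:
            level_est = est[np.array([r.abundance for r in records]) == level]
            if level_est.size and (level_est > negative_control_max).all():
                detection_limit = level
                break
    return BenchmarkMetrics(
        pearson_r=float(r),
        per_species_error=per_species_error,
        detection_limit=detection_limit,
        negative_control_max=negative_control_max,
    )


def degrader_recovery(
    records: list[BenchmarkRecord],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Known vs estimated degrader fractions, per degradation gene.

    Returns the paired table plus a per-gene Pearson r (NaN when fewer
    than three distinct known levels are present).
    """
    rows = []
    for r in records:
        for gene, estv in r.degrader_estimated.items():
            rows.append(
                {
                    "community_id": r.community_id,
                    "gene": gene,
                    "known_fraction": r.degrader_known,
                    "estimated_fraction": estv,
                }
            )
    table = pd.DataFrame(rows, columns=["community_id", "gene", "known_fraction", "estimated_fraction"])
    correlations: dict[str, float] = {}
    for gene, sub in table.groupby("gene"):
        if sub["known_fraction"].nunique() >= 3:
            correlations[gene], _ = stats.pearsonr(
                sub["known_fraction"], sub["estimated_fraction"]
            )
        else:
            correlations[gene] = float("nan")
    return table, correlations
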