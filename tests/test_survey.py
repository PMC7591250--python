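import numpy as np
import pandas as pd
import pytest

from phzquant.quantify import SampleQuantification
from phzquant.survey import (
    SurveyError,
    SurveyTable,
    aggregate_by_habitat,
    build_survey_table,
    quantify_batch,
    taxon_habitat_matrix,
)


def _quant(sample_id, phz, taxa=None, marker=100.0):
    taxa = taxa or {}
    total = sum(taxa.values())
    return SampleQuantification(
        sample_id=sample_id,
        marker_score=marker,
        trait_scores={"phz": phz * marker},
        trait_fractions={"phz": phz},
        taxon_breakdown={t: v / total for t, v in taxa.items()} if total else {},
        taxon_signal=dict(taxa),
        phz_rich=phz >= 0.0025,
        high=phz >= 0.005,
    )


def _metadata(rows):
    return pd.DataFrame(rows, columns=["sample_id", "habitat_class", "sub_habitat"])


def _table(fractions_by_class, taxa_by_sample=None):
    quants, meta = [], []
    for cls, fracs in fractions_by_class.items():
        for i, f in enumerate(fracs):
            sid = f"{cls}{i}"
            taxa = (taxa_by_sample or {}).get(sid)
            quants.append(_quant(sid, f, taxa))
            meta.append((sid, cls, "x"))
    return build_survey_table(quants, _metadata(meta))


# -- fixtures for the hit-file batch path --------------------------------

OUTFMT6_LINE = "{rid}\t{target}\t{pid}\t50\t2\t0\t1\t150\t10\t59\t1e-20\t100\n"


def _write_hit_file(path, catalog, marker_reads=200, phz_reads=0):
    lines = []
    n = 0
    for fam in catalog.marker_families:
        target = next(p.protein_id for p in catalog.proteins if p.family == fam)
        for _ in range(marker_reads):
            lines.append(OUTFMT6_LINE.format(rid=f"r{n}", target=target, pid=95.0))
            n += 1
    for fam in catalog.phz_families:
        target = next(p.protein_id for p in catalog.proteins if p.family == fam)
        for _ in range(phz_reads):
            lines.append(OUTFMT6_LINE.format(rid=f"r{n}", target=target, pid=92.0))
            n += 1
    path.write_text("".join(lines))
    return path


class TestQuantifyBatch:
    def test_batch_over_hit_files(self, tmp_path, tiny_catalog):
        inputs = {}
        for i in range(3):
            p = _write_hit_file(tmp_path / f"s{i}.tsv", tiny_catalog,
                                marker_reads=100, phz_reads=i)
            inputs[f"s{i}"] = p
        quants, failures = quantify_batch(inputs, tiny_catalog)
        assert len(quants) == 3 and not failures
        fracs = {q.sample_id: q.trait_fractions["phz"] for q in quants}
        assert fracs["s0"] == 0.0
        assert fracs["s2"] > fracs["s1"] > 0

    def test_malformed_file_logged_not_fatal(self, tmp_path, tiny_catalog):
        good = _write_hit_file(tmp_path / "good.tsv", tiny_catalog, 50, 1)
        bad = tmp_path / "bad.tsv"
        bad.write_text("r1\tp\tnot_a_number\n")
        quants, failures = quantify_batch(
            [("good", good), ("bad", bad)], tiny_catalog
        )
        assert [q.sample_id for q in quants] == ["good"]
        assert set(failures) == {"bad"}

    def test_all_failures_is_an_error(self, tmp_path, tiny_catalog):
        bad = tmp_path / "bad.tsv"
        bad.write_text("broken\n")
        with pytest.raises(SurveyError):
            quantify_batch([("bad", bad)], tiny_catalog)

    def test_unknown_input_type_rejected(self, tiny_catalog):
        with pytest.raises(SurveyError):
            quantify_batch({}, tiny_catalog, input_type="bam")


class TestBuildSurveyTable:
    def test_join_and_columns(self, tiny_catalog):
        table = _table({"soil": [0.001], "rhizosphere": [0.01]})
        assert set(table.frame.habitat_class) == {"soil", "rhizosphere"}
        assert len(table.frame) == 2

    def test_missing_metadata_is_an_error(self):
        with pytest.raises(SurveyError, match="no metadata"):
            build_survey_table([_quant("s1", 0.01)], _metadata([("other", "soil", "x")]))

    def test_unknown_habitat_class_rejected(self):
        with pytest.raises(SurveyError, match="habitat"):
            build_survey_table([_quant("s1", 0.01)], _metadata([("s1", "ocean", "x")]))


class TestAggregateByHabitat:
    def test_identical_distributions_fold_one(self):
        table = _table({"soil": [0.001, 0.002, 0.004],
                        "rhizosphere": [0.001, 0.002, 0.004]})
        summary = aggregate_by_habitat(table)
        assert summary.fold_mean == pytest.approx(1.0)

    def test_doubled_fractions_fold_two(self):
        soil = [0.001, 0.002, 0.003, 0.004]
        table = _table({"soil": soil, "rhizosphere": [2 * f for f in soil]})
        summary = aggregate_by_habitat(table)
        assert summary.fold_mean == pytest.approx(2.0)

    def test_seeded_shift_detected_by_rank_sum(self):
        rng = np.random.default_rng(55)
        soil = rng.lognormal(np.log(0.001), 0.5, size=20)
        rhizo = 3.0 * rng.lognormal(np.log(0.001), 0.5, size=20)
        table = _table({"soil": list(soil), "rhizosphere": list(rhizo)})
        summary = aggregate_by_habitat(table)
        assert summary.rank_sum_p < 0.05
        assert summary.fold_mean == pytest.approx(3.0, rel=0.5)

    def test_enrichment_of_high_samples(self):
        table = _table({"soil": [0.001] * 9 + [0.006],
                        "rhizosphere": [0.006] * 5 + [0.001] * 5})
        summary = aggregate_by_habitat(table)
        assert summary.enrichment_defined
        assert summary.enrichment_high == pytest.approx(5.0)

    def test_enrichment_undefined_without_high_soil(self):
        table = _table({"soil": [0.001] * 5, "rhizosphere": [0.006] * 5})
        summary = aggregate_by_habitat(table)
        assert not summary.enrichment_defined
        assert np.isnan(summary.enrichment_high)

    def test_missing_class_is_an_error(self):
        quants = [_quant("s1", 0.01)]
        table = build_survey_table(quants, _metadata([("s1", "soil", "x")]))
        with pytest.raises(SurveyError):
            aggregate_by_habitat(table)

    def test_permutation_invariance(self):
        fracs = {"soil": [0.001, 0.003, 0.002], "rhizosphere": [0.004, 0.009, 0.002]}
        a = aggregate_by_habitat(_table(fracs))
        b = aggregate_by_habitat(
            _table({k: v[::-1] for k, v in fracs.items()})
        )
        assert a.fold_mean == pytest.approx(b.fold_mean)
        assert a.rank_sum_p == pytest.approx(b.rank_sum_p)

    def test_scale_invariance_of_fold_and_enrichment(self):
        fracs = {"soil": [0.002, 0.004, 0.006], "rhizosphere": [0.004, 0.008, 0.016]}
        a = aggregate_by_habitat(_table(fracs))
        # common multiplicative factor below classification thresholds matters
        # only for the high-sample counts, so compare fold and p only
        b = aggregate_by_habitat(
            _table({k: [7 * f for f in v] for k, v in fracs.items()})
        )
        assert a.fold_mean == pytest.approx(b.fold_mean)
        assert a.rank_sum_p == pytest.approx(b.rank_sum_p)


class TestTaxonHabitatMatrix:
    def test_single_habitat_single_taxon(self):
        quants = [_quant("s1", 0.01, {"Streptomycetales": 5.0}),
                  _quant("s2", 0.01, {"Streptomycetales": 2.0})]
        meta = _metadata([("s1", "soil", "x"), ("s2", "soil", "x")])
        mat = taxon_habitat_matrix(build_survey_table(quants, meta))
        assert mat.loc["Streptomycetales", "soil"] == pytest.approx(1.0)

    def test_columns_sum_to_one(self):
        table = _table(
            {"soil": [0.01, 0.02], "rhizosphere": [0.01]},
            taxa_by_sample={
                "soil0": {"A": 1.0, "B": 3.0},
                "soil1": {"B": 2.0},
                "rhizosphere0": {"A": 0.5},
            },
        )
        mat = taxon_habitat_matrix(table)
        assert mat.sum(axis=0).to_numpy() == pytest.approx([1.0, 1.0])

    def test_pooling_recovers_designed_dominance(self):
        table = _table(
            {"soil": [0.01, 0.01], "rhizosphere": [0.01, 0.01]},
            taxa_by_sample={
                "soil0": {"A": 9.0, "B": 1.0},
                "soil1": {"A": 8.0, "B": 2.0},
                "rhizosphere0": {"A": 1.0, "B": 9.0},
                "rhizosphere1": {"B": 10.0},
            },
        )
        mat = taxon_habitat_matrix(table)
        assert mat.loc["A", "soil"] > 0.8
        assert mat.loc["B", "rhizosphere"] > 0.9

    def test_zero_signal_habitat_gives_zero_column(self):
        table = _table(
            {"soil": [0.0], "rhizosphere": [0.01]},
            taxa_by_sample={"rhizosphere0": {"A": 1.0}},
        )
        mat = taxon_habitat_matrix(table)
        assert mat["soil"].sum() == 0.0
        assert mat["rhizosphere"].sum() == pytest.approx(1.0)

    def test_mean_update_when_adding_zero_signal_sample(self):
        base = {"soil": [0.002, 0.004], "rhizosphere": [0.01]}
        before = aggregate_by_habitat(_table(base))
        after = aggregate_by_habitat(
            _table({"soil": base["soil"] + [0.0], "rhizosphere": base["rhizosphere"]})
        )
        n = len(base["soil"])
        expected = before.per_class.loc["soil", "mean"] * n / (n + 1)
        assert after.per_class.loc["soil", "mean"] == pytest.approx(expected)


class TestEndToEndFixture:
    def test_rhizosphere_vs_soil_fixture(self, tmp_path, tiny_catalog):
        """5 high-phz 'rhizosphere' + 3 low-phz 'soil' samples via hit files."""
        rng = np.random.default_rng(3)
        inputs, meta = {}, []
        for i in range(5):
            sid = f"wr{i + 1}"
            inputs[sid] = _write_hit_file(
                tmp_path / f"{sid}.tsv", tiny_catalog,
                marker_reads=100, phz_reads=int(rng.integers(8, 15)),
            )
            meta.append((sid, "rhizosphere", "wheat"))
        for i in range(3):
            sid = f"bs{i + 1}"
            inputs[sid] = _write_hit_file(
                tmp_path / f"{sid}.tsv", tiny_catalog,
                marker_reads=100, phz_reads=int(rng.integers(1, 4)),
            )
            meta.append((sid, "soil", "field"))
        quants, failures = quantify_batch(inputs, tiny_catalog)
        assert not failures
        table = build_survey_table(quants, _metadata(meta))
        summary = aggregate_by_habitat(table)
        assert summary.fold_mean > 1.5
        mat = taxon_habitat_matrix(table)
        assert (mat.sum(axis=0) > 0.999).all()
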