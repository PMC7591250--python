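import numpy as np
import pytest
from Bio.Seq import Seq

from phzquant import _align
from phzquant.search import (
    HitTable,
    SearchParams,
    best_hit_search,
    filter_hits,
    parse_hit_table,
    search_encoded,
    translate_six_frames,
    _packed_catalog,
)
from phzquant.catalog import ReferenceCatalog, ReferenceProtein

from conftest import AA20, mutate_protein, random_protein, reverse_translate
from oracle import oracle_best_hit


def _catalog(rng, n=20):
    prots = [
        ReferenceProtein(
            f"p{i:02d}", f"marker_{i + 1:02d}", "marker", "sp", "O", "G",
            random_protein(rng, int(rng.integers(80, 350))),
        )
        for i in range(n)
    ]
    return ReferenceCatalog(prots)


def _gene_read(rng, catalog, divergence, seg_len=40, read_len=150):
    """Error-free read whose core is a (possibly diverged) gene segment."""
    prot = catalog.proteins[int(rng.integers(0, len(catalog)))]
    start = int(rng.integers(0, prot.length_aa - seg_len))
    seg = mutate_protein(rng, prot.sequence[start : start + seg_len], divergence)
    nt = reverse_translate(seg)
    if rng.random() < 0.5:
        nt = str(Seq(nt).reverse_complement())
    flank = int(rng.integers(0, read_len - len(nt) + 1))
    pad = "".join(rng.choice(list("ACGT"), read_len - len(nt) - flank))
    lead = "".join(rng.choice(list("ACGT"), flank))
    return (lead + nt + pad)[:read_len]


class TestTranslateSixFrames:
    def test_known_frames(self):
        frames = translate_six_frames("ATGAAATGA")
        assert frames[0] == "MK*"

    def test_reverse_complement_frame(self):
        # rc of ATGAAA is TTTCAT -> FH
        assert translate_six_frames("ATGAAA")[3] == "FH"

    def test_short_sequence_gives_empty_peptides(self):
        assert translate_six_frames("AT") == [""] * 6

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            translate_six_frames("ATGU")

    def test_n_codons_become_x(self):
        assert translate_six_frames("ATGNNNAAA")[0] == "MXK"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_biopython_on_clean_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 151))
        frames = translate_six_frames(seq)
        rc = str(Seq(seq).reverse_complement())
        for f in range(3):
            n = (len(seq) - f) // 3
            expect = str(Seq(seq[f : f + 3 * n]).translate())
            assert frames[f] == expect
            n = (len(rc) - f) // 3
            expect = str(Seq(rc[f : f + 3 * n]).translate())
            assert frames[3 + f] == expect


class TestBestHitSearch:
    def test_exact_reverse_translation_maps_at_full_identity(self, tiny_catalog):
        prot = tiny_catalog.protein("m03")
        read = reverse_translate(prot.sequence[50:100])
        hits = best_hit_search([("r1", read)], tiny_catalog)
        row = hits.hits.iloc[0]
        assert row.target_protein_id == "m03"
        assert row.percent_identity == 100.0
        assert row.alignment_length == 50

    def test_score_tie_broken_by_catalog_order(self):
        rng = np.random.default_rng(3)
        shared = random_protein(rng, 60)
        prots = [
            ReferenceProtein("first", "marker_01", "marker", "s", "O", "G",
                             shared + random_protein(rng, 40)),
            ReferenceProtein("second", "marker_02", "marker", "s", "O", "G",
                             shared + random_protein(rng, 40)),
        ]
        catalog = ReferenceCatalog(prots)
        read = reverse_translate(shared[5:45])
        hits = best_hit_search([("r1", read)], catalog)
        assert hits.hits.iloc[0].target_protein_id == "first"

    def test_strand_symmetry(self, tiny_catalog):
        rng = np.random.default_rng(5)
        reads = [(f"r{i}", _gene_read(rng, tiny_catalog, 0.1)) for i in range(40)]
        rc_reads = [(rid, str(Seq(s).reverse_complement())) for rid, s in reads]
        fwd = best_hit_search(reads, tiny_catalog).hits
        rev = best_hit_search(rc_reads, tiny_catalog).hits
        assert list(fwd.target_protein_id) == list(rev.target_protein_id)
        assert list(fwd.percent_identity) == list(rev.percent_identity)

    def test_deterministic_repeat(self, tiny_catalog):
        rng = np.random.default_rng(6)
        reads = [(f"r{i}", _gene_read(rng, tiny_catalog, 0.15)) for i in range(30)]
        a = best_hit_search(reads, tiny_catalog).hits
        b = best_hit_search(reads, tiny_catalog).hits
        assert a.equals(b)

    def test_gzip_fasta_input(self, tiny_catalog, tmp_path):
        import gzip

        prot = tiny_catalog.protein("m05")
        read = reverse_translate(prot.sequence[10:60])
        path = tmp_path / "reads.fasta.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(f">gz1\n{read}\n")
        hits = best_hit_search(path, tiny_catalog)
        assert list(hits.hits.target_protein_id) == ["m05"]

    def test_empty_read_set_gives_empty_table(self, tiny_catalog):
        hits = best_hit_search([], tiny_catalog)
        assert len(hits) == 0 and hits.provenance == "internal"


class TestOracleEquivalence:
    """The internal aligner against exhaustive pure-python Smith-Waterman."""

    def _compare(self, reads, catalog, band):
        hits = best_hit_search(reads, catalog)
        impl = {
            r.read_id: (r.target_protein_id, round(r.score), r.alignment_length,
                        round(r.percent_identity, 6))
            for r in hits.hits.itertuples()
        }
        seqs = [p.sequence for p in catalog.proteins]
        mismatches = []
        for rid, seq in reads:
            o = oracle_best_hit(seq, seqs, band=band)
            expected = None if o is None else (
                catalog.proteins[o[0]].protein_id, o[1], o[3],
                round(100 * o[2] / o[3], 6),
            )
            if expected != impl.get(rid):
                mismatches.append((rid, expected, impl.get(rid)))
        assert not mismatches

    def test_equals_full_smith_waterman_on_gene_reads(self):
        """Exhaustive SW over seeded pairs, reads derived from references."""
        rng = np.random.default_rng(42)
        catalog = _catalog(rng, n=20)
        reads = [
            (f"g{i}", _gene_read(rng, catalog, [0.0, 0.05, 0.1, 0.2][i % 4]))
            for i in range(60)
        ]
        self._compare(reads, catalog, band=None)

    def test_equals_band_restricted_dp_on_arbitrary_reads(self):
        """Band-restricted exhaustive DP, random plus gene-derived reads."""
        rng = np.random.default_rng(43)
        catalog = _catalog(rng, n=25)
        reads = [(f"n{i}", "".join(rng.choice(list("ACGT"), 150))) for i in range(120)]
        reads += [(f"g{i}", _gene_read(rng, catalog, 0.1)) for i in range(40)]
        self._compare(reads, catalog, band=SearchParams().band)


class TestEngines:
    def test_c_and_numba_engines_agree(self, small_refs):
        pytest.importorskip("phzquant._calign")
        catalog, species = small_refs
        from phzquant.simulate import compose_community, draw_reads

        spec = compose_community(species, 0.02, degrader_fraction=0.01,
                                 seed=9, library_size=20_000)
        mat, _, _ = draw_reads(spec, species)
        lens = np.full(mat.shape[0], mat.shape[1], dtype=np.int64)
        packed = _packed_catalog(catalog, 5)
        for params in (SearchParams(), SearchParams(min_report_score=36)):
            res_c = search_encoded(mat, lens, packed, params, engine="c")
            res_n = search_encoded(mat, lens, packed, params, engine="numba")
            for a, b in zip(res_c, res_n):
                np.testing.assert_array_equal(a, b)


class TestParseHitTable:
    OUTFMT6 = (
        "r1\tp01\t95.0\t50\t2\t0\t1\t150\t10\t59\t1e-20\t100\n"
        "r2\tp02\t83.3\t45\t7\t0\t1\t135\t5\t49\t1e-10\t80\n"
        "r3\tp01\t79.9\t44\t9\t1\t1\t132\t3\t46\t1e-8\t70\n"
    )

    def test_parses_records(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.OUTFMT6)
        hits = parse_hit_table(path)
        assert len(hits) == 3 and hits.provenance == "external"
        row = hits.hits.set_index("read_id").loc["r2"]
        assert row.percent_identity == 83.3
        assert row.alignment_length == 45

    def test_duplicate_read_keeps_first_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.OUTFMT6 + "r1\tp09\t99.0\t50\t0\t0\t1\t150\t1\t50\t1e-30\t200\n")
        hits = parse_hit_table(path)
        assert len(hits) == 3
        assert hits.hits.set_index("read_id").loc["r1"].target_protein_id == "p01"

    def test_malformed_line_reports_position(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.OUTFMT6 + "r9\tp01\tnot_a_number\t44\t9\t1\t1\t132\t3\t46\t1e-8\t70\n")
        with pytest.raises(ValueError, match="line 4"):
            parse_hit_table(path)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            parse_hit_table(tmp_path / "x.tsv", format="sam")


class TestFilterHits:
    def _table(self, idents):
        import pandas as pd

        return HitTable(
            hits=pd.DataFrame(
                {
                    "read_id": [f"r{i}" for i in range(len(idents))],
                    "target_protein_id": ["p"] * len(idents),
                    "percent_identity": idents,
                    "alignment_length": [50] * len(idents),
                    "score": [100.0] * len(idents),
                }
            ),
            provenance="external",
        )

    def test_boundary_identity_is_retained(self):
        out = filter_hits(self._table([79.9, 80.0, 95.0]), 80.0)
        assert list(out.hits.percent_identity) == [80.0, 95.0]
        assert out.identity_threshold_applied == 80.0

    def test_zero_threshold_keeps_everything(self):
        out = filter_hits(self._table([10.0, 50.0]), 0.0)
        assert len(out) == 2

    def test_empty_table_passes_through(self):
        out = filter_hits(self._table([]), 80.0)
        assert len(out) == 0

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(1)
        idents = rng.uniform(0, 100, 50).round(2)
        t80 = filter_hits(self._table(list(idents)), 80.0)
        assert filter_hits(t80, 80.0).hits.equals(t80.hits)
        t90 = filter_hits(t80, 90.0)
        assert set(t90.hits.read_id) <= set(t80.hits.read_id)

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            filter_hits(self._table([50.0]), 101.0)
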