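"""Record parsing, category mapping and collection summaries."""

import pytest

from bgcnet import bgc_io, synthetic_data
from bgcnet.bgc_io import BGCRecord, DomainHit


def _toy_record(**overrides):
    base = dict(
        bgc_id="bgc1",
        genome_id="g1",
        collection="biofilm",
        contig_id="c1",
        start=0,
        end=1000,
        product_types=["terpene"],
        on_contig_edge=False,
        domains=[DomainHit("PF00001", 50.5), DomainHit("PF00002")],
    )
    base.update(overrides)
    return BGCRecord(**base)


class TestCategoryMapping:
    @pytest.mark.parametrize(
        "products, expected",
        [
            (["lanthipeptide-class-ii"], "RiPP"),  # lanthipeptides count as RiPPs
            (["NRPS", "T1PKS"], "Hybrids"),
            (["terpene"], "Terpene"),
            ([], "Others"),
            (["totally-unknown-product"], "Others"),
            (["NRPS", "NRPS-like"], "NRP"),  # same base class twice is not a hybrid
            (["terpene", "unknown-thing"], "Terpene"),  # Others is ignored for hybrid calls
            (["lassopeptide", "terpene", "T2PKS"], "Hybrids"),
        ],
    )
    def test_six_category_rule(self, products, expected):
        assert bgc_io.map_category(products) == expected

    def test_every_base_class_reachable(self):
        seen = {bgc_io.product_base_class(p) for p in ("NRPS", "T1PKS", "terpene", "thiopeptide")}
        assert seen == {"NRP", "Polyketide", "Terpene", "RiPP"}


class TestGenBankIO:
    def test_region_parse(self, tmp_path):
        rec = _toy_record()
        path = tmp_path / "region.gbk"
        bgc_io.write_region_genbank([rec], path)
        parsed = bgc_io.parse_region_genbank(path, genome_id="g1", collection="biofilm")
        assert len(parsed) == 1
        got = parsed[0]
        assert got.category == "Terpene"
        assert got.on_contig_edge is False
        assert [(d.domain_id, d.bitscore) for d in got.domains] == [
            ("PF00001", 50.5),
            ("PF00002", 1.0),
        ]
        assert (got.start, got.end) == (0, 1000)

    def test_contig_edge_flag(self, tmp_path):
        path = tmp_path / "edge.gbk"
        bgc_io.write_region_genbank([_toy_record(on_contig_edge=True)], path)
        assert bgc_io.parse_region_genbank(path)[0].on_contig_edge is True

    def test_round_trip_domain_multisets(self, tmp_path):
        records, _ = synthetic_data.gen_bgc_collection(
            n_families=5, members_per_family=1, vocab_size=300, core_size=6, seed=3
        )
        path = tmp_path / "five.gbk"
        bgc_io.write_region_genbank(records, path)
        parsed = bgc_io.parse_region_genbank(path)
        assert len(parsed) == 5
        want = [sorted((d.domain_id, d.bitscore) for d in r.domains) for r in records]
        got = [sorted((d.domain_id, d.bitscore) for d in r.domains) for r in parsed]
        assert got == want

    def test_file_without_region_errors(self, tmp_path):
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        path = tmp_path / "plain.gbk"
        SeqIO.write(
            [SeqRecord(Seq("ATGC"), id="x", annotations={"molecule_type": "DNA"})],
            str(path),
            "genbank",
        )
        with pytest.raises(ValueError, match="region"):
            bgc_io.parse_region_genbank(path)


class TestDomainTable:
    def test_bitscore_token_parsing(self, tmp_path):
        path = tmp_path / "t.tsv"
        bgc_io.write_domain_table(
            [_toy_record(domains=[DomainHit("PF00001", 50.5), DomainHit("PF00002")])], path
        )
        [rec] = bgc_io.parse_domain_table(path)
        assert [(d.domain_id, d.bitscore) for d in rec.domains] == [
            ("PF00001", 50.5),
            ("PF00002", 1.0),
        ]

    def test_empty_domains_allowed(self, tmp_path):
        path = tmp_path / "t.tsv"
        bgc_io.write_domain_table([_toy_record(domains=[])], path)
        [rec] = bgc_io.parse_domain_table(path)
        assert rec.domains == []

    def test_round_trip_100_records(self, tmp_path):
        records, _ = synthetic_data.gen_bgc_collection(
            n_families=20, members_per_family=5, vocab_size=2000, core_size=10, seed=7
        )
        assert len(records) == 100
        path = tmp_path / "r.tsv"
        bgc_io.write_domain_table(records, path)
        parsed = bgc_io.parse_domain_table(path)
        assert parsed == records
        # a second write is byte-identical (canonical format)
        path2 = tmp_path / "r2.tsv"
        bgc_io.write_domain_table(parsed, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_duplicate_bgc_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        recs = [_toy_record(), _toy_record(genome_id="g2")]
        bgc_io.write_domain_table(recs, path)
        with pytest.raises(ValueError, match="duplicate bgc_id"):
            bgc_io.parse_domain_table(path)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        header = "\t".join(bgc_io.DOMAIN_TABLE_COLUMNS)
        path.write_text(header + "\nb1\tg1\tc\tc1\tzero\t10\tterpene\tFalse\tPF1\n")
        with pytest.raises(ValueError, match="non-integer"):
            bgc_io.parse_domain_table(path)


class TestSummaries:
    def test_small_worked_example(self):
        records = [
            _toy_record(bgc_id=f"b{i}", genome_id="g1", on_contig_edge=(i == 0))
            for i in range(3)
        ] + [_toy_record(bgc_id="b3", genome_id="g2")]
        summary = bgc_io.summarize_collection(records, None, ["g1", "g2"])
        assert summary.bgcs_per_genome_mean == 2.0
        assert summary.bgcs_per_genome_median == 2.0
        assert summary.contig_edge_fraction == 0.25

    def test_zero_bgc_genomes_count(self):
        records = [_toy_record(genome_id="g1")]
        summary = bgc_io.summarize_collection(records, None, ["g1", "g2", "g3"])
        assert summary.bgcs_per_genome_median == 0.0
        assert summary.bgcs_per_genome_mean == pytest.approx(1 / 3)

    def test_against_independent_tally(self, small_collection):
        records, _ = small_collection
        genome_ids = sorted({r.genome_id for r in records})
        taxonomy = synthetic_data.gen_taxonomy(genome_ids, n_genera=3, seed=5)
        summary = bgc_io.summarize_collection(records, taxonomy, genome_ids)
        # brute-force tally, independent of the implementation
        counts = {g: sum(r.genome_id == g for r in records) for g in genome_ids}
        assert summary.n_bgcs == len(records)
        assert summary.bgcs_per_genome_mean == pytest.approx(
            sum(counts.values()) / len(genome_ids)
        )
        edge = sum(r.on_contig_edge for r in records)
        assert summary.contig_edge_fraction == pytest.approx(edge / len(records))
        assert sum(summary.category_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        for genus, density in summary.per_genus_density.items():
            genomes = [g for g in genome_ids if taxonomy.genus_of(g) == genus]
            assert density == pytest.approx(
                sum(counts[g] for g in genomes) / len(genomes)
            )

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            bgc_io.summarize_collection([], None, [])
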