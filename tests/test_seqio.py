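import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcode_eval import (
    ConcatAlignment,
    HeaderDialect,
    LocusAlignment,
    SeqRecord,
    apply_sampling_filters,
    concatenate,
    drop_singleton_species,
    read_alignment,
    write_alignment,
)
from barcode_eval.errors import (
    DuplicateSampleError,
    HeaderParseError,
    InputError,
    RaggedAlignmentError,
)
from conftest import make_aln


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")


class TestReadAlignment:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(
            p,
            [
                ("X1|Dendrobium_nobile", "acgu-ACGT-"),
                ("X2|Dendrobium_nobile", "ACGTNACGTN"),
                ("Y1|Coelogyne_ovalis", "ACGTTACGTT"),
            ],
        )
        aln = read_alignment(p, locus="ITS")
        assert len(aln) == 3 and aln.length == 10
        # lowercase uppercased, U mapped to T
        assert aln.records[0].residues == "ACGT-ACGT-"
        assert aln.records[0].sample_id == "X1"
        assert aln.records[0].species == "Dendrobium_nobile"

    def test_ragged_alignment_names_offender(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("a|Sp_x", "ACGTACGTAC"), ("b|Sp_y", "ACGTACGTA")])
        with pytest.raises(RaggedAlignmentError, match="b"):
            read_alignment(p, locus="ITS")

    def test_duplicate_sample_id(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("a|Sp_x", "ACGT"), ("a|Sp_y", "ACGT")])
        with pytest.raises(DuplicateSampleError):
            read_alignment(p, locus="ITS")

    def test_bad_header_reports_line(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("a|Sp_x", "ACGT"), ("no_separator_here", "ACGT")])
        with pytest.raises(HeaderParseError, match=r":3:"):
            read_alignment(p, locus="ITS")

    def test_custom_dialect(self, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(p, [("Genus_sp;s1", "ACGT")])
        dialect = HeaderDialect(separator=";", fields=("species", "sample_id"))
        aln = read_alignment(p, locus="matK", dialect=dialect)
        assert aln.records[0].sample_id == "s1"
        assert aln.records[0].species == "Genus_sp"


class TestRoundTrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.text(string.ascii_lowercase + string.digits, min_size=1, max_size=8),
                st.sampled_from(["Sp_a", "Sp_b", "Sp_c"]),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        ),
        seqs=st.data(),
    )
    def test_read_write_identity(self, tmp_path_factory, data, seqs):
        length = seqs.draw(st.integers(5, 40))
        rows = [
            (
                sid,
                sp,
                seqs.draw(
                    st.text("ACGTN-", min_size=length, max_size=length).filter(
                        lambda s: set(s) != {"-"}
                    )
                ),
            )
            for sid, sp in data
        ]
        aln = make_aln("ITS", rows)
        p = tmp_path_factory.mktemp("rt") / "a.fasta"
        write_alignment(aln, p)
        back = read_alignment(p, locus="ITS")
        assert back == aln

    def test_empty_write_rejected(self):
        with pytest.raises(InputError):
            write_alignment(LocusAlignment(locus="ITS", records=[]), "/dev/null")

    def test_concat_partitions_sidecar(self, tmp_path):
        a = make_aln("ITS", [("s1", "Sp_a", "ACGT"), ("s2", "Sp_b", "ACCT")])
        b = make_aln("matK", [("s1", "Sp_a", "GGGGGG"), ("s2", "Sp_b", "GGGTGG")])
        cat = concatenate([a, b])
        p = tmp_path / "cat.fasta"
        write_alignment(cat, p)
        side = (tmp_path / "cat.fasta.partitions.tsv").read_text().splitlines()
        assert side[0] == "locus\tstart\tend"
        assert side[1] == "ITS\t0\t4" and side[2] == "matK\t4\t10"


class TestSamplingFilters:
    def test_min_len_removal(self):
        short = "AC" + "-" * 298 + "GT" + "-" * 298  # 4 ungapped bases
        long = "ACGT" * 150  # 600 ungapped
        aln = make_aln("matK", [("a", "Sp_x", short), ("b", "Sp_x", long)])
        out, log = apply_sampling_filters(aln)
        assert [r.sample_id for r in out.records] == ["b"]
        assert len(log) == 1 and log.entries[0].reason == "min_len"

    def test_its2_exempt_from_min_len(self):
        short = "ACGT" + "-" * 596
        aln = make_aln("ITS2", [("a", "Sp_x", short), ("b", "Sp_x", short)])
        out, log = apply_sampling_filters(aln)
        assert len(out) == 2 and len(log) == 0

    def test_species_cap_keeps_longest_ties_lexicographic(self):
        # 25 individuals; 5 shortest must go; ties broken by sample_id
        rows = []
        for i in range(25):
            ungapped = 400 if i < 22 else 350
            seq = "A" * ungapped + "-" * (500 - ungapped)
            rows.append((f"s{i:02d}", "Sp_x", seq))
        aln = make_aln("matK", rows)
        out, log = apply_sampling_filters(aln, max_per_species=20)
        assert len(out) == 20 and len(log) == 5
        kept = {r.sample_id for r in out.records}
        # the three 350-bp ones are all dropped, plus lexicographically
        # largest of the 400-bp ties
        assert {"s22", "s23", "s24"} & kept == set()
        assert "s21" not in kept and "s20" not in kept

    def test_noop_and_idempotence(self, toy_alignment):
        aln = make_aln(
            "matK",
            [(f"s{i}", "Sp_x", "ACGT" * 100) for i in range(5)],
        )
        once, log1 = apply_sampling_filters(aln)
        assert once == aln and len(log1) == 0
        # idempotence on a filtered result
        rows = [
            (f"t{i:02d}", "Sp_y", "ACGT" * (80 + i) + "-" * (4 * (24 - i)))
            for i in range(25)
        ]
        first, loga = apply_sampling_filters(make_aln("matK", rows))
        second, logb = apply_sampling_filters(first)
        assert second == first and len(logb) == 0

    def test_filter_log_conservation(self):
        width = 4 * (50 + 20 * 24)
        rows = [
            (
                f"s{i:02d}",
                "Sp_x",
                "ACGT" * (50 + 20 * i) + "-" * (width - 4 * (50 + 20 * i)),
            )
            for i in range(25)
        ]
        rows.append(("zz", "Sp_y", "AC" + "-" * (width - 2)))
        aln = make_aln("matK", rows)
        out, log = apply_sampling_filters(aln)
        assert len(log) == len(aln) - len(out)

    def test_all_removed_is_error(self):
        aln = make_aln("matK", [("a", "Sp_x", "ACGT" + "-" * 396)])
        with pytest.raises(InputError):
            apply_sampling_filters(aln)


class TestSingletonsAndConcat:
    def test_singleton_removal(self):
        aln = make_aln(
            "ITS",
            [
                ("a1", "Sp_a", "ACGT"),
                ("a2", "Sp_a", "ACGT"),
                ("a3", "Sp_a", "ACGT"),
                ("b1", "Sp_b", "ACGT"),
                ("c1", "Sp_c", "ACGT"),
                ("c2", "Sp_c", "ACGT"),
            ],
        )
        out, removed = drop_singleton_species(aln)
        assert removed == ["Sp_b"]
        assert sorted(out.species_counts()) == ["Sp_a", "Sp_c"]

    def test_no_singletons_unchanged(self, toy_alignment):
        out, removed = drop_singleton_species(toy_alignment)
        assert out == toy_alignment and removed == []

    def test_all_singletons_empty(self):
        aln = make_aln("ITS", [("a", "Sp_a", "ACGT"), ("b", "Sp_b", "ACGT")])
        out, removed = drop_singleton_species(aln)
        assert len(out) == 0 and removed == ["Sp_a", "Sp_b"]

    def test_concat_intersection(self):
        its = make_aln(
            "ITS",
            [("s1", "Sp_a", "AAAA"), ("s2", "Sp_a", "AAAT"), ("s3", "Sp_b", "TTTT")],
        )
        matk = make_aln(
            "matK",
            [("s2", "Sp_a", "GG"), ("s3", "Sp_b", "GC"), ("s4", "Sp_c", "CC")],
        )
        cat = concatenate([its, matk])
        assert sorted(r.sample_id for r in cat.records) == ["s2", "s3"]
        assert cat.length == 6 == sum(e - s for _, s, e in cat.partitions)
        assert cat.locus == "ITS+matK"
        rec = {r.sample_id: r for r in cat.records}
        assert rec["s2"].residues == "AAATGG"

    def test_concat_single_shared_sample(self):
        a = make_aln("ITS", [("s1", "Sp_a", "AAAA"), ("x", "Sp_b", "TTTT")])
        b = make_aln("matK", [("s1", "Sp_a", "GG"), ("y", "Sp_c", "CC")])
        cat = concatenate([a, b])
        assert len(cat) == 1

    def test_concat_conflicting_species(self):
        a = make_aln("ITS", [("s1", "Sp_x", "AAAA")])
        b = make_aln("matK", [("s1", "Sp_y", "GG")])
        with pytest.raises(InputError, match="conflicting species"):
            concatenate([a, b])

    def test_concat_empty_intersection(self):
        a = make_aln("ITS", [("s1", "Sp_a", "AAAA")])
        b = make_aln("matK", [("s2", "Sp_a", "GG")])
        with pytest.raises(InputError, match="no sample"):
            concatenate([a, b])
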