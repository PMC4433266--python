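import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smallrna.preprocessing import (
    DEFAULT_ADAPTER_3P,
    CleaningParams,
    ReadCategoryCounts,
    UniqueTag,
    clean_reads,
    find_adapter,
    length_distribution,
    merge_tag_counts,
    overlap_summary,
    read_collapsed_fasta,
    round_half_up,
    write_collapsed_fasta,
)

AD3 = DEFAULT_ADAPTER_3P


def _write_fastq(path, reads):
    with open(path, "w") as out:
        for i, seq in enumerate(reads):
            out.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestCleanReads:
    def test_insert_null(self, tmp_path):
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, [AD3])  # adapter only, zero-length insert
        tags, counts = clean_reads(fq)
        assert counts.insert_null == 1
        assert counts.clean_reads == 0
        assert tags == {}

    def test_below_18nt(self, tmp_path):
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, ["ACGACGACGACGACG" + AD3])  # 15 nt insert
        _, counts = clean_reads(fq)
        assert counts.below_18nt == 1

    def test_polya(self, tmp_path):
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, ["A" * 30 + AD3])
        _, counts = clean_reads(fq)
        assert counts.polyA == 1

    def test_adaptor3_null(self, tmp_path):
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, ["ACG" * 10])
        _, counts = clean_reads(fq)
        assert counts.adaptor3_null == 1

    def test_adaptor5_contaminant(self, tmp_path):
        params = CleaningParams()
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, [params.adapter_5p[:10] + "ACGACGACG" + AD3])
        _, counts = clean_reads(fq, params)
        assert counts.adaptor5_contaminant == 1

    def test_clean_tag(self, tmp_path):
        insert = "ACGTGCATGCATCGATCGATC"  # 21 nt
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, [insert + AD3] * 3)
        tags, counts = clean_reads(fq)
        assert counts.clean_reads == 3
        assert tags == {insert: 3}

    def test_low_quality_n(self, tmp_path):
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, ["ACGTNCATGCATCGATCGATC" + AD3])
        _, counts = clean_reads(fq)
        assert counts.high_quality == 0
        assert counts.total_reads == 1

    def test_empty_file(self, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        tags, counts = clean_reads(fq)
        assert tags == {}
        assert counts.total_reads == 0
        assert counts.clean_reads == 0

    def test_malformed_fastq(self, tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r0\nACGT\nplus-line-missing\n")
        with pytest.raises(ValueError, match="malformed FASTQ"):
            clean_reads(fq)

    def test_category_partition(self, tmp_path):
        params = CleaningParams()
        reads = [
            AD3,
            "ACGACGACGACGACG" + AD3,
            "A" * 30 + AD3,
            "ACG" * 10,
            params.adapter_5p[:10] + "ACGACGACG" + AD3,
            "ACGTGCATGCATCGATCGATC" + AD3,
        ] * 4
        fq = tmp_path / "a.fastq"
        _write_fastq(fq, reads)
        _, c = clean_reads(fq, params)
        discarded = (
            c.adaptor3_null
            + c.insert_null
            + c.adaptor5_contaminant
            + c.below_18nt
            + c.polyA
        )
        assert discarded + c.clean_reads == c.high_quality
        assert c.clean_reads == c.derived_clean()

    def test_clean_fasta_roundtrip(self, tmp_path):
        """Re-cleaning an already-clean collapsed FASTA is a no-op."""
        tags = [
            UniqueTag("ACGTGCATGCATCGATCGATC", 3, 2),
            UniqueTag("GGGTGCATGCATCGATCGAT", 0, 5),
        ]
        fa = tmp_path / "clean.fasta"
        write_collapsed_fasta(tags, fa)
        out_tags, counts = clean_reads(fa)
        assert out_tags == {t.sequence: t.total for t in tags}
        assert counts.clean_reads == sum(t.total for t in tags)
        assert counts.clean_reads == counts.total_reads


class TestFindAdapter:
    def test_exact(self):
        assert find_adapter("ACGT" + AD3, AD3) == 4

    def test_one_mismatch_in_extension(self):
        mutated = AD3[:10] + ("A" if AD3[10] != "A" else "C") + AD3[11:]
        assert find_adapter("ACGT" + mutated, AD3) == 4

    def test_absent(self):
        assert find_adapter("ACGT" * 10, AD3) == -1

    def test_leftmost(self):
        read = AD3 + "ACGT" + AD3
        assert find_adapter(read, AD3) == 0


class TestOverlapSummary:
    def test_printed_table_percentages(self):
        # Frozen two-library overlap counts; derived percentages.
        ov_counts = {
            "shared": (717567, 35482562),
            "lib1": (1868426, 2252922),
            "lib2": (1923164, 2362061),
        }
        from smallrna.preprocessing import OverlapSummary

        ov = OverlapSummary(
            total_unique=sum(v[0] for v in ov_counts.values()),
            shared_unique=ov_counts["shared"][0],
            lib1_specific_unique=ov_counts["lib1"][0],
            lib2_specific_unique=ov_counts["lib2"][0],
            total_reads=sum(v[1] for v in ov_counts.values()),
            shared_reads=ov_counts["shared"][1],
            lib1_specific_reads=ov_counts["lib1"][1],
            lib2_specific_reads=ov_counts["lib2"][1],
        )
        pct = ov.percentages
        assert pct["shared_unique"] == 15.91
        assert pct["lib1_specific_unique"] == 41.44
        assert pct["lib2_specific_unique"] == 42.65
        assert pct["shared_reads"] == 88.49

    def test_single_lib1_tag(self):
        ov = overlap_summary([UniqueTag("A" * 20, 5, 0)])
        assert ov.lib1_specific_unique == 1
        assert ov.shared_unique == 0
        assert ov.total_unique == 1

    def test_all_shared(self):
        tags = [UniqueTag("A" * 20, 2, 3), UniqueTag("C" * 20, 1, 1)]
        ov = overlap_summary(tags)
        assert ov.percentages["shared_unique"] == 100.00
        assert ov.shared_unique + ov.lib1_specific_unique + ov.lib2_specific_unique == ov.total_unique

    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50)).filter(
                lambda t: t[0] + t[1] > 0
            ),
            min_size=1,
            max_size=30,
        ),
        st.randoms(),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, counts, rnd):
        def seq_for(i: int) -> str:  # distinct 20-mer per index
            digits = [(i >> (2 * k)) & 3 for k in range(20)]
            return "".join("ACGT"[d] for d in digits)

        tags = [UniqueTag(seq_for(i), c1, c2) for i, (c1, c2) in enumerate(counts)]
        ov1 = overlap_summary(tags)
        shuffled = tags[:]
        rnd.shuffle(shuffled)
        assert overlap_summary(shuffled) == ov1


class TestLengthDistribution:
    def test_all_21(self):
        tags = [UniqueTag("A" * 21, 1, 0), UniqueTag("C" * 21, 2, 1)]
        assert length_distribution(tags, "unique") == {21: 1.0}

    def test_read_weighting(self):
        tags = [UniqueTag("A" * 21, 3, 0), UniqueTag("C" * 24, 1, 0)]
        assert length_distribution(tags, "reads") == {21: 0.75, 24: 0.25}

    def test_simulated_mode_is_21(self, small_clean):
        tags, _, _ = small_clean
        dist = length_distribution(tags, "reads")
        assert max(dist, key=dist.get) == 21

    def test_sums_to_one(self, small_clean):
        tags, _, _ = small_clean
        for weighting in ("unique", "reads"):
            assert abs(sum(length_distribution(tags, weighting).values()) - 1.0) < 1e-9


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(15.905, 15.91), (88.494, 88.49), (41.435, 41.44), (0.005, 0.01)],
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value, 2) == expected


class TestCollapsedFasta:
    def test_roundtrip(self, tmp_path):
        tags = [UniqueTag("ACGTGCATGCATCGATCGATC", 3, 2),
                UniqueTag("GGGTGCATGCATCGATCGAT", 1, 0)]
        path = tmp_path / "tags.fasta"
        write_collapsed_fasta(tags, path)
        back = read_collapsed_fasta(path)
        assert back == tags
        header = path.read_text().splitlines()[0]
        assert header.startswith(">tag1_x5")


class TestReadCategoryCounts:
    def test_partition_identity_validate(self):
        c = ReadCategoryCounts(
            total_reads=100, high_quality=90, adaptor3_null=5, insert_null=2,
            adaptor5_contaminant=1, below_18nt=3, polyA=1, clean_reads=78,
        )
        c.validate()
        assert c.derived_clean() == 78

    def test_bad_identity_rejected(self):
        c = ReadCategoryCounts(total_reads=10, high_quality=10, clean_reads=5)
        with pytest.raises(ValueError):
            c.validate()


def test_simulated_category_counts_match_manifest(small_dataset, small_clean):
    """Category accounting equals the simulator's truth labels exactly."""
    import csv

    _, c1, c2 = small_clean
    truth = {1: {}, 2: {}}
    with open(small_dataset.manifest) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            lib = int(row["library"])
            truth[lib][row["category"]] = truth[lib].get(row["category"], 0) + 1
    for counts, tlab in ((c1, truth[1]), (c2, truth[2])):
        assert counts.adaptor3_null == tlab.get("adaptor3_null", 0)
        assert counts.insert_null == tlab.get("insert_null", 0)
        assert counts.adaptor5_contaminant == tlab.get("adaptor5_contaminant", 0)
        assert counts.below_18nt == tlab.get("short", 0)
        assert counts.polyA == tlab.get("polyA", 0)
        clean_truth = (
            tlab.get("clean_mirna", 0)
            + tlab.get("isoform", 0)
            + tlab.get("star", 0)
            + tlab.get("ncRNA_fragment", 0)
        )
        assert counts.clean_reads == clean_truth
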