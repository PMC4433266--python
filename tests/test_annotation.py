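import itertools

import numpy as np
import pytest

from smallrna._seq import revcomp
from smallrna.annotation import (
    NCRNA_CLASSES,
    classify_ncrna,
    collapse_members,
    identify_conserved,
    is_end_variant,
    load_class_reference,
    load_mature_reference,
    map_to_transcripts,
    annotate_tags,
)
from smallrna.preprocessing import UniqueTag


def brute_force_end_variant(a: str, b: str, max_diff: int = 2) -> bool:
    """Oracle: enumerate end trims of both sequences.

    At each end at most one of the two sequences may be trimmed (the
    other would have to extend, i.e. a trim of the opposite sequence is
    the same alignment); total trimmed length <= max_diff and the
    trimmed cores must be identical.
    """
    la, lb = len(a), len(b)
    for t5a in range(0, max_diff + 1):
        for t3a in range(0, max_diff + 1 - t5a):
            for t5b in range(0, max_diff + 1 - t5a - t3a):
                for t3b in range(0, max_diff + 1 - t5a - t3a - t5b):
                    if t5a and t5b:
                        continue
                    if t3a and t3b:
                        continue
                    ca = a[t5a : la - t3a]
                    cb = b[t5b : lb - t3b]
                    if ca and ca == cb:
                        return True
    return False


class TestClassifyNcrna:
    def _ref(self):
        rng = np.random.default_rng(0)
        seqs = {}
        for cls in NCRNA_CLASSES:
            seqs[cls] = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        return [(f"{cls}_ref", cls, seq) for cls, seq in seqs.items()], seqs

    def test_substring_hit(self):
        ref, seqs = self._ref()
        tag = UniqueTag(seqs["rRNA"][40:61], 3, 1)
        assignments, unannotated = classify_ncrna([tag], ref)
        assert assignments[tag.sequence] == "rRNA"
        assert unannotated == []

    @pytest.mark.parametrize(
        "pair", list(itertools.combinations(NCRNA_CLASSES, 2))
    )
    def test_precedence(self, pair):
        """Tag present in two classes gets the higher-precedence one."""
        window = "ACGTACGTACGTACGTACGTA"
        ref = [
            (f"{cls}_ref", cls, "CCCC" + window + "GGGG") for cls in pair
        ]
        tag = UniqueTag(window, 1, 1)
        assignments, _ = classify_ncrna([tag], ref)
        expected = min(pair, key=NCRNA_CLASSES.index)
        assert assignments[window] == expected

    def test_no_match(self):
        ref, _ = self._ref()
        tag = UniqueTag("T" * 21, 1, 0)
        assignments, unannotated = classify_ncrna([tag], ref)
        assert assignments == {}
        assert unannotated == [tag]

    def test_unlabeled_reference_error(self, tmp_path):
        fa = tmp_path / "bad.fasta"
        fa.write_text(">anonymous\nACGTACGTACGT\n")
        with pytest.raises(ValueError, match="class"):
            load_class_reference(fa)


class TestIdentifyConserved:
    REF = {"ACGTGCATGCATCGATCGATC": ("gbi-miR166a", "MIR166")}

    def test_exact_above_threshold(self):
        tag = UniqueTag("ACGTGCATGCATCGATCGATC", 12, 15)
        assert identify_conserved([tag], self.REF) == {
            tag.sequence: ("gbi-miR166a", "MIR166")
        }

    def test_below_threshold_one_library(self):
        tag = UniqueTag("ACGTGCATGCATCGATCGATC", 12, 9)
        assert identify_conserved([tag], self.REF) == {}

    def test_either_library_mode(self):
        tag = UniqueTag("ACGTGCATGCATCGATCGATC", 12, 9)
        assert identify_conserved([tag], self.REF, require_both=False) != {}

    def test_one_mismatch_rejected(self):
        tag = UniqueTag("TCGTGCATGCATCGATCGATC", 50, 50)
        assert identify_conserved([tag], self.REF) == {}

    def test_family_parsing(self, tmp_path):
        fa = tmp_path / "mature.fasta"
        fa.write_text(">gbi-miR166a MIR166\nUCGGACCAGGCUUCAUUCCCC\n")
        ref = load_mature_reference(fa)
        assert ref == {"TCGGACCAGGCTTCATTCCCC": ("gbi-miR166a", "MIR166")}


class TestEndVariant:
    def test_one_nt_extension(self):
        x = "ACGTGCATGCATCGATCGATC"
        assert is_end_variant(x, x + "G")

    def test_three_nt_extension_rejected(self):
        x = "ACGTGCATGCATCGATCGATC"
        assert not is_end_variant(x, x + "GGG")

    def test_internal_substitution_rejected(self):
        x = "ACGTGCATGCATCGATCGATC"
        y = x[:10] + ("A" if x[10] != "A" else "C") + x[11:]
        assert not is_end_variant(x, y)

    def test_opposite_end_shifts(self):
        x = "ACGTGCATGCATCGATCGATC"
        assert is_end_variant("G" + x[:-1], x)  # +1 at 5', -1 at 3'

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            core = "".join(bases[rng.integers(0, 4, 21)])
            a = core
            # random end edits of total length <= 4
            def edit(s):
                n5, n3 = int(rng.integers(0, 3)), int(rng.integers(0, 3))
                if rng.random() < 0.5:
                    s = s[n5:] if n5 else s
                else:
                    s = "".join(bases[rng.integers(0, 4, n5)]) + s
                if rng.random() < 0.5:
                    s = s[: len(s) - n3] if n3 else s
                else:
                    s = s + "".join(bases[rng.integers(0, 4, n3)])
                return s

            b = edit(core)
            assert is_end_variant(a, b) == brute_force_end_variant(a, b), (a, b)


class TestCollapseMembers:
    def _tags(self, seqs):
        return [UniqueTag(s, 10 + i, 10) for i, s in enumerate(seqs)]

    def test_one_member_for_end_variant(self):
        x = "ACGTGCATGCATCGATCGATC"
        tags = self._tags([x, x + "G"])
        conserved = {t.sequence: ("r", "MIR166") for t in tags}
        members = collapse_members(conserved, tags)
        assert len(members) == 1
        assert len(members[0].isoform_tags) == 2
        assert members[0].count_lib1 == sum(t.count_lib1 for t in tags)

    def test_two_members_for_distant_variants(self):
        x = "ACGTGCATGCATCGATCGATC"
        tags = self._tags([x, x + "GGG"])
        conserved = {t.sequence: ("r", "MIR166") for t in tags}
        assert len(collapse_members(conserved, tags)) == 2

    def test_internal_substitution_two_members(self):
        x = "ACGTGCATGCATCGATCGATC"
        y = x[:10] + ("A" if x[10] != "A" else "C") + x[11:]
        tags = self._tags([x, y])
        conserved = {t.sequence: ("r", "MIR166") for t in tags}
        assert len(collapse_members(conserved, tags)) == 2

    def test_representative_is_top_count(self):
        x = "ACGTGCATGCATCGATCGATC"
        tags = [UniqueTag(x, 5, 5), UniqueTag(x + "G", 50, 50)]
        conserved = {t.sequence: ("r", "MIR166") for t in tags}
        (member,) = collapse_members(conserved, tags)
        assert member.representative.sequence == x + "G"
        assert all(
            member.representative.total >= t.total for t in member.isoform_tags
        )

    def test_naming_by_descending_count(self):
        x = "ACGTGCATGCATCGATCGATC"
        z = "TTTTTTGGGGGCCCCCAAAAA"
        tags = [UniqueTag(x, 5, 5), UniqueTag(z, 100, 100)]
        conserved = {t.sequence: ("r", "MIR166") for t in tags}
        members = collapse_members(conserved, tags)
        assert [m.member_id for m in members] == ["miR166a-1", "miR166b-2"]
        assert members[0].representative.sequence == z

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        seqs = set()
        for _ in range(8):
            core = "".join(bases[rng.integers(0, 4, 21)])
            seqs.add(core)
            seqs.add(core + "".join(bases[rng.integers(0, 4, 1)]))
        tags = self._tags(sorted(seqs))
        conserved = {t.sequence: ("r", "MIR399") for t in tags}
        members = collapse_members(conserved, tags)
        # collapse again from the first result's isoforms
        again = collapse_members(conserved, tags)
        assert [sorted(t.sequence for t in m.isoform_tags) for m in members] == [
            sorted(t.sequence for t in m.isoform_tags) for m in again
        ]
        assert len(members) <= len(tags)


class TestMapToTranscripts:
    TX = {"t1": "A" * 100 + "ACGTGCATGCATCGATCGATC" + "G" * 80}

    def test_forward_hit(self):
        tag = UniqueTag("ACGTGCATGCATCGATCGATC", 1, 1)
        hits = map_to_transcripts([tag], self.TX)
        assert hits[tag.sequence] == [("t1", 100, "+")]

    def test_reverse_hit(self):
        tag = UniqueTag(revcomp("ACGTGCATGCATCGATCGATC"), 1, 1)
        hits = map_to_transcripts([tag], self.TX)
        assert hits[tag.sequence] == [("t1", 100, "-")]

    def test_absent(self):
        tag = UniqueTag("CT" * 10 + "C", 1, 1)  # absent on both strands
        assert map_to_transcripts([tag], self.TX)[tag.sequence] == []


class TestAnnotationSummary:
    def test_partition(self, small_annotated, small_clean):
        tags, _, _ = small_clean
        _, _, _, summary = small_annotated
        for lib in (0, 1):
            total = sum(v[lib] for v in summary.unique.values())
            assert total == summary.total_unique[lib]
            total_r = sum(v[lib] for v in summary.reads.values())
            assert total_r == summary.total_reads[lib]

    def test_families_recovered(self, small_dataset, small_annotated):
        """Planted conserved matures above threshold are all recovered."""
        _, conserved, _, _ = small_annotated
        truth = small_dataset.truth
        for rec in truth.hairpins:
            if rec.kind != "conserved":
                continue
            c1 = truth.actual_counts[(rec.mirna_id, 1)]
            c2 = truth.actual_counts[(rec.mirna_id, 2)]
            if c1 >= 10 and c2 >= 10:
                assert rec.mature in conserved
                assert conserved[rec.mature][1] == rec.family
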