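"""Reference I/O: parsing, coordinate conventions, pyrimidine orientation,
motif counting, and the reverse-complement symmetry they must all obey."""

import numpy as np
import pandas as pd
import pytest

from apomut import refio
from apomut.refio import (
    GenomeContext,
    count_motifs,
    motif_class_trimers,
    pyrimidine_normalize,
    read_bedgraph,
    read_fasta,
    read_genes,
    read_mutations,
    revcomp,
)

from conftest import random_genome


class TestReadFasta:
    def test_parse_and_casefold(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>c\nacgt\n")
        g = read_fasta(p)
        assert g.length("chr1") == 4
        assert g.chroms["c"] == "ACGT"

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nAC\n>a\nGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_non_acgtn_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACXT\n")
        with pytest.raises(ValueError, match="non-ACGTN"):
            read_fasta(p)


class TestPyrimidineNormalize:
    def test_purine_ref_is_flipped(self):
        g = GenomeContext({"c": "ATGAT"})  # central G at pos 2, plus 3-mer TGA
        ctx, alt, strand = pyrimidine_normalize(g, "c", 2, "G", "A")
        assert (ctx, alt, strand) == ("TCA", "T", "-")

    def test_pyrimidine_ref_kept(self):
        g = GenomeContext({"c": "ATCAT"})
        ctx, alt, strand = pyrimidine_normalize(g, "c", 2, "C", "G")
        assert (ctx, alt, strand) == ("TCA", "G", "+")

    def test_n_in_window_flagged(self):
        g = GenomeContext({"c": "ANCAT"})
        ctx, alt, strand = pyrimidine_normalize(g, "c", 2, "C", "T")
        assert ctx is None

    def test_ref_mismatch_raises(self):
        g = GenomeContext({"c": "ATCAT"})
        with pytest.raises(ValueError, match="does not match"):
            pyrimidine_normalize(g, "c", 2, "G", "A")

    def test_involution_under_reverse_complement(self):
        """A record and its mirror image yield identical (context, alt)."""
        rng = np.random.default_rng(7)
        g = random_genome(rng, 2_000)
        L = g.length("chr1")
        pos = rng.integers(1, L - 1, size=200)
        for p in pos:
            ref = g.base("chr1", int(p))
            alt = next(b for b in "ACGT" if b != ref)
            ctx, a, _ = pyrimidine_normalize(g, "chr1", int(p), ref, alt)
            gm = refio.mirror_genome(g)
            pm = L - 1 - int(p)
            ctx_m, a_m, _ = pyrimidine_normalize(gm, "chr1", pm, revcomp(ref), revcomp(alt))
            assert (ctx, a) == (ctx_m, a_m)


class TestReadMutations:
    def _write(self, tmp_path, rows):
        p = tmp_path / "m.tsv"
        p.write_text("sample\tchrom\tpos\tref\talt\n" + "\n".join(rows) + "\n")
        return p

    def test_one_based_conversion_and_context(self, tmp_path):
        g = GenomeContext({"chr1": "TCAG"})
        p = self._write(tmp_path, ["s1\tchr1\t2\tC\tT"])
        df, counters = read_mutations(p, g)
        assert df.loc[0, "pos"] == 1
        assert df.loc[0, "pyr_context"] == "TCA"
        assert df.loc[0, "pyr_alt"] == "T"
        assert counters["rows_kept"] == 1

    def test_indels_dropped_and_counted(self, tmp_path):
        g = GenomeContext({"chr1": "TCAG"})
        p = self._write(tmp_path, ["s1\tchr1\t2\tCA\tT", "s1\tchr1\t2\tC\tG"])
        df, counters = read_mutations(p, g)
        assert counters["indels_dropped"] == 1
        assert len(df) == 1

    def test_ref_mismatch_strict_raises(self, tmp_path):
        g = GenomeContext({"chr1": "TCAG"})
        p = self._write(tmp_path, ["s1\tchr1\t2\tG\tA"])
        with pytest.raises(ValueError, match="ref mismatch"):
            read_mutations(p, g)

    def test_ref_mismatch_lenient_drops(self, tmp_path):
        g = GenomeContext({"chr1": "TCAG"})
        p = self._write(tmp_path, ["s1\tchr1\t2\tG\tA", "s1\tchr1\t2\tC\tG"])
        df, counters = read_mutations(p, g, strict=False)
        assert counters["ref_mismatch"] == 1
        assert len(df) == 1


class TestCountMotifs:
    def test_hand_count_both_strands(self):
        g = GenomeContext({"c": "TCATGA"})
        plus, minus = count_motifs(g, None, "TCN", per_strand=True)
        assert (plus, minus) == (1, 1)

    def test_no_motifs(self):
        g = GenomeContext({"c": "AAAA"})
        assert count_motifs(g, None, "TCN") == 0

    def test_overlapping_intervals_rejected(self):
        g = GenomeContext({"c": "TCATGATCA"})
        iv = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 3], "end": [5, 8]})
        with pytest.raises(ValueError, match="overlap"):
            count_motifs(g, iv, "TCN")

    def test_brute_force_oracle_and_strand_sum(self):
        rng = np.random.default_rng(13)
        g = random_genome(rng, 20_000)
        seq = g.chroms["chr1"]
        for motif_class in ("TCN", "TCW", "NCN", "non_tcn_c"):
            trimers = set(motif_class_trimers(motif_class))
            exp_plus = sum(seq[i - 1 : i + 2] in trimers for i in range(1, len(seq) - 1))
            exp_minus = sum(revcomp(seq[i - 1 : i + 2]) in trimers for i in range(1, len(seq) - 1))
            plus, minus = count_motifs(g, None, motif_class, per_strand=True)
            assert (plus, minus) == (exp_plus, exp_minus)
            assert count_motifs(g, None, motif_class) == plus + minus

    def test_partition_sums_to_whole_genome(self):
        rng = np.random.default_rng(17)
        g = random_genome(rng, 10_000)
        cuts = np.sort(rng.choice(np.arange(1, 10_000), size=9, replace=False))
        edges = np.concatenate(([0], cuts, [10_000]))
        iv = pd.DataFrame({"chrom": "chr1", "start": edges[:-1], "end": edges[1:]})
        assert count_motifs(g, iv, "TCN") == count_motifs(g, None, "TCN")

    def test_mirror_invariance(self):
        rng = np.random.default_rng(19)
        g = random_genome(rng, 5_000)
        gm = refio.mirror_genome(g)
        assert count_motifs(g, None, "TCN", per_strand=True) == tuple(
            reversed(count_motifs(gm, None, "TCN", per_strand=True))
        )
        assert count_motifs(g, None, "NCN") == count_motifs(gm, None, "NCN")


class TestIntervalReaders:
    def test_bedgraph_roundtrip(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t1000\t56.2\nchr1\t1000\t2000\t57.0\n")
        df = read_bedgraph(p)
        assert len(df) == 2 and df.loc[0, "value"] == 56.2

    def test_bedgraph_empty(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("")
        assert len(read_bedgraph(p)) == 0

    def test_bedgraph_overlap_rejected(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t1000\t1\nchr1\t500\t1500\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_bedgraph(p)

    def test_bed6_and_gff3_agree(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t200\tg1\t0\t+\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        a = read_genes(bed)
        b = read_genes(gff)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_strand_rejected(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t200\tg1\t0\t.\n")
        with pytest.raises(ValueError, match="strand"):
            read_genes(bed)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t100\t200\tg1\t0\t+\nchr1\t300\t400\tg1\t0\t-\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genes(bed)
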