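"""Readers, labeling, window extraction and the 70:20:10 split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpgnet import seqdata
from cpgnet.seqdata import (
    CpGSite,
    FastaFormatError,
    GenomeSequence,
    METHYLATED,
    SplitSpec,
    UNMETHYLATED,
)


class TestReadFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chrT\nACGT\n")
        recs = seqdata.read_fasta(p)
        assert len(recs) == 1
        assert recs[0].name == "chrT"
        assert recs[0].residues == "ACGT"
        assert recs[0].length == 4

    def test_multirecord_case_folding(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacg\nt\n>b\nNNNN\n")
        recs = seqdata.read_fasta(p)
        assert [r.length for r in recs] == [4, 4]
        assert recs[0].residues == "ACGT"

    def test_ambiguity_normalized_to_n(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACRT\n")
        (rec,) = seqdata.read_fasta(p)
        assert rec.residues == "ACNT"
        assert rec.n_ambiguous_normalized == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            seqdata.read_fasta(tmp_path / "nope.fa")

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("ACGT\n>chr1\nACGT\n")
        with pytest.raises(FastaFormatError, match="line 1"):
            seqdata.read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FastaFormatError):
            seqdata.read_fasta(p)


class TestMethylationTable:
    def test_coordinate_dialects(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tpos\tbeta_percent\nchr4\t1001\t75.0\n")
        (s1,) = seqdata.read_methylation_table(p, dialect="tsv1")
        assert (s1.pos, s1.beta) == (1000, 75.0)
        p.write_text("chrom\tpos\tbeta_percent\nchr4\t1000\t75.0\n")
        (s0,) = seqdata.read_methylation_table(p, dialect="bed0")
        assert (s0.pos, s0.beta) == (1000, 75.0)

    def test_out_of_range_beta_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tpos\tbeta_percent\nchr1\t10\t120\nchr1\t20\t50\n")
        sites = seqdata.read_methylation_table(p)
        assert len(sites) == 1 and sites[0].pos == 20

    def test_non_numeric_beta_raises(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tpos\tbeta_percent\nchr1\t10\thigh\n")
        with pytest.raises(ValueError):
            seqdata.read_methylation_table(p)

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tpos\tbeta_percent\nchr1\t10\t50\n")
        with pytest.raises(ValueError, match="dialect"):
            seqdata.read_methylation_table(p, dialect="vcf")

    def test_round_trip(self, tmp_path, balanced_sites):
        for dialect in ("bed0", "tsv1"):
            p = tmp_path / f"{dialect}.tsv"
            seqdata.write_methylation_table(balanced_sites, p, dialect=dialect)
            back = seqdata.read_methylation_table(p, dialect=dialect)
            assert [(s.chrom, s.pos, s.beta) for s in back] == [
                (s.chrom, s.pos, s.beta) for s in balanced_sites
            ]


class TestLabeling:
    @pytest.mark.parametrize(
        "beta,expected",
        [
            (50.0, METHYLATED),       # threshold is inclusive
            (49.99, UNMETHYLATED),
            (0.0, UNMETHYLATED),
            (100.0, METHYLATED),
        ],
    )
    def test_threshold(self, beta, expected):
        assert seqdata.label_site(beta) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            seqdata.label_site(101.0)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_label_law_on_sites(self, beta):
        site = CpGSite(chrom="c", pos=0, beta=beta)
        assert site.label == (METHYLATED if beta >= 50 else UNMETHYLATED)


class TestWindows:
    def test_window_geometry(self):
        residues = "A" * 850 + "ACGT" * 75 + "A" * 100
        g = GenomeSequence("c", residues[:2000] + "A" * 0)
        # put a CG at pos 1000
        res = residues[:1000] + "CG" + residues[1002:]
        g = GenomeSequence("c", res[:2000].ljust(2000, "A"))
        site = CpGSite(chrom="c", pos=1000, beta=80)
        w = seqdata.extract_window(g, site, 300)
        assert w is not None
        assert len(w.seq) == 300
        assert w.center_offset == 150
        assert w.seq == g.residues[850:1150]
        assert w.seq[150:152] == "CG"

    def test_left_overrun_skipped(self):
        g = GenomeSequence("c", ("A" * 100 + "CG" + "A" * 9898))
        site = CpGSite(chrom="c", pos=100, beta=80)
        assert seqdata.extract_window(g, site, 300) is None

    def test_non_cg_site_skipped(self, tiny_genome):
        site = CpGSite(chrom="chrT", pos=0, beta=80)  # "AA"
        assert seqdata.extract_window(tiny_genome, site, 10) is None

    def test_every_window_centered_on_cg(self, tiny_genome):
        sites = [CpGSite(chrom="chrT", pos=p, beta=60) for p in (8, 20, 30)]
        windows, skipped = seqdata.extract_windows(tiny_genome, sites, 10)
        for w in windows:
            assert w.seq[w.width // 2 : w.width // 2 + 2] == "CG"
        # pos 8 has a full [3, 13) window; pos 30 overruns on the right
        assert skipped == 1

    def test_n_heavy_windows_skipped(self):
        g = GenomeSequence("c", "N" * 495 + "ACGTA" + "N" * 500)
        site = CpGSite(chrom="c", pos=496, beta=80)
        windows, skipped = seqdata.extract_windows(g, [site], 100)
        assert windows == [] and skipped == 1


class TestSubsample:
    def test_ratio_preserved(self, balanced_sites):
        sub = seqdata.subsample_sites(balanced_sites, 30, seed=1)
        n_meth = sum(s.label == METHYLATED for s in sub)
        assert len(sub) == 30
        assert abs(n_meth - 15) <= 1

    def test_identity_when_n_equals_total(self, balanced_sites):
        sub = seqdata.subsample_sites(balanced_sites, len(balanced_sites), seed=0)
        assert sorted((s.chrom, s.pos) for s in sub) == sorted(
            (s.chrom, s.pos) for s in balanced_sites
        )

    def test_deterministic(self, balanced_sites):
        a = seqdata.subsample_sites(balanced_sites, 20, seed=5)
        b = seqdata.subsample_sites(balanced_sites, 20, seed=5)
        assert [(s.pos) for s in a] == [(s.pos) for s in b]

    def test_too_many_requested(self, balanced_sites):
        with pytest.raises(ValueError):
            seqdata.subsample_sites(balanced_sites, 61, seed=0)


class TestSplit:
    def test_paper_sizes_at_5000(self):
        tr, te, va = seqdata.split_dataset(5000, SplitSpec(seed=0))
        assert (len(tr), len(te), len(va)) == (3500, 1000, 500)

    def test_floor_rule_small_n(self):
        tr, te, va = seqdata.split_dataset(10, SplitSpec(seed=0))
        assert (len(tr), len(te), len(va)) == (7, 2, 1)

    @given(st.integers(min_value=3, max_value=500), st.integers(0, 2**20))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_partition_property(self, n, seed):
        tr, te, va = seqdata.split_dataset(n, SplitSpec(seed=seed))
        combined = np.concatenate([tr, te, va])
        assert len(combined) == n
        assert set(combined.tolist()) == set(range(n))

    def test_seed_determinism(self):
        a = seqdata.split_dataset(100, SplitSpec(seed=9))
        b = seqdata.split_dataset(100, SplitSpec(seed=9))
        for x, y in zip(a, b):
            assert (x == y).all()

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))

    def test_split_manifest_round_trip(self, tmp_path):
        import pandas as pd

        ids = [f"chr1:{i}" for i in range(10)]
        splits = seqdata.split_dataset(10, SplitSpec(seed=3))
        seqdata.write_split_manifest(ids, splits, tmp_path / "splits.tsv")
        df = pd.read_csv(tmp_path / "splits.tsv", sep="\t")
        assert list(df["site_id"]) == ids
        assert (df["split"] == "train").sum() == 7
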