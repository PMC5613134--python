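import numpy as np
import pandas as pd
import pytest

from hybridgs.genotypes import (
    FactorialDesign,
    PathwayAnnotation,
    collapse_redundant,
    filter_polymorphic,
    infer_hybrid_genotypes,
    read_design_csv,
    read_parents_vcf,
    read_pathway_bed,
    select_pathway_snps,
)
from hybridgs.synthetic_data import write_study

from conftest import make_panel


class TestFilterPolymorphic:
    def test_rule_on_hand_cases(self):
        # loci: 0 monomorphic everywhere, 1 segregates only in females,
        # 2 segregates in both, 3 monomorphic-1 everywhere
        f = make_panel([[0, 0, 0, 1], [0, 1, 1, 1]], "female")
        m = make_panel([[0, 1, 0, 1], [0, 1, 1, 1]], "male", prefix="M")
        np.testing.assert_array_equal(
            filter_polymorphic(f, m), [False, True, True, False]
        )
        np.testing.assert_array_equal(
            filter_polymorphic(f, m, mode="both"), [False, False, True, False]
        )

    def test_all_polymorphic_keeps_everything(self):
        f = make_panel([[0, 1], [1, 0]], "female")
        m = make_panel([[1, 0], [0, 1]], "male", prefix="M")
        assert filter_polymorphic(f, m).all()

    def test_mismatched_loci_name_first_discordant(self):
        f = make_panel([[0, 1], [1, 0]], "female")
        m = make_panel([[0, 1], [1, 0]], "male", prefix="M")
        m.loci.loc[1, "pos"] = 999
        with pytest.raises(ValueError, match="locus index 1"):
            filter_polymorphic(f, m)


class TestCollapseRedundant:
    def test_duplicate_and_complement_group_together(self):
        # col0 == col1, col2 == 1 - col0, col3 independent
        cols = np.array([[0, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 1]])
        f = make_panel(cols[:2], "female")
        m = make_panel(cols[2:], "male", prefix="M")
        mask, groups = collapse_redundant(f, m)
        np.testing.assert_array_equal(mask, [True, False, False, True])
        assert groups["s1"] == "s0" and groups["s2"] == "s0" and groups["s3"] == "s3"

    def test_distinct_columns_all_kept(self):
        f = make_panel([[0, 0, 1], [1, 0, 1]], "female")
        m = make_panel([[0, 1, 1], [1, 1, 0]], "male", prefix="M")
        mask, groups = collapse_redundant(f, m)
        assert mask.all()
        assert all(groups[k] == k for k in groups)

    def test_grouping_is_an_equivalence_relation(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 2, size=(8, 30))
        # plant chained duplicates/complements: 3 copies of column 0
        base[:, 10] = base[:, 0]
        base[:, 20] = 1 - base[:, 10]
        f = make_panel(base[:4], "female")
        m = make_panel(base[4:], "male", prefix="M")
        _, groups = collapse_redundant(f, m)
        # transitivity: member -> referent -> referent is stable
        for member, ref in groups.items():
            assert groups[ref] == ref
        assert groups["s10"] == groups["s20"] == groups["s0"]

    def test_filter_then_collapse_idempotent(self, small_study):
        f, m = small_study.females, small_study.males
        keep = filter_polymorphic(f, m)
        f1, m1 = f.subset_loci(keep), m.subset_loci(keep)
        mask, _ = collapse_redundant(f1, m1)
        f2, m2 = f1.subset_loci(mask), m1.subset_loci(mask)
        assert filter_polymorphic(f2, m2).all()
        mask2, _ = collapse_redundant(f2, m2)
        assert mask2.all()

    def test_empty_locus_set_errors(self):
        f = make_panel(np.zeros((2, 1), dtype=np.int8), "female")
        m = make_panel(np.zeros((2, 1), dtype=np.int8), "male", prefix="M")
        with pytest.raises(ValueError, match="empty"):
            collapse_redundant(f.subset_loci([False]), m.subset_loci([False]))


class TestInferHybridGenotypes:
    def _toy(self):
        f = make_panel([[0, 1, 1], [1, 0, 1]], "female", prefix="F")
        m = make_panel([[1, 1, 0], [0, 0, 1]], "male", prefix="M")
        crosses = pd.DataFrame(
            {
                "hybrid_id": ["F1xM1", "F1xM2", "F2xM1", "F2xM2"],
                "female_id": ["F1", "F1", "F2", "F2"],
                "male_id": ["M1", "M2", "M1", "M2"],
            }
        )
        design = FactorialDesign(crosses, pd.DataFrame({"E1": [True] * 4}))
        return f, m, design

    def test_hand_enumeration(self):
        f, m, design = self._toy()
        hyb = infer_hybrid_genotypes(design, f, m)
        np.testing.assert_array_equal(hyb["F1xM1"], [[0, 1], [1, 1], [1, 0]])
        np.testing.assert_array_equal(hyb["F2xM2"], [[1, 0], [0, 0], [1, 1]])

    def test_heterozygosity_equals_parent_hamming_distance(self):
        f, m, design = self._toy()
        hyb = infer_hybrid_genotypes(design, f, m)
        for hid, fid, mid in design.crosses.itertuples(index=False):
            fa = f.alleles[f.parent_ids.index(fid)]
            ma = m.alleles[m.parent_ids.index(mid)]
            het = (hyb[hid][:, 0] != hyb[hid][:, 1]).sum()
            assert het == (fa != ma).sum()

    def test_unknown_parent_errors(self):
        f, m, design = self._toy()
        design.crosses.loc[0, "female_id"] = "F9"
        with pytest.raises(KeyError, match="F9"):
            infer_hybrid_genotypes(design, f, m)


class TestSelectPathwaySnps:
    def test_window_boundary_arithmetic(self):
        loci = pd.DataFrame(
            {"chrom": ["Chr01"] * 3, "pos": [3999, 4000, 7000], "id": ["a", "b", "c"]}
        )
        ann = PathwayAnnotation(
            genes=pd.DataFrame(
                {"chrom": ["Chr01"], "start": [5000], "end": [6000], "id": ["g1"]}
            ),
            window=1000,
        )
        np.testing.assert_array_equal(
            select_pathway_snps(loci, ann), [False, True, True]
        )

    def test_zero_window_includes_gene_start(self):
        loci = pd.DataFrame({"chrom": ["Chr01"], "pos": [5000], "id": ["a"]})
        ann = PathwayAnnotation(
            genes=pd.DataFrame(
                {"chrom": ["Chr01"], "start": [5000], "end": [6000], "id": ["g1"]}
            ),
            window=0,
        )
        assert select_pathway_snps(loci, ann).all()

    def test_empty_result_warns(self):
        loci = pd.DataFrame({"chrom": ["Chr02"], "pos": [5000], "id": ["a"]})
        ann = PathwayAnnotation(
            genes=pd.DataFrame(
                {"chrom": ["Chr01"], "start": [5000], "end": [6000], "id": ["g1"]}
            ),
            window=0,
        )
        with pytest.warns(UserWarning, match="no SNPs"):
            mask = select_pathway_snps(loci, ann)
        assert not mask.any()


class TestFileRoundTrips:
    def test_vcf_design_bed_round_trip(self, small_study, tmp_path):
        paths = write_study(small_study, tmp_path)
        females = read_parents_vcf(str(paths["females_vcf"]), "female")
        assert females.parent_ids == small_study.females.parent_ids
        np.testing.assert_array_equal(females.alleles, small_study.females.alleles)
        pd.testing.assert_frame_equal(
            females.loci.astype({"pos": int}), small_study.females.loci.astype({"pos": int})
        )

        design = read_design_csv(str(paths["design_csv"]))
        pd.testing.assert_frame_equal(design.crosses, small_study.design.crosses)
        assert design.is_connected()

        ann = read_pathway_bed(str(paths["pathway_bed"]), window=1000)
        got = ann.genes[["chrom", "start", "end", "id"]].reset_index(drop=True)
        want = small_study.pathway.genes[["chrom", "start", "end", "id"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(got.astype({"start": int, "end": int}),
                                      want.astype({"start": int, "end": int}))

    def test_heterozygous_parent_call_rejected(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=Chr01,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "Chr01\t10\ts1\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        with pytest.raises(ValueError, match="heterozygous"):
            read_parents_vcf(str(vcf), "female")
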