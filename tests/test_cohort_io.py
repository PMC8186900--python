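import numpy as np
import pandas as pd
import pytest

import panelburden as pb
from panelburden.cohort import MISSING, VariantSite


class TestReadGenotypes:
    def test_dosage_is_alt_allele_count(self, make_vcf):
        path = make_vcf(["s1", "s2", "s3"], [("1", 100, "A", "G", ["0/0", "0/1", "1/1"])])
        G = pb.read_genotypes(path)
        assert G.samples == ["s1", "s2", "s3"]
        assert G.dosage.tolist() == [[0], [1], [2]]

    @pytest.mark.parametrize(
        "gt,expected",
        [("./.", MISSING), ("0/.", MISSING), ("./1", MISSING), ("0|1", 1), ("1|1", 2)],
    )
    def test_missing_and_phased_conventions(self, make_vcf, gt, expected):
        path = make_vcf(["s1"], [("1", 100, "A", "G", [gt])], name=f"{hash(gt) % 997}.vcf")
        assert pb.read_genotypes(path).dosage[0, 0] == expected

    def test_multiallelic_record_kept_with_alt_count(self, make_vcf):
        path = make_vcf(["s1"], [("1", 100, "A", "G,T", ["0/1"])])
        G = pb.read_genotypes(path)
        assert G.sites[0].n_alt_alleles == 2
        assert G.sites[0].site_id == "1:100:A:G"  # first alt keys the site

    def test_sample_filter_restricts_and_keeps_header_order(self, make_vcf):
        records = [("1", 100, "A", "G", ["0/0", "0/1", "1/1"])]
        path = make_vcf(["s1", "s2", "s3"], records)
        G = pb.read_genotypes(path, sample_filter=["s3", "s1"])  # order from header
        assert G.samples == ["s1", "s3"]
        assert G.dosage.tolist() == [[0], [2]]

    def test_column_permutation_invariance(self, make_vcf):
        """Permuting VCF sample columns (with matching filter) gives the
        identical GenotypeMatrix."""
        a = make_vcf(["s1", "s2", "s3"], [("1", 100, "A", "G", ["0/0", "0/1", "1/1"])], "a.vcf")
        b = make_vcf(["s2", "s3", "s1"], [("1", 100, "A", "G", ["0/1", "1/1", "0/0"])], "b.vcf")
        Ga = pb.read_genotypes(a, sample_filter=["s1", "s2", "s3"])
        Gb = pb.read_genotypes(b, sample_filter=["s1", "s2", "s3"])
        # identical modulo sample ordering
        ia = np.argsort(Ga.samples)
        ib = np.argsort(Gb.samples)
        assert [Ga.samples[i] for i in ia] == [Gb.samples[i] for i in ib]
        assert np.array_equal(Ga.dosage[ia], Gb.dosage[ib])

    def test_errors(self, make_vcf, tmp_path):
        with pytest.raises(FileNotFoundError):
            pb.read_genotypes(tmp_path / "absent.vcf")
        path = make_vcf(["s1"], [("1", 100, "A", "G", ["0/1"])])
        with pytest.raises(KeyError, match="absent from VCF header"):
            pb.read_genotypes(path, sample_filter=["nope"])


class TestVariantSite:
    def test_invalid_alleles_and_positions_rejected(self):
        with pytest.raises(ValueError):
            VariantSite("1", 0, "A", ("G",))
        with pytest.raises(ValueError):
            VariantSite("1", 10, "AX", ("G",))
        with pytest.raises(ValueError):
            VariantSite("1", 10, "A", ("",))


class TestReadAnnotations:
    def _write(self, tmp_path, rows, columns=None):
        columns = columns or ["site_id", "Gene", "Func", "ExonicFunc", "ExAC_ALL",
                              "Polyphen2", "SIFT", "MutationTaster"]
        path = tmp_path / "ann.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    def test_full_row_parsed(self, tmp_path):
        path = self._write(tmp_path, [["1:100:A:G", "GENE1", "exonic", "nonsynonymous SNV",
                                       "0.0005", "0.998", "0.001", "D"]])
        (v,) = pb.read_annotations(path)
        assert (v.gene, v.func_region, v.exac_af) == ("GENE1", "exonic", 0.0005)
        assert (v.polyphen2, v.sift, v.mutation_taster) == (0.998, 0.001, "D")

    def test_dot_scores_become_unknown(self, tmp_path):
        path = self._write(tmp_path, [["1:100:A:G", "GENE1", "exonic", "nonsynonymous SNV",
                                       ".", ".", ".", "."]])
        (v,) = pb.read_annotations(path)
        assert v.exac_af is None and v.polyphen2 is None and v.sift is None
        assert v.mutation_taster is None

    def test_orphan_rows_flagged_not_dropped(self, tmp_path):
        path = self._write(tmp_path, [["1:100:A:G", "G1", "exonic", "nonsynonymous SNV",
                                       "0.001", "0.99", "0.01", "D"],
                                      ["1:200:C:T", "G1", "exonic", "nonsynonymous SNV",
                                       "0.001", "0.99", "0.01", "D"]])
        anns = pb.read_annotations(path, known_site_ids={"1:100:A:G"})
        assert [a.orphan for a in anns] == [False, True]

    def test_missing_column_and_duplicate_site_errors(self, tmp_path):
        path = self._write(tmp_path, [["1:100:A:G", "G1", "exonic", "x", "0", "0", "0"]],
                           columns=["site_id", "Gene", "Func", "ExonicFunc", "ExAC_ALL",
                                    "Polyphen2", "SIFT"])
        with pytest.raises(ValueError, match="MutationTaster"):
            pb.read_annotations(path)
        dup = self._write(tmp_path, [["1:100:A:G", "G1", "exonic", "x", "0", "0", "0", "D"]] * 2)
        with pytest.raises(ValueError, match="duplicated site_id"):
            pb.read_annotations(dup)


class TestReadPhenotypes:
    def _write(self, tmp_path, rows):
        path = tmp_path / "phen.tsv"
        pd.DataFrame(rows, columns=["sample_id", "group", "subgroup"]).to_csv(
            path, sep="\t", index=False
        )
        return path

    def test_group_and_subgroup_counts(self, tmp_path):
        rows = [[f"c{i}", "case", "ASD" if i < 3 else ""] for i in range(5)]
        rows += [[f"k{i}", "control", ""] for i in range(4)]
        phen = pb.read_phenotypes(self._write(tmp_path, rows))
        assert phen.group_counts() == (5, 4)
        assert len(phen.in_subgroup("ASD")) == 3

    @pytest.mark.parametrize(
        "rows,match",
        [
            ([["s1", "patient", ""]], "unknown group"),
            ([["s1", "case", ""], ["s1", "case", ""]], "duplicate sample"),
            ([["s1", "control", "ASD"]], "subgroup"),
        ],
    )
    def test_invalid_tables_rejected(self, tmp_path, rows, match):
        with pytest.raises(ValueError, match=match):
            pb.read_phenotypes(self._write(tmp_path, rows))


class TestWriteResults:
    def test_round_trip_with_provenance(self, tmp_path):
        df = pd.DataFrame({"gene": ["A", "B"], "p": [0.123456789012345, 1e-12], "n": [1, 2]})
        path = tmp_path / "out.tsv"
        pb.write_results(df, path, provenance={"stage": "test", "seed": 7})
        back = pb.read_results(path)
        pd.testing.assert_frame_equal(back, df)
        assert open(path).readline().startswith("# stage: test")

    def test_empty_table_writes_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["gene", "p"])
        path = tmp_path / "empty.tsv"
        pb.write_results(df, path)
        assert pb.read_results(path).columns.tolist() == ["gene", "p"]
        assert len(pb.read_results(path)) == 0
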