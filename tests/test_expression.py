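import numpy as np
import pandas as pd
import pytest

import ribodelta as rd
from ribodelta.expression import presence_flags

from conftest import random_nb_matrix
from oracles import tmm_factors_oracle


class TestCountMatrixIO:
    def test_round_trip_is_lossless(self, tiny_matrix, tmp_path):
        tiny_matrix.write(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = rd.read_count_matrix(tmp_path / "c.tsv", tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(
            back.counts, tiny_matrix.counts, check_dtype=False, check_names=False
        )
        assert list(back.samples.columns[:3]) == ["condition", "replicate", "assay"]
        assert list(back.counts.columns) == list(tiny_matrix.counts.columns)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        (tmp_path / "c.tsv").write_text("gene_id\ts1\ng1\t3\ng1\t4\n")
        (tmp_path / "m.tsv").write_text("sample\tcondition\treplicate\tassay\ns1\tA\t1\tRNA\n")
        with pytest.raises(ValueError, match="g1"):
            rd.read_count_matrix(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_non_integer_count_names_cell(self, tmp_path):
        (tmp_path / "c.tsv").write_text("gene_id\ts1\ng1\t3.5\n")
        (tmp_path / "m.tsv").write_text("sample\tcondition\treplicate\tassay\ns1\tA\t1\tRNA\n")
        with pytest.raises(ValueError, match="g1"):
            rd.read_count_matrix(tmp_path / "c.tsv", tmp_path / "m.tsv")

    def test_simulator_output_round_trips(self, small_sim, tmp_path):
        _, rna, _, _ = small_sim
        rna.write(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = rd.read_count_matrix(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert (back.counts.to_numpy() == rna.counts.to_numpy()).all()


class TestCpmRpkm:
    def test_cpm_arithmetic(self, tiny_matrix):
        c = rd.cpm(tiny_matrix)
        assert c.loc["g1", "s1"] == pytest.approx(5 / 112 * 1e6)
        assert (c.loc["g2"] == 0).all()

    def test_cpm_columns_sum_to_one_million(self, tiny_matrix):
        assert rd.cpm(tiny_matrix).sum(axis=0).to_numpy() == pytest.approx([1e6, 1e6])

    def test_rpkm_formula_and_scaling(self, tiny_matrix):
        r = rd.rpkm(tiny_matrix)
        c = rd.cpm(tiny_matrix)
        expected = c.div(tiny_matrix.gene_lengths / 1e3, axis=0)
        pd.testing.assert_frame_equal(r, expected)
        # doubling a gene's length halves its RPKM
        longer = rd.CountMatrix(
            tiny_matrix.counts, tiny_matrix.samples, tiny_matrix.gene_lengths * 2
        )
        pd.testing.assert_frame_equal(rd.rpkm(longer), r / 2)

    def test_rpkm_requires_lengths(self, tiny_matrix):
        no_len = rd.CountMatrix(tiny_matrix.counts, tiny_matrix.samples)
        with pytest.raises(ValueError, match="length"):
            rd.rpkm(no_len)


class TestExpressionFilter:
    def _matrix(self, cpm_rows):
        # two conditions x 3 replicates, library size 1e6 so CPM == count
        counts = pd.DataFrame(
            cpm_rows,
            index=[f"g{i}" for i in range(len(cpm_rows))],
            columns=[f"{c}_r{r}" for c in "AB" for r in (1, 2, 3)],
        )
        filler = int(1e6) - counts.sum(axis=0).max()
        counts.loc["filler"] = [int(1e6) - s for s in counts.sum(axis=0)]
        samples = pd.DataFrame(
            {
                "condition": ["A"] * 3 + ["B"] * 3,
                "replicate": [1, 2, 3] * 2,
                "assay": ["RNA"] * 6,
            },
            index=counts.columns,
        )
        return rd.CountMatrix(counts=counts, samples=samples)

    def test_detected_in_all_replicates_of_one_condition_is_kept(self):
        m = self._matrix([[2, 2, 2, 0, 0, 0]])
        mask, det = rd.filter_expressed(m, 1.0)
        assert mask["g0"]
        assert det.loc["g0", "A"] and not det.loc["g0", "B"]

    def test_one_low_replicate_everywhere_removes_gene(self):
        m = self._matrix([[2, 2, 0, 2, 2, 0]])
        mask, _ = rd.filter_expressed(m, 1.0)
        assert not mask["g0"]

    def test_all_conditions_scope_is_stricter(self):
        m = self._matrix([[2, 2, 2, 0, 0, 0], [2, 2, 2, 3, 3, 3]])
        any_mask, _ = rd.filter_expressed(m, 1.0, scope="any_condition")
        all_mask, _ = rd.filter_expressed(m, 1.0, scope="all_conditions")
        assert any_mask["g0"] and not all_mask["g0"]
        assert any_mask["g1"] and all_mask["g1"]

    def test_zero_threshold_keeps_any_nonzero_gene(self, small_sim):
        _, rna, _, _ = small_sim
        mask, _ = rd.filter_expressed(rna, 0.0)
        has_signal = (rna.counts > 0).any(axis=1)
        # threshold 0 keeps every gene: CPM >= 0 holds even at zero counts
        assert mask.all() or (mask == has_signal).all()

    def test_matches_brute_force_rule(self, small_sim):
        _, rna, _, _ = small_sim
        mask, _ = rd.filter_expressed(rna, 1.0)
        c = rna.counts / rna.counts.sum(axis=0) * 1e6
        expected = np.zeros(len(rna.gene_ids), dtype=bool)
        for cond in rna.conditions:
            cols = rna.condition_samples(cond)
            expected |= (c[cols] >= 1.0).all(axis=1).to_numpy()
        assert (mask.to_numpy() == expected).all()

    def test_negative_threshold_rejected(self, small_sim):
        _, rna, _, _ = small_sim
        with pytest.raises(ValueError):
            rd.filter_expressed(rna, -0.5)


class TestPresenceFlags:
    @pytest.mark.parametrize(
        "rpkms, present",
        [((1.5, 1.2, 3.0), True), ((1.5, 0.9, 3.0), False)],
    )
    def test_rule_application(self, rpkms, present):
        r = pd.DataFrame([rpkms], index=["g"], columns=["a1", "a2", "a3"])
        samples = pd.DataFrame(
            {"condition": ["A"] * 3, "replicate": [1, 2, 3], "assay": ["RNA"] * 3},
            index=r.columns,
        )
        assert presence_flags(r, samples).loc["g", "A"] == present

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(3)
        r = pd.DataFrame(
            rng.exponential(2.0, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        )
        samples = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3, "replicate": [1, 2, 3] * 2,
             "assay": ["RNA"] * 6},
            index=r.columns,
        )
        flags = presence_flags(r, samples)
        for g in r.index:
            assert flags.loc[g, "A"] == all(r.loc[g, f"s{j}"] > 1 for j in range(3))
            assert flags.loc[g, "B"] == all(r.loc[g, f"s{j}"] > 1 for j in range(3, 6))


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]},
                              index=["g1", "g2", "g3"])
        samples = pd.DataFrame(
            {"condition": ["A", "A"], "replicate": [1, 2], "assay": ["RNA"] * 2},
            index=counts.columns,
        )
        norm = rd.tmm_normalize(rd.CountMatrix(counts, samples))
        assert norm.factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_uniform_scaling_gives_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30, 40], "s2": [30, 60, 90, 120]},
                              index=list("abcd"))
        samples = pd.DataFrame(
            {"condition": ["A", "A"], "replicate": [1, 2], "assay": ["RNA"] * 2},
            index=counts.columns,
        )
        norm = rd.tmm_normalize(rd.CountMatrix(counts, samples))
        assert norm.factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        m = random_nb_matrix(rng)
        norm = rd.tmm_normalize(m)
        expected = tmm_factors_oracle(m.counts.to_numpy())
        assert norm.factors.to_numpy() == pytest.approx(expected, abs=1e-8)

    def test_geometric_mean_is_one(self, small_sim):
        _, rna, _, _ = small_sim
        norm = rd.tmm_normalize(rna)
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(23)
        m = random_nb_matrix(rng, n_genes=150)
        perm = rng.permutation(m.counts.index)
        shuffled = rd.CountMatrix(m.counts.loc[perm], m.samples.copy())
        f1 = rd.tmm_normalize(m).factors
        f2 = rd.tmm_normalize(shuffled).factors
        assert f1.to_numpy() == pytest.approx(f2.to_numpy(), abs=1e-12)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["g1", "g2"])
        samples = pd.DataFrame(
            {"condition": ["A", "A"], "replicate": [1, 2], "assay": ["RNA"] * 2},
            index=counts.columns,
        )
        with pytest.raises(ValueError, match="s2"):
            rd.tmm_normalize(rd.CountMatrix(counts, samples))

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Cross-check against the reference R implementation (edgeR)."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(41)
        m = random_nb_matrix(rng, n_genes=300)
        csv = tmp_path / "counts.csv"
        m.counts.to_csv(csv)
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.csv("{csv}", row.names=1))\n'
            'f <- calcNormFactors(x, method="TMM")\n'
            'cat(sprintf("%.12f", f), sep="\\n")\n'
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        expected = np.array([float(v) for v in proc.stdout.split()])
        ours = rd.tmm_normalize(m).factors.to_numpy()
        assert ours == pytest.approx(expected, abs=1e-6)
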