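"""Genotype QC chain, conflict detection, imputation, ledger accounting."""

import numpy as np
import pandas as pd
import pytest

import stepblup as sb
from stepblup.core import ValidationError
from stepblup.qc import QCReport, QCStep, remove_animals


def make_panel(dosages, chroms=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_map = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
        }
    )
    return sb.GenotypePanel(dosages, tuple(f"a{i}" for i in range(n)), snp_map)


class TestAnimalMissingness:
    def test_strictly_greater_removed_exactly_at_threshold_kept(self):
        nan = np.nan
        d = np.zeros((3, 100))
        d[1, :10] = nan   # exactly 10% -> kept ("more than" is strict)
        d[2, :11] = nan   # 11% -> removed
        panel = make_panel(d)
        out, report = sb.filter_animals_missingness(panel, 0.10)
        assert out.animal_ids == ("a0", "a1")
        step = report.steps[-1]
        assert (step.n_removed, step.n_remaining) == (1, 2)

    def test_planted_missingness_recovered(self, rng):
        d = rng.integers(0, 3, size=(30, 200)).astype(float)
        bad = {3, 17, 28}
        for i in bad:
            idx = rng.choice(200, size=60, replace=False)  # 30% missing
            d[i, idx] = np.nan
        panel = make_panel(d)
        out, _ = sb.filter_animals_missingness(panel, 0.10)
        removed = set(panel.animal_ids) - set(out.animal_ids)
        assert removed == {f"a{i}" for i in bad}

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            sb.filter_animals_missingness(
                make_panel(np.zeros((0, 5)).reshape(0, 5)), 0.1
            )


class TestSnpFilters:
    def test_low_maf_removed(self):
        # p = 0.005 across 100 animals: one heterozygote
        d = np.zeros((100, 2))
        d[0, 0] = 1.0
        d[:50, 1] = 1.0  # healthy SNP p=0.25
        out, _ = sb.filter_snps(make_panel(d), maf_min=0.01)
        assert list(out.snp_map["snp"]) == ["s1"]

    def test_het_excess_removed(self):
        # p=0.5 with 90% heterozygotes: |0.9 - 0.5| = 0.4 > 0.15
        d = np.ones((100, 2))
        d[:5, 0], d[5:10, 0] = 0.0, 2.0  # 90 hets
        d[:25, 1], d[25:50, 1] = 0.0, 2.0  # 50 hets at p=0.5 -> dev 0
        out, _ = sb.filter_snps(make_panel(d))
        assert list(out.snp_map["snp"]) == ["s1"]

    def test_unknown_position_and_sex_chromosomes_dropped(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], (4, 1)).T.reshape(4, 4)
        d = np.ones((10, 4))
        d[:3] = 0.0
        d[3:6] = 2.0
        panel = make_panel(d, chroms=["1", "X", "5", "3"],
                           pos=[100, 200, 0, 400])
        out, report = sb.filter_snps(panel, het_dev_max=0.99, maf_min=0.01)
        assert list(out.snp_map["snp"]) == ["s0", "s3"]
        names = [s.name for s in report.steps if s.scope == "snps"]
        assert names == ["input", "unknown_position", "sex_chromosomes",
                         "call_rate", "maf", "het_departure"]

    def test_call_rate_strict(self):
        d = np.ones((100, 2))
        d[:2, 0] = np.nan   # call rate 0.98 exactly -> kept
        d[:3, 1] = np.nan   # 0.97 -> removed
        d[10:40, :] = 0.0
        out, _ = sb.filter_snps(make_panel(d), call_rate_min=0.98,
                                het_dev_max=0.99)
        assert list(out.snp_map["snp"]) == ["s0"]

    def test_order_matters_maf_computed_after_call_rate(self):
        # SNP fails call rate; if MAF ran first on it nothing else changes,
        # but the ledger must attribute the removal to call_rate.
        d = np.ones((100, 1))
        d[:50, 0] = 0.0
        d[:5, 0] = np.nan
        out, report = sb.filter_snps(make_panel(d), call_rate_min=0.98,
                                     het_dev_max=0.99)
        by_name = {s.name: s for s in report.steps}
        assert by_name["call_rate"].n_removed == 1
        assert by_name["maf"].n_removed == 0


class TestQCReportAccounting:
    def test_study_scale_ledger_arithmetic(self):
        """Feeding the published per-step SNP removal counts through the
        report reproduces the retained total: 45304 - 302 - 1150 - 2677
        - 6684 - 31 = 34460."""
        report = QCReport()
        report.add(QCStep("snps", "input", 0, 45304))
        removals = [
            ("unknown_position", 302),
            ("sex_chromosomes", 1150),
            ("call_rate", 2677),
            ("maf", 6684),
            ("het_departure", 31),
        ]
        n = 45304
        for name, r in removals:
            n -= r
            report.add(QCStep("snps", name, r, n))
        assert report.last_remaining("snps") == 34460

    def test_inconsistent_step_rejected(self):
        report = QCReport()
        report.add(QCStep("snps", "input", 0, 100))
        with pytest.raises(ValidationError, match="accounting"):
            report.add(QCStep("snps", "maf", 5, 96))

    def test_counts_non_increasing_through_filter_chain(self, rng):
        d = rng.integers(0, 3, size=(40, 300)).astype(float)
        d[rng.random(d.shape) < 0.05] = np.nan
        panel = make_panel(d, chroms=[str(1 + j % 30) for j in range(300)])
        panel, report = sb.filter_animals_missingness(panel, 0.10)
        panel, report = sb.filter_snps(panel, report=report)
        for scope in ("animals", "snps"):
            remaining = [s.n_remaining for s in report.steps if s.scope == scope]
            assert all(a >= b for a, b in zip(remaining, remaining[1:]))
        assert report.last_remaining("snps") == panel.n_snps
        assert report.last_remaining("animals") == panel.n_animals

    def test_named_animal_removal_steps_account(self):
        d = np.ones((5, 10))
        d[:, :5] = 0.0
        panel = make_panel(d)
        panel, report = remove_animals(panel, ["a1", "a3"], "mendelian_conflicts")
        assert panel.n_animals == 3
        assert report.steps[-1].n_removed == 2


class TestMendelianConflicts:
    def test_identical_genotypes_zero_rate(self):
        d = np.tile(np.array([0.0, 1, 2, 1, 0]), (2, 1))
        panel = make_panel(d.reshape(2, 5))
        out = sb.mendelian_conflict_rate(panel, [("a0", "a1")])
        assert out["conflict_rate"].iloc[0] == 0.0
        assert not out["flagged"].iloc[0]

    def test_fully_opposing_homozygotes_rate_one(self):
        d = np.vstack([np.zeros(8), np.full(8, 2.0)])
        out = sb.mendelian_conflict_rate(make_panel(d), [("a0", "a1")])
        assert out["conflict_rate"].iloc[0] == 1.0
        assert out["flagged"].iloc[0]

    def test_no_informative_snps_gives_sentinel(self):
        d = np.array([[np.nan, 1.0], [1.0, np.nan]])
        out = sb.mendelian_conflict_rate(make_panel(d), [("a0", "a1")])
        assert np.isnan(out["conflict_rate"].iloc[0])
        assert out["flagged"].iloc[0]

    def test_true_trio_with_genotyping_error_stays_below_threshold(self, rng):
        m = 5000
        p = rng.uniform(0.1, 0.9, size=m)
        sire = rng.binomial(2, p).astype(float)
        # offspring inherits one sire allele, one population allele
        off = rng.binomial(1, sire / 2.0) + rng.binomial(1, p)
        err = rng.random(m) < 0.01
        off = off.astype(float)
        off[err] = rng.binomial(2, p[err])
        snp_map = pd.DataFrame({"snp": [f"s{j}" for j in range(m)],
                                "chrom": "1", "pos": np.arange(m) + 1})
        panel = sb.GenotypePanel(np.vstack([sire, off]), ("S", "O"), snp_map)
        out = sb.mendelian_conflict_rate(panel, [("S", "O")])
        rate = out["conflict_rate"].iloc[0]
        assert 0.0 < rate < 0.02  # ~1% errors rarely create opposing homozygotes
        assert not out["flagged"].iloc[0]


class TestPedigreeGenomicConflicts:
    def _mats(self, g, a, ids=("x", "y", "z")):
        G = sb.RelationshipMatrix(np.array(g), ids, "G")
        A = sb.RelationshipMatrix(np.array(a), ids, "A22")
        return G, A

    def test_duplicate_detected(self):
        G, A = self._mats(
            [[1.0, 0.99, 0.0], [0.99, 1.0, 0.0], [0.0, 0.0, 1.0]],
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
        )
        out = sb.detect_pedigree_genomic_conflicts(G, A)
        assert out["class"].tolist() == ["duplicate"]
        assert set(out.loc[0, ["id1", "id2"]]) == {"x", "y"}

    def test_false_relative_detected(self):
        G, A = self._mats(
            [[1.0, 0.01, 0.0], [0.01, 1.0, 0.0], [0.0, 0.0, 1.0]],
            [[1.0, 0.25, 0.0], [0.25, 1.0, 0.0], [0.0, 0.0, 1.0]],
        )
        out = sb.detect_pedigree_genomic_conflicts(G, A)
        assert out["class"].tolist() == ["false_relative"]

    def test_missed_relative_detected(self):
        G, A = self._mats(
            [[1.0, 0.26, 0.0], [0.26, 1.0, 0.0], [0.0, 0.0, 1.0]],
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
        )
        out = sb.detect_pedigree_genomic_conflicts(G, A)
        assert out["class"].tolist() == ["missed_relative"]

    def test_identical_matrices_no_conflicts(self, rng):
        ped = sb.parse_pedigree(
            [("s", None, None), ("d", None, None), ("o", "s", "d")]
        )
        A = sb.build_A(ped)
        G = sb.RelationshipMatrix(A.values.copy(), A.ids, "G")
        A22 = sb.RelationshipMatrix(A.values.copy(), A.ids, "A22")
        assert sb.detect_pedigree_genomic_conflicts(G, A22).empty

    def test_symmetric_in_pair_order(self):
        G, A = self._mats(
            [[1.0, 0.95, 0.3], [0.95, 1.0, 0.0], [0.3, 0.0, 1.0]],
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.2], [0.0, 0.2, 1.0]],
        )
        out1 = sb.detect_pedigree_genomic_conflicts(G, A)
        # reverse the id order of both matrices together
        ids_r = tuple(reversed(G.ids))
        Gr = G.submatrix(ids_r)
        Ar = A.submatrix(ids_r)
        out2 = sb.detect_pedigree_genomic_conflicts(Gr, Ar)
        key = lambda df: {
            frozenset((row["id1"], row["id2"])): row["class"]
            for _, row in df.iterrows()
        }
        assert key(out1) == key(out2)

    def test_mismatched_ids_rejected(self):
        G = sb.RelationshipMatrix(np.eye(2), ("a", "b"), "G")
        A = sb.RelationshipMatrix(np.eye(2), ("b", "a"), "A22")
        with pytest.raises(sb.AlignmentError):
            sb.detect_pedigree_genomic_conflicts(G, A)


class TestImputation:
    def test_no_missing_unchanged(self):
        panel = make_panel(np.array([[0.0, 1], [2, 1]]))
        out = sb.impute_missing(panel)
        np.testing.assert_array_equal(out.dosages, panel.dosages)

    def test_half_frequency_snp_imputes_to_one(self):
        d = np.array([[0.0, 1.0], [2.0, 1.0], [np.nan, 1.0], [2.0, np.nan]])
        out = sb.impute_missing(make_panel(d))
        # SNP 0: observed mean (0+2+2)/3 = 4/3; SNP 1: mean 1.0
        assert out.dosages[2, 0] == pytest.approx(4.0 / 3.0)
        assert out.dosages[3, 1] == pytest.approx(1.0)
        assert not np.isnan(out.dosages).any()

    def test_mcar_imputation_preserves_snp_means(self, rng):
        d = rng.integers(0, 3, size=(200, 50)).astype(float)
        mask = rng.random(d.shape) < 0.02
        dm = d.copy()
        dm[mask] = np.nan
        out = sb.impute_missing(make_panel(dm))
        observed_mean = np.nanmean(dm, axis=0)
        np.testing.assert_allclose(out.dosages.mean(axis=0), observed_mean,
                                   atol=1e-12)

    def test_all_missing_snp_is_error(self):
        d = np.array([[np.nan, 1.0], [np.nan, 0.0]])
        with pytest.raises(ValidationError, match="no observed calls"):
            sb.impute_missing(make_panel(d))
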