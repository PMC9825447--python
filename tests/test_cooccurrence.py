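import numpy as np
import pandas as pd
import pytest

from metabrepo import (
    BinaryProfile,
    FilterPredicateSet,
    Polarity,
    SampleTable,
    Spectrum,
    as_repository,
    binarize_peak_matrix,
    find_copartitioned_pairs,
    flavonoid_candidate_filter,
    generate_profile_dataset,
    load_gene_profiles,
    profile_similarity,
)
from metabrepo.alignment import PeakMatrix
from metabrepo.core import MetabRepoError
from .conftest import make_peak

SPECIES = ("sp1", "sp2", "sp3", "sp4")


def profile(eid, vec, kind="metabolite", species=SPECIES):
    return BinaryProfile(eid, kind, species, np.array(vec, dtype=np.uint8))


def matrix_from(rows, samples):
    return PeakMatrix(pd.DataFrame(rows, index=[f"T{i}" for i in range(len(rows))],
                                   columns=samples))


class TestBinarize:
    species_of = {"a1": "spA", "a2": "spA", "b1": "spB", "c1": "spC"}

    def test_single_species_presence(self):
        m = matrix_from([[1.0, np.nan, np.nan, np.nan]], ["a1", "a2", "b1", "c1"])
        prof = binarize_peak_matrix(m, self.species_of)[0]
        assert prof.species == ("spA", "spB", "spC")
        assert prof.vector.tolist() == [1, 0, 0]

    def test_replicates_collapse_to_one_species(self):
        m = matrix_from([[2.0, 3.0, np.nan, np.nan]], ["a1", "a2", "b1", "c1"])
        prof = binarize_peak_matrix(m, self.species_of)[0]
        assert prof.vector.tolist() == [1, 0, 0]

    def test_everywhere_gives_all_ones(self):
        m = matrix_from([[1.0, 1.0, 1.0, 1.0]], ["a1", "a2", "b1", "c1"])
        assert binarize_peak_matrix(m, self.species_of)[0].vector.tolist() == [1, 1, 1]

    def test_unmapped_sample_is_error(self):
        m = matrix_from([[1.0]], ["zz"])
        with pytest.raises(MetabRepoError, match="zz"):
            binarize_peak_matrix(m, self.species_of)

    def test_idempotent_under_sample_duplication(self):
        m1 = matrix_from([[1.0, np.nan, 5.0, np.nan]], ["a1", "a2", "b1", "c1"])
        m2 = matrix_from([[1.0, 1.0, np.nan, 5.0, np.nan]], ["a1", "a1b", "a2", "b1", "c1"])
        species = dict(self.species_of, a1b="spA")
        v1 = binarize_peak_matrix(m1, self.species_of)[0].vector
        v2 = binarize_peak_matrix(m2, species)[0].vector
        assert v1.tolist() == v2.tolist()


class TestGeneProfiles:
    def test_counts_binarized(self, tmp_path):
        path = tmp_path / "og.tsv"
        path.write_text(
            "Orthogroup\tspA\tspB\tspC\tTotal\n"
            "OG1\t0\t3\t1\t4\n"
            "OG2\t0\t0\t0\t0\n"
        )
        profs = load_gene_profiles(path)
        assert profs[0].species == ("spA", "spB", "spC")  # Total dropped
        assert profs[0].vector.tolist() == [0, 1, 1]
        assert profs[1].vector.tolist() == [0, 0, 0]  # all-zero row retained

    def test_negative_count_located(self, tmp_path):
        path = tmp_path / "og.tsv"
        path.write_text("Orthogroup\tspA\nOG1\t-2\n")
        with pytest.raises(MetabRepoError, match="row 2"):
            load_gene_profiles(path)

    def test_non_numeric_count_located(self, tmp_path):
        path = tmp_path / "og.tsv"
        path.write_text("Orthogroup\tspA\tspB\nOG1\t1\tmany\n")
        with pytest.raises(MetabRepoError, match="spB"):
            load_gene_profiles(path)


class TestSimilarity:
    def test_identical(self):
        p = profile("m", [1, 1, 0, 0])
        q = profile("g", [1, 1, 0, 0], kind="gene")
        assert profile_similarity(p, q, "exact") == 1.0
        assert profile_similarity(p, q, "jaccard") == 1.0
        assert profile_similarity(p, q, "hamming") == 0.0

    def test_disjoint(self):
        p = profile("m", [1, 1, 0, 0])
        q = profile("g", [0, 0, 1, 1])
        assert profile_similarity(p, q, "jaccard") == 0.0
        assert profile_similarity(p, q, "exact") == 0.0

    def test_hand_example(self):
        p = profile("m", [1, 1, 0, 0])
        q = profile("g", [1, 1, 1, 0])
        assert profile_similarity(p, q, "jaccard") == pytest.approx(2 / 3)
        assert profile_similarity(p, q, "hamming") == 1.0

    def test_both_empty_jaccard_zero(self):
        assert profile_similarity(profile("m", [0] * 4), profile("g", [0] * 4)) == 0.0

    def test_species_list_mismatch(self):
        p = profile("m", [1, 0], species=("a", "b"))
        with pytest.raises(MetabRepoError):
            profile_similarity(p, profile("g", [1, 0], species=("x", "y")))

    def test_jaccard_one_iff_hamming_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = profile("m", rng.integers(0, 2, 6), species=tuple("abcdef"))
            q = profile("g", rng.integers(0, 2, 6), species=tuple("abcdef"))
            if p.presence + q.presence == 0:
                continue
            ham0 = profile_similarity(p, q, "hamming") == 0
            jac1 = profile_similarity(p, q, "jaccard") == 1.0
            assert ham0 == jac1


class TestCoPartitionMining:
    def test_planted_pair_ranked_first(self):
        metab, genes, truth = generate_profile_dataset(12, 40, 40, 1, seed=5)
        pairs = find_copartitioned_pairs(metab, genes, max_mismatch=0)
        planted = set(truth.planted_pairs)
        assert (pairs[0].metabolite_id, pairs[0].gene_id) in planted

    def test_no_identical_patterns_empty(self):
        metab = [profile("m", [1, 1, 0, 0])]
        genes = [profile("g", [1, 0, 1, 0], kind="gene")]
        assert find_copartitioned_pairs(metab, genes, max_mismatch=0) == []

    def test_all_ones_excluded_by_presence_bounds(self):
        metab = [profile("m", [1, 1, 1, 1])]
        genes = [profile("g", [1, 1, 1, 1], kind="gene")]
        assert find_copartitioned_pairs(metab, genes, max_mismatch=0) == []

    def test_relaxed_budget_sorted_by_mismatch(self):
        metab = [profile("m", [1, 1, 0, 0, 0, 0], species=tuple("abcdef"))]
        genes = [
            profile("g_exact", [1, 1, 0, 0, 0, 0], "gene", tuple("abcdef")),
            profile("g_near", [1, 1, 1, 0, 0, 0], "gene", tuple("abcdef")),
        ]
        pairs = find_copartitioned_pairs(metab, genes, max_mismatch=1)
        assert [p.gene_id for p in pairs] == ["g_exact", "g_near"]
        assert [p.mismatch for p in pairs] == [0, 1]
        assert pairs[1].jaccard == pytest.approx(2 / 3)

    def test_matches_brute_force_scan(self):
        metab, genes, _ = generate_profile_dataset(10, 60, 60, 3, seed=7)
        got = {
            (p.metabolite_id, p.gene_id)
            for p in find_copartitioned_pairs(metab, genes, max_mismatch=0)
        }
        expected = set()
        n = len(metab[0].species)
        for m in metab:
            if not 2 <= m.presence <= n - 2:
                continue
            for g in genes:
                if not 2 <= g.presence <= n - 2:
                    continue
                if np.array_equal(m.vector, g.vector):
                    expected.add((m.entity_id, g.entity_id))
        assert got == expected


class TestFlavonoidFilter:
    def candidate_peak(self, pid="c", score=0.7, db_hits=0, with_ms3=True):
        spectra = [Spectrum(300.0, 2, [(150.0, 10.0)])]
        if with_ms3:
            spectra.append(Spectrum(150.0, 3, [(77.0, 5.0)]))
        ann = {"db_hit_count": db_hits}
        if score is not None:
            ann["flavonoid_score_ms3"] = score
        return make_peak(pid, 300.0, 10.0, spectra=spectra, annotations=ann)

    def repo_with(self, peaks):
        return as_repository([SampleTable(sample_id="A", peaks=peaks)])

    def test_db_hit_excludes(self):
        repo = self.repo_with([self.candidate_peak("x", db_hits=3)])
        assert flavonoid_candidate_filter(repo) == []

    def test_missing_ms3_excludes(self):
        repo = self.repo_with([self.candidate_peak("x", with_ms3=False)])
        assert flavonoid_candidate_filter(repo) == []

    def test_threshold_inclusive_at_0_500(self):
        # the lowest accepted aglycone-similarity score is exactly 0.500
        repo = self.repo_with([self.candidate_peak("x", score=0.500)])
        assert flavonoid_candidate_filter(repo) == [("A", "x")]
        repo = self.repo_with([self.candidate_peak("y", score=0.499)])
        assert flavonoid_candidate_filter(repo) == []

    def test_missing_annotation_fails_required_predicate(self):
        peak = self.candidate_peak("x")
        del peak.annotations["db_hit_count"]
        assert flavonoid_candidate_filter(self.repo_with([peak])) == []

    def test_predicates_can_be_relaxed(self):
        peak = self.candidate_peak("x", db_hits=5, with_ms3=False)
        peak.annotations["flavonoid_score_ms3"] = 0.9
        preds = FilterPredicateSet(require_no_db_hit=False, require_ms3=False)
        assert flavonoid_candidate_filter(self.repo_with([peak]), preds) == [("A", "x")]

    def test_deterministic_order(self):
        peaks = [self.candidate_peak(pid) for pid in ("b", "a", "c")]
        got = flavonoid_candidate_filter(self.repo_with(peaks))
        assert got == [("A", "a"), ("A", "b"), ("A", "c")]
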