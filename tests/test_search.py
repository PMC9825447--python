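import math

import numpy as np
import pytest

from metabrepo import (
    Polarity,
    SampleTable,
    Spectrum,
    THINGMR_TOLERANCE,
    ToleranceSpec,
    as_repository,
    category_summary,
    cosine_score,
    cross_repo_search,
    neutral_loss_search,
    precursor_search,
    spectral_search,
)
from metabrepo.core import MetabRepoError, mz_match, rt_match
from metabrepo.rt_calibration import RTModel
from .conftest import make_peak


# ---- brute-force linear-scan oracles -------------------------------------

def oracle_precursor(repo, mz, rt, tol, polarity):
    hits = set()
    for t in repo.tables(polarity):
        for p in t.peaks:
            if mz_match(mz, p.mz, tol) and (
                rt is None or rt_match(rt, p.rt, tol, repo.total_elution_time)
            ):
                hits.add((t.sample_id, p.peak_id))
    return hits


def oracle_cosine(qa, qb):
    """Dict-based nominal-bin cosine, independent of the library path."""
    def bins(spec):
        d = {}
        for m, i in spec.fragments:
            d[math.floor(m + 0.5)] = d.get(math.floor(m + 0.5), 0.0) + i
        return d

    da, db = bins(qa), bins(qb)
    dot = sum(v * db.get(k, 0.0) for k, v in da.items())
    na = math.sqrt(sum(v * v for v in da.values()))
    nb = math.sqrt(sum(v * v for v in db.values()))
    return 0.0 if na * nb == 0 else dot / (na * nb)


def oracle_loss(repo, loss, tol_da):
    hits = set()
    for t in repo.samples:
        for p in t.peaks:
            for s in p.spectra:
                if any(abs((s.precursor_mz - m) - loss) <= tol_da for m, _ in s.fragments):
                    hits.add((t.sample_id, p.peak_id))
    return hits


class TestPrecursorSearch:
    def test_query_finds_itself(self, small_repo):
        peak = small_repo.samples[0].peaks[0]
        res = precursor_search(peak.mz, peak.rt, THINGMR_TOLERANCE, small_repo, "positive")
        assert (small_repo.samples[0].sample_id, peak.peak_id) in {
            (h.sample_id, h.peak_id) for h in res.hits
        }

    def test_window_between_peaks_is_empty(self, tol_ppm):
        a = SampleTable(sample_id="A", peaks=[make_peak("p1", 500.0, 10.0),
                                              make_peak("p2", 500.1, 10.0)])
        repo = as_repository([a])
        narrow = ToleranceSpec(0.1, "ppm", 1.0, "min")
        res = precursor_search(500.05, 10.0, narrow, repo, "positive")
        assert res.hits == []

    def test_rt_omitted_is_superset(self, small_repo):
        peak = small_repo.samples[1].peaks[0]
        with_rt = precursor_search(peak.mz, peak.rt, THINGMR_TOLERANCE, small_repo, "positive")
        without = precursor_search(peak.mz, None, THINGMR_TOLERANCE, small_repo, "positive")
        set_with = {(h.sample_id, h.peak_id) for h in with_rt.hits}
        set_without = {(h.sample_id, h.peak_id) for h in without.hits}
        assert set_with <= set_without

    def test_matches_linear_scan_oracle(self, small_repo):
        rng = np.random.default_rng(42)
        peaks = [p for t in small_repo.samples for p in t.peaks]
        for _ in range(25):
            p = peaks[rng.integers(len(peaks))]
            rt = None if rng.random() < 0.3 else p.rt + float(rng.normal(0, 0.2))
            rt = None if rt is not None and rt < 0 else rt
            res = precursor_search(p.mz, rt, THINGMR_TOLERANCE, small_repo, "positive")
            got = {(h.sample_id, h.peak_id) for h in res.hits}
            assert got == oracle_precursor(small_repo, p.mz, rt, THINGMR_TOLERANCE, "positive")

    def test_rt_bucketing_uses_floor_minutes(self, small_repo):
        peak = small_repo.samples[0].peaks[0]
        res = precursor_search(peak.mz, None, THINGMR_TOLERANCE, small_repo, "positive")
        for bucket, hits in res.by_rt_column().items():
            for h in hits:
                assert math.floor(h.rt) == bucket


class TestSpectralSearch:
    def test_self_similarity_is_one(self):
        s = Spectrum(300.0, 2, [(120.1, 50.0), (180.2, 10.0), (55.0, 3.0)])
        score, matched = cosine_score(s, s)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert matched == 3

    def test_disjoint_bins_score_zero(self):
        a = Spectrum(300.0, 2, [(100.0, 1.0)])
        b = Spectrum(300.0, 2, [(200.0, 1.0)])
        assert cosine_score(a, b)[0] == 0.0

    def test_two_fragment_hand_example(self):
        a = Spectrum(300.0, 2, [(100.0, 1.0), (200.0, 1.0)])
        b = Spectrum(300.0, 2, [(100.0, 1.0)])
        assert cosine_score(a, b)[0] == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = Spectrum(300.0, 2, [(float(m), float(i)) for m, i in
                                    zip(rng.uniform(50, 290, 6), rng.uniform(0.1, 10, 6))])
            b = Spectrum(300.0, 2, [(float(m), float(i)) for m, i in
                                    zip(rng.uniform(50, 290, 6), rng.uniform(0.1, 10, 6))])
            scaled = Spectrum(300.0, 2, [(m, 7.3 * i) for m, i in b.fragments])
            assert cosine_score(a, b)[0] == pytest.approx(cosine_score(b, a)[0], abs=1e-12)
            assert cosine_score(a, scaled)[0] == pytest.approx(cosine_score(a, b)[0], abs=1e-12)
            assert 0.0 <= cosine_score(a, b)[0] <= 1.0 + 1e-12

    def test_matches_oracle_and_ranking(self, small_repo):
        query = next(
            s for t in small_repo.samples for p in t.peaks for s in p.spectra
        )
        hits = spectral_search(query, small_repo, "positive", min_score=0.0)
        for h in hits[:20]:
            peak = small_repo.sample(h.sample_id).peak(h.peak_id)
            best = max(oracle_cosine(query, s) for s in peak.spectra)
            assert h.score <= best + 1e-12
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_level_filter_restricts_library(self, small_repo):
        query = next(
            s for t in small_repo.samples for p in t.peaks for s in p.spectra
        )
        hits = spectral_search(query, small_repo, "positive", level_filter={3})
        assert all(h.ms_level == 3 for h in hits)


class TestNeutralLossSearch:
    def test_hexose_loss_arithmetic(self):
        p = make_peak(
            "p", 449.1078, 22.0,
            spectra=[Spectrum(449.1078, 2, [(287.0550, 100.0)])],
        )
        repo = as_repository([SampleTable(sample_id="A", peaks=[p])])
        hits = neutral_loss_search(162.0528, 0.01, repo)
        assert [(h.sample_id, h.peak_id) for h in hits] == [("A", "p")]
        assert hits[0].matched_fragment == pytest.approx(287.0550)
        # exact arithmetic still matches at tolerance zero (inclusive bound)
        assert len(neutral_loss_search(162.0528, 0.0, repo)) == 1

    def test_loss_larger_than_precursors_empty(self, small_repo):
        assert neutral_loss_search(5000.0, 0.01, small_repo) == []

    def test_matches_oracle(self, small_repo):
        from metabrepo.synthetic import HEXOSE_LOSS

        hits = neutral_loss_search(HEXOSE_LOSS, 0.01, small_repo)
        got = {(h.sample_id, h.peak_id) for h in hits}
        assert got == oracle_loss(small_repo, HEXOSE_LOSS, 0.01)
        assert got, "generator should plant hexose losses"


class TestCrossRepoSearch:
    def test_identity_model_equals_plain_search(self, small_repo):
        peak = small_repo.samples[0].peaks[0]
        model = RTModel.identity()
        res = cross_repo_search(peak, small_repo, small_repo, model, THINGMR_TOLERANCE)
        plain = precursor_search(peak.mz, peak.rt, THINGMR_TOLERANCE, small_repo, "positive")
        assert {(h.sample_id, h.peak_id) for h in res.hits} == {
            (h.sample_id, h.peak_id) for h in plain.hits
        }
        assert not res.query["rt_extrapolated"]

    def test_extrapolation_flagged(self, small_repo):
        peak = small_repo.samples[0].peaks[0]
        model = RTModel("a", "b", "linear", (1.0, 0.0), (peak.rt + 5, peak.rt + 10), 0.0, 4)
        res = cross_repo_search(peak, small_repo, small_repo, model, THINGMR_TOLERANCE)
        assert res.query["rt_extrapolated"]
        assert all(h.extrapolated_rt for h in res.hits)


class TestCategorySummary:
    def metadata(self):
        return {"A": "fruit", "B": "fruit", "C": "fruit", "D": "fruit", "E": "grain"}

    def result_with_hits(self, samples):
        from metabrepo.search import SearchHit, SearchResult

        return SearchResult(
            query={},
            hits=[SearchHit(s, "p", 100.0, 1.0, 1.0) for s in samples],
        )

    def test_ratios(self):
        res = self.result_with_hits(["A", "B"])
        ratios = category_summary(res, self.metadata())
        assert ratios["fruit"] == pytest.approx(0.5)
        assert ratios["grain"] == 0.0

    def test_full_category(self):
        res = self.result_with_hits(["A", "B", "C", "D"])
        assert category_summary(res, self.metadata())["fruit"] == 1.0

    def test_distinct_samples_counted(self):
        res = self.result_with_hits(["A", "A", "A"])
        assert category_summary(res, self.metadata())["fruit"] == pytest.approx(0.25)

    def test_missing_sample_is_error(self):
        res = self.result_with_hits(["Z"])
        with pytest.raises(MetabRepoError, match="Z"):
            category_summary(res, self.metadata())
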