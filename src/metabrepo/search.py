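"""Tolerance-based queries against a repository.

Three complementary search modes map onto how a mass spectrometrist hunts
for a feature:

* precursor search — all peaks whose precursor m/z (and optionally RT) match
  a query within given tolerances; omitting RT searches the whole run and
  turns up candidate isomers;
* spectral search — cosine similarity between product-ion spectra after
  binning fragment masses to nominal (integer) values, robust to the low
  mass accuracy of ion-trap fragment data; an MS2 query against MS3 library
  spectra finds candidate derivatives sharing an aglycone fragmentation;
* neutral-loss search — peaks with a fragment at precursor minus a given
  loss mass (e.g. 162.0528 Da for a hexose unit).

Results can be summarized per sample category as the ratio of samples with a
hit over samples in the category, and a query can be forwarded to a second
repository on a different chromatographic platform by converting the RT
through a fitted :class:`~metabrepo.rt_calibration.RTModel`.

The m/z index is a sorted array with a binary-search window per query; the
behavioural contract is exactly the brute-force linear scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    MetabRepoError,
    Peak,
    Polarity,
    Repository,
    Spectrum,
    ToleranceSpec,
    mz_match,
    rt_match,
)
from .rt_calibration import RTModel, convert_rt

__all__ = [
    "SearchHit",
    "SearchResult",
    "precursor_search",
    "spectral_search",
    "neutral_loss_search",
    "cross_repo_search",
    "category_summary",
    "nominal_bins",
    "cosine_score",
]


@dataclass
class SearchHit:
    sample_id: str
    peak_id: str
    mz: float
    rt: float
    intensity: float
    delta_ppm: Optional[float] = None
    delta_rt: Optional[float] = None
    score: Optional[float] = None
    matched_bins: Optional[int] = None
    matched_fragment: Optional[float] = None
    ms_level: Optional[int] = None
    extrapolated_rt: bool = False


@dataclass
class SearchResult:
    """Hits plus the query echo; hits grouped by sample and nominal-RT column."""

    query: dict
    hits: list[SearchHit] = field(default_factory=list)

    def by_sample(self) -> dict[str, list[SearchHit]]:
        out: dict[str, list[SearchHit]] = {}
        for h in self.hits:
            out.setdefault(h.sample_id, []).append(h)
        return out

    def by_rt_column(self) -> dict[int, list[SearchHit]]:
        """Hits bucketed by nominal retention time (floor of minutes)."""
        out: dict[int, list[SearchHit]] = {}
        for h in self.hits:
            out.setdefault(int(math.floor(h.rt)), []).append(h)
        return dict(sorted(out.items()))


def _iter_peaks(repo: Repository, polarity: Polarity):
    for table in repo.tables(polarity):
        for peak in table.peaks:
            yield table.sample_id, peak


def _mz_index(repo: Repository, polarity: Polarity):
    """Sorted (mz, sample_id, peak ref) arrays, cached on the repository."""
    cache = getattr(repo, "_mz_index_cache", None)
    if cache is None:
        cache = {}
        repo._mz_index_cache = cache
    if polarity not in cache:
        entries = list(_iter_peaks(repo, polarity))
        mzs = np.array([p.mz for _, p in entries], dtype=float)
        order = np.argsort(mzs, kind="stable")
        cache[polarity] = (
            mzs[order],
            [entries[i] for i in order],
        )
    return cache[polarity]


def precursor_search(
    mz: float,
    rt: Optional[float],
    tol: ToleranceSpec,
    repo: Repository,
    polarity: Union[str, Polarity],
) -> SearchResult:
    """All peaks matching a precursor m/z (and RT when given) within tolerance.

    With ``rt=None`` the whole chromatographic run is searched (candidate-
    isomer mode).
    """
    if mz <= 0:
        raise MetabRepoError(f"query m/z must be > 0, got {mz}")
    polarity = Polarity.coerce(polarity)
    sorted_mz, entries = _mz_index(repo, polarity)
    half = tol.mz_tol_da(mz)
    lo = int(np.searchsorted(sorted_mz, mz - half, side="left"))
    hi = int(np.searchsorted(sorted_mz, mz + half, side="right"))
    hits = []
    for sample_id, peak in entries[lo:hi]:
        if not mz_match(mz, peak.mz, tol):
            continue
        if rt is not None and not rt_match(rt, peak.rt, tol, repo.total_elution_time):
            continue
        hits.append(
            SearchHit(
                sample_id=sample_id,
                peak_id=peak.peak_id,
                mz=peak.mz,
                rt=peak.rt,
                intensity=peak.intensity,
                delta_ppm=(peak.mz - mz) / mz * 1e6,
                delta_rt=None if rt is None else peak.rt - rt,
            )
        )
    hits.sort(key=lambda h: (abs(h.delta_ppm), h.sample_id, h.peak_id))
    query = {
        "mode": "precursor",
        "mz": mz,
        "rt": rt,
        "polarity": polarity.value,
        "mz_tol": tol.mz_tol,
        "mz_unit": tol.mz_unit,
        "rt_tol": tol.rt_tol,
        "rt_unit": tol.rt_unit,
    }
    return SearchResult(query=query, hits=hits)


def nominal_bins(spectrum: Spectrum) -> dict[int, float]:
    """Bin fragments to nominal mass (round half up), summing intensities."""
    bins: dict[int, float] = {}
    for m, i in spectrum.fragments:
        b = int(math.floor(m + 0.5))
        bins[b] = bins.get(b, 0.0) + i
    return bins


def cosine_score(a: Spectrum, b: Spectrum) -> tuple[float, int]:
    """Cosine of the nominal-mass-binned intensity vectors.

    Returns ``(score, matched_bin_count)``. The score is in [0, 1] for
    nonnegative intensities and invariant to uniform scaling of either side.
    """
    ba = nominal_bins(a)
    bb = nominal_bins(b)
    na = math.sqrt(sum(v * v for v in ba.values()))
    nb = math.sqrt(sum(v * v for v in bb.values()))
    if na == 0 or nb == 0:
        return 0.0, 0
    shared = set(ba) & set(bb)
    dot = sum(ba[k] * bb[k] for k in shared)
    matched = sum(1 for k in shared if ba[k] > 0 and bb[k] > 0)
    return dot / (na * nb), matched


def spectral_search(
    query: Spectrum,
    repo: Repository,
    polarity: Union[str, Polarity],
    min_score: float = 0.0,
    level_filter: Optional[set[int]] = None,
) -> list[SearchHit]:
    """Rank library spectra by nominal-mass cosine similarity to the query.

    ``level_filter`` restricts the library side by MS level; passing ``{3}``
    with an MS2 query performs the derivative search (same fragmentation in
    MS3 as the query shows in MS2, e.g. glycosides of a known aglycone).
    """
    if not 0 <= min_score <= 1:
        raise MetabRepoError(f"min_score must be in [0, 1], got {min_score}")
    hits = []
    for sample_id, peak in _iter_peaks(repo, Polarity.coerce(polarity)):
        for spec in peak.spectra:
            if level_filter is not None and spec.ms_level not in level_filter:
                continue
            score, matched = cosine_score(query, spec)
            if score >= min_score:
                hits.append(
                    SearchHit(
                        sample_id=sample_id,
                        peak_id=peak.peak_id,
                        mz=peak.mz,
                        rt=peak.rt,
                        intensity=peak.intensity,
                        score=score,
                        matched_bins=matched,
                        ms_level=spec.ms_level,
                    )
                )
    hits.sort(key=lambda h: (-h.score, -h.intensity, h.sample_id, h.peak_id))
    return hits


def neutral_loss_search(
    loss: float,
    tol_da: float,
    repo: Repository,
    polarity: Optional[Union[str, Polarity]] = None,
) -> list[SearchHit]:
    """Peaks with a fragment at (spectrum precursor m/z - loss) within tol_da.

    Each hit reports the matching fragment mass; the bound is inclusive, so
    ``tol_da=0`` still matches exact arithmetic.
    """
    if loss <= 0:
        raise MetabRepoError(f"neutral loss must be > 0, got {loss}")
    if tol_da < 0:
        raise MetabRepoError(f"tolerance must be >= 0, got {tol_da}")
    polarities = (
        [Polarity.coerce(polarity)] if polarity is not None else list(Polarity)
    )
    hits = []
    for pol in polarities:
        for sample_id, peak in _iter_peaks(repo, pol):
            for spec in peak.spectra:
                matching = [
                    m
                    for m, _ in spec.fragments
                    if abs((spec.precursor_mz - m) - loss) <= tol_da
                ]
                if matching:
                    hits.append(
                        SearchHit(
                            sample_id=sample_id,
                            peak_id=peak.peak_id,
                            mz=peak.mz,
                            rt=peak.rt,
                            intensity=peak.intensity,
                            matched_fragment=matching[0],
                            ms_level=spec.ms_level,
                        )
                    )
                    break  # one hit per peak
    hits.sort(key=lambda h: (h.sample_id, h.peak_id))
    return hits


def cross_repo_search(
    peak: Peak,
    source: Repository,
    target: Repository,
    model: RTModel,
    tol: ToleranceSpec,
) -> SearchResult:
    """Search a peak's counterpart in another repository via an RT conversion.

    The query RT is mapped through the fitted platform-to-platform regression;
    hits are flagged when the conversion had to extrapolate outside the
    anchor range.
    """
    converted, extrapolated = convert_rt(model, peak.rt)
    result = precursor_search(
        mz=peak.mz, rt=converted, tol=tol, repo=target, polarity=peak.polarity
    )
    result.query.update(
        {
            "mode": "cross-repo precursor",
            "source_platform": source.platform_id,
            "target_platform": target.platform_id,
            "source_rt": peak.rt,
            "converted_rt": converted,
            "rt_extrapolated": extrapolated,
        }
    )
    for h in result.hits:
        h.extrapolated_rt = extrapolated
    return result


def category_summary(
    result: SearchResult, metadata: Union[pd.DataFrame, dict]
) -> dict[str, float]:
    """Per-category hit ratios: distinct samples with a hit / samples in category.

    ``metadata`` maps sample_id -> category (dict, or a metadata DataFrame
    with ``sample_id``/``category`` columns). Categories with no hits report
    0.0; a hit on a sample absent from the metadata is an error.
    """
    if isinstance(metadata, pd.DataFrame):
        cat_of = dict(zip(metadata["sample_id"], metadata["category"]))
    else:
        cat_of = dict(metadata)
    totals: dict[str, int] = {}
    for cat in cat_of.values():
        totals[cat] = totals.get(cat, 0) + 1
    hit_samples = {h.sample_id for h in result.hits}
    for s in hit_samples:
        if s not in cat_of:
            raise MetabRepoError(f"sample {s!r} missing from metadata")
    counts: dict[str, int] = {c: 0 for c in totals}
    for s in hit_samples:
        counts[cat_of[s]] += 1
    return {c: counts[c] / totals[c] for c in sorted(totals)}
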