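"""Sample-specificity and saturation statistics on aligned peaks.

Two per-entity statistics quantify how widely a feature is shared:

* PSR (peak share rate) of a TUP: the fraction of all samples in which the
  TUP was detected, ``PSR = n_samples / N``.
* APSR (averaged peak share rate) of a sample: the plain mean of the PSRs of
  the TUPs detected in that sample. A low APSR flags a sample rich in
  sample-specific chemistry.

Saturation analysis asks whether the pool of distinct features is exhausted
by the samples at hand: the accumulation curve counts TUPs in random sample
subsets of growing size, and two estimators give the expected number of new
unique features per added sample — the tail slope of the curve, and the
singleton count divided by the number of samples. On repositories whose
share-count distribution follows a power law the two agree closely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .alignment import TUP, align_samples, singleton_count
from .core import (
    MetabRepoError,
    Peak,
    Repository,
    SampleTable,
    ToleranceSpec,
)

__all__ = [
    "psr",
    "apsr",
    "specificity_report",
    "samples_shared",
    "saturation_curve",
    "slope_estimator",
    "singleton_estimator",
    "round_half_away",
    "average_peaks_per_sample",
    "share_count_distribution",
    "power_law_fit",
]


def psr(tup: TUP, n_total: int) -> float:
    """Peak share rate: fraction of the N samples where the TUP was detected."""
    if n_total <= 0:
        raise MetabRepoError(f"total sample count must be >= 1, got {n_total}")
    k = tup.n_samples
    if not 1 <= k <= n_total:
        raise MetabRepoError(
            f"TUP {tup.tup_id}: n_samples {k} outside [1, {n_total}]"
        )
    return k / n_total


def apsr(sample_id: str, tups: list[TUP], n_total: int) -> float:
    """Averaged peak share rate of one sample (unweighted mean over its TUPs)."""
    rates = [psr(t, n_total) for t in tups if any(s == sample_id for s, _ in t.members)]
    if not rates:
        raise MetabRepoError(f"sample {sample_id!r} has no TUP membership; APSR undefined")
    return float(np.mean(rates))


def specificity_report(tups: list[TUP], n_total: int) -> dict:
    """Per-TUP PSR and per-sample APSR in one pass.

    Returns a dict with ``psr`` (Series over tup_id), ``apsr`` (Series over
    sample_id), ``n_peaks`` (peaks per sample) and ``n_total``.
    """
    psr_by_tup = pd.Series(
        {t.tup_id: psr(t, n_total) for t in tups}, dtype=float, name="psr"
    )
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for t in tups:
        rate = psr(t, n_total)
        for s in {s for s, _ in t.members}:
            sums[s] = sums.get(s, 0.0) + rate
            counts[s] = counts.get(s, 0) + 1
    apsr_by_sample = pd.Series(
        {s: sums[s] / counts[s] for s in sums}, dtype=float, name="apsr"
    ).sort_index()
    n_peaks = pd.Series(
        {s: sum(1 for t in tups for ss, _ in t.members if ss == s) for s in sums},
        dtype=int,
        name="n_peaks",
    ).sort_index()
    return {
        "psr": psr_by_tup,
        "apsr": apsr_by_sample,
        "n_peaks": n_peaks,
        "n_total": n_total,
    }


def samples_shared(peak: Peak, repo: Repository, tol: ToleranceSpec) -> int:
    """Number of samples containing >= 1 peak matching the query peak.

    A sample counts once no matter how many of its peaks match; for a peak
    that is itself in the repository the result is therefore >= 1.
    """
    from .search import precursor_search  # local import to avoid a cycle

    result = precursor_search(
        mz=peak.mz, rt=peak.rt, tol=tol, repo=repo, polarity=peak.polarity
    )
    return len({h.sample_id for h in result.hits})


def saturation_curve(
    tables: list[SampleTable],
    tol: ToleranceSpec,
    step: int = 25,
    replicates: int = 10,
    seed: Optional[int] = None,
    total_elution: Optional[float] = None,
) -> pd.DataFrame:
    """TUP accumulation curve over random sample subsets.

    For each subset size n in {step, 2*step, ..., N} (the full N is always
    included), draws ``replicates`` uniform subsets without replacement,
    aligns each and counts TUPs. Returns a DataFrame with columns
    ``n_samples, mean_tups, sd_tups``. Reproducible given ``seed``.
    """
    n = len(tables)
    if step < 1:
        raise MetabRepoError(f"step must be >= 1, got {step}")
    if step > n:
        raise MetabRepoError(f"step {step} exceeds sample count {n}")
    if replicates < 1:
        raise MetabRepoError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(seed)
    sizes = list(range(step, n + 1, step))
    if sizes[-1] != n:
        sizes.append(n)
    rows = []
    for size in sizes:
        counts = []
        for _ in range(replicates):
            idx = rng.choice(n, size=size, replace=False)
            subset = [tables[i] for i in idx]
            tups, _ = align_samples(subset, tol, total_elution=total_elution)
            counts.append(len(tups))
        rows.append(
            {
                "n_samples": size,
                "mean_tups": float(np.mean(counts)),
                "sd_tups": float(np.std(counts, ddof=1)) if replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def slope_estimator(curve: pd.DataFrame, window: float = 0.25) -> float:
    """Least-squares tail slope of the accumulation curve (TUPs per added sample).

    ``window`` is the trailing fraction of curve points used for the fit
    (at least two points).
    """
    if not 0 < window <= 1:
        raise MetabRepoError(f"window must be in (0, 1], got {window}")
    n_pts = len(curve)
    k = max(2, math.ceil(window * n_pts))
    if n_pts < 2:
        raise MetabRepoError("slope estimation needs >= 2 curve points")
    tail = curve.iloc[-k:]
    slope = np.polyfit(tail["n_samples"].to_numpy(float), tail["mean_tups"].to_numpy(float), 1)[0]
    return float(slope)


def singleton_estimator(singletons: int, n_total: int) -> float:
    """Average sample-unique TUPs per sample: singleton count / N."""
    if n_total < 1:
        raise MetabRepoError(f"total sample count must be >= 1, got {n_total}")
    return singletons / n_total


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def average_peaks_per_sample(n_peaks: int, n_samples: int) -> int:
    """Mean detected peaks per sample, reported as a rounded integer."""
    if n_samples < 1:
        raise MetabRepoError(f"sample count must be >= 1, got {n_samples}")
    return round_half_away(n_peaks / n_samples)


def share_count_distribution(tups: list[TUP]) -> dict[int, int]:
    """Histogram mapping k (samples sharing) -> number of TUPs shared by exactly k."""
    if not tups:
        raise MetabRepoError("share-count distribution of an empty TUP list is undefined")
    hist: dict[int, int] = {}
    for t in tups:
        k = t.n_samples
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def power_law_fit(
    histogram: Union[dict[int, int], pd.Series], weights: str = "count"
) -> tuple[float, float]:
    """Fit count ~ c * k^(-alpha) by least squares on log10-log10 axes.

    Only nonzero bins enter the fit (>= 3 required). By default each bin is
    weighted by its count, so every TUP contributes equally; the unweighted
    per-bin line (``weights="none"``) is biased low on sampled data because
    sparse tail bins survive only when their count is nonzero. Returns
    ``(alpha, r2)`` where ``alpha`` is the negated slope and ``r2`` the
    (weighted) coefficient of determination.
    """
    if isinstance(histogram, pd.Series):
        histogram = histogram.to_dict()
    if weights not in ("count", "none"):
        raise MetabRepoError(f"weights must be 'count' or 'none', got {weights!r}")
    ks = np.array([k for k, c in histogram.items() if c > 0], dtype=float)
    cs = np.array([c for c in histogram.values() if c > 0], dtype=float)
    if ks.size < 3:
        raise MetabRepoError(f"power-law fit needs >= 3 nonzero bins, got {ks.size}")
    x = np.log10(ks)
    y = np.log10(cs)
    w = cs if weights == "count" else np.ones_like(cs)
    design = np.vstack([x, np.ones_like(x)]).T
    sw = np.sqrt(w)
    slope, intercept = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)[0]
    fitted = slope * x + intercept
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), r2
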