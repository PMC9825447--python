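"""Cross-sample peak alignment into tentative unique peaks (TUPs).

A TUP is a group of peaks from different samples sharing the same or similar
precursor m/z and retention time; it is the row unit of the aligned peak
matrix and the entity on which sample-specificity statistics are defined.

The grouping algorithm is greedy and deterministic: peaks are pooled across
samples and sorted by descending intensity; the most intense unassigned peak
seeds a TUP, and the group then absorbs, one at a time, the unassigned peak
from a not-yet-represented sample that is within both tolerances of the
current consensus and minimizes the normalized distance

    d = (dmz / mz_tol)^2 + (drt / rt_tol)^2,

with the consensus (median m/z, median RT over members) recomputed after
every attachment. At most one peak per sample joins a TUP, so per-sample
presence/absence is always well defined. A peak that fits no group seeds a
new TUP; there is no unassigned state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import MetabRepoError, Polarity, SampleTable, ToleranceSpec

__all__ = ["TUP", "PeakMatrix", "AlignmentError", "align_samples", "singleton_count"]


class AlignmentError(MetabRepoError):
    pass


@dataclass
class TUP:
    """One cross-sample alignment group (tentative unique peak)."""

    tup_id: str
    polarity: Polarity
    consensus_mz: float
    consensus_rt: float
    members: list[tuple[str, str]] = field(default_factory=list)  # (sample_id, peak_id)

    @property
    def n_samples(self) -> int:
        return len({s for s, _ in self.members})


@dataclass
class PeakMatrix:
    """TUP x sample intensity matrix; NaN marks absence."""

    data: pd.DataFrame  # index: tup_id, columns: sample_id

    @property
    def tup_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def presence(self) -> pd.DataFrame:
        return self.data.notna()

    def n_samples_per_tup(self) -> pd.Series:
        return self.data.notna().sum(axis=1)


def align_samples(
    tables: list[SampleTable],
    tol: ToleranceSpec,
    total_elution: Optional[float] = None,
) -> tuple[list[TUP], PeakMatrix]:
    """Group peaks from many samples into TUPs under m/z and RT tolerances.

    All tables must share one polarity. Every input peak ends up in exactly
    one TUP, and every member of a TUP is within tolerance of the TUP's final
    consensus (verified exhaustively before returning).
    """
    if not tables:
        return [], PeakMatrix(pd.DataFrame())
    polarities = {t.polarity for t in tables}
    if len(polarities) > 1:
        raise AlignmentError(
            f"cannot align mixed polarities: {sorted(p.value for p in polarities)}"
        )
    polarity = tables[0].polarity

    sample_ids = [t.sample_id for t in tables]
    n_total = sum(len(t) for t in tables)
    if n_total == 0:
        return [], PeakMatrix(pd.DataFrame(columns=sample_ids))

    mz = np.empty(n_total)
    rt = np.empty(n_total)
    inten = np.empty(n_total)
    samp = np.empty(n_total, dtype=np.int64)
    sid_arr = np.empty(n_total, dtype=object)
    pid_arr = np.empty(n_total, dtype=object)
    k = 0
    for si, t in enumerate(tables):
        for p in t.peaks:
            mz[k], rt[k], inten[k], samp[k] = p.mz, p.rt, p.intensity, si
            sid_arr[k], pid_arr[k] = t.sample_id, p.peak_id
            k += 1

    # Seed order: descending intensity; ties ascending mz, rt, sample_id, peak_id.
    seed_order = np.lexsort((pid_arr, sid_arr, rt, mz, -inten))
    mz_order = np.argsort(mz, kind="stable")
    mz_sorted = mz[mz_order]

    rt_half = tol.rt_tol_min(total_elution)
    assigned = np.zeros(n_total, dtype=bool)
    sample_used = np.zeros(len(tables), dtype=bool)

    tups: list[TUP] = []
    # A rare post-check ejection can unassign a peak that precedes the current
    # seed cursor, so sweep the seed order until everything is assigned.
    while not assigned.all():
        for i in seed_order:
            if assigned[i]:
                continue
            members = [int(i)]
            assigned[i] = True
            sample_used[:] = False
            sample_used[samp[i]] = True
            cmz = float(mz[i])
            crt = float(rt[i])
            member_mz = [cmz]
            member_rt = [crt]
            while True:
                mz_half = tol.mz_tol_da(cmz)
                lo = np.searchsorted(mz_sorted, cmz - mz_half, side="left")
                hi = np.searchsorted(mz_sorted, cmz + mz_half, side="right")
                cand = mz_order[lo:hi]
                if cand.size == 0:
                    break
                ok = ~assigned[cand]
                ok &= ~sample_used[samp[cand]]
                ok &= np.abs(rt[cand] - crt) <= rt_half
                cand = cand[ok]
                if cand.size == 0:
                    break
                d = ((mz[cand] - cmz) / mz_half) ** 2 + ((rt[cand] - crt) / rt_half) ** 2
                j = int(cand[int(np.argmin(d))])
                members.append(j)
                assigned[j] = True
                sample_used[samp[j]] = True
                member_mz.append(float(mz[j]))
                member_rt.append(float(rt[j]))
                cmz = float(np.median(member_mz))
                crt = float(np.median(member_rt))
            # Exhaustive tolerance post-check against the final consensus;
            # eject the worst offender until the invariant holds (ejected
            # peaks re-enter the pool and seed their own group later).
            while len(members) > 1:
                mz_half = tol.mz_tol_da(cmz)
                dev_mz = np.abs(np.asarray(member_mz) - cmz)
                dev_rt = np.abs(np.asarray(member_rt) - crt)
                bad = (dev_mz > mz_half) | (dev_rt > rt_half)
                if not bad.any():
                    break
                d = (dev_mz / mz_half) ** 2 + (dev_rt / rt_half) ** 2
                worst = int(np.argmax(np.where(bad, d, -np.inf)))
                assigned[members[worst]] = False
                del members[worst], member_mz[worst], member_rt[worst]
                cmz = float(np.median(member_mz))
                crt = float(np.median(member_rt))
            tups.append(
                TUP(
                    tup_id=f"T{len(tups) + 1:06d}",
                    polarity=polarity,
                    consensus_mz=cmz,
                    consensus_rt=crt,
                    members=[(sid_arr[m], pid_arr[m]) for m in members],
                )
            )

    matrix = _build_matrix(tups, sample_ids, sid_arr, pid_arr, inten)
    return tups, matrix


def _build_matrix(
    tups: list[TUP],
    sample_ids: list[str],
    sid_arr: np.ndarray,
    pid_arr: np.ndarray,
    inten: np.ndarray,
) -> PeakMatrix:
    lookup = {(s, p): v for s, p, v in zip(sid_arr, pid_arr, inten)}
    col_index = {s: j for j, s in enumerate(sample_ids)}
    arr = np.full((len(tups), len(sample_ids)), np.nan)
    for i, tup in enumerate(tups):
        for s, p in tup.members:
            arr[i, col_index[s]] = lookup[(s, p)]
    df = pd.DataFrame(arr, index=[t.tup_id for t in tups], columns=sample_ids)
    return PeakMatrix(df)


def singleton_count(tups: list[TUP]) -> int:
    """Number of TUPs detected in exactly one sample."""
    return sum(1 for t in tups if t.n_samples == 1)
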