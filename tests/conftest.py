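import numpy as np
import pytest

from metabrepo import (
    Peak,
    Polarity,
    Repository,
    SampleTable,
    Spectrum,
    SynthConfig,
    THINGMR_TOLERANCE,
    ToleranceSpec,
    as_repository,
    generate_repository,
)


def make_peak(pid="P1", mz=300.0, rt=10.0, intensity=1e5, polarity="positive", **kw):
    return Peak(peak_id=pid, mz=mz, rt=rt, intensity=intensity, polarity=polarity, **kw)


@pytest.fixture
def tol_ppm():
    """5 ppm / 1 min: the high-resolution platform's recommended tolerances."""
    return ToleranceSpec(5.0, "ppm", 1.0, "min")


@pytest.fixture
def two_sample_tables():
    """Two samples sharing one compound at identical (mz, rt)."""
    a = SampleTable(
        sample_id="A",
        polarity=Polarity.POSITIVE,
        peaks=[make_peak("p1", 300.0, 10.0, 5e5), make_peak("p2", 420.0, 25.0, 2e5)],
    )
    b = SampleTable(
        sample_id="B",
        polarity=Polarity.POSITIVE,
        peaks=[make_peak("p1", 300.0, 10.0, 4e5)],
    )
    return [a, b]


@pytest.fixture(scope="session")
def small_synth():
    """Small planted repository shared by several test modules."""
    cfg = SynthConfig(n_samples=8, n_compounds=150, seed=3, spectrum_rate=0.5)
    tables, truth = generate_repository(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_repo(small_synth):
    _, tables, _ = small_synth
    return as_repository(tables)


def assign_of(tups):
    """(sample_id, peak_id) -> tup_id map for ground-truth comparison."""
    out = {}
    for t in tups:
        for m in t.members:
            out[m] = t.tup_id
    return out


def check_partition_and_tolerance(tables, tups, tol, total_elution=None):
    """Every peak in exactly one TUP; every member within tolerance of consensus."""
    n_peaks = sum(len(t) for t in tables)
    seen = set()
    peak_of = {(t.sample_id, p.peak_id): p for t in tables for p in t.peaks}
    rt_half = tol.rt_tol_min(total_elution)
    for tup in tups:
        sample_ids = [s for s, _ in tup.members]
        assert len(sample_ids) == len(set(sample_ids)), "two peaks of one sample in a TUP"
        for member in tup.members:
            assert member not in seen, "peak assigned to two TUPs"
            seen.add(member)
            p = peak_of[member]
            assert abs(p.mz - tup.consensus_mz) <= tol.mz_tol_da(tup.consensus_mz)
            assert abs(p.rt - tup.consensus_rt) <= rt_half
    assert len(seen) == n_peaks, "partition does not cover all peaks"
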