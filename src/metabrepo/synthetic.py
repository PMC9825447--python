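"""Seeded generators for repositories, platform pairs and profile datasets.

The generators emulate the statistical structure the analyses assume — most
importantly a truncated power-law distribution of samples-per-compound, the
shape empirically observed for share counts in large aligned repositories —
and return the planted ground truth (compound positions, per-peak labels,
platform correspondences, planted profile pairs) so recovery can be scored
exactly.

Design notes
------------
* Planted compounds are rejection-sampled to stay at least twice the
  alignment tolerance apart in (m/z, RT) jointly, so the planted grouping is
  unambiguous and recoverable in principle.
* Jitter defaults (1 ppm m/z, 0.1 min RT) sit well inside the recommended
  search tolerances; stress configurations can push them to the boundary.
* Spectra are structurally plausible, not chemically simulated: random
  neutral losses, with a planted hexose-loss (162.0528 Da) subset for
  neutral-loss search tests.
* Everything is bit-reproducible given the config seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    MetabRepoError,
    Peak,
    Polarity,
    Repository,
    SampleTable,
    Spectrum,
    THINGMR_TOLERANCE,
    ToleranceSpec,
)
from .cooccurrence import BinaryProfile

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "HEXOSE_LOSS",
    "sample_share_counts",
    "generate_repository",
    "generate_platform_pair",
    "generate_profile_dataset",
]

HEXOSE_LOSS = 162.0528  # anhydro-hexose, the canonical glycoside neutral loss


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic repository.

    Defaults describe a mid-sized Q-ToF-style repository: 50 samples, 5000
    compounds whose samples-per-compound counts follow a truncated power law
    with exponent 2, instrument jitter well inside the 20 ppm / 0.5 min
    search tolerances, log-normal intensities, and product-ion spectra on a
    minority of peaks (15%, the coverage DDA typically achieves).
    """

    n_samples: int = 50
    n_compounds: int = 5000
    alpha: float = 2.0
    mz_range: tuple[float, float] = (100.0, 1000.0)
    rt_range: tuple[float, float] = (1.0, 40.0)
    mz_jitter_ppm: float = 1.0
    rt_jitter_sd: float = 0.1
    intensity_log_mean: float = 12.0
    intensity_log_sd: float = 1.0
    fragment_count_mean: float = 6.0
    spectrum_rate: float = 0.15
    hexose_fraction: float = 0.1
    dropout: float = 0.0
    polarity: Polarity = Polarity.POSITIVE
    separation_tol: ToleranceSpec = field(default_factory=lambda: THINGMR_TOLERANCE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_compounds < 1:
            raise MetabRepoError("n_samples and n_compounds must be >= 1")
        if self.alpha <= 0:
            raise MetabRepoError(f"alpha must be > 0, got {self.alpha}")
        for name, lo, hi in (("mz_range", *self.mz_range), ("rt_range", *self.rt_range)):
            if not lo < hi:
                raise MetabRepoError(f"{name} must be a nonempty interval, got ({lo}, {hi})")
        if self.mz_jitter_ppm < 0 or self.rt_jitter_sd < 0:
            raise MetabRepoError("jitter magnitudes must be >= 0")
        if not 0 <= self.dropout < 1:
            raise MetabRepoError(f"dropout must be in [0, 1), got {self.dropout}")
        if not 0 <= self.spectrum_rate <= 1:
            raise MetabRepoError(f"spectrum_rate must be in [0, 1], got {self.spectrum_rate}")


@dataclass
class GroundTruth:
    """Planted truth accompanying a generated dataset."""

    compounds: dict[str, dict] = field(default_factory=dict)
    labels: dict[tuple[str, str], str] = field(default_factory=dict)
    shared_compounds: list[str] = field(default_factory=list)
    warp: Optional[tuple[float, ...]] = None
    compounds_target: dict[str, dict] = field(default_factory=dict)
    labels_target: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def true_singletons(self, target: bool = False) -> int:
        compounds = self.compounds_target if target else self.compounds
        return sum(1 for c in compounds.values() if len(c["samples"]) == 1)


def sample_share_counts(
    n: int, alpha: float, k_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n counts from the truncated power law P(k) ~ k^(-alpha), k in 1..k_max."""
    if k_max < 1:
        raise MetabRepoError(f"k_max must be >= 1, got {k_max}")
    ks = np.arange(1, k_max + 1, dtype=float)
    p = ks ** (-alpha)
    p /= p.sum()
    return rng.choice(np.arange(1, k_max + 1), size=n, p=p)


def _place_compounds(cfg: SynthConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Rejection-sample (mz, rt) compound positions >= 2x tolerance apart."""
    tol = cfg.separation_tol
    positions: list[tuple[float, float]] = []
    mz_sorted: list[float] = []
    entries: list[tuple[float, float]] = []  # sorted by mz alongside mz_sorted
    attempts = 0
    max_attempts = 200 * cfg.n_compounds
    while len(positions) < cfg.n_compounds:
        attempts += 1
        if attempts > max_attempts:
            raise MetabRepoError(
                "could not place compounds with the requested separation; "
                "widen mz/rt ranges or reduce n_compounds"
            )
        mz = float(rng.uniform(*cfg.mz_range))
        rt = float(rng.uniform(*cfg.rt_range))
        sep_mz = 2 * tol.mz_tol_da(mz)
        sep_rt = 2 * tol.rt_tol_min()
        lo = bisect.bisect_left(mz_sorted, mz - sep_mz)
        hi = bisect.bisect_right(mz_sorted, mz + sep_mz)
        if any(abs(entries[j][1] - rt) < sep_rt for j in range(lo, hi)):
            continue
        positions.append((mz, rt))
        idx = bisect.bisect_left(mz_sorted, mz)
        mz_sorted.insert(idx, mz)
        entries.insert(idx, (mz, rt))
    return positions


def _make_spectrum(
    precursor_mz: float, ms_level: int, cfg: SynthConfig, rng: np.random.Generator
) -> Spectrum:
    n_frag = max(1, int(rng.poisson(cfg.fragment_count_mean)))
    frags = []
    if rng.random() < cfg.hexose_fraction and precursor_mz - HEXOSE_LOSS > 50:
        frags.append((precursor_mz - HEXOSE_LOSS, float(rng.uniform(0.2, 1.0))))
    while len(frags) < n_frag:
        m = float(rng.uniform(50.0, max(51.0, precursor_mz - 10.0)))
        frags.append((m, float(rng.uniform(0.01, 1.0))))
    return Spectrum(precursor_mz=precursor_mz, ms_level=ms_level, fragments=frags)


def _emit_tables(
    cfg: SynthConfig,
    positions: Sequence[tuple[float, float]],
    rng: np.random.Generator,
    force_sample0: Optional[set[int]] = None,
    rt_transform=None,
) -> tuple[list[SampleTable], GroundTruth]:
    """Assign compounds to samples and emit jittered peaks with ground truth."""
    force_sample0 = force_sample0 or set()
    shares = sample_share_counts(len(positions), cfg.alpha, cfg.n_samples, rng)
    membership: list[np.ndarray] = []
    for ci, k in enumerate(shares):
        chosen = rng.choice(cfg.n_samples, size=int(k), replace=False)
        if ci in force_sample0 and 0 not in chosen:
            chosen[0] = 0  # pooled reference sample always carries shared compounds
        membership.append(np.sort(chosen))

    truth = GroundTruth()
    per_sample: list[list[Peak]] = [[] for _ in range(cfg.n_samples)]
    counters = [0] * cfg.n_samples
    for ci, (true_mz, true_rt) in enumerate(positions):
        cid = f"C{ci + 1:06d}"
        rt_emit = true_rt if rt_transform is None else float(rt_transform(true_rt))
        emitted: list[str] = []
        for si in membership[ci]:
            if cfg.dropout > 0 and rng.random() < cfg.dropout:
                continue
            counters[si] += 1
            pid = f"P{counters[si]:06d}"
            mz = true_mz * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6)
            rt = max(0.0, rt_emit + rng.normal(0.0, cfg.rt_jitter_sd))
            intensity = float(rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd))
            spectra = []
            annotations: dict = {}
            if rng.random() < cfg.spectrum_rate:
                ms2 = _make_spectrum(mz, 2, cfg, rng)
                spectra.append(ms2)
                if rng.random() < 0.3:
                    frag_mz = max(m for m, _ in ms2.fragments)
                    spectra.append(_make_spectrum(frag_mz, 3, cfg, rng))
                    annotations["flavonoid_score_ms3"] = round(float(rng.uniform(0, 1)), 3)
            if rng.random() < 0.8:
                annotations["db_hit_count"] = int(rng.poisson(2))
            sid = f"S{si + 1:03d}"
            per_sample[si].append(
                Peak(
                    peak_id=pid,
                    mz=mz,
                    rt=rt,
                    intensity=intensity,
                    polarity=cfg.polarity,
                    adduct="[M+H]+" if cfg.polarity == Polarity.POSITIVE else "[M-H]-",
                    spectra=spectra,
                    annotations=annotations,
                )
            )
            truth.labels[(sid, pid)] = cid
            emitted.append(sid)
        truth.compounds[cid] = {"mz": true_mz, "rt": rt_emit, "samples": emitted}

    categories = ("plant", "animal", "microbe", "food", "environment")
    tables = [
        SampleTable(
            sample_id=f"S{si + 1:03d}",
            name=f"synthetic sample {si + 1}",
            category=categories[si % len(categories)],
            species=f"sp{si + 1:03d}",
            polarity=cfg.polarity,
            peaks=per_sample[si],
        )
        for si in range(cfg.n_samples)
    ]
    return tables, truth


def generate_repository(cfg: SynthConfig) -> tuple[list[SampleTable], GroundTruth]:
    """Generate per-sample peak tables with planted compound ground truth."""
    rng = np.random.default_rng(cfg.seed)
    positions = _place_compounds(cfg, rng)
    return _emit_tables(cfg, positions, rng)


def as_repository(
    tables: list[SampleTable],
    platform_id: str = "synthetic",
    total_elution: Optional[float] = None,
    tol: Optional[ToleranceSpec] = None,
) -> Repository:
    """Wrap generated tables in a Repository with a covering elution time."""
    if total_elution is None:
        max_rt = max((p.rt for t in tables for p in t.peaks), default=1.0)
        total_elution = max_rt + 2.0
    return Repository(
        platform_id=platform_id,
        total_elution_time=total_elution,
        samples=tables,
        default_tolerance=tol or THINGMR_TOLERANCE,
    )


def generate_platform_pair(
    cfg: SynthConfig,
    warp: tuple[float, ...] = (0.4, 2.0),
    overlap: float = 0.7,
    rt_noise_sd: Optional[float] = None,
) -> tuple[Repository, Repository, GroundTruth]:
    """Two repositories sharing compounds, with RTs warped between platforms.

    ``warp`` holds polynomial coefficients (highest degree first) mapping a
    source RT onto the target platform; it must be strictly increasing over
    the configured RT range. Shared compounds (fraction ``overlap``) always
    appear in the first sample of each platform — a pooled reference sample —
    so anchor discovery between the two reference tables sees all of them.
    """
    if not 0 < overlap <= 1:
        raise MetabRepoError(f"overlap must be in (0, 1], got {overlap}")
    coeffs = np.asarray(warp, dtype=float)
    deriv = np.polyder(coeffs) if coeffs.size > 1 else np.array([0.0])
    lo, hi = cfg.rt_range
    grid = np.linspace(lo, hi, 64)
    if not (np.polyval(deriv, grid) > 0).all():
        raise MetabRepoError("warp must be strictly monotone increasing over the RT range")
    noise = cfg.rt_jitter_sd if rt_noise_sd is None else rt_noise_sd

    rng = np.random.default_rng(cfg.seed)
    positions = _place_compounds(cfg, rng)
    n_shared = max(1, round(overlap * cfg.n_compounds))
    shared_idx = set(range(n_shared))

    tables_a, truth = _emit_tables(cfg, positions, rng, force_sample0=shared_idx)

    cfg_b = replace(cfg, rt_jitter_sd=noise)
    shared_positions = positions[:n_shared]
    tables_b, truth_b = _emit_tables(
        cfg_b,
        shared_positions,
        rng,
        force_sample0=set(range(n_shared)),
        rt_transform=lambda rt: float(np.polyval(coeffs, rt)),
    )

    truth.shared_compounds = [f"C{i + 1:06d}" for i in range(n_shared)]
    truth.warp = tuple(float(c) for c in coeffs)
    truth.compounds_target = truth_b.compounds
    truth.labels_target = truth_b.labels
    repo_a = as_repository(tables_a, platform_id="platform-A")
    repo_b = as_repository(tables_b, platform_id="platform-B")
    return repo_a, repo_b, truth


def generate_profile_dataset(
    n_species: int,
    n_metab: int,
    n_genes: int,
    n_planted_pairs: int,
    seed: int = 0,
) -> tuple[list[BinaryProfile], list[BinaryProfile], GroundTruth]:
    """Metabolite and gene presence/absence profiles with planted exact pairs.

    Each planted pair shares one random pattern with presence in
    ``[2, n_species - 2]``; decoys are drawn uniformly over 0/1 patterns,
    resampled while identical to a planted pattern.
    """
    if n_species < 4:
        raise MetabRepoError(f"need >= 4 species for a valid planted pattern, got {n_species}")
    if n_planted_pairs > min(n_metab, n_genes):
        raise MetabRepoError("more planted pairs than profiles on one side")
    rng = np.random.default_rng(seed)
    species = tuple(f"sp{j + 1:03d}" for j in range(n_species))

    planted_patterns = []
    for _ in range(n_planted_pairs):
        presence = int(rng.integers(2, n_species - 1))  # in [2, n_species - 2]
        vec = np.zeros(n_species, dtype=np.uint8)
        vec[rng.choice(n_species, size=presence, replace=False)] = 1
        planted_patterns.append(vec)
    planted_keys = {v.tobytes() for v in planted_patterns}

    def decoy() -> np.ndarray:
        while True:
            vec = rng.integers(0, 2, size=n_species).astype(np.uint8)
            if vec.tobytes() not in planted_keys:
                return vec

    metab, genes = [], []
    truth = GroundTruth()
    for i in range(n_metab):
        mid = f"M{i + 1:05d}"
        vec = planted_patterns[i] if i < n_planted_pairs else decoy()
        metab.append(BinaryProfile(mid, "metabolite", species, vec.copy()))
    for i in range(n_genes):
        gid = f"OG{i + 1:07d}"
        vec = planted_patterns[i] if i < n_planted_pairs else decoy()
        genes.append(BinaryProfile(gid, "gene", species, vec.copy()))
    truth.planted_pairs = [
        (f"M{i + 1:05d}", f"OG{i + 1:07d}") for i in range(n_planted_pairs)
    ]
    return metab, genes, truth
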