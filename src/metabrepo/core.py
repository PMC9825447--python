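"""Domain types and tolerance semantics for comparable untargeted LC-MS repositories.

A repository is a set of per-sample peak tables acquired on one chromatographic
platform under a uniform protocol, so that any two peaks can be compared by
precursor m/z and retention time under platform-wide tolerances. The types here
are deliberately plain: a :class:`Peak` is one detected feature, a
:class:`SampleTable` is one sample's peak list, and a :class:`Repository` ties
the tables to the platform metadata (total elution time, default tolerances)
that the comparison semantics need.

Tolerance semantics live here as well (:func:`mz_match`, :func:`rt_match`).
All tolerance comparisons are inclusive, and ppm tolerances are resolved
against the query-side m/z so that a search result never depends on the hit
set itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

__all__ = [
    "Polarity",
    "ToleranceSpec",
    "Spectrum",
    "Peak",
    "SampleTable",
    "Repository",
    "MetabRepoError",
    "ValidationError",
    "mz_match",
    "rt_match",
    "mz_window",
    "rt_window",
]


class MetabRepoError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(MetabRepoError):
    """An object violates a structural invariant."""


class Polarity(str, Enum):
    """ESI ionization mode. Peaks in different modes are never compared."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    @classmethod
    def coerce(cls, value: Union[str, "Polarity"]) -> "Polarity":
        if isinstance(value, cls):
            return value
        v = str(value).strip().lower()
        aliases = {
            "positive": cls.POSITIVE,
            "pos": cls.POSITIVE,
            "+": cls.POSITIVE,
            "negative": cls.NEGATIVE,
            "neg": cls.NEGATIVE,
            "-": cls.NEGATIVE,
        }
        if v not in aliases:
            raise ValidationError(f"unknown polarity: {value!r}")
        return aliases[v]


@dataclass(frozen=True)
class ToleranceSpec:
    """Matching tolerances for precursor m/z and retention time.

    Parameters
    ----------
    mz_tol : float
        Strictly positive magnitude of the m/z tolerance.
    mz_unit : {"ppm", "Da"}
        Unit of ``mz_tol``. For ppm, the reference mass is the query-side m/z.
    rt_tol : float
        Strictly positive magnitude of the retention-time tolerance.
    rt_unit : {"min", "percent"}
        Minutes, or percent of the platform's total elution (gradient) time.
        Percent tolerances can only be resolved when the total elution time
        is known.
    """

    mz_tol: float
    mz_unit: str = "ppm"
    rt_tol: float = 1.0
    rt_unit: str = "min"

    def __post_init__(self) -> None:
        if self.mz_unit not in ("ppm", "Da"):
            raise ValidationError(f"mz_unit must be 'ppm' or 'Da', got {self.mz_unit!r}")
        if self.rt_unit not in ("min", "percent"):
            raise ValidationError(f"rt_unit must be 'min' or 'percent', got {self.rt_unit!r}")
        if not self.mz_tol > 0:
            raise ValidationError(f"mz_tol must be > 0, got {self.mz_tol}")
        if not self.rt_tol > 0:
            raise ValidationError(f"rt_tol must be > 0, got {self.rt_tol}")

    def mz_tol_da(self, ref_mz: float) -> float:
        """Absolute m/z half-window (Da) at the reference (query-side) mass."""
        if self.mz_unit == "Da":
            return self.mz_tol
        return self.mz_tol * 1e-6 * ref_mz

    def rt_tol_min(self, total_elution: Optional[float] = None) -> float:
        """Absolute RT half-window in minutes."""
        if self.rt_unit == "min":
            return self.rt_tol
        if total_elution is None:
            raise ValidationError(
                "percent-of-gradient RT tolerance requires the total elution time"
            )
        return self.rt_tol / 100.0 * total_elution


# Recommended search tolerances for the two published platform families:
# high-resolution FT platform (5 ppm / 1 min over a 107-min gradient) and
# the Q-ToF platform (20 ppm / 0.5 min over a 42-min gradient).
FOODMR_TOLERANCE = ToleranceSpec(5.0, "ppm", 1.0, "min")
THINGMR_TOLERANCE = ToleranceSpec(20.0, "ppm", 0.5, "min")


def mz_match(mz_a: float, mz_b: float, tol: ToleranceSpec) -> bool:
    """Inclusive m/z match; ``mz_a`` is the query side and fixes the ppm reference."""
    if mz_a <= 0 or mz_b <= 0:
        raise ValidationError(f"m/z values must be positive, got {mz_a}, {mz_b}")
    return abs(mz_a - mz_b) <= tol.mz_tol_da(mz_a)


def rt_match(
    rt_a: float,
    rt_b: float,
    tol: ToleranceSpec,
    total_elution: Optional[float] = None,
) -> bool:
    """Inclusive retention-time match in minutes."""
    if rt_a < 0 or rt_b < 0:
        raise ValidationError(f"retention times must be >= 0, got {rt_a}, {rt_b}")
    return abs(rt_a - rt_b) <= tol.rt_tol_min(total_elution)


def mz_window(mz: float, tol: ToleranceSpec) -> tuple[float, float]:
    """Inclusive (lo, hi) m/z window around a query mass."""
    w = tol.mz_tol_da(mz)
    return mz - w, mz + w


def rt_window(
    rt: float, tol: ToleranceSpec, total_elution: Optional[float] = None
) -> tuple[float, float]:
    """Inclusive (lo, hi) RT window in minutes around a query retention time."""
    w = tol.rt_tol_min(total_elution)
    return rt - w, rt + w


@dataclass
class Spectrum:
    """One product-ion spectrum (MS2 or MS3) attached to a peak.

    ``fragments`` is a nonempty list of ``(m/z, intensity)`` pairs with
    positive fragment masses and nonnegative intensities.
    """

    precursor_mz: float
    ms_level: int
    fragments: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.ms_level not in (2, 3):
            raise ValidationError(f"ms_level must be 2 or 3, got {self.ms_level}")
        if self.precursor_mz <= 0:
            raise ValidationError(f"precursor_mz must be > 0, got {self.precursor_mz}")
        if not self.fragments:
            raise ValidationError("a spectrum must have at least one fragment")
        self.fragments = [(float(m), float(i)) for m, i in self.fragments]
        for m, i in self.fragments:
            if m <= 0:
                raise ValidationError(f"fragment m/z must be > 0, got {m}")
            if i < 0:
                raise ValidationError(f"fragment intensity must be >= 0, got {i}")


@dataclass
class Peak:
    """One detected LC-MS feature.

    ``annotations`` carries precomputed per-peak flags consumed as data, e.g.
    ``db_hit_count`` (compound-database hits for the measured mass/adduct) and
    ``flavonoid_score_ms2`` / ``flavonoid_score_ms3`` (aglycone-similarity
    scores in [0, 1] from a spectral pattern search).
    """

    peak_id: str
    mz: float
    rt: float
    intensity: float
    polarity: Polarity
    adduct: Optional[str] = None
    spectra: list[Spectrum] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polarity = Polarity.coerce(self.polarity)
        if self.mz <= 0:
            raise ValidationError(f"peak {self.peak_id}: m/z must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ValidationError(f"peak {self.peak_id}: rt must be >= 0, got {self.rt}")
        if self.intensity < 0:
            raise ValidationError(
                f"peak {self.peak_id}: intensity must be >= 0, got {self.intensity}"
            )

    def has_ms_level(self, level: int) -> bool:
        return any(s.ms_level == level for s in self.spectra)


@dataclass
class SampleTable:
    """The peak list of one sample."""

    sample_id: str
    name: str = ""
    category: str = ""
    species: Optional[str] = None
    polarity: Polarity = Polarity.POSITIVE
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.polarity = Polarity.coerce(self.polarity)
        seen = set()
        for p in self.peaks:
            if p.peak_id in seen:
                raise ValidationError(
                    f"sample {self.sample_id}: duplicate peak_id {p.peak_id!r}"
                )
            seen.add(p.peak_id)
            if p.polarity != self.polarity:
                raise ValidationError(
                    f"sample {self.sample_id}: peak {p.peak_id} polarity "
                    f"{p.polarity.value} differs from table polarity {self.polarity.value}"
                )

    def peak(self, peak_id: str) -> Peak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(f"no peak {peak_id!r} in sample {self.sample_id}")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class Repository:
    """All sample tables of one platform plus the platform metadata."""

    platform_id: str
    total_elution_time: float
    samples: list[SampleTable] = field(default_factory=list)
    default_tolerance: ToleranceSpec = field(default_factory=lambda: THINGMR_TOLERANCE)

    def __post_init__(self) -> None:
        if self.total_elution_time <= 0:
            raise ValidationError(
                f"total_elution_time must be > 0, got {self.total_elution_time}"
            )
        seen = set()
        for t in self.samples:
            if t.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {t.sample_id!r}")
            seen.add(t.sample_id)

    def sample(self, sample_id: str) -> SampleTable:
        for t in self.samples:
            if t.sample_id == sample_id:
                return t
        raise KeyError(f"no sample {sample_id!r} in repository {self.platform_id}")

    def tables(self, polarity: Optional[Union[str, Polarity]] = None) -> list[SampleTable]:
        if polarity is None:
            return list(self.samples)
        pol = Polarity.coerce(polarity)
        return [t for t in self.samples if t.polarity == pol]

    def n_peaks(self) -> int:
        return sum(len(t) for t in self.samples)

    def validate(self) -> list[str]:
        """Collect invariant violations as human-readable messages.

        Structural invariants are already enforced at construction; this adds
        the repository-level checks (RT inside the gradient, spectrum levels).
        """
        problems: list[str] = []
        for t in self.samples:
            for p in t.peaks:
                if p.rt > self.total_elution_time:
                    problems.append(
                        f"{t.sample_id}/{p.peak_id}: rt {p.rt} min exceeds total "
                        f"elution time {self.total_elution_time} min"
                    )
                for s in p.spectra:
                    if s.ms_level not in (2, 3):
                        problems.append(
                            f"{t.sample_id}/{p.peak_id}: ms_level {s.ms_level}"
                        )
        return problems
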