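"""Presence/absence co-profiling of metabolites against gene families.

A metabolite detected only in the species that carry a particular gene family
is a strong lead for a species-specific pathway. This module codes TUPs and
orthogroups as 0/1 vectors over a shared ordered species list, compares all
metabolite profiles against all gene profiles, and returns pairs whose
patterns agree within a mismatch budget (exact pattern match at budget 0).

It also houses the multi-predicate candidate miner used to flag potential
novel flavonoid derivatives: peaks with no compound-database hit, an MS3
spectrum, and a high aglycone-similarity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import PeakMatrix
from .core import MetabRepoError, Repository

__all__ = [
    "BinaryProfile",
    "CoPartitionPair",
    "FilterPredicateSet",
    "binarize_peak_matrix",
    "load_gene_profiles",
    "profile_similarity",
    "find_copartitioned_pairs",
    "flavonoid_candidate_filter",
]


@dataclass
class BinaryProfile:
    """0/1 presence vector of one entity over an ordered species list."""

    entity_id: str
    kind: str  # "metabolite" | "gene"
    species: tuple[str, ...]
    vector: np.ndarray  # uint8, same length as species

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.uint8)
        if self.vector.ndim != 1 or self.vector.size != len(self.species):
            raise MetabRepoError(
                f"profile {self.entity_id}: vector length {self.vector.size} "
                f"!= species list length {len(self.species)}"
            )
        if not np.isin(self.vector, (0, 1)).all():
            raise MetabRepoError(f"profile {self.entity_id}: entries must be 0/1")

    @property
    def presence(self) -> int:
        return int(self.vector.sum())


@dataclass(frozen=True)
class CoPartitionPair:
    metabolite_id: str
    gene_id: str
    mismatch: int  # Hamming distance
    jaccard: float


@dataclass(frozen=True)
class FilterPredicateSet:
    """Conjunction of per-peak predicates for candidate mining."""

    require_no_db_hit: bool = True
    require_ms3: bool = True
    min_flavonoid_score: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.min_flavonoid_score <= 1:
            raise MetabRepoError(
                f"min_flavonoid_score must be in [0, 1], got {self.min_flavonoid_score}"
            )


def binarize_peak_matrix(
    matrix: PeakMatrix,
    species_of_sample: dict[str, str],
    species_order: Optional[Sequence[str]] = None,
) -> list[BinaryProfile]:
    """Collapse the TUP x sample matrix to TUP x species presence profiles.

    A species is coded 1 for a TUP when the TUP has a member in at least one
    sample of that species; replicate samples of one species collapse to a
    single column.
    """
    for s in matrix.sample_ids:
        if s not in species_of_sample:
            raise MetabRepoError(f"sample {s!r} has no species mapping")
    if species_order is None:
        species_order = sorted(set(species_of_sample[s] for s in matrix.sample_ids))
    species = tuple(species_order)
    col_of = {sp: j for j, sp in enumerate(species)}
    present = matrix.presence().to_numpy()
    out = []
    for i, tup_id in enumerate(matrix.tup_ids):
        vec = np.zeros(len(species), dtype=np.uint8)
        for j, sample_id in enumerate(matrix.sample_ids):
            if present[i, j]:
                vec[col_of[species_of_sample[sample_id]]] = 1
        out.append(BinaryProfile(tup_id, "metabolite", species, vec))
    return out


def load_gene_profiles(path: Union[str, Path]) -> list[BinaryProfile]:
    """Binarize an orthogroup gene-count table (orthogroups x species TSV).

    Accepts the standard layout of orthology-inference output: first column
    the orthogroup id, one column of nonnegative gene counts per species, and
    an optional trailing ``Total`` column (dropped). A count >= 1 codes as
    presence. All-zero rows are retained.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    if df.shape[1] < 2:
        raise MetabRepoError(f"{path}: need an orthogroup column plus species columns")
    id_col = df.columns[0]
    species_cols = [c for c in df.columns[1:] if c.lower() != "total"]
    species = tuple(species_cols)
    out = []
    for i, row in df.iterrows():
        vec = np.zeros(len(species), dtype=np.uint8)
        for j, col in enumerate(species_cols):
            text = row[col]
            try:
                count = int(text)
            except ValueError:
                raise MetabRepoError(
                    f"{path}: row {i + 2}, column {col!r}: non-numeric count {text!r}"
                ) from None
            if count < 0:
                raise MetabRepoError(
                    f"{path}: row {i + 2}, column {col!r}: negative count {count}"
                )
            vec[j] = 1 if count >= 1 else 0
        out.append(BinaryProfile(row[id_col], "gene", species, vec))
    return out


def profile_similarity(p: BinaryProfile, q: BinaryProfile, metric: str = "jaccard") -> float:
    """Similarity of two profiles over the same species list.

    ``exact``: 1.0 if identical else 0.0. ``jaccard``: |p AND q| / |p OR q|
    (0.0 when both are empty). ``hamming``: mismatch count (lower is more
    similar).
    """
    if p.species != q.species:
        raise MetabRepoError(
            f"profiles {p.entity_id} and {q.entity_id} have different species lists"
        )
    if metric == "exact":
        return 1.0 if np.array_equal(p.vector, q.vector) else 0.0
    if metric == "hamming":
        return float(np.sum(p.vector != q.vector))
    if metric == "jaccard":
        union = int(np.sum(p.vector | q.vector))
        if union == 0:
            return 0.0
        return float(np.sum(p.vector & q.vector)) / union
    raise MetabRepoError(f"unknown metric {metric!r}")


def find_copartitioned_pairs(
    metab: Sequence[BinaryProfile],
    genes: Sequence[BinaryProfile],
    max_mismatch: int = 0,
    min_presence: int = 2,
    max_presence: Optional[int] = None,
) -> list[CoPartitionPair]:
    """All metabolite/gene profile pairs agreeing within a mismatch budget.

    Profiles with a presence count outside ``[min_presence, max_presence]``
    (default ``[2, n_species - 2]``) are excluded as uninformative. With
    ``max_mismatch=0`` this is exact pattern matching. Pairs come back
    sorted by ascending mismatch, then descending Jaccard, then ids.
    """
    if max_mismatch < 0:
        raise MetabRepoError(f"max_mismatch must be >= 0, got {max_mismatch}")
    if not metab or not genes:
        return []
    species = metab[0].species
    for prof in list(metab) + list(genes):
        if prof.species != species:
            raise MetabRepoError(
                f"profile {prof.entity_id} has a different species list"
            )
    n_species = len(species)
    if max_presence is None:
        max_presence = n_species - 2

    def admissible(profiles: Sequence[BinaryProfile]):
        keep = [p for p in profiles if min_presence <= p.presence <= max_presence]
        if not keep:
            return [], np.zeros((0, n_species), dtype=np.int16)
        return keep, np.stack([p.vector for p in keep]).astype(np.int16)

    m_keep, m_mat = admissible(metab)
    g_keep, g_mat = admissible(genes)
    if not m_keep or not g_keep:
        return []

    # Hamming distance via two rectangular products; intersection for Jaccard.
    inter = m_mat @ g_mat.T
    mism = (m_mat @ (1 - g_mat.T)) + ((1 - m_mat) @ g_mat.T)
    union = inter + mism
    pairs = []
    rows, cols = np.nonzero(mism <= max_mismatch)
    for i, j in zip(rows, cols):
        u = int(union[i, j])
        pairs.append(
            CoPartitionPair(
                metabolite_id=m_keep[i].entity_id,
                gene_id=g_keep[j].entity_id,
                mismatch=int(mism[i, j]),
                jaccard=0.0 if u == 0 else float(inter[i, j]) / u,
            )
        )
    pairs.sort(key=lambda p: (p.mismatch, -p.jaccard, p.metabolite_id, p.gene_id))
    return pairs


def flavonoid_candidate_filter(
    repo: Repository, preds: FilterPredicateSet = FilterPredicateSet()
) -> list[tuple[str, str]]:
    """Mine peaks satisfying the novel-flavonoid predicate conjunction.

    A peak qualifies when (where required) its ``db_hit_count`` annotation is
    present and zero, it carries at least one MS3 spectrum, and its
    ``flavonoid_score_ms3`` annotation meets the threshold (inclusive). A
    missing annotation fails the predicate that needs it. Results are sorted
    by (sample_id, peak_id).
    """
    out = []
    for table in repo.samples:
        for peak in table.peaks:
            if preds.require_no_db_hit:
                if peak.annotations.get("db_hit_count") != 0:
                    continue
            if preds.require_ms3 and not peak.has_ms_level(3):
                continue
            score = peak.annotations.get("flavonoid_score_ms3")
            if score is None or score < preds.min_flavonoid_score:
                continue
            out.append((table.sample_id, peak.peak_id))
    out.sort()
    return out
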