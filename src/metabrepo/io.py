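"""Readers and writers for peak tables, MGF spectra, metadata and bundles.

Formats
-------
Peak tables are delimited text (TSV by default, comma accepted), UTF-8, with a
required header declaring at least ``peak_id, mz, rt, intensity, polarity``.
An optional ``adduct`` column and any further columns are carried through;
extra columns are stored as per-peak annotations (numeric where possible).
A column-mapping dict adapts foreign layouts to the canonical header.

Spectra travel as MGF; the TITLE field encodes ``sample_id|peak_id|msN`` so a
spectrum can be re-attached to its peak. Sample metadata is a TSV with columns
``sample_id, name, category, species, platform``.

A *repository bundle* is a directory with ``repository.json`` (platform id,
total elution time, default tolerances), ``metadata.tsv``, per-sample tables
under ``samples/``, and an optional ``spectra.mgf``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from pyteomics import mgf as _mgf

from .core import (
    MetabRepoError,
    Peak,
    Polarity,
    Repository,
    SampleTable,
    Spectrum,
    ToleranceSpec,
    ValidationError,
)

__all__ = [
    "PeakTableFormatError",
    "SpectrumFormatError",
    "read_peak_table",
    "write_peak_table",
    "read_spectra",
    "write_spectra",
    "attach_spectra",
    "read_metadata",
    "write_metadata",
    "read_repository",
    "write_repository",
]

REQUIRED_COLUMNS = ("peak_id", "mz", "rt", "intensity", "polarity")
OPTIONAL_COLUMNS = ("adduct",)


class PeakTableFormatError(MetabRepoError):
    """A peak-table file does not conform to the documented layout."""


class SpectrumFormatError(MetabRepoError):
    """An MGF block is missing required fields or cannot be attributed."""


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _coerce_annotation(text: str):
    """Store extra columns as int/float when they parse, else raw string."""
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def read_peak_table(
    path: Union[str, Path],
    *,
    sample_id: Optional[str] = None,
    name: str = "",
    category: str = "",
    species: Optional[str] = None,
    sep: Optional[str] = None,
    column_map: Optional[dict] = None,
) -> SampleTable:
    """Read one sample's peak table from delimited text.

    Parameters
    ----------
    sample_id : str, optional
        Defaults to the file stem.
    column_map : dict, optional
        Maps canonical column names to the file's column names, adapting
        foreign layouts (e.g. ``{"mz": "Precursor m/z"}``).
    """
    path = Path(path)
    if not path.exists():
        raise PeakTableFormatError(f"no such file: {path}")
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    if column_map:
        inverse = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inverse)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PeakTableFormatError(f"{path}: missing required column {col!r}")

    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    peaks: list[Peak] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        pid = rec["peak_id"]
        if pid in seen:
            raise PeakTableFormatError(f"{path}:{line_no}: duplicate peak_id {pid!r}")
        seen.add(pid)
        numeric = {}
        for col in ("mz", "rt", "intensity"):
            try:
                numeric[col] = float(rec[col])
            except ValueError:
                raise PeakTableFormatError(
                    f"{path}:{line_no}: non-numeric {col} value {rec[col]!r}"
                ) from None
            if math.isnan(numeric[col]):
                raise PeakTableFormatError(f"{path}:{line_no}: missing {col} value")
        annotations = {
            c: _coerce_annotation(rec[c]) for c in extra_cols if rec[c] != ""
        }
        adduct = rec.get("adduct") or None
        try:
            peaks.append(
                Peak(
                    peak_id=pid,
                    mz=numeric["mz"],
                    rt=numeric["rt"],
                    intensity=numeric["intensity"],
                    polarity=Polarity.coerce(rec["polarity"]),
                    adduct=adduct,
                    annotations=annotations,
                )
            )
        except ValidationError as exc:
            raise PeakTableFormatError(f"{path}:{line_no}: {exc}") from exc

    polarity = peaks[0].polarity if peaks else Polarity.POSITIVE
    try:
        return SampleTable(
            sample_id=sample_id or path.stem,
            name=name,
            category=category,
            species=species,
            polarity=polarity,
            peaks=peaks,
        )
    except ValidationError as exc:
        raise PeakTableFormatError(f"{path}: {exc}") from exc


def write_peak_table(table: SampleTable, path: Union[str, Path], sep: str = "\t") -> None:
    """Write a sample table so that :func:`read_peak_table` round-trips it.

    Floats are written with ``repr`` (shortest exact representation), so the
    round-trip is field-exact. Spectra are not part of the table format; use
    :func:`write_spectra` alongside.
    """
    path = Path(path)
    ann_cols: list[str] = []
    for p in table.peaks:
        for k in p.annotations:
            if k not in ann_cols:
                ann_cols.append(k)
    cols = list(REQUIRED_COLUMNS) + ["adduct"] + ann_cols
    rows = []
    for p in table.peaks:
        row = {
            "peak_id": p.peak_id,
            "mz": repr(p.mz),
            "rt": repr(p.rt),
            "intensity": repr(p.intensity),
            "polarity": p.polarity.value,
            "adduct": p.adduct or "",
        }
        for k in ann_cols:
            v = p.annotations.get(k, "")
            row[k] = repr(v) if isinstance(v, float) else str(v)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")


def read_spectra(path: Union[str, Path]) -> list[tuple[str, str, Spectrum]]:
    """Read an MGF file into ``(sample_id, peak_id, Spectrum)`` entries.

    The TITLE of each block must be ``sample_id|peak_id|msN`` with N in {2, 3};
    PEPMASS carries the precursor m/z.
    """
    path = Path(path)
    out: list[tuple[str, str, Spectrum]] = []
    with _mgf.MGF(str(path)) as reader:
        for i, block in enumerate(reader):
            params = block.get("params", {})
            title = params.get("title", "")
            parts = title.split("|")
            if len(parts) != 3 or not parts[2].lower().startswith("ms"):
                raise SpectrumFormatError(
                    f"{path}: block {i}: unparseable TITLE {title!r} "
                    "(expected sample_id|peak_id|msN)"
                )
            sample_id, peak_id, level_tag = parts
            try:
                ms_level = int(level_tag[2:])
            except ValueError:
                raise SpectrumFormatError(
                    f"{path}: block {i}: bad ms level tag {level_tag!r}"
                ) from None
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                raise SpectrumFormatError(f"{path}: block {i}: missing PEPMASS")
            mz_arr = block.get("m/z array")
            int_arr = block.get("intensity array")
            if mz_arr is None or len(mz_arr) == 0:
                raise SpectrumFormatError(f"{path}: block {i}: no fragment lines")
            try:
                spec = Spectrum(
                    precursor_mz=float(pepmass[0]),
                    ms_level=ms_level,
                    fragments=list(zip(map(float, mz_arr), map(float, int_arr))),
                )
            except ValidationError as exc:
                raise SpectrumFormatError(f"{path}: block {i}: {exc}") from exc
            out.append((sample_id, peak_id, spec))
    return out


def write_spectra(
    entries: list[tuple[str, str, Spectrum]], path: Union[str, Path]
) -> None:
    """Write ``(sample_id, peak_id, Spectrum)`` entries to MGF."""
    blocks = []
    for sample_id, peak_id, spec in entries:
        blocks.append(
            {
                "m/z array": [m for m, _ in spec.fragments],
                "intensity array": [i for _, i in spec.fragments],
                "params": {
                    "title": f"{sample_id}|{peak_id}|ms{spec.ms_level}",
                    "pepmass": spec.precursor_mz,
                },
            }
        )
    _mgf.write(blocks, str(path), file_mode="w")


def attach_spectra(
    tables: list[SampleTable], entries: list[tuple[str, str, Spectrum]]
) -> None:
    """Attach MGF entries to their peaks in-place; unknown refs raise."""
    by_sample = {t.sample_id: t for t in tables}
    for sample_id, peak_id, spec in entries:
        if sample_id not in by_sample:
            raise SpectrumFormatError(f"spectrum refers to unknown sample {sample_id!r}")
        by_sample[sample_id].peak(peak_id).spectra.append(spec)


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, name, category, species, platform)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("sample_id", "name", "category"):
        if col not in df.columns:
            raise PeakTableFormatError(f"{path}: metadata missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise PeakTableFormatError(f"{path}: duplicate sample_id {dup!r} in metadata")
    return df.set_index("sample_id", drop=False)


def write_metadata(repo: Repository, path: Union[str, Path]) -> None:
    rows = [
        {
            "sample_id": t.sample_id,
            "name": t.name,
            "category": t.category,
            "species": t.species or "",
            "platform": repo.platform_id,
        }
        for t in repo.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")


def _tol_to_json(tol: ToleranceSpec) -> dict:
    return {
        "mz_tol": tol.mz_tol,
        "mz_unit": tol.mz_unit,
        "rt_tol": tol.rt_tol,
        "rt_unit": tol.rt_unit,
    }


def write_repository(repo: Repository, directory: Union[str, Path]) -> None:
    """Write a repository bundle (tables, metadata, spectra, platform config)."""
    directory = Path(directory)
    (directory / "samples").mkdir(parents=True, exist_ok=True)
    meta = {
        "platform_id": repo.platform_id,
        "total_elution_time": repo.total_elution_time,
        "default_tolerance": _tol_to_json(repo.default_tolerance),
    }
    (directory / "repository.json").write_text(json.dumps(meta, indent=2))
    write_metadata(repo, directory / "metadata.tsv")
    entries: list[tuple[str, str, Spectrum]] = []
    for t in repo.samples:
        write_peak_table(t, directory / "samples" / f"{t.sample_id}.tsv")
        for p in t.peaks:
            for s in p.spectra:
                entries.append((t.sample_id, p.peak_id, s))
    if entries:
        write_spectra(entries, directory / "spectra.mgf")


def read_repository(directory: Union[str, Path]) -> Repository:
    """Read a repository bundle written by :func:`write_repository`."""
    directory = Path(directory)
    cfg_path = directory / "repository.json"
    if not cfg_path.exists():
        raise PeakTableFormatError(f"{directory}: missing repository.json")
    cfg = json.loads(cfg_path.read_text())
    tol = ToleranceSpec(**cfg["default_tolerance"])
    meta = read_metadata(directory / "metadata.tsv")
    tables = []
    for sample_id, row in meta.iterrows():
        table_path = directory / "samples" / f"{sample_id}.tsv"
        tables.append(
            read_peak_table(
                table_path,
                sample_id=sample_id,
                name=row["name"],
                category=row["category"],
                species=row.get("species") or None,
            )
        )
    mgf_path = directory / "spectra.mgf"
    if mgf_path.exists():
        attach_spectra(tables, read_spectra(mgf_path))
    return Repository(
        platform_id=cfg["platform_id"],
        total_elution_time=float(cfg["total_elution_time"]),
        samples=tables,
        default_tolerance=tol,
    )
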