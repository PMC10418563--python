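"""Spectrum containers and I/O.

MS/MS spectra enter the tool three ways: MGF files (the canonical interchange
format), mzML files (read-only, MS2 scans with a recorded precursor m/z), or
Universal Spectrum Identifiers (USIs) resolved against a local spectrum store.
This module provides the `Spectrum` container used everywhere downstream, the
parsers/writers for those formats, and an optional peak-preprocessing step
(close-peak merging and precursor-region removal).

Intensities are kept raw at I/O time; any weighting (e.g. square-root) is
applied inside the similarity scorer only, so stored libraries remain
transformation-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import base64
import zlib

import numpy as np
from lxml import etree as _etree
from pyteomics import mgf as _pymgf

from .exceptions import (
    MgfFormatError,
    SpectrumNotFoundError,
    StoreLookupError,
    UsiParseError,
)

__all__ = [
    "Peak",
    "Spectrum",
    "UsiRef",
    "SpectrumStore",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "parse_usi",
    "normalize_spectrum",
]


class Peak(NamedTuple):
    """One fragment ion: mass-to-charge (Th) and abundance (arbitrary units)."""

    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A single MS/MS spectrum: precursor ion plus fragment peak list.

    Peaks are stored as parallel numpy arrays sorted ascending by m/z; the
    constructor sorts and validates. ``source_id`` is an opaque provenance
    string (file + scan, USI-formattable for library entries).
    """

    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int | None = None
    source_id: str = ""
    polarity: str | None = None

    def __post_init__(self) -> None:
        mz = np.atleast_1d(np.asarray(self.mz, dtype=float))
        inten = np.atleast_1d(np.asarray(self.intensity, dtype=float))
        if mz.size == 0:
            mz = np.empty(0, dtype=float)
            inten = np.empty(0, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if not (math.isfinite(self.precursor_mz) and self.precursor_mz > 0):
            raise ValueError(f"precursor_mz must be finite and > 0, got {self.precursor_mz}")
        if mz.size:
            if not np.all(np.isfinite(mz)) or np.any(mz <= 0):
                raise ValueError("peak m/z values must be finite and positive")
            if not np.all(np.isfinite(inten)) or np.any(inten < 0):
                raise ValueError("peak intensities must be finite and non-negative")
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.intensity = inten[order]
        if self.polarity is not None and self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be 'positive'/'negative'/None, got {self.polarity!r}")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def is_empty(self) -> bool:
        """True for peak-less spectra (retained at parse time but flagged)."""
        return self.mz.size == 0

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    def with_source_id(self, source_id: str) -> "Spectrum":
        return replace(self, source_id=source_id)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into a list of `Spectrum`.

    One spectrum per BEGIN IONS/END IONS block. ``source_id`` comes from the
    TITLE line when present, else ``<filename>#<block ordinal>``. Blocks with
    no peaks are retained (``is_empty`` flags them). A block without PEPMASS
    raises `MgfFormatError` naming the block.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with _pymgf.MGF(str(path)) as reader:
        for ordinal, block in enumerate(reader, start=1):
            params = block.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MgfFormatError(f"{path.name}: block {ordinal} is missing PEPMASS")
            charge = None
            raw_charge = params.get("charge")
            if raw_charge:
                charge = int(raw_charge[0])
            polarity = None
            if charge is not None and charge != 0:
                polarity = "positive" if charge > 0 else "negative"
            title = str(params.get("title", "")).strip()
            source_id = title if title else f"{path.name}#{ordinal}"
            inten = np.asarray(block["intensity array"], dtype=float)
            spectra.append(
                Spectrum(
                    precursor_mz=float(pepmass[0]),
                    mz=np.asarray(block["m/z array"], dtype=float),
                    intensity=inten,
                    charge=charge,
                    source_id=source_id,
                    polarity=polarity,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF. Peak values use repr precision so that
    ``read_mgf(write_mgf(s))`` round-trips numerically."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            if s.source_id:
                fh.write(f"TITLE={s.source_id}\n")
            fh.write(f"PEPMASS={float(s.precursor_mz)!r}\n")
            if s.charge is not None:
                sign = "+" if s.charge >= 0 else "-"
                fh.write(f"CHARGE={abs(s.charge)}{sign}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{float(m)!r} {float(i)!r}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# mzML (read-only, MS2)
# ---------------------------------------------------------------------------

# cvParam accessions used by the mzML reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv(elem, accession: str):
    for cv in elem.iter("{*}cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value", "")
    return None


def _decode_binary_array(array_elem) -> tuple[str | None, np.ndarray]:
    kind = None
    if _cv(array_elem, _ACC_MZ_ARRAY) is not None:
        kind = "mz"
    elif _cv(array_elem, _ACC_INT_ARRAY) is not None:
        kind = "intensity"
    dtype = "<f4" if _cv(array_elem, _ACC_F32) is not None else "<f8"
    binary = array_elem.find("{*}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if _cv(array_elem, _ACC_ZLIB) is not None:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read MS2 scans with a recorded precursor m/z from an mzML file.

    Minimal streaming reader for the mzML 1.1 spectrum layout (64/32-bit
    float arrays, optional zlib compression). Scans at other MS levels, or
    without a selected precursor ion, are silently skipped; mzML is
    supported read-only.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    for _, elem in _etree.iterparse(str(path), tag="{*}spectrum"):
        try:
            level = _cv(elem, _ACC_MS_LEVEL)
            if level != "2":
                continue
            sel = elem.find(".//{*}selectedIon")
            if sel is None:
                continue
            pmz = _cv(sel, _ACC_SELECTED_MZ)
            if pmz is None:
                continue
            charge = _cv(sel, _ACC_CHARGE)
            polarity = None
            if _cv(elem, _ACC_POSITIVE) is not None:
                polarity = "positive"
            elif _cv(elem, _ACC_NEGATIVE) is not None:
                polarity = "negative"
            mz = np.empty(0)
            inten = np.empty(0)
            for array_elem in elem.iter("{*}binaryDataArray"):
                kind, values = _decode_binary_array(array_elem)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    inten = values
            spectra.append(
                Spectrum(
                    precursor_mz=float(pmz),
                    mz=mz,
                    intensity=inten,
                    charge=int(charge) if charge else None,
                    source_id=str(elem.get("id", f"{path.name}#{len(spectra) + 1}")),
                    polarity=polarity,
                )
            )
        finally:
            elem.clear()
    return spectra


# ---------------------------------------------------------------------------
# USI
# ---------------------------------------------------------------------------

_INDEX_TYPES = ("scan", "index")


@dataclass(frozen=True)
class UsiRef:
    """Parsed Universal Spectrum Identifier (``mzspec:`` convention)."""

    collection: str
    run: str
    index_type: str
    index_value: int

    def __post_init__(self) -> None:
        if self.index_type not in _INDEX_TYPES:
            raise UsiParseError(f"index type must be scan/index, got {self.index_type!r}")
        if self.index_value < 0:
            raise UsiParseError(f"index value must be non-negative, got {self.index_value}")

    def __str__(self) -> str:
        return f"mzspec:{self.collection}:{self.run}:{self.index_type}:{self.index_value}"


def parse_usi(text: str) -> UsiRef:
    """Parse ``mzspec:<collection>:<run>:scan|index:<n>`` into a `UsiRef`.

    Attribute segments after the index are tolerated and ignored. The
    canonical re-serialization (``str(ref)``) is the normalized form.
    """
    parts = text.strip().split(":")
    if not parts or parts[0] != "mzspec":
        raise UsiParseError(f"USI must start with 'mzspec:', got {text!r}")
    if len(parts) < 5:
        raise UsiParseError(f"USI needs >= 5 colon-separated segments, got {len(parts)}")
    collection, run, index_type, raw_value = parts[1], parts[2], parts[3], parts[4]
    if not collection:
        raise UsiParseError("empty collection segment")
    if not run:
        raise UsiParseError("empty run segment")
    if index_type not in _INDEX_TYPES:
        raise UsiParseError(f"index-type segment must be scan/index, got {index_type!r}")
    try:
        value = int(raw_value)
    except ValueError:
        raise UsiParseError(f"index segment is not an integer: {raw_value!r}") from None
    if value < 0:
        raise UsiParseError(f"index segment is negative: {raw_value!r}")
    return UsiRef(collection=collection, run=run, index_type=index_type, index_value=value)


class SpectrumStore:
    """Local stand-in for a remote USI resolver.

    Maps (collection, run) to a parsed spectrum file. ``scan`` indices are
    1-based positions within the run; ``index`` indices are 0-based.
    """

    def __init__(self) -> None:
        self._runs: dict[tuple[str, str], list[Spectrum]] = {}

    def add_run(self, collection: str, run: str, spectra: list[Spectrum]) -> None:
        self._runs[(collection, run)] = list(spectra)

    def add_mgf(self, collection: str, run: str, path: str | Path) -> None:
        self.add_run(collection, run, read_mgf(path))

    def __len__(self) -> int:
        return len(self._runs)

    def resolve(self, ref: UsiRef) -> Spectrum:
        """Return the spectrum a USI points at, provenance set to the USI."""
        key = (ref.collection, ref.run)
        if key not in self._runs:
            raise StoreLookupError(f"unknown collection/run {ref.collection}:{ref.run}")
        spectra = self._runs[key]
        pos = ref.index_value - 1 if ref.index_type == "scan" else ref.index_value
        if not (0 <= pos < len(spectra)):
            raise SpectrumNotFoundError(
                f"{ref.index_type} {ref.index_value} not found in "
                f"{ref.collection}:{ref.run} ({len(spectra)} spectra)"
            )
        return spectra[pos].with_source_id(str(ref))


def resolve_usi(ref: UsiRef, store: SpectrumStore) -> Spectrum:
    """Functional alias for `SpectrumStore.resolve`."""
    return store.resolve(ref)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_spectrum(
    s: Spectrum,
    merge_tol: float = 0.002,
    precursor_window: float | None = 17.0,
) -> Spectrum:
    """Merge close peaks and strip the precursor region.

    Peaks whose consecutive gaps are <= ``merge_tol`` Th are merged into one
    peak (intensity-summed, intensity-weighted mean m/z). Peaks at or above
    ``precursor_mz - precursor_window`` are removed (precursor + small
    neutral-loss clutter such as water loss); pass ``precursor_window=None``
    to disable. The operation is idempotent and preserves m/z ordering.
    """
    mz = s.mz
    inten = s.intensity
    if merge_tol > 0 and mz.size > 1:
        gaps = np.diff(mz)
        # groups are maximal runs of peaks with gap <= merge_tol
        breaks = np.flatnonzero(gaps > merge_tol) + 1
        groups = np.split(np.arange(mz.size), breaks)
        new_mz = np.empty(len(groups))
        new_int = np.empty(len(groups))
        for k, idx in enumerate(groups):
            w = inten[idx]
            total = w.sum()
            new_int[k] = total
            new_mz[k] = np.average(mz[idx], weights=w) if total > 0 else mz[idx].mean()
        mz, inten = new_mz, new_int
    if precursor_window is not None:
        keep = mz < s.precursor_mz - precursor_window
        mz, inten = mz[keep], inten[keep]
    return replace(s, mz=mz, intensity=inten)
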