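"""Reading, validating and preprocessing centroided MALDI-TOF peak lists.

Spectra are handled as centroided (m/z, intensity) pairs over the acquisition
window 700-3700 m/z. Only centroided data are supported; profile-mode mzML is
rejected rather than centroided here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .reference_panels import MZ_MAX, MZ_MIN


class PeakListError(ValueError):
    pass


@dataclass(frozen=True)
class PeakList:
    """A centroided spectrum: ascending unique m/z with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    range_lo: float = MZ_MIN
    range_hi: float = MZ_MAX
    specimen_id: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise PeakListError("m/z and intensity arrays must be 1-D and equal length")
        if mz.size:
            if np.any(np.diff(mz) <= 0):
                raise PeakListError("m/z values must be strictly ascending and unique")
            if mz[0] < self.range_lo or mz[-1] > self.range_hi:
                raise PeakListError(
                    f"peaks outside acquisition range "
                    f"[{self.range_lo:g}, {self.range_hi:g}]")
        if np.any(inten < 0):
            raise PeakListError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_intensity(self) -> float:
        """Intensity of the base (most intense) peak; 0 for an empty spectrum."""
        return float(self.intensity.max()) if len(self) else 0.0

    def with_flags(self, *flags: str) -> "PeakList":
        return replace(self, flags=self.flags | frozenset(flags))


def make_peaklist(mz, intensity=None, **kwargs) -> PeakList:
    """Build a PeakList from possibly unsorted/duplicated pairs.

    Duplicate m/z values keep the maximum intensity. Intensity defaults to 1
    for every peak (convenient for nominal-mass test spectra).
    """
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    intensity = np.asarray(intensity, dtype=float)
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    best = np.zeros(uniq.size)
    np.maximum.at(best, inverse, intensity)
    return PeakList(uniq, best, **kwargs)


def read_peaklist(path: str | Path, dialect: str | None = None, **kwargs) -> PeakList:
    """Read a two-column delimited peak list (m/z, intensity).

    ``dialect`` is "tsv" or "csv"; by default it is inferred from the file
    extension (tab otherwise). An optional single header row is skipped; any
    other non-numeric cell raises with its line number. Duplicate m/z values
    keep the maximum intensity; an empty file yields an empty PeakList.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"

    mzs: list[float] = []
    intens: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=sep), 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise PeakListError(f"{path.name}:{lineno}: expected two columns")
            try:
                mz, inten = float(row[0]), float(row[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise PeakListError(
                    f"{path.name}:{lineno}: non-numeric value in {row[:2]}") from None
            mzs.append(mz)
            intens.append(inten)
    kwargs.setdefault("specimen_id", path.stem)
    return make_peaklist(mzs, intens, **kwargs)


def write_peaklist(pl: PeakList, path: str | Path, dialect: str = "tsv") -> None:
    """Write m/z (4 decimals) and intensity as delimited text."""
    sep = "," if dialect == "csv" else "\t"
    lines = [f"{mz:.4f}{sep}{inten:.6g}" for mz, inten in zip(pl.mz, pl.intensity)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


_ACC_PROFILE = "MS:1000128"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _decode_binary_array(bda) -> np.ndarray:
    import base64
    import zlib

    accessions = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
    binary = bda.find("{*}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path, spectrum_index: int = 0) -> PeakList:
    """Read one centroided spectrum from an mzML file, clipped to the window.

    A focused reader (64/32-bit float arrays, zlib or no compression) built on
    lxml. Profile-mode spectra are rejected with instructions to centroid
    upstream.
    """
    from lxml import etree

    path = Path(path)
    found = -1
    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        found += 1
        if found != spectrum_index:
            spectrum.clear()
            continue
        accessions = {cv.get("accession"): cv
                      for cv in spectrum.iter("{*}cvParam")}
        if _ACC_PROFILE in accessions:
            raise PeakListError(
                "profile-mode spectrum: centroid the data before loading "
                "(peak picking is out of scope)")
        mz = inten = None
        for bda in spectrum.iter("{*}binaryDataArray"):
            local = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
            if _ACC_MZ_ARRAY in local:
                mz = _decode_binary_array(bda)
            elif _ACC_INTENSITY_ARRAY in local:
                inten = _decode_binary_array(bda)
        if mz is None or inten is None:
            raise PeakListError(
                f"{path.name}: spectrum {spectrum_index} lacks m/z or "
                "intensity arrays")
        keep = (mz >= MZ_MIN) & (mz <= MZ_MAX)
        sid = spectrum.get("id", path.stem)
        return make_peaklist(mz[keep], inten[keep], specimen_id=str(sid))
    raise IndexError(f"{path.name}: no spectrum at index {spectrum_index}")


def filter_peaks(pl: PeakList, min_intensity_fraction: float = 0.01) -> PeakList:
    """Drop peaks below a fraction of the base-peak intensity.

    Idempotent at a fixed fraction; an empty spectrum passes through. The
    default 0.01 is a conservative noise floor (no intensity threshold is
    prescribed by the reference workflow, which relies on expert reading).
    """
    if not 0.0 <= min_intensity_fraction <= 1.0:
        raise ValueError("min_intensity_fraction must lie in [0, 1]")
    if not len(pl):
        return pl
    keep = pl.intensity >= min_intensity_fraction * pl.base_intensity
    return replace(pl, mz=pl.mz[keep], intensity=pl.intensity[keep])
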