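"""Peak-list and spectrum I/O, centroiding, and linear mass recalibration.

TSV dialect: tab-separated, dot decimal, UTF-8, header row required
(``mz<TAB>intensity`` with an optional third ``snr`` column).

mzML reading is deliberately minimal (stdlib XML + base64): 64/32-bit
float arrays, optional zlib compression, MS level / polarity / centroid
flags from CV params.  Vendor binary formats are out of scope.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple
from xml.etree import ElementTree

import numpy as np

__all__ = [
    "Peak",
    "PeakList",
    "Spectrum",
    "read_peaklist",
    "write_peaklist",
    "centroid",
    "recalibrate",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: Optional[float] = None


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks, m/z ascending, intensities strictly positive."""

    peaks: Tuple[Peak, ...]
    polarity: str = "negative"
    ms_level: int = 1
    provenance: str = ""

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak m/z values must be strictly increasing")
        if any(p.intensity <= 0 for p in self.peaks):
            raise ValueError("peak intensities must be positive")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @staticmethod
    def from_arrays(
        mz: Sequence[float],
        intensity: Sequence[float],
        snr: Optional[Sequence[float]] = None,
        **meta,
    ) -> "PeakList":
        snrs = snr if snr is not None else [None] * len(mz)
        order = np.argsort(np.asarray(mz, dtype=float), kind="stable")
        peaks = tuple(
            Peak(float(mz[i]), float(intensity[i]), None if snrs[i] is None else float(snrs[i]))
            for i in order
        )
        return PeakList(peaks, **meta)


@dataclass(frozen=True)
class Spectrum:
    """Profile-mode spectrum."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    ms_level: int = 1
    precursor_mz: Optional[float] = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("profile m/z must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


def _read_tsv(path: Path) -> PeakList:
    rows: List[Peak] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or (len(lines) == 1 and not lines[0].strip()):
        return PeakList((), provenance=str(path))
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["mz", "intensity"]:
        raise ValueError(f"{path}: expected header 'mz\\tintensity', got {lines[0]!r}")
    has_snr = len(header) > 2 and header[2] == "snr"
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            mz = float(fields[0])
            intensity = float(fields[1])
            snr = float(fields[2]) if has_snr and len(fields) > 2 and fields[2] else None
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
        if intensity <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive intensity {intensity}")
        rows.append(Peak(mz, intensity, snr))
    rows.sort(key=lambda p: p.mz)
    return PeakList(tuple(rows), provenance=str(path))


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    has_snr = any(p.snr is not None for p in pl)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mz\tintensity" + ("\tsnr" if has_snr else "") + "\n")
        for p in pl:
            row = f"{p.mz:.6f}\t{p.intensity:.6f}"
            if has_snr:
                row += "\t" + ("" if p.snr is None else f"{p.snr:.6f}")
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# mzML (minimal reader)
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

_CV_POLARITY = {"MS:1000129": "negative", "MS:1000130": "positive"}


def _decode_binary(elem) -> np.ndarray:
    accs = {cv.get("accession") for cv in elem.iter(f"{_NS}cvParam")}
    dtype = "<f8" if "MS:1000523" in accs else "<f4"
    data_elem = elem.find(f"{_NS}binary")
    raw = base64.b64decode(data_elem.text or "")
    if "MS:1000574" in accs:  # zlib compression
        raw = zlib.decompress(raw)
    item = np.dtype(dtype)
    n = len(raw) // item.itemsize
    return np.frombuffer(raw, dtype=item, count=n).astype(float)


def _read_mzml(path: Path) -> List[PeakList | Spectrum]:
    tree = ElementTree.parse(path)
    out: List[PeakList | Spectrum] = []
    for spec in tree.iter(f"{_NS}spectrum"):
        accs = {
            cv.get("accession"): cv.get("value")
            for cv in spec.findall(f"{_NS}cvParam")
        }
        polarity = next(
            (pol for acc, pol in _CV_POLARITY.items() if acc in accs), "unknown"
        )
        ms_level = int(accs.get("MS:1000511", 1))
        centroided = "MS:1000127" in accs
        precursor = None
        sel = spec.find(
            f"{_NS}precursorList/{_NS}precursor/{_NS}selectedIonList/{_NS}selectedIon"
        )
        if sel is not None:
            for cv in sel.findall(f"{_NS}cvParam"):
                if cv.get("accession") == "MS:1000744":
                    precursor = float(cv.get("value"))
        mz = inten = None
        for arr in spec.iter(f"{_NS}binaryDataArray"):
            arr_accs = {cv.get("accession") for cv in arr.findall(f"{_NS}cvParam")}
            if "MS:1000514" in arr_accs:
                mz = _decode_binary(arr)
            elif "MS:1000515" in arr_accs:
                inten = _decode_binary(arr)
        if mz is None or inten is None:
            continue
        if centroided:
            keep = inten > 0
            out.append(
                PeakList.from_arrays(
                    mz[keep], inten[keep], polarity=polarity,
                    ms_level=ms_level, provenance=str(path),
                )
            )
        else:
            out.append(
                Spectrum(mz, inten, polarity=polarity, ms_level=ms_level,
                         precursor_mz=precursor)
            )
    return out


def read_peaklist(path: str | Path, format: Optional[str] = None):
    """Read a peak list (TSV) or spectra (mzML).

    Returns a :class:`PeakList` for TSV input; for mzML, a list with one
    :class:`PeakList` (centroided) or :class:`Spectrum` (profile) per
    spectrum element.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Centroiding
# ---------------------------------------------------------------------------


def centroid(
    spec: Spectrum, snr_threshold: float = 3.0, noise_window: float = 20.0
) -> PeakList:
    """Peak-pick a profile spectrum.

    Local maxima whose intensity is at least ``snr_threshold`` times the
    robust local noise (1.4826 x MAD of intensities within ``noise_window``
    Da) become centroids; each centroid m/z is the intensity-weighted mean
    over the contiguous region above half the apex intensity.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    mz, inten = spec.mz, spec.intensity
    if mz.size == 0:
        raise ValueError("profile spectrum is empty")
    apex = np.flatnonzero(
        (inten[1:-1] > 0)
        & (inten[1:-1] >= inten[:-2])
        & (inten[1:-1] > inten[2:])
    ) + 1

    peaks_mz: List[float] = []
    peaks_int: List[float] = []
    peaks_snr: List[float] = []
    for i in apex:
        lo = np.searchsorted(mz, mz[i] - noise_window / 2)
        hi = np.searchsorted(mz, mz[i] + noise_window / 2)
        window = inten[lo:hi]
        med = np.median(window)
        noise = 1.4826 * np.median(np.abs(window - med))
        snr = inten[i] / noise if noise > 0 else float("inf")
        if snr < snr_threshold:
            continue
        half = inten[i] / 2.0
        l = i
        while l > 0 and inten[l - 1] >= half:
            l -= 1
        r = i
        while r < len(inten) - 1 and inten[r + 1] >= half:
            r += 1
        seg_mz, seg_int = mz[l:r + 1], inten[l:r + 1]
        peaks_mz.append(float(np.average(seg_mz, weights=seg_int)))
        peaks_int.append(float(inten[i]))
        peaks_snr.append(float(snr))

    # merge apexes that collapsed to the same centroid region
    order = np.argsort(peaks_mz)
    uniq: List[Tuple[float, float, float]] = []
    for j in order:
        if uniq and abs(peaks_mz[j] - uniq[-1][0]) < 1e-9:
            continue
        uniq.append((peaks_mz[j], peaks_int[j], peaks_snr[j]))
    return PeakList(
        tuple(Peak(m, i, s) for m, i, s in uniq),
        polarity=spec.polarity,
        ms_level=spec.ms_level,
        provenance="centroid",
    )


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------


def recalibrate(
    pl: PeakList, references: Sequence[Tuple[float, float]]
) -> Tuple[PeakList, np.ndarray]:
    """Linear least-squares m/z recalibration.

    ``references`` are (observed m/z, true m/z) pairs; returns the corrected
    peak list and the post-fit residuals at the references (true - corrected).
    """
    if len(references) < 2:
        raise ValueError("at least 2 reference pairs are required")
    obs = np.array([r[0] for r in references], dtype=float)
    true = np.array([r[1] for r in references], dtype=float)
    if np.ptp(obs) <= 0:
        raise ValueError("reference observed m/z values are degenerate")
    slope, intercept = np.polyfit(obs, true, 1)
    residuals = true - (slope * obs + intercept)
    corrected = tuple(
        replace(p, mz=slope * p.mz + intercept) for p in pl
    )
    return PeakList(corrected, pl.polarity, pl.ms_level, pl.provenance), residuals
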