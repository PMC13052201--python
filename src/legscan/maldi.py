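"""Peak integration and specificity-matrix construction from MALDI-TOF spectra.

Cyclization reactions are quantified from the relative peak areas of the
unprocessed precursor, the linear hydrolysis product and the cyclic product;
the sum of the three areas stands in for the total peptide signal.  Site/
residue specificity is expressed as fold change relative to the alanine
variant at the same scanned position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import DEMETHYL_MONO, PeptideVariant, SpeciesSet

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "ReactionQuant",
    "SpecificityMatrix",
    "READOUTS",
    "read_spectrum",
    "integrate_peak",
    "quantify_reaction",
    "build_specificity_matrix",
    "fold_change",
]


@dataclass
class Spectrum:
    """A centroid or profile mass spectrum (m/z ascending, intensity >= 0)."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size


def read_spectrum(path: str | Path, format: str = "xy") -> Spectrum:
    """Read a spectrum from two-column text (``xy``) or mzML.

    Unsorted rows are sorted ascending with a warning.  Non-numeric rows or
    negative intensities raise with the offending line number.
    """
    path = Path(path)
    if format == "xy":
        mz_list, int_list = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.replace(",", " ").split()
                try:
                    x, y = float(parts[0]), float(parts[1])
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: cannot parse row {s!r}") from exc
                if y < 0:
                    raise ValueError(f"{path}:{lineno}: negative intensity {y}")
                mz_list.append(x)
                int_list.append(y)
        mz = np.array(mz_list)
        inten = np.array(int_list)
    elif format == "mzml":
        mz, inten = _read_mzml_first_spectrum(path)
        if np.any(inten < 0):
            raise ValueError(f"{path}: negative intensity in mzML spectrum")
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    order = np.argsort(mz, kind="stable")
    if not np.array_equal(order, np.arange(mz.size)):
        warnings.warn(f"{path}: m/z not sorted; sorting ascending", stacklevel=2)
        mz, inten = mz[order], inten[order]
    return Spectrum(mz=mz, intensity=inten, label=path.stem)


def _read_mzml_first_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Decode the first spectrum of an mzML file (m/z + intensity arrays).

    Handles the standard binary encodings: 32/64-bit float, optional zlib
    compression.
    """
    import base64
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = etree.parse(str(path))
    spectrum = tree.find(f".//{ns}spectrum")
    if spectrum is None:
        raise ValueError(f"{path}: no spectrum element in mzML")
    arrays: dict[str, np.ndarray] = {}
    for bda in spectrum.iter(f"{ns}binaryDataArray"):
        accessions = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
        binary = bda.find(f"{ns}binary")
        raw = base64.b64decode(binary.text or "")
        if "MS:1000574" in accessions:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = np.float32 if "MS:1000521" in accessions else np.float64
        values = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)
        if "MS:1000514" in accessions:
            arrays["mz"] = values
        elif "MS:1000515" in accessions:
            arrays["intensity"] = values
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError(f"{path}: mzML spectrum lacks m/z or intensity array")
    return arrays["mz"], arrays["intensity"]


def integrate_peak(
    spectrum: Spectrum,
    center_mz: float,
    window_da: float = 1.0,
    baseline: str = "local_linear",
) -> float:
    """Trapezoidal peak area over ``center_mz ± window_da``.

    With ``baseline='local_linear'`` a straight line through the interpolated
    intensities at the two window edges is subtracted first.  The result is
    clamped at zero; a window falling outside the spectrum yields area 0 with
    a warning.
    """
    if window_da <= 0:
        raise ValueError("window_da must be positive")
    if baseline not in ("none", "local_linear"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    lo, hi = center_mz - window_da, center_mz + window_da
    if hi < spectrum.mz[0] or lo > spectrum.mz[-1]:
        warnings.warn(
            f"window [{lo:.3f}, {hi:.3f}] outside spectrum range; area set to 0",
            stacklevel=2,
        )
        return 0.0
    mask = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    x = spectrum.mz[mask]
    y = spectrum.intensity[mask]
    # include interpolated edge points so the integral covers the full window
    y_lo = float(np.interp(lo, spectrum.mz, spectrum.intensity))
    y_hi = float(np.interp(hi, spectrum.mz, spectrum.intensity))
    x = np.concatenate(([max(lo, spectrum.mz[0])], x, [min(hi, spectrum.mz[-1])]))
    y = np.concatenate(([y_lo], y, [y_hi]))
    keep = np.concatenate(([True], np.diff(x) > 0))
    x, y = x[keep], y[keep]
    if x.size < 2:
        return 0.0
    if baseline == "local_linear":
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        y = y - base
    area = float(np.trapezoid(y, x))
    return max(area, 0.0)


@dataclass
class ReactionQuant:
    """Areas and area fractions of one variant's three reaction species."""

    area_precursor: float
    area_linear: float
    area_cyclic: float
    variant_id: str = ""

    @property
    def total(self) -> float:
        return self.area_precursor + self.area_linear + self.area_cyclic

    @property
    def defined(self) -> bool:
        return self.total > 0

    def _frac(self, a: float) -> float:
        if not self.defined:
            return float("nan")
        return a / self.total

    @property
    def f_precursor(self) -> float:
        return self._frac(self.area_precursor)

    @property
    def f_linear(self) -> float:
        return self._frac(self.area_linear)

    @property
    def f_cyclic(self) -> float:
        return self._frac(self.area_cyclic)


READOUTS = ("cyclic", "total_lytic", "linear")


def _readout_value(q: ReactionQuant, readout: str) -> float:
    if readout == "cyclic":
        return q.f_cyclic
    if readout == "linear":
        return q.f_linear
    if readout == "total_lytic":
        return q.f_linear + q.f_cyclic
    raise ValueError(f"unknown readout {readout!r}; expected one of {READOUTS}")


def quantify_reaction(
    spectrum: Spectrum,
    species: SpeciesSet,
    window_da: float = 1.0,
    include_satellites: bool = False,
    baseline: str = "local_linear",
) -> ReactionQuant:
    """Integrate the precursor/linear/cyclic peaks of one reaction spectrum.

    Satellite (Δ14) areas are added to their parent only when
    ``include_satellites`` is set and the species set carries them.
    """
    areas = {}
    for key in ("precursor", "linear", "cyclic"):
        sp = species[key]
        a = integrate_peak(spectrum, sp.mz_mono, window_da, baseline)
        if include_satellites:
            sat = species.species.get(key + "_demethyl")
            sat_mz = sat.mz_mono if sat is not None else sp.mz_mono + DEMETHYL_MONO
            a += integrate_peak(spectrum, sat_mz, window_da, baseline)
        areas[key] = a
    q = ReactionQuant(
        area_precursor=areas["precursor"],
        area_linear=areas["linear"],
        area_cyclic=areas["cyclic"],
        variant_id=species.variant_id,
    )
    if not q.defined:
        log.warning("total area 0 for %s: fractions undefined", species.variant_id)
    return q


def fold_change(quant_a: ReactionQuant, quant_b: ReactionQuant, readout: str = "cyclic") -> float:
    """Readout ratio a/b (e.g. cyclic-product fold change over wild type)."""
    denom = _readout_value(quant_b, readout)
    if not denom > 0:
        raise ZeroDivisionError(f"reference quant has non-positive {readout} readout")
    return _readout_value(quant_a, readout) / denom


@dataclass
class SpecificityMatrix:
    """Site x residue fold-change matrix, normalized to the Ala variant per site.

    ``values`` is a DataFrame with P-site rows and residue columns; undefined
    cells (Ala readout zero, or missing variant) are NaN and flagged in
    ``undefined`` / ``missing``.
    """

    values: pd.DataFrame
    readout: str
    undefined: set[tuple[str, str]] = field(default_factory=set)
    missing: set[tuple[str, str]] = field(default_factory=set)

    def cell(self, site: str, residue: str) -> float:
        return float(self.values.loc[site, residue])


def build_specificity_matrix(
    quants: dict[str, ReactionQuant],
    library: list[PeptideVariant],
    readout: str = "cyclic",
) -> SpecificityMatrix:
    """Build the Ala-normalized specificity matrix for one readout.

    ``quants`` maps variant ``library_id`` to its quantification.  Every cell
    is readout(variant) / readout(Ala variant of the same site); cells whose
    Ala reference is zero are flagged undefined rather than infinite.
    """
    if readout not in READOUTS:
        raise ValueError(f"unknown readout {readout!r}; expected one of {READOUTS}")
    sites: list[str] = []
    residues: set[str] = set()
    by_cell: dict[tuple[str, str], str] = {}
    for v in library:
        if v.varied_site is None or v.varied_residue is None:
            raise ValueError(f"variant {v.library_id!r} has no site/residue annotation")
        if v.varied_site not in sites:
            sites.append(v.varied_site)
        residues.add(v.varied_residue)
        cell = (v.varied_site, v.varied_residue)
        if cell in by_cell:
            raise ValueError(f"duplicate variant for cell {cell}")
        by_cell[cell] = v.library_id
    cols = sorted(residues)
    values = pd.DataFrame(np.nan, index=sites, columns=cols)
    undefined: set[tuple[str, str]] = set()
    missing: set[tuple[str, str]] = set()
    for site in sites:
        ala_id = by_cell.get((site, "A"))
        if ala_id is None or ala_id not in quants:
            raise ValueError(f"no alanine reference variant for site {site}")
        ref = _readout_value(quants[ala_id], readout)
        for res in cols:
            cell = (site, res)
            vid = by_cell.get(cell)
            if vid is None or vid not in quants:
                missing.add(cell)
                continue
            val = _readout_value(quants[vid], readout)
            if not ref > 0 or np.isnan(val):
                undefined.add(cell)
                continue
            values.loc[site, res] = val / ref
    return SpecificityMatrix(values=values, readout=readout, undefined=undefined, missing=missing)
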