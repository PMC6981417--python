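"""MS1 peak-list annotation against the theoretical ion library.

Matching is isotope-envelope aware: MALDI-QIT spectra of gangliosides
show broad isotope clusters, and two species whose monoisotopic lines
are ~1 Da apart (e.g. the mono-lactonized OAcGD2 Cer16 ion at 1669.88
and OAcGM1 Cer24 at 1670.97) merge into a single apex-picked signal.
A library ion is therefore reported as a candidate for an observed peak
when its monoisotopic m/z falls within the tolerance of the peak itself
or of the peak shifted up by k isotope spacings (k small, default 1).
Candidates are never auto-selected; isobar resolution is delegated to
the MS/MS module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import IonSpecies, ValidationError

__all__ = [
    "Spectrum",
    "Candidate",
    "Annotation",
    "PeaklistParseError",
    "EmptySpectrumError",
    "read_peaklist",
    "match_peaks",
    "presence_table",
    "annotation_report",
    "ISOTOPE_SPACING",
]

# 13C-12C spacing, the dominant isotope step for these lipids
ISOTOPE_SPACING = 1.00336

DEFAULT_SCAN_RANGE = (1000.0, 3000.0)


class PeaklistParseError(ValueError):
    """Malformed peak-list input; message carries line numbers."""


class EmptySpectrumError(ValueError):
    """Peak list contained no usable peaks."""


@dataclass
class Spectrum:
    """A centroided peak list with optional MS/MS children.

    ``truth`` is an optional per-peak ground-truth label list attached by
    the simulators (None for contaminant peaks); analysis code ignores it.
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    msms: dict[float, "Spectrum"] = field(default_factory=dict)
    truth: Optional[list] = None
    mz_range: Optional[tuple[float, float]] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D and aligned")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.truth is not None:
            self.truth = [self.truth[i] for i in order]
        if self.mz_range is not None:
            lo, hi = self.mz_range
            if self.n_peaks and (self.mz[0] < lo or self.mz[-1] > hi):
                raise ValidationError(
                    f"peaks outside scan range [{lo}, {hi}]")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.n_peaks else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})

    def write_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def read_peaklist(
    path,
    format: Optional[str] = None,
    sample_id: Optional[str] = None,
    mz_range: Optional[tuple[float, float]] = None,
) -> Spectrum:
    """Read a two-column (m/z, intensity) CSV/TSV or a centroided mzML.

    A single header line is auto-detected.  Malformed rows raise
    PeaklistParseError with their line numbers.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv",
                  "mzml": "mzml"}.get(suffix, "csv")
    if format == "mzml":
        return _read_mzml(path, sample_id, mz_range)
    sep = "\t" if format == "tsv" else ","
    mzs, intens, errors = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(sep)]
            if len(cells) < 2:
                errors.append(f"line {lineno}: expected 2 columns")
                continue
            try:
                mzs.append(float(cells[0]))
                intens.append(float(cells[1]))
            except ValueError:
                if lineno == 1 and not mzs:
                    continue  # header line
                errors.append(f"line {lineno}: non-numeric cell in {cells[:2]}")
    if errors:
        raise PeaklistParseError(
            f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    if not mzs:
        raise EmptySpectrumError(f"{path}: no peaks parsed")
    return Spectrum(sample_id, np.array(mzs), np.array(intens),
                    mz_range=mz_range)


def _read_mzml(path, sample_id, mz_range):
    """Minimal centroided-mzML reader (64/32-bit float arrays, plain or
    zlib-compressed).  Takes the first non-empty MS1 spectrum."""
    import base64
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = etree.parse(str(path))
    for spec in tree.iter(f"{ns}spectrum"):
        level = 1
        for cv in spec.iterfind(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000511":
                level = int(cv.get("value"))
        if level != 1:
            continue
        arrays = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            raw = base64.b64decode((bda.findtext(f"{ns}binary") or "").strip())
            if "MS:1000574" in accs:  # zlib
                raw = zlib.decompress(raw)
            dtype = "<f4" if "MS:1000521" in accs else "<f8"
            data = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in accs:
                arrays["mz"] = data
            elif "MS:1000515" in accs:
                arrays["intensity"] = data
        if arrays.get("mz") is not None and arrays["mz"].size:
            return Spectrum(sample_id, arrays["mz"], arrays["intensity"],
                            mz_range=mz_range)
    raise EmptySpectrumError(f"{path}: no non-empty MS1 spectrum found")


@dataclass(frozen=True)
class Candidate:
    """One library ion explaining a peak; ``isotope_offset`` counts the
    isotope layers assumed between the observed apex and the ion's
    monoisotopic line; ``delta_mz`` is the residual after that shift."""

    ion: IonSpecies
    delta_mz: float
    isotope_offset: int = 0


@dataclass
class Annotation:
    peak_mz: float
    intensity: float
    candidates: list[Candidate]

    @property
    def status(self) -> str:
        if not self.candidates:
            return "unassigned"
        return "unique" if len(self.candidates) == 1 else "isobaric"

    @property
    def top(self) -> Optional[Candidate]:
        return self.candidates[0] if self.candidates else None


def match_peaks(
    spectrum: Spectrum,
    library: Sequence[IonSpecies],
    tolerance: float = 0.3,
    max_isotope_layers: int = 1,
    isotope_spacing: float = ISOTOPE_SPACING,
) -> list[Annotation]:
    """Annotate every peak; none are dropped.

    Candidates are sorted by |residual|, ties broken by ascending species
    complexity then label, so output is deterministic.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be > 0")
    if not library:
        raise ValidationError("library must be non-empty")
    lib_mz = np.array([ion.mz for ion in library])
    order = np.argsort(lib_mz, kind="stable")
    lib_mz = lib_mz[order]
    lib = [library[i] for i in order]

    annotations = []
    for mz, inten in zip(spectrum.mz, spectrum.intensity):
        best: dict[int, Candidate] = {}
        for k in range(max_isotope_layers + 1):
            target = mz + k * isotope_spacing
            lo = np.searchsorted(lib_mz, target - tolerance, side="left")
            hi = np.searchsorted(lib_mz, target + tolerance, side="right")
            for j in range(lo, hi):
                delta = lib_mz[j] - target
                prev = best.get(j)
                if prev is None or abs(delta) < abs(prev.delta_mz):
                    best[j] = Candidate(lib[j], float(delta), k)
        cands = sorted(
            best.values(),
            key=lambda c: (abs(c.delta_mz), c.ion.complexity, c.ion.label),
        )
        annotations.append(Annotation(float(mz), float(inten), cands))
    return annotations


def presence_table(
    annotations_by_sample: Mapping[str, Sequence[Annotation]],
    trace_threshold: float = 0.01,
    species: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Sample x species matrix of {present, trace, absent}.

    A species is supported by the peaks for which it is the top
    candidate; it is 'trace' when its strongest supporting peak falls
    below ``trace_threshold`` of the sample's base peak.
    """
    if not 0 < trace_threshold < 1:
        raise ValidationError("trace_threshold must lie in (0, 1)")
    if not annotations_by_sample:
        raise ValidationError("at least one annotated sample required")
    all_species: set[str] = set(species or [])
    support: dict[str, dict[str, float]] = {}
    for sample, annots in annotations_by_sample.items():
        base = max((a.intensity for a in annots), default=0.0)
        strongest: dict[str, float] = {}
        for a in annots:
            if a.top is None:
                continue
            label = a.top.ion.species_label
            rel = a.intensity / base if base > 0 else 0.0
            strongest[label] = max(strongest.get(label, 0.0), rel)
        support[sample] = strongest
        all_species.update(strongest)
    cols = species if species is not None else sorted(all_species)
    table = pd.DataFrame("absent", index=list(annotations_by_sample),
                         columns=list(cols))
    for sample, strongest in support.items():
        for label, rel in strongest.items():
            if label not in table.columns:
                continue
            table.loc[sample, label] = (
                "present" if rel >= trace_threshold else "trace")
    table.index.name = "sample"
    return table


def annotation_report(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Flat report: one row per peak with its candidate list."""
    rows = []
    for a in annotations:
        rows.append({
            "peak_mz": a.peak_mz,
            "intensity": a.intensity,
            "status": a.status,
            "candidates": "; ".join(
                f"{c.ion.label} (d={c.delta_mz:+.3f}, k={c.isotope_offset})"
                for c in a.candidates),
        })
    return pd.DataFrame(rows)
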