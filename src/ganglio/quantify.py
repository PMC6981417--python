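"""Relative quantification of ganglioside species from apex intensities.

The quantification statistic is the peak apex (maximum height), summed
per species over its ceramide variants and adduct states, then
normalized to 100% of the total ganglioside content per sample.  The
O-acetylated fraction is the summed percentage of species carrying the
OAc prefix.  Isobaric peaks are apportioned by MS/MS-derived shares
when available and split equally (with a flag) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotate import Annotation
from .chem import ValidationError

__all__ = [
    "AggregationResult",
    "AbundanceTable",
    "EmptyTableError",
    "UndefinedAbundanceError",
    "aggregate_species",
    "relative_abundance",
    "abundance_table",
]


class EmptyTableError(ValueError):
    """All peaks unassigned; nothing to aggregate."""


class UndefinedAbundanceError(ValueError):
    """Total intensity is zero; relative abundances undefined."""


@dataclass
class AggregationResult:
    """Per-species summed apex intensity for one sample.

    ``fallback_peaks`` indexes the isobaric peaks that were split equally
    for lack of MS/MS shares.
    """

    intensities: pd.Series
    fallback_peaks: list[int] = field(default_factory=list)


def aggregate_species(
    annotations: Sequence[Annotation],
    isobar_shares: Optional[Mapping[int, Mapping[str, float]]] = None,
) -> AggregationResult:
    """Sum peak apex intensity per species label.

    ``isobar_shares`` maps an annotation index to {ion label: share}
    (as produced by ``msms.split_isobaric_intensity``); shares for a
    peak are applied to its intensity before summation.  Unassigned
    peaks are excluded; isobaric peaks without shares are split equally
    among their candidates and flagged.
    """
    isobar_shares = isobar_shares or {}
    totals: dict[str, float] = {}
    fallback: list[int] = []
    n_assigned = 0
    for idx, ann in enumerate(annotations):
        if not ann.candidates:
            continue
        n_assigned += 1
        if ann.status == "unique":
            shares = {ann.candidates[0].ion.species_label: 1.0}
        elif idx in isobar_shares:
            shares = {}
            by_label = {c.ion.label: c.ion.species_label
                        for c in ann.candidates}
            for ion_label, share in isobar_shares[idx].items():
                sp = by_label.get(ion_label, ion_label)
                shares[sp] = shares.get(sp, 0.0) + share
        else:
            fallback.append(idx)
            n = len(ann.candidates)
            shares = {}
            for c in ann.candidates:
                sp = c.ion.species_label
                shares[sp] = shares.get(sp, 0.0) + 1.0 / n
        for sp, share in shares.items():
            totals[sp] = totals.get(sp, 0.0) + ann.intensity * share
    if n_assigned == 0:
        raise EmptyTableError("every peak is unassigned")
    series = pd.Series(totals, dtype=float).sort_index()
    return AggregationResult(series, fallback)


@dataclass
class AbundanceTable:
    """Sample x species relative abundances in % of total content.

    Rows sum to 100; ``oac_fraction`` is the per-sample percentage held
    by O-acetylated species; ``trace`` flags entries below the trace
    floor (still included in the totals).
    """

    data: pd.DataFrame
    oac_fraction: pd.Series
    trace: pd.DataFrame

    def species_value(self, sample: str, species: str) -> Optional[float]:
        if species not in self.data.columns:
            return None
        value = self.data.loc[sample, species]
        return None if pd.isna(value) else float(value)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out["OAc_fraction"] = self.oac_fraction
        out.to_csv(path, sep="\t")

    def oac_summary(self) -> pd.DataFrame:
        """Two-column OAc vs non-OAc percentage summary (pie-chart view)."""
        return pd.DataFrame({
            "OAc": self.oac_fraction,
            "non-OAc": 100.0 - self.oac_fraction,
        })


def relative_abundance(
    intensities: pd.Series | AggregationResult,
    sample_id: str = "sample",
    trace_floor: float = 0.001,
) -> AbundanceTable:
    """Normalize per-species intensities to percentages for one sample."""
    if isinstance(intensities, AggregationResult):
        intensities = intensities.intensities
    if intensities.empty or (intensities > 0).sum() == 0:
        raise UndefinedAbundanceError("total intensity is zero")
    if (intensities < 0).any():
        raise ValidationError("intensities must be >= 0")
    total = float(intensities.sum())
    pct = intensities / total * 100.0
    pct = pct * (100.0 / pct.sum())  # exact renormalization
    oac = float(pct[[s for s in pct.index if s.startswith("OAc")]].sum())
    data = pct.to_frame(name=sample_id).T
    trace = data < trace_floor * 100.0
    data.index.name = "sample"
    return AbundanceTable(
        data=data,
        oac_fraction=pd.Series({sample_id: oac}, name="OAc_fraction"),
        trace=trace,
    )


def abundance_table(
    per_sample: Mapping[str, pd.Series | AggregationResult],
    trace_floor: float = 0.001,
) -> AbundanceTable:
    """Stack single-sample abundances into one multi-sample table."""
    if not per_sample:
        raise EmptyTableError("no samples provided")
    parts = [relative_abundance(v, sample_id=k, trace_floor=trace_floor)
             for k, v in per_sample.items()]
    data = pd.concat([p.data for p in parts]).fillna(0.0)
    oac = pd.concat([p.oac_fraction for p in parts])
    trace = pd.concat([p.trace for p in parts]).astype("boolean")
    trace = trace.fillna(True).astype(bool)
    data.index.name = "sample"
    return AbundanceTable(data, oac, trace)
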