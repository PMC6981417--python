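"""Ground-truthed synthetic inputs: MS1 spectra, MS/MS spectra, Ct tables.

The MS1 generator emulates negative-mode MALDI spectra of acidic
glycosphingolipid extracts: one centroid per (species, ceramide
variant, adduct state) with apex intensity proportional to the species'
true relative abundance, multiplicative log-normal intensity noise
(shot-to-shot variation), Gaussian m/z jitter, and uniform-random
contaminant peaks in the scan range.  At zero noise every generator is
an exact inverse of the corresponding analysis stage, which is the
round-trip surface the test-suite leans on.

Scenario presets encode the qualitative expression patterns seen in
neuroectoderm-derived cell lines: an a-series-dominant parental
pattern, an Hs 578T-like pattern with OAcGM1/OAcGD2, and a GD3-synthase
over-expressing pattern rich in b/c-series and O-acetylated species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import DEFAULT_SCAN_RANGE, Spectrum
from .chem import (
    AdductState,
    CeramideSpec,
    IonSpecies,
    ValidationError,
    composition_of,
    max_dehydrations,
)
from .msms import predict_fragments
from .pathway import CtTable, PATHWAY_GENES

__all__ = [
    "GroundTruthProfile",
    "SCENARIOS",
    "simulate_profile",
    "simulate_ms1",
    "simulate_msms",
    "simulate_qpcr",
]

# species label -> true % of total ganglioside content (sums to 100)
SCENARIOS: dict[str, dict[str, float]] = {
    # a-series only
    "parental": {"GM3": 30.0, "GM2": 45.0, "GM1": 25.0},
    # a-series dominant with OAcGM1/OAcGD2/OAcGD3/OAcGT3 (Hs 578T-like)
    "hs578t_like": {
        "GM3": 15.0, "GM2": 30.0, "GM1": 30.0, "GD2": 4.0,
        "OAcGM1": 8.0, "OAcGD2": 7.0, "OAcGD3": 3.0, "OAcGT3": 3.0,
    },
    # GD3-synthase over-expression: b/c-series plus OAc species
    "gd3s_plus": {
        "GM3": 8.0, "GM2": 10.0, "GM1": 6.0, "GD3": 14.0, "GD2": 12.0,
        "GD1b": 6.0, "GT3": 8.0, "GT2": 5.0,
        "OAcGD3": 17.0, "OAcGD2": 8.0, "OAcGT3": 5.0, "OAcGT2": 1.0,
    },
}

# ceramide mixture shared by default: C16/C24 major, minors per the
# observed fatty-acid distribution, C24 also mono-unsaturated
DEFAULT_CERAMIDE_WEIGHTS = {
    "d18:1/16:0": 0.45,
    "d18:1/24:0": 0.30,
    "d18:1/24:1": 0.10,
    "d18:1/18:0": 0.06,
    "d18:1/22:0": 0.05,
    "d18:1/14:0": 0.04,
}

# adduct-state weights by sialyl count: oligosialylated species are
# observed mainly as their lactones
_DEHYDRATION_WEIGHTS = {
    1: {0: 1.0},
    2: {1: 0.85, 0: 0.15},
    3: {2: 0.85, 1: 0.15},
}

_DEFAULT_ACETYL_POSITIONS = {
    "OAcGM1": "inner",
    "OAcGD3": "terminal",
    "OAcGD2": "inner",
    "OAcGT3": "terminal",
    "OAcGT2": "inner",
}


@dataclass(frozen=True)
class GroundTruthProfile:
    """True relative abundances plus the nuisance structure of a sample."""

    abundances: Mapping[str, float]  # species label -> % (sums to 100)
    ceramide_weights: Mapping[str, Mapping[str, float]]  # per species
    acetyl_positions: Mapping[str, str]  # OAc label -> position
    adduct_weights: Mapping[str, Mapping[int, float]]  # label -> {n_dehyd: w}
    seed: int = 0

    def __post_init__(self):
        total = sum(self.abundances.values())
        if abs(total - 100.0) > 1e-6:
            raise ValidationError(
                f"abundances must sum to 100, got {total}")
        if any(v < 0 for v in self.abundances.values()):
            raise ValidationError("abundances must be >= 0")
        for label, weights in self.ceramide_weights.items():
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValidationError(
                    f"ceramide weights for {label} must sum to 1")

    @property
    def species_labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.abundances))

    def ions(self) -> list[tuple[IonSpecies, float]]:
        """Expected (ion, relative intensity weight) pairs, noise-free."""
        out = []
        for label, abundance in self.abundances.items():
            if abundance <= 0:
                continue
            acetylated = label.startswith("OAc")
            name = label[3:] if acetylated else label
            species = composition_of(name)
            pos = self.acetyl_positions.get(label) if acetylated else None
            for cer_label, w_cer in self.ceramide_weights[label].items():
                cer = CeramideSpec.parse(cer_label)
                for n_dehyd, w_add in self.adduct_weights[label].items():
                    adduct = AdductState(
                        n_dehydrations=n_dehyd,
                        n_acetyl=1 if acetylated else 0,
                        acetyl_position=pos,
                    )
                    ion = IonSpecies.create(species, cer, adduct)
                    out.append((ion, abundance * w_cer * w_add))
        return out


def simulate_profile(
    scenario: str | Mapping[str, float],
    seed: int = 0,
    acetyl_positions: Optional[Mapping[str, str]] = None,
) -> GroundTruthProfile:
    """Build a reproducible ground-truth profile from a preset name or an
    explicit {species label: %} mapping."""
    if isinstance(scenario, str):
        try:
            abundances = dict(SCENARIOS[scenario])
        except KeyError:
            raise ValidationError(
                f"unknown scenario {scenario!r}; presets: "
                f"{', '.join(SCENARIOS)}") from None
    else:
        abundances = dict(scenario)
    positions = dict(_DEFAULT_ACETYL_POSITIONS)
    positions.update(acetyl_positions or {})
    cer_weights = {}
    adduct_weights = {}
    for label in abundances:
        name = label[3:] if label.startswith("OAc") else label
        species = composition_of(name)  # validates the symbol
        n_sia = species.composition["Neu5Ac"]
        cer_weights[label] = dict(DEFAULT_CERAMIDE_WEIGHTS)
        adduct_weights[label] = dict(_DEHYDRATION_WEIGHTS[n_sia])
    positions = {
        label: pos for label, pos in positions.items() if label in abundances
    }
    # a single sialic acid can only be 'inner'
    for label in abundances:
        if label.startswith("OAc"):
            species = composition_of(label[3:])
            if len(species.neu5ac_positions) == 1:
                positions[label] = "inner"
            positions.setdefault(label, species.neu5ac_positions[-1])
    return GroundTruthProfile(
        abundances=abundances,
        ceramide_weights=cer_weights,
        acetyl_positions=positions,
        adduct_weights=adduct_weights,
        seed=seed,
    )


def simulate_ms1(
    profile: GroundTruthProfile,
    jitter_sd: float = 0.0,
    noise_peaks: int = 0,
    intensity_cv: float = 0.0,
    seed: Optional[int] = None,
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
    base_intensity: float = 1000.0,
    sample_id: str = "synthetic",
) -> Spectrum:
    """One centroid per expected ion plus contaminant peaks.

    Intensity noise is multiplicative log-normal with unit mean and
    coefficient of variation ``intensity_cv``; m/z jitter is Gaussian.
    Ground truth (the generating ion's label, or None for contaminants)
    rides along in ``Spectrum.truth``.
    """
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be >= 0")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    mzs, intens, truth = [], [], []
    sigma = math.sqrt(math.log(1.0 + intensity_cv**2)) if intensity_cv else 0.0
    for ion, weight in profile.ions():
        noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma else 1.0
        mzs.append(ion.mz + (rng.normal(0.0, jitter_sd) if jitter_sd else 0.0))
        intens.append(base_intensity * weight / 100.0 * noise)
        truth.append(ion.label)
    lo, hi = scan_range
    for _ in range(noise_peaks):
        mzs.append(rng.uniform(lo, hi))
        intens.append(rng.uniform(0.0, base_intensity * 0.02))
        truth.append(None)
    return Spectrum(sample_id, np.array(mzs), np.array(intens), truth=truth)


def simulate_msms(
    ion: IonSpecies,
    coverage: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_intensity: float = 100.0,
) -> Spectrum:
    """Noisy random subset of the predicted fragment spectrum.

    The retained subset is the prefix of a seed-determined permutation
    of the fragment list, so for a fixed seed a higher coverage always
    contains the fragments of a lower one (common random numbers across
    a coverage sweep).  At coverage 1 and zero noise the peak list
    equals ``predict_fragments`` exactly.
    """
    if not 0 < coverage <= 1:
        raise ValidationError("coverage must lie in (0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    fragments = predict_fragments(ion)
    perm = rng.permutation(len(fragments))
    keep = sorted(perm[: max(1, math.ceil(coverage * len(fragments)))])
    mzs, intens, truth = [], [], []
    for idx in keep:
        frag = fragments[idx]
        noise = rng.normal(0.0, noise_sd * base_intensity) if noise_sd else 0.0
        mzs.append(frag.mz)
        intens.append(max(base_intensity + noise, 1e-9))
        truth.append(frag.label)
    return Spectrum(f"msms:{ion.label}", np.array(mzs), np.array(intens),
                    truth=truth)


def simulate_qpcr(
    true_log2_ratios: Mapping[str, float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "ACTB",
    condition_names: tuple[str, str] = ("A", "B"),
    base_ct: float = 25.0,
    reference_ct: float = 18.0,
) -> tuple[CtTable, CtTable]:
    """Inverse-construct Ct tables so that -ddCt recovers the true
    log2 ratios exactly at zero noise."""
    if ct_noise_sd < 0:
        raise ValidationError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(true_log2_ratios)
    name_a, name_b = condition_names

    def noisy(value):
        return value + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0)

    row_a = {gene: noisy(base_ct - ratio)
             for gene, ratio in true_log2_ratios.items()}
    row_b = {gene: noisy(base_ct) for gene in genes}
    row_a[reference_gene] = noisy(reference_ct)
    row_b[reference_gene] = noisy(reference_ct)
    table_a = CtTable(pd.DataFrame([row_a], index=[name_a]), reference_gene)
    table_b = CtTable(pd.DataFrame([row_b], index=[name_b]), reference_gene)
    return table_a, table_b
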