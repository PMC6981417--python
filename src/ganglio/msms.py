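"""Negative-mode glycosidic fragment prediction and O-acetyl localization.

Fragments follow the Domon-Costello nomenclature: for every glycosidic
edge of the head-group topology the non-reducing side yields B/C ions
and the ceramide side Y/Z ions, all singly deprotonated.  The O-acetyl
increment travels with whichever side of the cleavage carries the
acetylated sialic acid, which is what makes inner vs terminal
acetylation distinguishable.  Sialo-lactones are opened before
prediction (fragment masses come from the non-dehydrated form); water
losses can be added as satellite peaks for oligosialylated fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .annotate import Annotation, Spectrum
from .chem import (
    AdductState,
    DEFAULT_MONOMERS,
    IonSpecies,
    MonomerTable,
    ValidationError,
    ceramide_mass,
)

__all__ = [
    "FragmentIon",
    "LocalizationResult",
    "predict_fragments",
    "localize_acetyl",
    "split_isobaric_intensity",
    "DEFAULT_MS2_TOLERANCE",
    "DEFAULT_MARGIN_THRESHOLD",
]

DEFAULT_MS2_TOLERANCE = 0.5
DEFAULT_MARGIN_THRESHOLD = 2.0


@dataclass(frozen=True)
class FragmentIon:
    kind: str  # B | C | Y | Z
    cleavage_node: str  # topology node whose parent edge is cleaved
    label: str  # e.g. B1, Y2
    contains_acetyl: bool
    mz: float
    satellite: bool = False  # water-loss satellite of a sialylated fragment


def predict_fragments(
    ion: IonSpecies,
    monomers: Optional[MonomerTable] = None,
    include_water_loss: bool = False,
) -> list[FragmentIon]:
    """All single-glycosidic-cleavage B/C/Y/Z fragments of ``ion``.

    For each tree edge the B ion is the dehydro non-reducing part minus a
    proton, C = B + water; the Y ion is the intact ceramide-side molecule
    minus a proton, Z = Y - water.  B/Y (and C/Z) pairs from one cleavage
    are complementary: mz(B) + mz(Y) = mz([M-H]-) - proton.
    """
    monomers = monomers or DEFAULT_MONOMERS
    species = ion.species
    acetyl_node = (
        species.acetyl_node_id(ion.adduct.acetyl_position)
        if ion.adduct.n_acetyl
        else None
    )
    cer = ceramide_mass(ion.ceramide)
    fragments: list[FragmentIon] = []
    for node in species.nodes:
        sub = species.subtree_ids(node.id)
        nr_residues = [species.node(i).residue for i in sub]
        red_residues = [n.residue for n in species.nodes if n.id not in sub]
        nr_mass = sum(monomers.residue_masses[r] for r in nr_residues)
        red_mass = cer + sum(monomers.residue_masses[r] for r in red_residues)
        ac_on_nr = acetyl_node in sub
        if ac_on_nr:
            nr_mass += monomers.acetyl
        elif acetyl_node is not None:
            red_mass += monomers.acetyl
        b = nr_mass - monomers.proton
        y = red_mass - monomers.proton
        n_nr = len(nr_residues)
        n_red = len(red_residues)
        fragments.extend([
            FragmentIon("B", node.id, f"B{n_nr}", ac_on_nr, b),
            FragmentIon("C", node.id, f"C{n_nr}", ac_on_nr, b + monomers.water),
            FragmentIon("Y", node.id, f"Y{n_red}", not ac_on_nr
                        and acetyl_node is not None, y),
            FragmentIon("Z", node.id, f"Z{n_red}", not ac_on_nr
                        and acetyl_node is not None, y - monomers.water),
        ])
        if include_water_loss:
            for frag, residues in ((fragments[-4], nr_residues),
                                   (fragments[-2], red_residues)):
                if residues.count("Neu5Ac") >= 2:
                    fragments.append(replace(
                        frag, mz=frag.mz - monomers.water,
                        label=frag.label + "-H2O", satellite=True))
    fragments.sort(key=lambda f: (f.mz, f.label))
    return fragments


@dataclass
class LocalizationResult:
    """Per-position diagnostic-intensity scores and the resulting call.

    ``call`` is a position label, or 'ambiguous' when no diagnostic
    fragment matched or the best/second score ratio fell below the
    margin threshold; ``status`` explains ambiguous calls.
    """

    candidate_positions: tuple[str, ...]
    scores: dict[str, float]
    call: str
    margin: float
    status: str = "ok"


def _diagnostic_sets(
    ion: IonSpecies,
    monomers: MonomerTable,
    tolerance: float,
) -> dict[str, list[FragmentIon]]:
    """Predicted fragments per acetyl position, restricted to fragments
    whose m/z differs by >= 2 x tolerance from the same fragment under at
    least one alternative position (position-informative fragments)."""
    positions = ion.species.neu5ac_positions
    per_pos: dict[str, dict[tuple, FragmentIon]] = {}
    for pos in positions:
        adduct = AdductState(n_dehydrations=0, n_acetyl=1,
                             acetyl_position=pos)
        variant = IonSpecies.create(ion.species, ion.ceramide, adduct,
                                    monomers)
        per_pos[pos] = {
            (f.kind, f.cleavage_node): f
            for f in predict_fragments(variant, monomers)
        }
    out: dict[str, list[FragmentIon]] = {}
    for pos in positions:
        diags = []
        for key, frag in per_pos[pos].items():
            others = [per_pos[q][key].mz for q in positions if q != pos]
            if any(abs(frag.mz - other) >= 2 * tolerance for other in others):
                diags.append(frag)
        out[pos] = diags
    return out


def _matched_intensity(frag_mz: Sequence[float], spectrum: Spectrum,
                       tolerance: float) -> float:
    """Summed intensity of observed peaks within tolerance of any
    predicted m/z (each observed peak counted once)."""
    if not len(frag_mz) or not spectrum.n_peaks:
        return 0.0
    targets = np.sort(np.asarray(frag_mz, dtype=float))
    idx = np.searchsorted(targets, spectrum.mz)
    matched = np.zeros(spectrum.n_peaks, dtype=bool)
    for shift in (0, -1):
        j = np.clip(idx + shift, 0, targets.size - 1)
        matched |= np.abs(spectrum.mz - targets[j]) <= tolerance
    return float(spectrum.intensity[matched].sum())


def localize_acetyl(
    precursor: Annotation,
    fragments: Spectrum,
    tolerance: float = DEFAULT_MS2_TOLERANCE,
    margin_threshold: float = DEFAULT_MARGIN_THRESHOLD,
    monomers: Optional[MonomerTable] = None,
) -> LocalizationResult:
    """Assign the O-acetyl to a sialic-acid position from MS/MS evidence.

    Scores each candidate position by the summed intensity of matched
    position-informative fragments and calls the argmax; the call is
    'ambiguous' when nothing diagnostic matched or the best/second ratio
    is below ``margin_threshold``.  Deterministic for fixed input.
    """
    monomers = monomers or DEFAULT_MONOMERS
    acetylated = [c for c in precursor.candidates if c.ion.adduct.n_acetyl]
    if not acetylated:
        raise ValidationError(
            "precursor has no O-acetylated candidate to localize")
    if not fragments.n_peaks:
        raise ValidationError("fragment spectrum is empty")
    ion = acetylated[0].ion
    positions = ion.species.neu5ac_positions
    diag = _diagnostic_sets(ion, monomers, tolerance)
    if all(not v for v in diag.values()):
        return LocalizationResult(positions, {p: 0.0 for p in positions},
                                  "ambiguous", 0.0,
                                  status="no diagnostic fragments predicted")
    scores = {
        pos: _matched_intensity([f.mz for f in diag[pos]], fragments,
                                tolerance)
        for pos in positions
    }
    ranked = sorted(positions, key=lambda p: (-scores[p], p))
    best, second = ranked[0], (ranked[1] if len(ranked) > 1 else None)
    if scores[best] <= 0:
        return LocalizationResult(positions, scores, "ambiguous", 0.0,
                                  status="no diagnostic fragments matched")
    margin = (scores[best] / scores[second]
              if second is not None and scores[second] > 0 else float("inf"))
    if margin < margin_threshold:
        return LocalizationResult(positions, scores, "ambiguous", margin,
                                  status="margin below threshold")
    return LocalizationResult(positions, scores, best, margin)


def split_isobaric_intensity(
    precursor: Annotation,
    fragments: Spectrum,
    tolerance: float = DEFAULT_MS2_TOLERANCE,
    monomers: Optional[MonomerTable] = None,
) -> tuple[dict[str, float], bool]:
    """Apportion an isobaric precursor's intensity across its candidates.

    Shares are proportional to the summed intensity of candidate-unique
    fragments (those >= 2 x tolerance away from every fragment of every
    other candidate).  Returns ({ion label: share}, fallback_flag); when
    no candidate matches any unique fragment the split is equal and the
    flag is set.  Shares always sum to 1.
    """
    monomers = monomers or DEFAULT_MONOMERS
    if precursor.status != "isobaric":
        raise ValidationError("precursor is not isobaric")
    cands = [c.ion for c in precursor.candidates]
    frag_sets = [predict_fragments(ion, monomers) for ion in cands]
    scores = []
    for i, frags in enumerate(frag_sets):
        other_mz = np.array([
            f.mz for j, fs in enumerate(frag_sets) if j != i for f in fs
        ])
        unique = [
            f.mz for f in frags
            if not other_mz.size
            or np.abs(other_mz - f.mz).min() >= 2 * tolerance
        ]
        scores.append(_matched_intensity(unique, fragments, tolerance))
    total = sum(scores)
    if total <= 0:
        n = len(cands)
        return {ion.label: 1.0 / n for ion in cands}, True
    return {ion.label: s / total for ion, s in zip(cands, scores)}, False
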