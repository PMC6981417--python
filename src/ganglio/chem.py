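"""Structural model of gangliosides and monoisotopic m/z calculus.

Gangliosides are sialylated glycosphingolipids: a glycan head-group built
from Hex (Glc/Gal), HexNAc (GalNAc/GlcNAc) and Neu5Ac (sialic acid)
residues on a ceramide anchor (sphingoid base amide-linked to a fatty
acid).  In negative-mode MALDI they are observed as singly deprotonated
ions; oligosialylated species additionally appear as sialo-lactones
([M-H2O-H]- and [M-2H2O-H]-) and any sialic acid may carry one O-acetyl
ester (+42.01057 Da, mass-silent as to the acetylated carbon).

All masses are monoisotopic.  Residue masses follow the usual glycomics
convention (free monosaccharide minus water), so the neutral mass of an
intact species is simply ``ceramide + sum(residues)``.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "MonomerTable",
    "CeramideSpec",
    "GangliosideSpecies",
    "AdductState",
    "IonSpecies",
    "LibraryConfig",
    "UnsupportedSpeciesError",
    "ValidationError",
    "composition_of",
    "ceramide_mass",
    "ion_mz",
    "enumerate_library",
    "report_mz",
    "SUPPORTED_SPECIES",
]

# Monoisotopic atomic masses (CODATA/IUPAC), used only to assemble the
# sphingoid-base and fatty-acid masses; glycan arithmetic goes through
# the MonomerTable residue masses.
_H = 1.00782503207
_C = 12.0
_N = 14.0030740048
_O = 15.9949146196


class UnsupportedSpeciesError(ValueError):
    """Raised for a Svennerholm symbol outside the supported set."""


class ValidationError(ValueError):
    """Raised when a spec violates its structural constraints."""


@dataclass(frozen=True)
class MonomerTable:
    """Immutable residue-mass table plus the adduct-state constants.

    ``residue_masses`` maps {Hex, HexNAc, Neu5Ac} to the monoisotopic
    residue mass (free monosaccharide minus water).
    """

    residue_masses: Mapping[str, float]
    water: float = 18.01056
    acetyl: float = 42.01057
    proton: float = 1.00728

    def __post_init__(self):
        for name, mass in self.residue_masses.items():
            if mass <= 0:
                raise ValidationError(f"non-positive residue mass for {name}")
        object.__setattr__(self, "residue_masses", dict(self.residue_masses))

    @classmethod
    def default(cls) -> "MonomerTable":
        cfg = _load_default_config()
        m = cfg["monomers"]
        return cls(
            residue_masses=dict(m["residue_masses"]),
            water=float(m["water"]),
            acetyl=float(m["acetyl"]),
            proton=float(m["proton"]),
        )


_SPHINGOID_FORMULAS = {
    # code -> (C, H, N, O) of the free base
    "d18:1": (18, 37, 1, 2),  # sphingosine
}

_SUPPORTED_ACYL_CARBONS = (14, 16, 18, 22, 24)


@dataclass(frozen=True)
class CeramideSpec:
    """Ceramide in lipidomics shorthand, e.g. d18:1/16:0.

    ``hydroxylation`` counts extra hydroxyls on the fatty acid (+O each),
    used for highly hydroxylated ceramides; default 0.
    """

    base: str = "d18:1"
    acyl_carbons: int = 16
    acyl_unsaturation: int = 0
    hydroxylation: int = 0

    def __post_init__(self):
        if self.base not in _SPHINGOID_FORMULAS:
            raise ValidationError(
                f"unsupported sphingoid base {self.base!r}; "
                f"supported: {sorted(_SPHINGOID_FORMULAS)}"
            )
        if self.acyl_carbons not in _SUPPORTED_ACYL_CARBONS:
            raise ValidationError(
                f"unsupported acyl chain C{self.acyl_carbons}; "
                f"supported carbons: {_SUPPORTED_ACYL_CARBONS}"
            )
        if self.acyl_unsaturation not in (0, 1):
            raise ValidationError("acyl unsaturation must be 0 or 1")
        if self.hydroxylation < 0:
            raise ValidationError("hydroxylation count must be >= 0")

    @classmethod
    def parse(cls, text: str) -> "CeramideSpec":
        """Parse 'd18:1/24:1' or the acyl part alone ('24:1')."""
        if "/" in text:
            base, acyl = text.split("/", 1)
        else:
            base, acyl = "d18:1", text
        carbons, unsat = acyl.split(":")
        return cls(base=base, acyl_carbons=int(carbons),
                   acyl_unsaturation=int(unsat))

    @property
    def label(self) -> str:
        return f"{self.base}/{self.acyl_carbons}:{self.acyl_unsaturation}"

    @property
    def mass(self) -> float:
        return ceramide_mass(self)


def ceramide_mass(cer: CeramideSpec) -> float:
    """Monoisotopic mass of the intact ceramide (amide, one water lost)."""
    c, h, n, o = _SPHINGOID_FORMULAS[cer.base]
    base = c * _C + h * _H + n * _N + o * _O
    k, u = cer.acyl_carbons, cer.acyl_unsaturation
    fatty_acid = k * _C + (2 * k - 2 * u) * _H + 2 * _O
    water = 2 * _H + _O
    return base + fatty_acid - water + cer.hydroxylation * _O


@dataclass(frozen=True)
class TreeNode:
    """One glycan residue in a rooted topology (root = ceramide)."""

    id: str
    residue: str  # Hex | HexNAc | Neu5Ac
    parent: Optional[str]  # None for children of the ceramide root


@dataclass(frozen=True)
class GangliosideSpecies:
    """A named ganglioside head-group: composition plus rooted topology.

    ``neu5ac_positions`` orders the oligosialyl-chain labels from the
    inner (Gal-linked) residue to the terminal one; they index into the
    sialyl-chain nodes of the topology.
    """

    name: str
    series: str  # one of {'0', 'a', 'b', 'c'}
    nodes: tuple[TreeNode, ...]
    neu5ac_positions: tuple[str, ...]

    @property
    def composition(self) -> Counter:
        return Counter(n.residue for n in self.nodes)

    @property
    def residue_count(self) -> int:
        return len(self.nodes)

    def node(self, node_id: str) -> TreeNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def children(self, node_id: Optional[str]) -> list[TreeNode]:
        return [n for n in self.nodes if n.parent == node_id]

    def subtree_ids(self, node_id: str) -> set[str]:
        out = {node_id}
        stack = [node_id]
        while stack:
            cur = stack.pop()
            for ch in self.children(cur):
                out.add(ch.id)
                stack.append(ch.id)
        return out

    def acetyl_node_id(self, position: str) -> str:
        """Topology node id of the sialyl-chain residue at ``position``."""
        if position not in self.neu5ac_positions:
            raise ValidationError(
                f"{self.name} has no sialyl position {position!r}; "
                f"available: {self.neu5ac_positions}"
            )
        idx = self.neu5ac_positions.index(position)
        return f"neu{idx + 1}"

    def mass(self, monomers: MonomerTable) -> float:
        return sum(monomers.residue_masses[n.residue] for n in self.nodes)


_POSITION_LABELS = {
    1: ("inner",),
    2: ("inner", "terminal"),
    3: ("inner", "middle", "terminal"),
}

# (series, n sialic acids on the inner Gal, elongation level)
# elongation: 0 = none, 1 = +GalNAc, 2 = +GalNAc+Gal, 3 = level 2 + LacNAc
_SPECIES_PLAN = {
    "GM3": ("a", 1, 0),
    "GM2": ("a", 1, 1),
    "GM1": ("a", 1, 2),
    "LacNAcGM1": ("a", 1, 3),
    "GD3": ("b", 2, 0),
    "GD2": ("b", 2, 1),
    "GD1b": ("b", 2, 2),
    "GT3": ("c", 3, 0),
    "GT2": ("c", 3, 1),
}

SUPPORTED_SPECIES = tuple(_SPECIES_PLAN)


def _build_species(name: str) -> GangliosideSpecies:
    series, n_sia, elong = _SPECIES_PLAN[name]
    nodes = [
        TreeNode("glc", "Hex", None),
        TreeNode("gal", "Hex", "glc"),
    ]
    # oligosialyl chain on the inner Gal
    prev = "gal"
    for i in range(1, n_sia + 1):
        nodes.append(TreeNode(f"neu{i}", "Neu5Ac", prev))
        prev = f"neu{i}"
    # elongation lane on the inner Gal: GalNAc -> Gal -> (LacNAc)
    if elong >= 1:
        nodes.append(TreeNode("galnac", "HexNAc", "gal"))
    if elong >= 2:
        nodes.append(TreeNode("gal2", "Hex", "galnac"))
    if elong >= 3:
        nodes.append(TreeNode("glcnac", "HexNAc", "gal2"))
        nodes.append(TreeNode("gal3", "Hex", "glcnac"))
    return GangliosideSpecies(
        name=name,
        series=series,
        nodes=tuple(nodes),
        neu5ac_positions=_POSITION_LABELS[n_sia],
    )


_SPECIES_CACHE = {name: _build_species(name) for name in _SPECIES_PLAN}


def composition_of(name: str) -> GangliosideSpecies:
    """Return the species model for a Svennerholm symbol.

    Raises UnsupportedSpeciesError for symbols outside the supported set.
    """
    try:
        return _SPECIES_CACHE[name]
    except KeyError:
        raise UnsupportedSpeciesError(
            f"unsupported ganglioside {name!r}; supported: "
            f"{', '.join(SUPPORTED_SPECIES)}"
        ) from None


def max_dehydrations(species: GangliosideSpecies) -> int:
    """Lactone cap: one fewer than the sialyl count, at most two."""
    n_sia = species.composition["Neu5Ac"]
    return min(2, max(0, n_sia - 1))


@dataclass(frozen=True)
class AdductState:
    """Deprotonated-ion state: lactone dehydrations and O-acetylation.

    ``acetyl_position`` names the acetylated sialic acid (a label from the
    species' ``neu5ac_positions``); the acetylated carbon (7 vs 9) is not
    mass-resolvable and is not modeled.
    """

    charge: int = -1
    n_dehydrations: int = 0
    n_acetyl: int = 0
    acetyl_position: Optional[str] = None

    def __post_init__(self):
        if self.charge != -1:
            raise ValidationError("only singly deprotonated ions supported")
        if not 0 <= self.n_dehydrations <= 2:
            raise ValidationError("n_dehydrations must be in 0..2")
        if self.n_acetyl not in (0, 1):
            raise ValidationError("n_acetyl must be 0 or 1")
        if (self.acetyl_position is not None) != (self.n_acetyl == 1):
            raise ValidationError(
                "acetyl_position must be set iff n_acetyl == 1")

    def validate_for(self, species: GangliosideSpecies) -> None:
        cap = max_dehydrations(species)
        if self.n_dehydrations > cap:
            raise ValidationError(
                f"{species.name} admits at most {cap} lactone dehydration(s), "
                f"got {self.n_dehydrations}"
            )
        if self.n_acetyl and self.acetyl_position not in species.neu5ac_positions:
            raise ValidationError(
                f"acetyl position {self.acetyl_position!r} not in "
                f"{species.neu5ac_positions} for {species.name}"
            )

    @property
    def label(self) -> str:
        if self.n_dehydrations == 0:
            return "[M-H]-"
        if self.n_dehydrations == 1:
            return "[M-H2O-H]-"
        return "[M-2H2O-H]-"


def ion_mz(
    species: GangliosideSpecies,
    cer: CeramideSpec,
    adduct: AdductState,
    monomers: Optional[MonomerTable] = None,
) -> float:
    """m/z of the deprotonated ion, full precision (rounding is the
    caller's concern)."""
    monomers = monomers or DEFAULT_MONOMERS
    adduct.validate_for(species)
    mass = (
        ceramide_mass(cer)
        + species.mass(monomers)
        + adduct.n_acetyl * monomers.acetyl
        - adduct.n_dehydrations * monomers.water
    )
    return mass - monomers.proton


@dataclass(frozen=True)
class IonSpecies:
    """A (species, ceramide, adduct-state) triple with its computed m/z."""

    species: GangliosideSpecies
    ceramide: CeramideSpec
    adduct: AdductState
    mz: float = field(default=0.0)

    @classmethod
    def create(
        cls,
        species: GangliosideSpecies,
        ceramide: CeramideSpec,
        adduct: AdductState,
        monomers: Optional[MonomerTable] = None,
    ) -> "IonSpecies":
        return cls(species, ceramide, adduct,
                   mz=ion_mz(species, ceramide, adduct, monomers))

    @property
    def species_label(self) -> str:
        """Quantification label: the OAc prefix marks acetylated forms."""
        prefix = "OAc" if self.adduct.n_acetyl else ""
        return prefix + self.species.name

    @property
    def label(self) -> str:
        return f"{self.species_label} {self.ceramide.label} {self.adduct.label}"

    @property
    def complexity(self) -> int:
        return self.species.residue_count + self.adduct.n_acetyl

    def __repr__(self):  # keep reprs short in reports
        return f"IonSpecies({self.label} @ {self.mz:.4f})"


@dataclass(frozen=True)
class LibraryConfig:
    """Axes of the theoretical-ion enumeration.

    ``acyls`` use lipidomics shorthand ('16:0'); dehydration counts run
    from zero to each species' lactone cap unless ``max_dehydrations``
    lowers it globally.
    """

    species: tuple[str, ...]
    bases: tuple[str, ...] = ("d18:1",)
    acyls: tuple[str, ...] = ("14:0", "16:0", "18:0", "22:0", "24:0", "24:1")
    max_dehydrations: Optional[int] = None
    max_acetyl: int = 1
    hydroxylations: tuple[int, ...] = (0,)

    def __post_init__(self):
        if not self.species:
            raise ValidationError("library config needs at least one species")
        for name in self.species:
            composition_of(name)  # raises on unknown symbols
        if self.max_acetyl not in (0, 1):
            raise ValidationError("max_acetyl must be 0 or 1")

    @classmethod
    def default(cls) -> "LibraryConfig":
        cfg = _load_default_config()["library"]
        return cls(
            species=tuple(cfg["species"]),
            bases=tuple(cfg["bases"]),
            acyls=tuple(cfg["acyls"]),
            max_dehydrations=cfg.get("max_dehydrations"),
            max_acetyl=int(cfg.get("max_acetyl", 1)),
        )

    @classmethod
    def from_yaml(cls, path) -> "LibraryConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)["library"]
        return cls(
            species=tuple(cfg["species"]),
            bases=tuple(cfg.get("bases", ("d18:1",))),
            acyls=tuple(cfg.get("acyls",
                                ("14:0", "16:0", "18:0", "22:0", "24:0", "24:1"))),
            max_dehydrations=cfg.get("max_dehydrations"),
            max_acetyl=int(cfg.get("max_acetyl", 1)),
        )


def enumerate_library(
    config: Optional[LibraryConfig] = None,
    monomers: Optional[MonomerTable] = None,
) -> list[IonSpecies]:
    """Cartesian product of valid (species, ceramide, adduct) combinations,
    deduplicated and sorted by m/z (ties by complexity, then label).

    The O-acetyl is placed on the terminal sialic acid canonically; the
    position does not affect the mass, so positional variants collapse in
    the deduplication.
    """
    config = config or LibraryConfig.default()
    monomers = monomers or DEFAULT_MONOMERS
    seen: set[tuple] = set()
    ions: list[IonSpecies] = []
    for name, base, acyl, hydroxy in itertools.product(
        config.species, config.bases, config.acyls, config.hydroxylations
    ):
        species = composition_of(name)
        cer = CeramideSpec.parse(f"{base}/{acyl}")
        if hydroxy:
            cer = replace(cer, hydroxylation=hydroxy)
        cap = max_dehydrations(species)
        if config.max_dehydrations is not None:
            cap = min(cap, config.max_dehydrations)
        for n_dehyd in range(cap + 1):
            for n_ac in range(config.max_acetyl + 1):
                pos = species.neu5ac_positions[-1] if n_ac else None
                key = (name, cer.label, n_dehyd, n_ac)
                if key in seen:
                    continue
                seen.add(key)
                adduct = AdductState(n_dehydrations=n_dehyd,
                                     n_acetyl=n_ac, acetyl_position=pos)
                ions.append(IonSpecies.create(species, cer, adduct, monomers))
    ions.sort(key=lambda i: (i.mz, i.complexity, i.label))
    return ions


def report_mz(mz: float, decimals: int = 1) -> float:
    """Round half-up at the requested precision (report presentation)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(mz)).quantize(q, rounding=ROUND_HALF_UP))


def _load_default_config() -> dict:
    text = resources.files("ganglio.data").joinpath(
        "default_library.yaml").read_text()
    return yaml.safe_load(text)


DEFAULT_MONOMERS = MonomerTable(
    residue_masses={"Hex": 162.05282, "HexNAc": 203.07937,
                    "Neu5Ac": 291.09542},
)
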