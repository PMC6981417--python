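"""Ganglioside biosynthesis pathway graph and differential mapping.

The default topology follows the canonical ganglio-series scheme:
GlcCer is galactosylated to LacCer (B4GALT6); ST3GAL5, ST8SIA1 and
ST8SIA5 then create the a-, b- and c-series precursors GM3, GD3 and
GT3, while the 0-series extends LacCer directly.  Each series precursor
begins a parallel elongation lane catalyzed by B4GALNT1, B3GALT4,
ST3GAL2 and ST8SIA5.  O-acetylated species hang off their parent
ganglioside via CASD1 (the only known human sialate
O-acetyltransferase); SLC33A1 (the Golgi acetyl-CoA transporter) is
carried as a gene node.

Differential values are mapped to colors on two diverging scales:
gene log2 ratios blue (<= -2) / white (0) / red (>= 2), metabolite
abundance deltas in percentage points green (<= -8) / white (0) /
fuchsia (>= 8); nodes without data are grey.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .chem import ValidationError
from .quantify import AbundanceTable

__all__ = [
    "CtTable",
    "PATHWAY_GENES",
    "build_default_pathway",
    "log2_ratio_from_ct",
    "delta_abundance",
    "colorize",
    "map_differential",
    "export_graph",
    "import_graph",
    "draw_pathway",
    "GREY",
]

PATHWAY_GENES = (
    "B4GALT6", "ST3GAL5", "ST8SIA1", "B4GALNT1", "B3GALT4",
    "ST3GAL2", "ST8SIA5", "SLC33A1", "CASD1",
)

GREY = "#808080"
_SCALES = {
    # scale -> (clamp bound, endpoint color for +, endpoint color for -)
    "gene": (2.0, (255, 0, 0), (0, 0, 255)),       # red / blue
    "metabolite": (8.0, (255, 0, 255), (0, 255, 0)),  # fuchsia / green
}

# (substrate, product, catalyzing gene) per elongation lane
_LANES = {
    "LacCer": ("GA2", "GA1", "GM1b", "GD1c"),
    "GM3": ("GM2", "GM1", "GD1a", "GT1a"),
    "GD3": ("GD2", "GD1b", "GT1b", "GQ1b"),
    "GT3": ("GT2", "GT1c", "GQ1c", "GP1c"),
}
_LANE_GENES = ("B4GALNT1", "B3GALT4", "ST3GAL2", "ST8SIA5")

_OAC_PARENTS = {
    "OAcGM1": "GM1",
    "OAcGD3": "GD3",
    "OAcGD2": "GD2",
    "OAcGT3": "GT3",
    "OAcGT2": "GT2",
}


def build_default_pathway() -> nx.DiGraph:
    """Directed acyclic pathway graph with metabolite and gene nodes."""
    g = nx.DiGraph()
    for gene in PATHWAY_GENES:
        g.add_node(gene, kind="gene", value=None, color=GREY)

    def met(name):
        if name not in g:
            g.add_node(name, kind="metabolite", value=None, color=GREY)

    def step(a, b, gene):
        met(a)
        met(b)
        g.add_edge(a, b, gene=gene)

    step("GlcCer", "LacCer", "B4GALT6")
    step("LacCer", "GM3", "ST3GAL5")
    step("GM3", "GD3", "ST8SIA1")
    step("GD3", "GT3", "ST8SIA5")
    for precursor, lane in _LANES.items():
        prev = precursor
        for product, gene in zip(lane, _LANE_GENES):
            step(prev, product, gene)
            prev = product
    for oac, parent in _OAC_PARENTS.items():
        step(parent, oac, "CASD1")
    assert nx.is_directed_acyclic_graph(g)
    return g


@dataclass
class CtTable:
    """qPCR Ct values, conditions (rows) x genes (columns).

    Replicate rows sharing a condition label are averaged.  The
    reference gene is a required field -- there is no silent default.
    """

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self):
        if self.reference_gene not in self.data.columns:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} missing from table")
        values = self.data.to_numpy(dtype=float)
        if ((values <= 0) | (values >= 45)).any():
            raise ValidationError("Ct values must lie in (0, 45)")
        if self.data[self.reference_gene].isna().any():
            raise ValidationError("reference gene Ct missing for a sample")

    @classmethod
    def read_csv(cls, path, reference_gene: str) -> "CtTable":
        return cls(pd.read_csv(path, index_col=0), reference_gene)

    def mean_ct(self, condition: str, gene: str) -> float:
        if gene not in self.data.columns:
            raise ValidationError(f"gene {gene!r} not in Ct table")
        if condition not in self.data.index:
            raise ValidationError(f"condition {condition!r} not in Ct table")
        val = self.data.loc[condition, gene]
        return float(val.mean() if hasattr(val, "mean") else val)


def log2_ratio_from_ct(
    ct: CtTable,
    gene: str,
    condition_a: str,
    condition_b: str,
) -> float:
    """Relative expression of A over B as -ddCt.

    ddCt = (Ct_gene - Ct_ref)_A - (Ct_gene - Ct_ref)_B; the returned
    log2 ratio is its negative, so higher expression in A is positive.
    """
    ref = ct.reference_gene
    dct_a = ct.mean_ct(condition_a, gene) - ct.mean_ct(condition_a, ref)
    dct_b = ct.mean_ct(condition_b, gene) - ct.mean_ct(condition_b, ref)
    return -(dct_a - dct_b)


@dataclass(frozen=True)
class DeltaResult:
    value: float
    imputed_a: bool = False
    imputed_b: bool = False


def delta_abundance(
    table_a: AbundanceTable,
    table_b: AbundanceTable,
    species: str,
    sample_a: Optional[str] = None,
    sample_b: Optional[str] = None,
) -> Optional[DeltaResult]:
    """Difference in percentage points (A - B) for one species.

    A species missing from one table counts as 0 with an imputation
    flag; missing from both yields None (no-data, rendered grey).
    """
    sample_a = sample_a or table_a.data.index[0]
    sample_b = sample_b or table_b.data.index[0]
    a = table_a.species_value(sample_a, species)
    b = table_b.species_value(sample_b, species)
    if a is None and b is None:
        return None
    return DeltaResult(
        value=(a or 0.0) - (b or 0.0),
        imputed_a=a is None,
        imputed_b=b is None,
    )


def colorize(value: Optional[float], scale: str) -> str:
    """Hex RGB for a differential value on the gene or metabolite scale.

    Linear interpolation between white at 0 and the endpoint color,
    clamped at the scale bound; None (no data) maps to grey.
    """
    if scale not in _SCALES:
        raise ValidationError(f"unknown scale {scale!r}; use gene|metabolite")
    if value is None:
        return GREY
    bound, pos_color, neg_color = _SCALES[scale]
    frac = min(abs(value) / bound, 1.0)
    endpoint = pos_color if value >= 0 else neg_color
    rgb = tuple(round(255 + frac * (c - 255)) for c in endpoint)
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def map_differential(
    graph: nx.DiGraph,
    gene_ratios: Optional[Mapping[str, float]] = None,
    metabolite_deltas: Optional[Mapping[str, Optional[float]]] = None,
) -> nx.DiGraph:
    """Attach differential values and colors to a pathway graph copy."""
    gene_ratios = gene_ratios or {}
    metabolite_deltas = metabolite_deltas or {}
    g = graph.copy()
    for node, attrs in g.nodes(data=True):
        if attrs["kind"] == "gene":
            value = gene_ratios.get(node)
            scale = "gene"
        else:
            value = metabolite_deltas.get(node)
            scale = "metabolite"
        attrs["value"] = value
        attrs["color"] = colorize(value, scale)
    return g


def _serializable(g: nx.DiGraph) -> nx.DiGraph:
    out = g.copy()
    for _, attrs in out.nodes(data=True):
        if attrs.get("value") is None:
            attrs["value"] = ""  # GraphML cannot carry None
        else:
            attrs["value"] = float(attrs["value"])
    return out


def export_graph(graph: nx.DiGraph, path, format: str = "graphml") -> None:
    """Write the colored graph as GraphML, node-link JSON or SIF."""
    if format == "graphml":
        nx.write_graphml(_serializable(graph), path)
    elif format == "json":
        data = nx.node_link_data(_serializable(graph), edges="edges")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b, attrs in graph.edges(data=True):
                fh.write(f"{a}\t{attrs.get('gene', 'edge')}\t{b}\n")
    else:
        raise ValidationError(
            f"unsupported export format {format!r}; use graphml|json|sif")


def import_graph(path, format: str = "graphml") -> nx.DiGraph:
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.DiGraph(g)
    elif format == "json":
        with open(path) as fh:
            g = nx.node_link_graph(json.load(fh), edges="edges")
    else:
        raise ValidationError("only graphml and json re-import supported")
    for _, attrs in g.nodes(data=True):
        if attrs.get("value") == "":
            attrs["value"] = None
    return g


def draw_pathway(graph: nx.DiGraph, path=None, figsize=(10, 8)):
    """Static render: series lanes as columns, gene nodes in a side strip."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lanes = ["LacCer", "GM3", "GD3", "GT3"]
    pos = {"GlcCer": (-1.0, 0.0)}
    for col, precursor in enumerate(lanes):
        pos[precursor] = (float(col), 0.0)
        for row, product in enumerate(_LANES[precursor], start=1):
            pos[product] = (float(col), -float(row))
    for oac, parent in _OAC_PARENTS.items():
        px, py = pos[parent]
        pos[oac] = (px + 0.45, py + 0.45)
    for i, gene in enumerate(PATHWAY_GENES):
        pos[gene] = (4.3, -0.6 * i)
    for node in graph.nodes:
        pos.setdefault(node, (5.5, 0.0))

    fig, ax = plt.subplots(figsize=figsize)
    colors = [graph.nodes[n].get("color", GREY) for n in graph.nodes]
    nx.draw_networkx(graph, pos=pos, ax=ax, node_color=colors,
                     node_size=900, font_size=7, edgecolors="black",
                     arrowsize=9)
    for a, b, attrs in graph.edges(data=True):
        if "gene" in attrs:
            x = (pos[a][0] + pos[b][0]) / 2
            y = (pos[a][1] + pos[b][1]) / 2
            ax.text(x, y, attrs["gene"], fontsize=5, style="italic",
                    ha="center", color="dimgrey")
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
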