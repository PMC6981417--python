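"""Independent brute-force mass oracle for the test suite.

Assembles full atomic compositions (C, H, N, O element counts) for
every supported (species, ceramide, adduct) combination and sums
monoisotopic atomic masses directly, without touching the residue-mass
table the package uses.  Deliberately naive and self-contained.
"""

from collections import Counter

MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}
ELECTRON = 0.00054857990946

# residue formulas: free monosaccharide minus water
RESIDUE_FORMULA = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "Neu5Ac": {"C": 11, "H": 17, "N": 1, "O": 8},
}

# glycan head-group residue multisets of the supported species
SPECIES_RESIDUES = {
    "GM3": {"Hex": 2, "Neu5Ac": 1},
    "GM2": {"Hex": 2, "HexNAc": 1, "Neu5Ac": 1},
    "GM1": {"Hex": 3, "HexNAc": 1, "Neu5Ac": 1},
    "LacNAcGM1": {"Hex": 4, "HexNAc": 2, "Neu5Ac": 1},
    "GD3": {"Hex": 2, "Neu5Ac": 2},
    "GD2": {"Hex": 2, "HexNAc": 1, "Neu5Ac": 2},
    "GD1b": {"Hex": 3, "HexNAc": 1, "Neu5Ac": 2},
    "GT3": {"Hex": 2, "Neu5Ac": 3},
    "GT2": {"Hex": 2, "HexNAc": 1, "Neu5Ac": 3},
}


def formula_mass(formula):
    return sum(MASS[el] * n for el, n in formula.items())


def ceramide_formula(acyl_carbons, acyl_unsaturation=0, hydroxylation=0):
    """d18:1 sphingosine amide-linked to a fatty acid, one water out."""
    f = Counter({"C": 18, "H": 37, "N": 1, "O": 2})  # sphingosine
    k, u = acyl_carbons, acyl_unsaturation
    f.update({"C": k, "H": 2 * k - 2 * u, "O": 2})  # fatty acid
    f.subtract({"H": 2, "O": 1})  # amide condensation
    f.update({"O": hydroxylation})
    return f


def neutral_formula(species, acyl_carbons, acyl_unsaturation=0,
                    n_dehydrations=0, n_acetyl=0):
    f = ceramide_formula(acyl_carbons, acyl_unsaturation)
    for residue, count in SPECIES_RESIDUES[species].items():
        for el, n in RESIDUE_FORMULA[residue].items():
            f[el] += n * count
    f.subtract({"H": 2 * n_dehydrations, "O": n_dehydrations})
    f.update({"C": 2 * n_acetyl, "H": 2 * n_acetyl, "O": n_acetyl})
    return f


def anion_mz(species, acyl_carbons, acyl_unsaturation=0,
             n_dehydrations=0, n_acetyl=0):
    """[M-H]- (possibly dehydrated/acetylated): neutral minus a proton."""
    mass = formula_mass(neutral_formula(
        species, acyl_carbons, acyl_unsaturation, n_dehydrations, n_acetyl))
    return mass - (MASS["H"] - ELECTRON)


def glycan_b_ion(residues, n_acetyl=0):
    """Deprotonated B fragment of a glycan moiety given residue counts."""
    f = Counter()
    for residue, count in residues.items():
        for el, n in RESIDUE_FORMULA[residue].items():
            f[el] += n * count
    f.update({"C": 2 * n_acetyl, "H": 2 * n_acetyl, "O": n_acetyl})
    return formula_mass(f) - (MASS["H"] - ELECTRON)


def ceramide_y0(acyl_carbons, acyl_unsaturation=0):
    """Deprotonated Y0 (bare ceramide) fragment."""
    return (formula_mass(ceramide_formula(acyl_carbons, acyl_unsaturation))
            - (MASS["H"] - ELECTRON))
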