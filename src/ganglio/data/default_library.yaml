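# Default monomer table and theoretical-ion library configuration.
#
# Residue masses are monoisotopic residue masses (free monosaccharide
# minus water) in Da. The library axes span the nine supported
# Svennerholm species, the d18:1 sphingoid base and the fatty-acyl set
# seen in neuroectoderm-derived cell lines (C16/C24 major; C14, C18,
# C22 minor; C24 saturated and mono-unsaturated). Lactone dehydrations
# run from zero up to each species' cap (sialyl count minus one, at
# most two) and at most one O-acetyl ester per ion.

monomers:
  residue_masses:
    Hex: 162.05282
    HexNAc: 203.07937
    Neu5Ac: 291.09542
  water: 18.01056
  acetyl: 42.01057
  proton: 1.00728

library:
  species: [GM3, GM2, GM1, LacNAcGM1, GD3, GD2, GD1b, GT3, GT2]
  bases: [d18:1]
  acyls: ["14:0", "16:0", "18:0", "22:0", "24:0", "24:1"]
  max_dehydrations: null
  max_acetyl: 1

annotate:
  tolerance: 0.3
  max_isotope_layers: 1
  isotope_spacing: 1.00336

msms:
  tolerance: 0.5
  margin_threshold: 2.0
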