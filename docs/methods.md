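# Methods

## Structural model and mass calculus

Each supported species (GM3, GM2, GM1, LacNAcGM1, GD3, GD2, GD1b, GT3,
GT2) is represented as a rooted residue tree: ceramide → Glc → Gal, an
oligosialyl chain of 1–3 Neu5Ac on the inner Gal (its length defines
the a/b/c series), and an elongation lane GalNAc → Gal (→ LacNAc for
LacNAcGM1) on the same Gal. Masses are additive over monoisotopic
residue masses (free monosaccharide minus water): Hex 162.05282,
HexNAc 203.07937, Neu5Ac 291.09542 Da. The ceramide mass is assembled
from atomic masses of the sphingoid base (d18:1, C18H37NO2) and the
fatty acid, minus one water for the amide bond; an optional
hydroxylation count adds 15.99491 Da each for highly hydroxylated
ceramides. Deprotonation subtracts the proton mass 1.00728 Da (the
alternative hydrogen-atom convention, 1.00783, is indistinguishable at
the 0.1 Da precision these spectra are reported at; the package fixes
the proton convention).

Adduct states model two chemistries seen on native acidic extracts:
sialo-lactonization (intramolecular esters between adjacent sialic
acids, −18.01056 Da each, capped at `min(2, n_Neu5Ac − 1)`) and mono
*O*-acetylation (+42.01057 Da on a designated sialic acid). Which
carbon of the sialic acid carries the ester (7 vs 9) is not mass
resolvable and is carried as metadata only. The default library is the
Cartesian product of 9 species × 6 ceramides (14:0, 16:0, 18:0, 22:0,
24:0, 24:1 on d18:1) × the valid adduct grid = 192 ions, enumerated
deterministically and sorted by m/z. The monomer table and library
axes ship as a YAML config (`ganglio/data/default_library.yaml`).

## MS1 annotation

Peak lists (CSV/TSV, or centroided mzML via a minimal built-in reader)
are matched against the library with a ±0.3 Da default tolerance,
chosen for MALDI-QIT-TOF mid-mode mass accuracy; it is a configuration
knob, not a measured instrument property.

Matching is **isotope-envelope aware**. Gangliosides at m/z 1500–2100
have broad isotope envelopes, and an apex-picked signal can hide a
second species whose monoisotopic line coincides with the A+k isotope
of the cluster. A library ion is therefore a candidate for a peak when
its monoisotopic m/z lies within tolerance of `peak + k·1.00336` for
some `k ≤ max_isotope_layers` (default 1; 1.00336 Da is the ¹³C–¹²C
spacing). Only non-negative k is used: a peak is always read as a
monoisotopic line, never as the mere isotope of a lighter species
(whose own monoisotopic peak would be annotated separately). This is
what makes the classic co-assigned signal near m/z 1670 work: the
mono-lactonized OAcGD2 Cer16 ion (1669.88) and OAcGM1 Cer24 (1670.97)
merge into one signal, and both are reported. The same mechanism
reproduces the GM2 Cer24 / OAcGD3 Cer16-lactone mixture near 1467. A
by-product of honest candidate reporting is a genuine three-way
coincidence at 1670: GT3 d18:1/14:0 [M−2H₂O−H]⁻ computes to 1669.844,
0.037 Da from the OAcGD2 lactone, and is listed as a third candidate —
it cannot be distinguished at MS1 and is left to MS/MS, like any other
isobar.

Every peak receives exactly one annotation (unique / isobaric /
unassigned; nothing is dropped), candidates sorted by |residual| with
ties broken by species complexity then label. Presence calls
(present / trace / absent) attribute a peak to its top (closest)
candidate; envelope-mate candidates are reported but do not assert
presence by themselves. `trace` means the species' strongest
supporting peak is below a relative-intensity threshold (default 1% of
the base peak).

## Fragment prediction and O-acetyl localization

For every glycosidic edge the non-reducing side yields B (dehydro
fragment − proton) and C (= B + water) ions, the ceramide side Y
(intact molecule − proton) and Z (= Y − water), all singly charged.
Complementarity mz(B)+mz(Y) = mz([M−H]⁻) − 1.00728 holds exactly, and
the acetyl increment sits on exactly one side of each cleavage.
Lactones are opened before prediction (fragment masses come from the
non-dehydrated form); optional −H₂O satellites can be attached to
fragments carrying ≥2 sialic acids. Internal (double-cleavage) and
cross-ring fragments are out of scope.

Localization scores each candidate acetyl position by the summed
intensity of matched *position-informative* fragments — those whose
predicted m/z differs by at least twice the MS2 tolerance (default
±0.5 Da) from the same fragment under **at least one** alternative
position. The "at least one" quantifier matters for trisialylated
species: a fragment set diagnostic against *every* other position does
not exist for the middle sialic acid (each of its informative
fragments is shared with exactly one neighbour), yet the aggregate
score still separates all three positions — with full coverage the
true position outscores its best rival exactly two-fold. The call is
the argmax; it degrades to `ambiguous` when nothing informative
matched or the best/second score ratio is below 2.0.

Isobaric precursor intensity is apportioned across candidates in
proportion to matched candidate-unique fragment intensity (unique =
≥ 2×tolerance from every fragment of every other candidate); when no
unique fragment matches at all, the split is equal and flagged.

## Quantification

The statistic is the apex (maximum height) of each annotated peak.
Species intensity sums over ceramide variants and adduct states
(lactone and full forms are pooled); unassigned peaks are excluded;
isobaric peaks use MS/MS shares when available and a flagged equal
split otherwise. Abundances are normalized to exactly 100% per sample;
the *O*-acetylated fraction is the summed share of OAc-prefixed
species and is invariant to how intensity distributes across a
species' ceramide variants. Entries below a relative floor (default
0.1%) are flagged as trace but stay in the totals.

## Pathway mapping

The built-in graph encodes the ganglio-series scheme: GlcCer
→(B4GALT6) LacCer, then ST3GAL5 / ST8SIA1 / ST8SIA5 create the a/b/c
precursors GM3 / GD3 / GT3; each series precursor (including LacCer
for the 0-series) starts a parallel elongation lane through B4GALNT1 →
B3GALT4 → ST3GAL2 → ST8SIA5. *O*-acetylated species attach as leaves
off their parent via CASD1 (the only known human sialate
*O*-acetyltransferase); SLC33A1 (Golgi acetyl-CoA transporter) is a
gene node without a catalytic edge. The graph is acyclic and exports
to GraphML, node-link JSON and SIF (Cytoscape-friendly), colors
embedded as node attributes.

Gene values are −ΔΔCt log2 ratios computed against a user-named
reference gene (deliberately required — no silent housekeeping-gene
default). Metabolite values are abundance differences in percentage
points; a species quantified in only one condition is imputed as 0
with a flag, one absent from both is no-data. Colors interpolate
linearly in RGB between white at 0 and the endpoint, clamped at ±2
(genes: blue/red) and ±8 (metabolites: green/fuchsia); no-data nodes
are grey (#808080). Endpoint colors are pure RGB primaries/secondaries
since only color names, not hex values, are conventional here.

## Synthetic data

`simulate_ms1` produces one centroid per expected (species, ceramide,
adduct) ion with intensity ∝ abundance × ceramide weight × adduct
weight. Noise model: multiplicative log-normal intensity noise with
unit mean (MALDI shot-to-shot variation), Gaussian m/z jitter, and
uniform-random contaminant peaks in the 1000–3000 scan range. The
default ceramide mixture is C16 0.45 / C24:0 0.30 / C24:1 0.10 /
C18 0.06 / C22 0.05 / C14 0.04 (C16 and C24 dominant, minors present,
C24 partly unsaturated); di/trisialylated species put 85% of their
weight on the maximal lactone and 15% one step below, reflecting that
oligosialylated species are observed mainly dehydrated. Presets:
`parental` (a-series only), `hs578t_like` (a-series plus OAcGM1,
OAcGD2, OAcGD3, OAcGT3 and minor GD2), `gd3s_plus` (b/c-series rich,
31% total OAc). Preset abundances encode qualitative expression
patterns, not measured values.

`simulate_msms` retains a random fragment subset: the prefix of a
seed-determined permutation, so for a fixed seed a higher coverage is
a superset of a lower one. This common-random-numbers design is what
makes accuracy-vs-coverage curves cleanly monotone. `simulate_qpcr`
inverse-constructs two Ct tables so the recovered log2 ratios equal
the planted ones exactly at zero noise.

What the generators deliberately do **not** emulate: isotope
envelopes and profile-mode peak shapes, in-source acetyl loss,
detector saturation, chemical background structure, or correlated
ceramide distributions across species. Passing round-trip tests
therefore demonstrates the internal consistency of the calculus and
the pipeline's statistical behaviour under the stated noise model, not
instrument-level performance on real extracts.

## Numerical choices and test scales

All comparisons use absolute Da tolerances (1e-6 for recomputability,
1e-4 against the atomic-sum oracle, which reflects the 5-decimal
rounding of the residue-mass table). Report rounding is half-up at one
decimal, matching how these masses are conventionally printed.
Candidate and enumeration ties break deterministically (complexity,
then label). Simulation studies in the test suite use 50–100 seeded
replicates per condition and 60 replicates per coverage level for
localization curves — sizes at which the asserted margins (recall
≥ 0.95, abundance error ≤ 2 points) are stable across seeds. The
localization margin threshold of 2.0 equals the worst-case noise-free
score ratio for trisialylated species, so full-coverage calls are
never ambiguous.

## Known limitations

* Fragment charge is fixed at 1−; no internal or A/X cross-ring ions.
* The acetylated carbon (O-7 vs O-9) is not modeled — mass-silent.
* Average (non-monoisotopic) masses, positive mode, and multiply
  charged ions are out of scope; species beyond the nine named ones
  are configurable but untested.
* mzML reading covers centroided spectra with plain or zlib-packed
  32/64-bit float arrays only.
* MS1 isobar coincidences (e.g. the three-way group at m/z 1670)
  are inherent to the mass calculus; resolution requires MS/MS and,
  failing that, remains an explicit equal-split flag in downstream
  quantification.
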