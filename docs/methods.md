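# Methods

## Sequence windows and mutation catalogs

Three windows are shipped in 1-based UniProt numbering: the APP fragment
M671–S730 (60 residues, β-secretase site through the end of the
transmembrane helix), PS1 D1 = A251–L286 (36 residues, part of TM6 plus the
perimembrane region, containing catalytic D257 and the endoproteolysis site
L286) and PS1 D2 = L364–A400 (37 residues around TM7, containing catalytic
D385). The window strings are cross-checked at construction against the
shipped catalogs: every catalogued wild-type letter, both endpoints of each
window, and both catalytic aspartates must match, which pins 20 of the 36
D1 positions and 14 of the 37 D2 positions directly.

Catalogs hold exactly the published FAD substitution lists — 14 in the APP
transmembrane window (L705V … L723P, with variant names such as Indiana for
V717F), 17 in D1 (Y256F … A285V) and 12 in D2 (S365Y … A396T, kept in the
published order, which is not position-sorted). Where a position carries
several pathogenic substitutions, only the named ones are shipped;
hypothetical second variants at single-variant positions are not guessed.
`apply_mutation` validates position and wild-type letter and returns a new
window (inputs are immutable); `validate_catalog` reports per-entry
pass/fail rather than raising, so foreign catalogs can be audited.

## Disorder scoring

The per-residue disorder index DI ∈ [0, 1] has two sources.

**Built-in scorer.** A closed-form order/disorder balance in the FoldIndex
tradition: over a sliding window of width w = 11 (odd, truncated — not
padded — at the sequence ends), the mean normalised Kyte–Doolittle
hydropathy ⟨H⟩ = mean((KD + 4.5)/9) and mean side-chain charge ⟨q⟩
(D, E = −1; K, R = +1; H treated neutral; termini uncharged) give a fold
index

    I = 2.785·⟨H⟩ − |⟨q⟩| − 1.151,

mapped to DI = 1/(1 + exp(k·I)) with steepness k = 5.0, chosen so |I| = 1
lands at DI ≈ 0.007/0.993. All coefficients, the scale and the charge map
are configurable through `ScorerParams`. This scorer is a transparent,
deterministic stand-in for trained disorder predictors: it makes the whole
ΔDI pipeline executable and testable offline, but no claim is made that its
per-mutation signs reproduce a trained predictor's.

**External adapter.** Trained-predictor output (e.g. DISOPRED3) enters the
same pipeline through a version-agnostic column format: whitespace-separated
`index residue mark probability` lines, mark `*`/`.` for
disordered/ordered, `#` comments, consecutive indices enforced. The writer
emits the identical dialect (6-decimal probabilities), so generated
fixtures round-trip bit-exactly. Mixing built-in and external profiles in
one difference is rejected — the two scales are not comparable.

## ΔDI statistics

ΔDI(i) = DI_mut(i) − DI_wt(i); positive means the mutation increases local
disorder. Published per-mutation disorder changes are single numbers whose
aggregation from per-residue output is not specified, so both defensible
aggregates are reported: `ddi_sum = 100·Σ ΔDI(i)` (primary) and
`ddi_peak = 100·max|ΔDI(i)|`. The ×100 scale puts a 0.10 average
probability shift over ~10 residues in the low-teens, the magnitude range
quoted for APP transmembrane mutants; this is a calibration convention, not
ground truth. A mutation's sign is the sign of `ddi_sum`, with
|ddi_sum| < 1e-9 counted as zero. Sign summaries report the majority
direction, counts, and the minority-sign mutations ("exceptions"); exact
ties give "no majority" and no exceptions. With the built-in scorer ΔDI is
exactly local: entries farther than ⌊w/2⌋ from the mutated position are
identically zero.

## Membrane-curvature model

PS1 embedded in a flat membrane is a cylinder with footprint diameter
D = 4.0 nm and membrane span t = 4.5 nm (typical of solved γ-secretase
structures; the defaults are configurable). In a spherical vesicle the
protein instead occupies a cone whose apex is the vesicle centre. The
stated organelle diameter Ω is taken as the cytosolic (outer) leaflet
diameter, so R_cyt = Ω/2 and the luminal footprint sits on
R_lum = R_cyt − t; this radius convention is the one that reproduces both
quoted early-endosome endpoints (≈12 Å at 40 nm and ≈4 Å at 100 nm)
simultaneously, and is documented as reverse-engineered from them. Chords
along one cone scale linearly with sphere radius, so the cytosolic
expansion (defined as the increase in footprint *chord*, which differs from
the arc definition by < 2 % at these curvatures) has the exact closed form

    d = D·R_cyt/R_lum − D = D·t/(Ω/2 − t),

returned in Å. Degenerate geometry (t ≥ Ω/2) raises rather than returning
a negative radius. d is strictly decreasing in Ω, strictly increasing in D
and t, and recovers the flat limit d → 0 as Ω → ∞.

Bias thresholds: d ≥ 4 Å is labelled M1-biased (the early-endosome range),
d ≤ 1 Å M2-biased (large late endosomes and the flat plasma membrane,
d = 0), in between intermediate. The thresholds come from the model's own
d ranges and are fully configurable. A known tension is recorded rather
than resolved: the "< 1 Å" late-endosome figure holds under this model only
toward the 400 nm end of the late-endosome range (d(250 nm) ≈ 1.5 Å, which
the default thresholds therefore label intermediate). No membrane
elasticity, lipid composition or pH effects are modelled.

## Structure comparison and M1/M2 classification

Coordinates are read from PDB or mmCIF via gemmi: hydrogens and waters are
dropped, the first-listed alternate-location conformer of each atom is
kept, and deposited residue numbering (with insertion codes) is preserved.
Superposition pairs Cα atoms by (residue number, insertion code) over the
TM7–TM9 anchor — the region that overlaps across solved γ-secretase
conformers — and solves the least-squares rotation by the Kabsch/SVD
construction with the determinant correction for proper rotations; the
test suite cross-checks the RMSD against an independent quaternion
(Horn) eigenvector oracle. Selections resolving to fewer than 3 common Cα
raise; near-degenerate (collinear) selections set a rank warning on the
result instead of failing, since the RMSD is still well-defined. Probe
displacement (e.g. TM6) reports per-residue Cα distances after applying
the anchor transform, listing unresolved probe residues as absent.

Contacts use the conventional 4.5 Å heavy-atom van der Waals criterion
(configurable): all inter-chain residue pairs whose minimum heavy-atom
distance is within the cutoff, computed with a KD-tree and reduced to
per-pair minima. The M1 score of a complex is the fraction of APP–PS1
contact pairs whose PS1 residue lies in D1, the M2 score likewise for D2;
a call requires a score gap above the margin (default 0.1), otherwise
ambiguous — as is a contact-free map. TM boundary ranges are not
machine-readable from published figures, so editable defaults are shipped
(TM6 244–264, TM7 381–401, TM8 407–429, TM9 433–453, consistent with
UniProt P49768 topology) and every region-dependent operation takes a
`RegionSpec` explicitly, including a per-structure APP numbering offset
for chains deposited in Aβ numbering (offset 671). Catalytic distances are
minimum heavy-atom distances from the VIAT stretch (APP 711–714, spanning
the Aβ42 cleavage boundary) to each aspartate's side chain, falling back
to Cα (flagged) when only backbone is modeled.

The module classifies supplied structures; it does not rebuild, minimise
or dock models, and it makes no attempt to reproduce displacement figures
defined against unreleased manually built coordinates.

## Synthetic fixtures

Toy complexes are ideal α-helices — Cα at radius 2.3 Å, rise 1.5 Å and
twist 100° per residue, poly-alanine, arbitrary axis/origin/phase — written
as minimal PDB ATOM records. They are geometric objects with exact known
ground truth (consecutive Cα–Cα distance 3.83 Å, constructed rotations and
separations), not physically realistic proteins: passing tests demonstrate
numerical correctness of the operations, not biological fidelity on real
structures (no side chains, no bends, no realistic packing). The M1/M2
presets place an APP helix 7 Å from a PS1 helix numbered over D1 or D2
respectively, with the other region's helix 40 Å away. Optional Gaussian
coordinate jitter is seeded and bitwise reproducible. Disorder-profile
pairs inject exact per-position score edits and round-trip through the file
dialect, recovering the injected differences ×100 in `ddi_sum`.

## Numerical conventions

Zero-sign tolerance |ddi_sum| < 1e-9; superposition rank warning at a
singular-value ratio of 1e-8; PDB coordinates carry 3 decimals (round-trip
tolerance 1e-3 Å); profile files carry 6-decimal probabilities. All
computations are deterministic; the only randomness in the package is the
opt-in, seeded fixture jitter.

## Problem sizes

Everything here is small and closed-form: windows of 36–60 residues,
catalogs of 12–17 mutations, toy complexes of ≤ 60 atoms. The full test
suite (including property-based checks against brute-force oracles) runs
in a few seconds on one CPU with no network access, and the acceptance
script in well under a second.
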