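# Methods

## Helical-wheel descriptors

An ideal α-helix advances 100° per residue around its axis (3.6
residues/turn), so residue *n* projects to azimuth (n−1)·100° on the helical
wheel. All descriptors are functions of the sequence alone:

- **Hydrophobicity scale.** Default is the Fauchère–Pliška octanol/water
  transfer scale (G = 0), the scale the HeliQuest web tool uses; any 20-entry
  scale can be substituted through `HydrophobicityScale`. Whole-segment means
  are used — no window smoothing.
- **Hydrophobic moment.** μH = (1/N)·|Σ H_i e^{iδ(n−1)}|, angles in degrees,
  δ = 100° by default and overridable. The moment is reported normalised by
  N (mean-moment convention); the unnormalised vector-sum magnitude is
  available via `normalize=False`. μH is invariant under a global azimuth
  offset and bounded by (1/N)Σ|H_i|; both are asserted in tests.
- **Net charge** counts K/R as +1 and D/E as −1 at neutral pH. Histidine is
  treated as neutral and termini are ignored, because the helix is an
  internal segment of a larger protein, not a free peptide.
- **Residue classes.** Polar {S,T,N,H,Q,E,D,K,R}, apolar
  {A,L,V,I,M,Y,W,F,P,C}, charged {E,D,K,R} ⊂ polar, bulky-hydrophobic
  {F,W} ⊂ apolar. Glycine belongs to neither the polar nor the apolar set,
  so polar + apolar + glycine partitions any sequence — a standing test
  invariant. The wheel-rendering colour classes group G with A ("small"),
  but counting always treats A as apolar; the colour tag is rendering-only.

## Feature matrix and PCA

Each helix contributes 28 features: length, net charge, ⟨H⟩, μH, the four
class counts, and the 20 per-residue counts (alphabetical). Each column is
z-scored (mean 0, SD 1, ddof = 1); zero-variance columns (e.g. `count_W` in
a W-free dataset) are dropped with a warning rather than failing the run.
PCA is the eigendecomposition of the covariance of the z-scored matrix —
i.e. correlation PCA — computed via SVD. Conventions chosen for
determinism:

- components ordered by descending eigenvalue;
- each eigenvector's sign fixed so its largest-|loading| entry is positive;
- loading-report ties broken alphabetically by feature name;
- quartiles in group summaries use linear interpolation.

Explained-variance ratios are always reported over *all* components (they
sum to 1); three components are retained by default, the smallest number
that explains more than half the variance in the motivating ten-group
dataset. `PCAResults.project` applies the stored means/SDs to new rows, so
training-matrix projection reproduces the stored scores exactly.

## Trajectory descriptors

Frames are coordinates in nm; on disk, multi-model PDB in Å. Protein vs.
lipid is assigned from residue names (PE/PC/PI pseudo-beads and common
phospholipids); heavy atoms are element ≠ H; phosphate-head atoms are those
named P, P*, or phosphate oxygens (O1P/OP1 style).

- **Helix axis**: first principal axis of the Cα cloud (SVD), oriented so
  its dot product with the N→C chord is positive. The principal-axis fit is
  robust to end fraying; the chord fixes the sign. On a finite ideal helix
  whose 100°/residue winding does not close an integer number of turns (24
  residues = 6.67 turns), the fit carries a small systematic offset
  (~0.2° at 24 residues) — well inside the 0.5° tolerance used in the
  recovery tests, but worth knowing when comparing to analytic axes.
- **Tilt** α = arcsin(axis_z) ∈ [−90°, +90°], positive when the N→C axis
  points toward +z (C terminus above the membrane plane). Mean, SD and SEM
  over frames are reported; per-replica aggregation is left to the caller,
  and persistence is always computed per simulation, not pooled.
- **Contacts**: a residue (heavy atoms) is in contact with a lipid class
  (phosphate atoms) when the minimum pairwise distance is strictly below
  the cutoff, default 0.45 nm. Persistence = longest unbroken run of
  contact frames × dt. `top_contacts` ranks residue/lipid-class pairs by
  persistence (ties: ascending residue number, then class name).
- **Compactness** r: per-frame minimum heavy-atom distance between a
  reference residue (e.g. the catalytic-pocket tyrosine of the conjugate)
  and the helix residues.
- **Alignment**: `align_frames_to_x` rotates each frame about z so the
  helix axis projects onto +x; z is untouched, so tilt is invariant — a
  test property. A numerically vertical axis leaves the frame unrotated
  with a warning.
- Periodic boundaries are off by default (synthetic data is unwrapped);
  when enabled with an orthorhombic box, minimum-image distances are used.

## CD helicity

% helix = −(MRE₂₂₂ + 2340)/303, so MRE₂₂₂ = −2340 ↦ 0 % and −32640 ↦ 100 %.
The published form of this calibration is often written without the leading
minus even though helical MRE at 222 nm is negative; the sign here is chosen
so helicity grows as the 222 nm band deepens, which is the only direction
consistent with the calibration constants. Estimates outside [0, 100] —
possible with noisy baselines — are clipped with a warning rather than
raised. MRE at 222 nm is linearly interpolated if the wavelength grid does
not sample it exactly; extrapolation outside the scanned range is an error.

## Synthetic generators

All generators are pure functions of (spec, seed) — same inputs, identical
bytes out.

**AH families.** Each group (family × phylum) draws a fixed-length consensus
helix, residue by residue: positions whose wheel azimuth lies within ±90° of
the membrane-facing direction sample from the group's hydrophobic-face
profile, the rest from its hydrophilic-face profile. Each member then
substitutes every position with probability 0.15, resampling from the same
face profile. The consensus-plus-substitution design reflects two features
of real homolog collections that independent sampling would miss: members
are related by descent, and the helix region is cut from a multiple
alignment, so per-group length is essentially constant. The substitution
rate is calibrated to within-group mean pairwise identity of ~75–80 %
(measured 75 % at rate 0.15; two members diverge independently from the
consensus, so identity ≈ (1−m)² plus coincidental matches), typical of a
conserved functional helix across one phylum. The default ten groups use
the canonical group sizes (1886 sequences) and face profiles that encode
only the documented family contrasts — ATG3-like: low hydrophobicity, no
W/F, little G; ATG2-like: high hydrophobicity with W and F;
ATG14/VPS34/NUP133-like: intermediate; Spo20-like: a largely charged polar
face. The profiles are tunable configuration, not claims about true residue
frequencies. What a green PCA test establishes is therefore that the
pipeline recovers planted compositional structure of realistic strength —
not that the real families have these exact frequencies.

**Trajectories.** An ideal α-helix backbone (Cα only: 100°/residue,
0.15 nm rise, 0.23 nm ring radius) is rigidly placed at per-frame tilt
α_t ~ Normal(μ_α, σ_α) with its centre 2.0 nm above a planar grid of lipid
phosphate beads (classes PE/PC/PI at 55/30/15 %), plus Gaussian coordinate
jitter (default 0.02 nm) on the helix atoms. Defaults μ_α = 5.0° and
σ_α = 7.5° emulate a wild-type-like helix whose tilt fluctuates over a
~30° range. Scripted contact episodes move a dedicated bead of the
requested lipid class to 0.3 nm from the requested residue's Cα, directed
radially outward from the helix axis — at that placement the nearest
neighbouring residues sit ≥ 0.6 nm away, outside the 0.45 nm cutoff, so an
episode creates exactly one contact pair; outside its episodes the bead
parks several nm away. Overlapping episodes for the same pair are merged
with a warning. The generator emulates rigid-body placement statistics
only: no internal helix dynamics, no secondary-structure fraying, no
realistic lipid packing — tests on it validate the descriptor operators,
not MD observables. The multi-microsecond atomistic quantities (wild-type
vs. 5W tilt means, the ~400 ns lipid contact) are explicitly out of desk
reach; the substituted acceptance checks are exact recovery of prescribed
tilt and scripted contacts.

**CD spectra.** A helical basis (208/222 nm minima, ~192 nm maximum) and a
coil basis (~198 nm minimum) are each rescaled so their value at 222 nm is
exactly the 100 %- and 0 %-helix calibration points (−32640 and −2340);
mixing them with weight f and adding per-point Gaussian noise yields a
spectrum whose noiseless helicity estimate is exactly 100·f. The curve
shapes away from 222 nm are plausible, not fitted basis spectra.

## Numerical choices and degenerate inputs

- Strict inequality for contacts (d = cutoff is not a contact).
- Empty boolean series → persistence 0 with a warning; empty atom
  selections, non-finite coordinates, dt ≤ 0 → errors.
- Sequences are validated against the 20 standard letters; unknown letters
  are rejected with the offending character and record id named, never
  silently remapped, because every downstream feature needs a defined
  per-residue value.
- Region coordinates are 1-based inclusive; nested extractions compose in
  parent-protein coordinates.
- Feature tables round-trip through TSV at full float precision.

## Known limitations

- The sequence generator has no phylogenetic tree within a group (star
  topology around the consensus) and no indels; per-group length is fixed.
- The trajectory generator's helix is Cα-only; "heavy-atom" contact
  selections therefore reduce to Cα for the synthetic protein.
- The CD model covers only the two-state helix/coil mixture at 222 nm; no
  deconvolution into further secondary-structure classes.
- PCA rank checking uses min(rows−1, columns), not the numerical rank; a
  request for components beyond the numerical rank of degenerate data
  yields near-zero eigenvalues rather than an error.
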