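# amphiprof

Tools for asking what makes an amphipathic α-helix (AH) *distinctive*.
Peripheral membrane proteins insert AHs into one bilayer leaflet; the
autophagy E2 enzyme ATG3 carries an unusually *weakly* hydrophobic AH at its
N terminus (residues 1–24, `MQNVINTVKGKALEVAEYLTPVLK`), and comparing such a
helix against AH families from other proteins (ATG14, ATG2, VPS34, NUP133,
Spo20) requires a quantitative, reproducible feature pipeline. `amphiprof`
provides that pipeline end to end, together with synthetic-data generators so
every stage runs — and is tested — without any downloads or MD engine.

## What it computes

**Helical-wheel descriptors** (`amphiprof.physchem`). Residue *n* of an
α-helix sits at azimuth (n−1)·100° on the helical wheel. For a sequence of
length N with per-residue hydrophobicities H_i (Fauchère–Pliška scale by
default):

- mean hydrophobicity ⟨H⟩ = (1/N) Σ H_i
- hydrophobic moment μH = (1/N) · |Σ H_i · e^{i·δ(n−1)}|, δ = 100°
- net charge z = #K + #R − #D − #E (neutral pH, internal segment)
- class counts: polar {S,T,N,H,Q,E,D,K,R}, apolar {A,L,V,I,M,Y,W,F,P,C},
  charged {E,D,K,R}, bulky-hydrophobic {F,W}, and glycine on its own.

**Family comparison** (`amphiprof.multivariate`). A 28-feature matrix
(8 summary descriptors + 20 residue counts) is z-scored per feature and
decomposed by PCA, statsmodels-style: `AmphipathicPCA(matrix, 3).fit()`
returns a `PCAResults` with loadings, explained-variance ratios, scores,
`project()` and `summary()`.

**Membrane-trajectory descriptors** (`amphiprof.trajectory`). From
multi-model PDB frames (protein + lipid atoms, nm in memory): the signed
helix tilt α = arcsin(axis_z) of the principal Cα axis (positive = C terminus
up), residue–lipid phosphate contacts at d < 0.45 nm, the maximum contact
persistence (longest unbroken run × frame interval), the k longest-lived
residue/lipid-class contacts, and the complex-compactness distance r.

**CD helicity** (`amphiprof.cd_helicity`). Percent α-helix from the mean
residue ellipticity at 222 nm: % helix = −(MRE₂₂₂ + 2340)/303, clipped to
[0, 100].

**Synthetic data** (`amphiprof.synthetic`). Ground-truth generators for all
of the above: homolog-like AH families (consensus + point substitutions,
face-structured residue sampling), rigid-helix membrane trajectories with
prescribed tilt and scripted contact episodes, and CD spectra from a known
helix fraction.

## Worked example

```python
from amphiprof.multivariate import AmphipathicPCA, build_matrix
from amphiprof.physchem import profile_sequence
from amphiprof.synthetic import generate_ah_dataset

records, labels, _ = generate_ah_dataset(seed=42)   # 1886 sequences, 10 groups
profiles = [profile_sequence(r.id, r.sequence) for r in records]
res = AmphipathicPCA(build_matrix(profiles, labels), n_components=3).fit()
print(res.summary())
```

```
Amphipathic-helix feature PCA
==============================================
rows: 1886   features: 28   components retained: 3
----------------------------------------------
component   eigenvalue  % variance       cum %
PC1             7.9500       28.39       28.39
PC2             4.1707       14.90       43.29
PC3             3.1671       11.31       54.60
----------------------------------------------
PC1 top loadings: hydrophobicity (+0.33), n_bulky (+0.32), count_G (+0.30)
PC2 top loadings: length (+0.37), n_apolar (+0.35), count_Q (+0.32)
PC3 top loadings: count_T (+0.43), count_N (+0.35), count_K (-0.31)
```

The first three components capture 54.6 % of the variance, and PC1 is loaded
by mean hydrophobicity and the bulky-residue count — the axes that set the
ATG3-like family (low ⟨H⟩, no W/F) apart from the strongly hydrophobic
ATG2-like family. Profiling the wild-type peptide itself:

```python
p = profile_sequence("hATG3_1-24", "MQNVINTVKGKALEVAEYLTPVLK")
# N=24  z=+1  <H>=0.423  muH=0.422  bulky=0
```

A command-line interface mirrors the library:

```bash
amphiprof simulate ah --seed 42 --out data/
amphiprof profile --fasta data/ah_dataset.fasta --out features.tsv
amphiprof pca --table features.tsv --labels data/labels.tsv --k 3 --report
amphiprof traj --pdb traj.pdb --dt 1.0 --cutoff 0.45 --top 10
amphiprof cd --spectrum spectrum.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline from scratch — dataset
generation with the ten canonical group sizes, peptide profiling, the 5W
tryptophan-substitution construction, z-scoring and PCA — and writes the
headline numbers as JSON:

```bash
python scripts/acceptance.py --seed 42 --out results/acceptance.json
```

See `docs/methods.md` for model details, parameter defaults, and what the
synthetic generators do and do not emulate.
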