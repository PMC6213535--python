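# oildrop

Fuzzy-oil-drop (FOD) scoring of protein hydrophobic cores, for structural
bioinformaticians studying globularity, misfolding and amyloid fibrils.

## The model

A well-folded globular protein buries hydrophobic residues centrally and
exposes hydrophilic ones. The FOD model idealizes this as a 3D Gaussian
hydrophobicity field peaking at the molecular center and decaying to near
zero at the surface (placed at 3σ along each principal axis). For a
structural unit of N residues, each reduced to one *effective point* (the
side-chain heavy-atom centroid; Cα for glycine), four aligned per-residue
distributions are compared, each normalized to sum to 1:

- **T** (theoretical): the Gaussian field evaluated at each effective point,
- **O** (observed): `O_i ∝ Σ_j (H_i + H_j) g(r_ij)`, a distance-weighted sum
  of intrinsic hydrophobicities with a polynomial contact kernel `g`
  (`g(0)=1`, `g(r≥c)=0`, default cutoff `c = 9 Å`),
- **H** (intrinsic): sequence-only hydrophobicity, normalized,
- **R** (uniform): `1/N` per residue.

The headline statistic is the relative distance built from Kullback–Leibler
divergences:

```
RD = D(O‖T) / (D(O‖T) + D(O‖REF))
```

with REF = R (giving RD(T-O-R)) or REF = H (giving RD(T-O-H)). RD < 0.5
means the observed distribution is closer to the monocentric ideal than to
the structure-free reference: the unit has a hydrophobic core. The
amyloid-like signature is high RD in both frames together with low or
negative Pearson correlations HvT and TvO but high HvO — intrinsic residue
properties dominate over any shared core, producing hydrophobicity bands
that propagate along a fibril axis. Units can be scored in different frames
(a chain within a superfibril, within one protofibril, or alone), and the
package also scores fragments, sliding 5-residue windows, residue-exclusion
variants, and inter-unit interfaces detected by atomic contact.

## Worked example

```python
from oildrop import (GlobuleSpec, FibrilSpec, HydrophobicCoreModel,
                     make_globule, make_fibril)

# a micelle-like globule: hydrophobic residues sorted to the center
globule = make_globule(GlobuleSpec(n=60, seed=7))
print(HydrophobicCoreModel(globule).fit().summary())

# one chain of a 5-copy VQIVYK stack, scored in the whole fibril's frame
fibril = make_fibril(FibrilSpec(peptide="VQIVYK", n_copies=5, seed=3))
print(HydrophobicCoreModel(fibril, gaussian_from="all",
                           profile_over="chain:C").fit().summary())
```

prints

```
Hydrophobic-core (fuzzy oil drop) status
================================================
structure:      globule-n60-f1-s7
gaussian frame: all
scored unit:    all  (n = 60)
...
RD(T-O-R):         0.430
classification: core_accordant
```

for the globule — RD(T-O-R) = 0.430 < 0.5, so the observed hydrophobicity
matches a central core — and, for the fibril chain,

```
RD(T-O-R):         0.794
RD(T-O-H):         0.927
classification: discordant
```

RD far above 0.5 in both frames: the chain's hydrophobicity is organized by
its intrinsic band pattern, not by a shared core. Real deposited structures
work the same way:

```
oildrop status fibril.pdb --gaussian-from all --gaussian-from chain:C
oildrop scan structure.pdb --profile-over chain:A --window 5
oildrop interface complex.pdb --group-a chains:A,B --group-b chains:C,D
oildrop compare model1.pdb model2.pdb model3.pdb
```

`compare` ranks inputs by decreasing globularity (increasing RD(T-O-R)).
The packaged intrinsic-hydrophobicity scale is a normalized Kyte–Doolittle
index; supply your own 2-column `AA3 value` table with `--scale`.

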