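# Methods

## Model

A structural unit is reduced to one effective point per residue: the
geometric (unweighted) center of its side-chain heavy atoms, the Cα for
glycine, and the Cα as a fallback for residues whose side chain is missing
from the coordinates. Cα-only inputs (coarse models, synthetic fixtures)
are therefore legal. The idealized hydrophobicity field is a 3D Gaussian
*capsule*: its center is the unweighted mean of the effective points, its
axes the covariance eigenvectors (eigenvalues descending mapped to x, y,
z), and each σ is the largest absolute extent of any point along that axis
divided by 3, so the surface of the point cloud sits at 3σ where the field
is `exp(-4.5) ≈ 0.011` of its peak. σ is floored at 1 Å so that nearly flat
or collinear units (short peptides) keep a well-defined field. Eigenvector
signs are fixed by making each axis's largest-magnitude component positive
(for determinism), with the third axis negated if needed to keep a proper
rotation; the theoretical profile is sign-invariant, so this only affects
the stored frame.

Four per-residue distributions, each normalized to sum to 1, are compared:

- `T_i ∝ exp(-Σ_axis x_i,axis² / (2 σ_axis²))` in the capsule frame;
- `O_i ∝ Σ_j (H_i + H_j) g(r_ij)`, summed over all residues of the
  *Gaussian frame* (including `j = i`, which contributes `2 H_i` since
  `g(0) = 1`; the self-term keeps single-residue input well defined and can
  be toggled). The kernel is the polynomial
  `g(r) = 1 − ½(7s² − 9s⁴ + 5s⁶ − s⁸)`, `s = r/c`, vanishing at and beyond
  the cutoff `c = 9 Å` (configurable);
- `H_i = H_i^r / Σ_j H_j^r`, the intrinsic (sequence-only) distribution;
- `R_i = 1/N`, the uniform reference.

The relative distance `RD = D(O‖T) / (D(O‖T) + D(O‖REF))` uses
Kullback–Leibler divergences in bits (RD itself is base-invariant, which
the tests assert to 1e-12). REF = R gives RD(T-O-R), REF = H gives
RD(T-O-H).

### Framing

A unit may be scored in the frame of a larger assembly: the capsule fit
*and* the pairwise O summation run over the `gaussian_from` selection, the
resulting T and O are restricted to the `profile_over` selection and
renormalized, while H and R are built on the scored residues alone. This
reproduces the three standard framings — chain-in-superfibril,
chain-in-protofibril, chain-alone — as well as interface scoring. The
observed profile of a chain inside a complex deliberately includes pairwise
contributions from the whole complex; scoring the chain in isolation is the
`profile_over = gaussian_from = chain` case.

### Derived statuses

Fragment and exclusion statuses restrict T, O, H to the residue subset and
renormalize (required for the divergences to remain well defined on
subsets) and rebuild R as 1/n over the subset. A full-range restriction is
a true no-op, bit-identical to the unit status. Window scans correlate raw
(un-renormalized) windowed profile values — Pearson correlation is
scale-invariant, so renormalization would change nothing — over an odd-width
moving frame (default 5 residues), assigning each value to the central
residue. A window containing a constant vector is reported as undefined,
never as zero. A window is flagged amyloid-like when HvT < 0, TvO < 0 and
HvO > 0.5.

### Classification

- `core_accordant`: RD(T-O-R) < 0.5;
- `amyloid_like`: RD(T-O-R) ≥ 0.5 and RD(T-O-H) ≥ 0.5 and HvT < 0.1 and
  TvO < 0.35 and HvO > 0.5;
- `discordant`: otherwise;
- `indeterminate`: correlations undefined (constant profiles, n < 3).

The correlation cutoffs are heuristics induced from the verbal criteria
"low (even negative) HvT and TvO, high HvO" and are fully configurable
(`Thresholds`); only the RD < 0.5 globularity cutoff is canonical.

## Intrinsic hydrophobicity scale

The packaged default is the Kyte–Doolittle hydropathy index mapped to
(0, 1] via `(KD + 5.0)/9.5`. The shift keeps every residue strictly
positive so the H reference distribution never vanishes on the support of
O, which would make RD(T-O-H) undefined for any sequence containing the
most hydrophilic residue. Any user scale can be supplied as a 2-column
`AA3 value` text table; all RD values and correlations are scale-relative,
so numeric agreement with results computed under a different (unpublished)
scale is expected only up to tolerance.

## Structure input

Parsing uses gemmi (PDB and mmCIF). Hydrogens and waters are removed;
hetero compounds are excluded unless whitelisted; alternate locations
resolve to the highest-occupancy conformer (ties: first encountered);
nonstandard residues with a standard parent (MSE→MET etc.) are remapped and
others dropped with a warning; multi-model (NMR) files default to model 1.
Fragment selections accept both 1-based local numbering (default) and
author numbering (`auth:` prefix), inclusive on both ends.

## Interface analysis

Interface residues are those of either group with at least one heavy-atom
pair within 4 Å of the other group (an approximation of PDBsum-style
non-bonded contact criteria; cutoff and minimum pair count configurable).
Membership is monotone in the cutoff. The interface is scored in the full
complex's Gaussian frame, with residues from both sides included.

## Synthetic structures

The generators produce Cα-only PDB models that exercise every code path
without downloads:

- **Globule** (default n = 60, radius 12 Å): points uniform in a sphere;
  with `sort_fraction = 1` the most hydrophobic residue *types* (rank-wise,
  scale-agnostic) occupy the most central positions. Residue identities are
  drawn uniformly from the 20 standard types. A 12 Å radius gives
  ≈ 120 Å³ per residue, matching typical protein packing.
- **Fibril**: identical extended peptides (Cα spacing 3.8 Å) stacked along
  z with a 4.8 Å rise — the conventional cross-β spacing, chosen here as a
  convention, with optional lateral jitter. Columns of identical residues
  propagate hydrophobicity bands along the stack axis.
- **Identity shuffle**: permutes residue identities (never coordinates) for
  a chosen fraction of residues, producing decoys of graded core disorder.

All generators are deterministic in (spec, seed).

What these fixtures show — and what they do not: the synthetic globule has
no backbone connectivity, no excluded volume and no realistic composition,
so its absolute RD is not comparable to a real protein's. Under the study
conditions the perfectly sorted globule sits near the accordance boundary
(median RD(T-O-R) ≈ 0.5 across generator seeds; the packaged fixture seed
scores 0.43), whereas the *contrast* between constructions — sorted vs
shuffled globules (monotone median RD across shuffle fractions), globules
vs banded fibril stacks, hydrophobic-core vs band-driven interfaces (sign
of HvT) — is large and stable. Passing tests therefore demonstrate that
the statistics order and separate hydrophobicity architectures correctly,
not that any particular real protein would score a particular value.

## Numerical choices

- Divergences in bits; `0·log(0/q) := 0`; `D(O‖REF)` undefined when REF
  vanishes where O > 0 (raised, not silently patched).
- RD = 0/0 (O = T = REF) raises an indeterminate-RD error.
- Undefined correlations are NaN plus an `indeterminate` classification,
  never 0.
- The observed profile has a dense O(N²) path and a cKDTree neighbor-list
  path (automatic above 400 residues); the tests assert both agree with an
  independent double loop to 1e-10.
- Profile sums are validated to 1 ± 1e-9 at construction.

## Problem sizes

The test suite and the acceptance script run on 30–80-residue synthetic
units, 20 replicates per shuffle fraction, 1000 random distribution pairs
for the divergence oracle, and 50 random fixtures for the neighbor-list
check; the full suite completes in a few seconds on one CPU.

## Known limitations

- No solvent accessibility, electrostatics or energy terms; hydrophobicity
  only.
- The contact criteria approximate, not reproduce, PDBsum's rules.
- Absolute RD values depend on the intrinsic scale and the O cutoff;
  cross-study comparisons should fix both.
- Very short peptides (< 15 aa) have no meaningful hydrophobic core; their
  RD only describes the shape of the hydrophobicity distribution.
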