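"""Synthetic labeled structures for testing and calibration.

Two families of toy structures are generated as minimal Calpha-only PDB
models:

* micelle-like globules — residues sampled inside a sphere, optionally with
  the most hydrophobic residue types placed most centrally (the monocentric
  ideal the Gaussian capsule encodes);
* fibrillar stacks — identical extended peptides stacked along one axis
  with a cross-beta-like rise, producing the alternating bands of high and
  low hydrophobicity that propagate along a fibril.

These are statistical fixtures, not physical models: no sterics, no real
secondary structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AtomRecord, Residue, StructureModel
from .scales import AA1_TO_AA3, HydrophobicityScale, default_scale

#: Conventional cross-beta inter-strand spacing (Angstrom).
DEFAULT_RISE = 4.8
#: Calpha-Calpha spacing of an extended chain (Angstrom).
EXTENDED_CA_SPACING = 3.8

CHAIN_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class GlobuleSpec:
    """Micelle-like globule: n residues inside a sphere of the given radius.

    ``sort_fraction`` is the fraction of residues whose hydrophobicity rank
    is matched to their centrality rank (1 = perfectly sorted core,
    0 = random placement). Sorting uses ranks, not values, so it is
    scale-agnostic.
    """

    n: int
    radius: float = 12.0
    sort_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 5:
            raise ValueError("globule needs n >= 5 residues")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.sort_fraction <= 1.0:
            raise ValueError("sort_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FibrilSpec:
    """Fibrillar stack of identical extended peptides.

    ``peptide`` is a one-letter sequence; ``n_copies`` chains are stacked
    along z with the given rise, each getting its own chain label.
    """

    peptide: str
    n_copies: int = 5
    rise: float = DEFAULT_RISE
    lateral_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("fibril needs n_copies >= 2")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        bad = [c for c in self.peptide.upper() if c not in AA1_TO_AA3]
        if bad or not self.peptide:
            raise ValueError(f"peptide has unknown residues: {bad}")


def _ca_residue(chain_id: str, number: int, aa3: str, xyz: np.ndarray) -> Residue:
    atom = AtomRecord(name="CA", element="C", coords=tuple(np.round(xyz, 3)))
    return Residue(chain_id=chain_id, seq_index=str(number), aa3=aa3, atoms=(atom,))


def make_globule(
    spec: GlobuleSpec, scale: HydrophobicityScale | None = None
) -> StructureModel:
    """Sample a globule; deterministic for a fixed (spec, seed)."""
    scale = scale or default_scale()
    rng = np.random.default_rng(spec.seed)

    # uniform sampling inside the sphere
    direction = rng.normal(size=(spec.n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = spec.radius * rng.random(spec.n) ** (1.0 / 3.0)
    xyz = direction * r[:, None]

    aa_pool = sorted(AA1_TO_AA3.values())
    identities = list(rng.choice(aa_pool, size=spec.n))

    # sorted assignment: most hydrophobic identity at the most central point
    centrality = np.argsort(np.linalg.norm(xyz - xyz.mean(0), axis=1))
    by_hydrophobicity = sorted(identities, key=lambda aa: scale[aa], reverse=True)
    assigned = [""] * spec.n
    for rank, pos in enumerate(centrality):
        assigned[pos] = by_hydrophobicity[rank]

    n_loose = int(round((1.0 - spec.sort_fraction) * spec.n))
    if n_loose > 1:
        loose = rng.choice(spec.n, size=n_loose, replace=False)
        perm = rng.permutation(n_loose)
        reshuffled = [assigned[loose[p]] for p in perm]
        for i, pos in enumerate(loose):
            assigned[pos] = reshuffled[i]

    residues = tuple(
        _ca_residue("A", i + 1, assigned[i], xyz[i]) for i in range(spec.n)
    )
    return StructureModel(
        id=f"globule-n{spec.n}-f{spec.sort_fraction:g}-s{spec.seed}",
        chains=("A",),
        residues=residues,
    )


def make_fibril(
    spec: FibrilSpec,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    chain_offset: int = 0,
) -> StructureModel:
    """Stack identical extended peptides along z; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    peptide = spec.peptide.upper()
    n_res = len(peptide)
    origin = np.asarray(origin, dtype=float)

    residues = []
    chains = []
    for copy in range(spec.n_copies):
        chain_id = CHAIN_LABELS[(chain_offset + copy) % len(CHAIN_LABELS)]
        chains.append(chain_id)
        jitter = (
            rng.normal(scale=spec.lateral_jitter, size=(n_res, 2))
            if spec.lateral_jitter > 0
            else np.zeros((n_res, 2))
        )
        for i, aa1 in enumerate(peptide):
            xyz = origin + np.array(
                [i * EXTENDED_CA_SPACING + jitter[i, 0],
                 jitter[i, 1],
                 copy * spec.rise]
            )
            residues.append(_ca_residue(chain_id, i + 1, AA1_TO_AA3[aa1], xyz))
    return StructureModel(
        id=f"fibril-{peptide}-x{spec.n_copies}-s{spec.seed}",
        chains=tuple(chains),
        residues=tuple(residues),
    )


def concat_models(models: list[StructureModel], new_id: str) -> StructureModel:
    """Merge models into one complex; chain labels must not collide."""
    chains: list[str] = []
    residues: list[Residue] = []
    for m in models:
        for c in m.chains:
            if c in chains:
                raise ValueError(f"chain label collision: {c}")
            chains.append(c)
        residues.extend(m.residues)
    return StructureModel(id=new_id, chains=tuple(chains), residues=tuple(residues))


def shuffle_identities(
    model: StructureModel, fraction: float, seed: int = 0
) -> StructureModel:
    """Randomly permute residue identities (not coordinates) for a fraction.

    fraction = 0 returns an identical model; fraction = 1 permutes all
    identities. Deterministic for a fixed seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(model.residues)
    m = int(round(fraction * n))
    if m < 2:
        return model
    chosen = rng.choice(n, size=m, replace=False)
    perm = rng.permutation(m)
    new_aa = {int(chosen[i]): model.residues[int(chosen[perm[i]])].aa3
              for i in range(m)}
    residues = tuple(
        dataclasses.replace(r, aa3=new_aa[i]) if i in new_aa else r
        for i, r in enumerate(model.residues)
    )
    return StructureModel(
        id=f"{model.id}-shuf{fraction:g}-s{seed}",
        chains=model.chains,
        residues=residues,
        model_number=model.model_number,
    )


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    """Record specs, seeds and ground-truth labels next to generated files."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
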