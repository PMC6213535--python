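"""Inter-unit interface detection and scoring.

Interface residues are found by heavy-atom proximity between two residue
groups (an approximation of PDBsum-style non-bonded contact criteria; the
default cutoff is 4 Angstrom). The interface is then scored as a fragment
of the full complex: the Gaussian capsule and the observed-profile pairwise
context come from the whole structure, the profiles are restricted to the
interface residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InterfaceError
from .field import DEFAULT_CUTOFF, build_profiles
from .io import ResidueSelection, StructureModel, select_residues
from .scales import HydrophobicityScale
from .stats import StatusReport, Thresholds, unit_status


@dataclass(frozen=True)
class ContactCriteria:
    """Heavy-atom distance criteria defining an inter-group contact."""

    cutoff: float = 4.0
    atom_set: str = "heavy"  # heavy atoms only (hydrogens are stripped on read)
    min_partner_atoms: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")
        if self.min_partner_atoms < 1:
            raise ValueError("min_partner_atoms must be >= 1")


def _atom_table(selection: ResidueSelection) -> tuple[np.ndarray, np.ndarray]:
    """All heavy-atom coordinates plus the residue index of each atom."""
    coords, owner = [], []
    for ri, res in enumerate(selection.members):
        for atom in res.atoms:
            coords.append(atom.coords)
            owner.append(ri)
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def contact_residues(
    model: StructureModel,
    group_a: ResidueSelection,
    group_b: ResidueSelection,
    criteria: ContactCriteria | None = None,
) -> ResidueSelection | None:
    """Residues of either group in atomic contact with the other group.

    Returns None when no contacts exist (an empty interface is a result,
    not an error). Groups must be disjoint.
    """
    criteria = criteria or ContactCriteria()
    keys_a, keys_b = set(group_a.keys()), set(group_b.keys())
    if keys_a & keys_b:
        raise InterfaceError("contact groups overlap")

    xyz_a, own_a = _atom_table(group_a)
    xyz_b, own_b = _atom_table(group_b)
    pairs = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=criteria.cutoff)

    counts_a = np.zeros(len(group_a), dtype=int)
    counts_b = np.zeros(len(group_b), dtype=int)
    for ia, hits in enumerate(pairs):
        if hits:
            counts_a[own_a[ia]] += len(hits)
            for ib in hits:
                counts_b[own_b[ib]] += 1

    hit_keys = {
        group_a.members[i].key
        for i in np.nonzero(counts_a >= criteria.min_partner_atoms)[0]
    } | {
        group_b.members[i].key
        for i in np.nonzero(counts_b >= criteria.min_partner_atoms)[0]
    }
    if not hit_keys:
        return None
    members = tuple(r for r in model.residues if r.key in hit_keys)
    return ResidueSelection(
        model, members,
        label=f"interface({group_a.label} | {group_b.label})",
    )


def interface_status(
    model: StructureModel,
    group_a: ResidueSelection,
    group_b: ResidueSelection,
    criteria: ContactCriteria | None = None,
    scale: HydrophobicityScale | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    thresholds: Thresholds | None = None,
) -> tuple[StatusReport, ResidueSelection]:
    """Score the interface residues in the full complex's Gaussian frame."""
    interface = contact_residues(model, group_a, group_b, criteria)
    if interface is None:
        raise InterfaceError(
            f"no contacts between {group_a.label} and {group_b.label}"
        )
    whole = select_residues(model, "all")
    profiles = build_profiles(
        gaussian_from=whole, profile_over=interface, scale=scale, cutoff=cutoff
    )
    return unit_status(profiles, thresholds), interface
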