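"""Shared fixtures: hand-written PDB texts and synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from oildrop import (
    FibrilSpec,
    GlobuleSpec,
    HydrophobicCoreModel,
    default_scale,
    make_fibril,
    make_globule,
)


def _atom_line(serial, name, resname, chain, resseq, x, y, z,
               element, altloc=" ", occ=1.00) -> str:
    name_f = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_f}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture(scope="session")
def two_residue_pdb(tmp_path_factory) -> str:
    """Minimal hand-written 2-residue PDB file."""
    lines = [
        _atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        _atom_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0, "C"),
        _atom_line(3, "CB", "ALA", "A", 1, 2.0, 1.0, 0.5, "C"),
        _atom_line(4, "N", "GLY", "A", 2, 3.3, 1.5, 0.0, "N"),
        _atom_line(5, "CA", "GLY", "A", 2, 4.0, 2.8, 0.1, "C"),
        "END",
    ]
    p = tmp_path_factory.mktemp("pdb") / "two_res.pdb"
    p.write_text("\n".join(lines) + "\n")
    return str(p)


@pytest.fixture(scope="session")
def toy3_pdb(tmp_path_factory) -> str:
    """3 residues with known atom coordinates for centroid oracles.

    ALA: single side-chain atom CB at (1,1,1)
    GLY: CA at (5,0,0)
    SER: side-chain CB (8,0,0) and OG (10,2,0) -> centroid (9,1,0)
    Also carries an altloc pair on SER CB (B has higher occupancy).
    """
    lines = [
        _atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
        _atom_line(2, "CB", "ALA", "A", 1, 1.0, 1.0, 1.0, "C"),
        _atom_line(3, "CA", "GLY", "A", 2, 5.0, 0.0, 0.0, "C"),
        _atom_line(4, "CA", "SER", "A", 3, 7.0, 0.0, 0.0, "C"),
        _atom_line(5, "CB", "SER", "A", 3, 0.0, 0.0, 0.0, "C", altloc="A", occ=0.3),
        _atom_line(6, "CB", "SER", "A", 3, 8.0, 0.0, 0.0, "C", altloc="B", occ=0.7),
        _atom_line(7, "OG", "SER", "A", 3, 10.0, 2.0, 0.0, "O"),
        "END",
    ]
    p = tmp_path_factory.mktemp("pdb") / "toy3.pdb"
    p.write_text("\n".join(lines) + "\n")
    return str(p)


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def sorted_globule():
    """Perfectly center-sorted 60-residue globule (the monocentric ideal)."""
    return make_globule(GlobuleSpec(n=60, radius=12.0, sort_fraction=1.0, seed=7))


@pytest.fixture(scope="session")
def random_globule():
    return make_globule(GlobuleSpec(n=60, radius=12.0, sort_fraction=0.0, seed=7))


@pytest.fixture(scope="session")
def vqivyk_fibril():
    """Five stacked copies of the tau-repeat hexapeptide VQIVYK."""
    return make_fibril(FibrilSpec(peptide="VQIVYK", n_copies=5, seed=3))


@pytest.fixture(scope="session")
def band_fibril():
    """Stack of a block-alternating peptide: hydrophobicity bands along z."""
    return make_fibril(FibrilSpec(peptide="VVVKKKVVVKKK", n_copies=5, seed=3))


@pytest.fixture(scope="session")
def sorted_globule_results(sorted_globule):
    return HydrophobicCoreModel(sorted_globule).fit()


@pytest.fixture(scope="session")
def fibril_results(vqivyk_fibril):
    return HydrophobicCoreModel(vqivyk_fibril).fit()


def random_point_set(rng, n, spread=15.0):
    """Random EffectivePointSet for property tests."""
    from oildrop import EffectivePointSet

    pts = rng.normal(scale=spread, size=(n, 3))
    h = rng.random(n)
    labels = tuple(("A", str(i + 1), "ALA") for i in range(n))
    return EffectivePointSet(points=pts, intrinsic=h, labels=labels)
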