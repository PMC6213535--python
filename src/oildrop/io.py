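"""Structure reading, residue selection, and effective-point reduction.

Parsing is delegated to gemmi (PDB and mmCIF). The in-memory model is a
flat, ordered list of standard amino-acid residues; each residue is later
reduced to a single *effective point* — the geometric center of its
side-chain heavy atoms (the Calpha for glycine) — which is the unit of all
fuzzy-oil-drop arithmetic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    MissingModelError,
    SelectionError,
    StructureFormatError,
)
from .scales import AA3_TO_AA1, STANDARD_AA3, HydrophobicityScale

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Nonstandard residues with an obvious standard parent.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "SEP": "SER", "TPO": "THR",
    "PTR": "TYR", "HYP": "PRO", "CSO": "CYS", "MLY": "LYS",
    "PYL": "LYS", "KCX": "LYS",
}


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_index: str  # author residue number + insertion code
    aa3: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.seq_index)

    @property
    def aa1(self) -> str:
        return AA3_TO_AA1.get(self.aa3, "X")


@dataclass(frozen=True)
class StructureModel:
    id: str
    chains: tuple[str, ...]
    residues: tuple[Residue, ...]
    model_number: int = 1

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate (chain, seq_index) pairs in {self.id}")

    def chain_residues(self, chain_id: str) -> tuple[Residue, ...]:
        return tuple(r for r in self.residues if r.chain_id == chain_id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ResidueSelection:
    model: StructureModel
    members: tuple[Residue, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.members:
            raise SelectionError(f"empty selection: {self.label}")

    def __len__(self) -> int:
        return len(self.members)

    def keys(self) -> list[tuple[str, str]]:
        return [r.key for r in self.members]

    def is_subset_of(self, other: "ResidueSelection") -> bool:
        return set(self.keys()) <= set(other.keys())


@dataclass(frozen=True)
class EffectivePointSet:
    """One representative 3D point + intrinsic hydrophobicity per residue."""

    points: np.ndarray  # (n, 3) Angstrom
    intrinsic: np.ndarray  # (n,) nonnegative
    labels: tuple[tuple[str, str, str], ...]  # (chain_id, seq_index, aa3)

    def __post_init__(self) -> None:
        if not (len(self.points) == len(self.intrinsic) == len(self.labels) >= 1):
            raise ValueError("points, intrinsic and labels must align and be non-empty")
        if np.any(self.intrinsic < 0):
            raise ValueError("intrinsic hydrophobicity must be nonnegative")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices: Sequence[int]) -> "EffectivePointSet":
        idx = np.asarray(indices, dtype=int)
        return EffectivePointSet(
            points=self.points[idx],
            intrinsic=self.intrinsic[idx],
            labels=tuple(self.labels[i] for i in idx),
        )


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties -> first encountered."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the surviving atoms
    chosen = set(id(a) for a in best.values())
    return [a for a in res if id(a) in chosen]


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    model_number: int = 1,
    hetero_whitelist: Iterable[str] = (),
) -> StructureModel:
    """Read a PDB/mmCIF file into a StructureModel.

    Hydrogens and waters are dropped; hetero compounds are excluded unless
    whitelisted; alternate locations are resolved to the highest-occupancy
    conformer; nonstandard residues with a standard parent (e.g. MSE) are
    remapped, others are excluded with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    model = None
    for m in st:
        if m.num == model_number:
            model = m
            break
    if model is None:
        if model_number == 1 and len(st) > 0:
            model = st[0]
        else:
            raise MissingModelError(
                f"model {model_number} absent from {path} "
                f"(available: {[m.num for m in st]})"
            )

    whitelist = set(hetero_whitelist)
    residues: list[Residue] = []
    chains: list[str] = []
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            aa3 = res.name.upper()
            is_het = res.het_flag == "H"
            if aa3 not in STANDARD_AA3:
                if aa3 in NONSTANDARD_PARENT:
                    aa3 = NONSTANDARD_PARENT[res.name.upper()]
                elif res.name.upper() in whitelist:
                    pass
                else:
                    if is_het is False:
                        logger.warning(
                            "excluding nonstandard residue %s %s/%s",
                            res.name, chain.name, res.seqid.num,
                        )
                    continue
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name or "X",
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    altloc=a.altloc or "",
                    is_hetero=is_het,
                )
                for a in _resolve_altlocs(res)
                if not a.is_hydrogen()
            ]
            if not atoms:
                continue
            seq_index = f"{res.seqid.num}{res.seqid.icode.strip()}"
            residues.append(
                Residue(chain_id=chain.name, seq_index=seq_index, aa3=aa3,
                        atoms=tuple(atoms))
            )
            if chain.name not in chains:
                chains.append(chain.name)

    if not residues:
        raise EmptyStructureError(f"no standard residues in {path}")
    return StructureModel(
        id=st.name or path.stem,
        chains=tuple(chains),
        residues=tuple(residues),
        model_number=model.num,
    )


# ---------------------------------------------------------------------------
# selection

def _parse_range(tokens: list[str]) -> tuple[str, int, int]:
    """Parse ['auth:'|'local:',] 'start-end' -> (mode, start, end)."""
    mode = "local"
    if tokens and tokens[0] in ("auth", "local"):
        mode = tokens.pop(0)
    if len(tokens) != 1 or "-" not in tokens[0]:
        raise SelectionError(f"bad range spec: {':'.join(tokens)}")
    lo, _, hi = tokens[0].partition("-")
    try:
        start, end = int(lo), int(hi)
    except ValueError as exc:
        raise SelectionError(f"non-integer range bounds: {tokens[0]}") from exc
    if start > end:
        raise SelectionError(f"range start {start} > end {end}")
    return mode, start, end


def select_residues(model: StructureModel, expr: str) -> ResidueSelection:
    """Select residues with a small expression grammar.

    Grammar::

        all
        chain:E
        chains:A,C,E
        chain:E:50-61            (local 1-based positions, inclusive)
        chain:E:auth:306-378     (author numbering, inclusive)
    """
    expr = expr.strip()
    if expr == "all":
        return ResidueSelection(model, model.residues, label="all")

    parts = expr.split(":")
    head = parts[0].lower()
    if head == "chains":
        if len(parts) != 2:
            raise SelectionError(f"bad expression: {expr}")
        wanted = [c.strip() for c in parts[1].split(",") if c.strip()]
        unknown = [c for c in wanted if c not in model.chains]
        if unknown:
            raise SelectionError(f"unknown chain(s) {unknown} in {model.id}")
        members = tuple(r for r in model.residues if r.chain_id in wanted)
        return ResidueSelection(model, members, label=f"chains {','.join(wanted)}")

    if head == "chain":
        if len(parts) < 2:
            raise SelectionError(f"bad expression: {expr}")
        chain_id = parts[1]
        if chain_id not in model.chains:
            raise SelectionError(f"unknown chain {chain_id!r} in {model.id}")
        chain_res = model.chain_residues(chain_id)
        if len(parts) == 2:
            return ResidueSelection(model, chain_res, label=f"chain {chain_id}")
        mode, start, end = _parse_range(parts[2:])
        if mode == "local":
            members = tuple(
                r for i, r in enumerate(chain_res, start=1) if start <= i <= end
            )
        else:
            def auth_num(r: Residue) -> int | None:
                digits = "".join(ch for ch in r.seq_index if ch.isdigit() or ch == "-")
                return int(digits) if digits else None

            members = tuple(
                r for r in chain_res
                if (n := auth_num(r)) is not None and start <= n <= end
            )
        if not members:
            raise SelectionError(f"empty selection: {expr}")
        return ResidueSelection(
            model, members, label=f"chain {chain_id} {mode} {start}-{end}"
        )

    raise SelectionError(f"unrecognized expression: {expr}")


# ---------------------------------------------------------------------------
# effective points


def residue_effective_point(residue: Residue, strict: bool = False) -> np.ndarray:
    """Geometric center of side-chain heavy atoms; Calpha for glycine.

    Falls back to the Calpha (or the all-atom centroid for atom-poor toy
    residues) when no side-chain atom is present.
    """
    coords = {a.name: np.asarray(a.coords) for a in residue.atoms}
    if residue.aa3 == "GLY":
        if "CA" in coords:
            return coords["CA"]
    side = [np.asarray(a.coords) for a in residue.atoms if a.name not in BACKBONE_ATOMS]
    if side:
        return np.mean(side, axis=0)
    if "CA" in coords:
        # Calpha-only residues (coarse models, synthetic fixtures) are legal;
        # only a residue that *has* other backbone atoms but lost its side
        # chain is worth flagging.
        if residue.aa3 != "GLY" and len(residue.atoms) > 1:
            logger.warning(
                "residue %s/%s %s has no side-chain atoms; using CA",
                residue.chain_id, residue.seq_index, residue.aa3,
            )
        return coords["CA"]
    if strict:
        raise ValueError(f"residue {residue.key} has no usable atoms")
    return np.mean([np.asarray(a.coords) for a in residue.atoms], axis=0)


def effective_points(
    selection: ResidueSelection,
    scale: HydrophobicityScale,
    strict: bool = False,
) -> EffectivePointSet:
    """Reduce each selected residue to (point, intrinsic hydrophobicity)."""
    pts, intr, labels = [], [], []
    for res in selection.members:
        if res.aa3 not in scale:
            if strict:
                raise ValueError(f"scale {scale.name!r} lacks {res.aa3}")
            logger.warning("skipping residue %s: not in scale", res.key)
            continue
        pts.append(residue_effective_point(res, strict=strict))
        intr.append(scale[res.aa3])
        labels.append((res.chain_id, res.seq_index, res.aa3))
    if not pts:
        raise EmptyStructureError(f"no scorable residues in {selection.label}")
    return EffectivePointSet(
        points=np.asarray(pts, dtype=float),
        intrinsic=np.asarray(intr, dtype=float),
        labels=tuple(labels),
    )


# ---------------------------------------------------------------------------
# minimal PDB writing (used by the synthetic generator and CLI)

def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal, standard-conforming PDB file."""
    lines = []
    serial = 1
    for chain_id in model.chains:
        for res in model.chain_residues(chain_id):
            num_str = "".join(c for c in res.seq_index if c.isdigit() or c == "-")
            icode = res.seq_index[len(num_str):] or " "
            for atom in res.atoms:
                x, y, z = atom.coords
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.aa3:>3s} "
                    f"{chain_id:1s}{int(num_str):4d}{icode:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {res.aa3:>3s} {chain_id:1s}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
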