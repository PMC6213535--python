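"""Intrinsic residue hydrophobicity scales.

A scale maps each of the 20 standard three-letter amino-acid codes to a
nonnegative intrinsic hydrophobicity. All fuzzy-oil-drop profiles are
scale-relative; the packaged default is a min-max-normalized
Kyte-Doolittle hydropathy index (values in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

STANDARD_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

AA1_TO_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Mapping aa3 -> intrinsic hydrophobicity, all values >= 0."""

    values: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = STANDARD_AA3 - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} misses residues: {sorted(missing)}")
        if any(v < 0 for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has negative values")
        if not any(v > 0 for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} is identically zero")

    def __getitem__(self, aa3: str) -> float:
        return self.values[aa3]

    def __contains__(self, aa3: str) -> bool:
        return aa3 in self.values

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "HydrophobicityScale":
        """Read a whitespace-separated ``AA3 value`` table ('#' comments)."""
        values: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            aa3, val = line.split()
            values[aa3.upper()] = float(val)
        return cls(values=values, name=name or Path(path).stem)


def _load_packaged(filename: str, name: str) -> HydrophobicityScale:
    text = resources.files("oildrop.data").joinpath(filename).read_text()
    values: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            aa3, val = line.split()
            values[aa3] = float(val)
    return HydrophobicityScale(values=values, name=name)


def default_scale() -> HydrophobicityScale:
    """The packaged normalized Kyte-Doolittle scale."""
    return _load_packaged("kd_normalized.txt", "kyte-doolittle-normalized")
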