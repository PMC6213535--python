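"""Model/Results front end for hydrophobic-core scoring.

`HydrophobicCoreModel` binds a structure to a scoring frame (which residues
define the Gaussian capsule, which residues are scored) and `fit()` returns
a `FODResults` carrying the profiles, the relative distances, the profile
correlations, the classification, and convenience methods for fragments,
sliding-window scans and residue exclusion.

Typical use::

    model = HydrophobicCoreModel.from_file("fibril.pdb",
                                           gaussian_from="all",
                                           profile_over="chain:C")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .field import DEFAULT_CUTOFF, GaussianCapsule, ProfileSet, build_profiles, fit_gaussian_capsule
from .io import (
    ResidueSelection,
    StructureModel,
    effective_points,
    read_structure,
    select_residues,
)
from .scales import HydrophobicityScale, default_scale
from .stats import (
    StatusReport,
    Thresholds,
    WindowScan,
    fragment_status,
    negative_cc_residues,
    sliding_window_scan,
    status_excluding,
    unit_status,
)


class HydrophobicCoreModel:
    """Scores one structural unit against the fuzzy-oil-drop ideal."""

    def __init__(
        self,
        structure: StructureModel,
        gaussian_from: str | ResidueSelection = "all",
        profile_over: str | ResidueSelection | None = None,
        scale: HydrophobicityScale | None = None,
        cutoff: float = DEFAULT_CUTOFF,
        include_self: bool = True,
        thresholds: Thresholds | None = None,
    ) -> None:
        self.structure = structure
        self.scale = scale or default_scale()
        self.cutoff = float(cutoff)
        self.include_self = include_self
        self.thresholds = thresholds or Thresholds()
        if isinstance(gaussian_from, str):
            gaussian_from = select_residues(structure, gaussian_from)
        self.gaussian_from = gaussian_from
        if profile_over is None:
            profile_over = gaussian_from
        elif isinstance(profile_over, str):
            profile_over = select_residues(structure, profile_over)
        self.profile_over = profile_over

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        format: str = "auto",
        model_number: int = 1,
        **kwargs,
    ) -> "HydrophobicCoreModel":
        structure = read_structure(path, format=format, model_number=model_number)
        return cls(structure, **kwargs)

    def fit(self) -> "FODResults":
        profiles = build_profiles(
            gaussian_from=self.gaussian_from,
            profile_over=self.profile_over,
            scale=self.scale,
            cutoff=self.cutoff,
            include_self=self.include_self,
        )
        capsule = fit_gaussian_capsule(
            effective_points(self.gaussian_from, self.scale)
        )
        status = unit_status(profiles, self.thresholds)
        return FODResults(model=self, profiles=profiles, capsule=capsule,
                          status=status)


@dataclass(frozen=True)
class FODResults:
    """Fitted capsule, profiles and headline statistics for one unit."""

    model: HydrophobicCoreModel
    profiles: ProfileSet
    capsule: GaussianCapsule
    status: StatusReport

    # -- headline estimates -------------------------------------------------
    @property
    def rd_tor(self) -> float:
        return self.status.rd_tor

    @property
    def rd_toh(self) -> float:
        return self.status.rd_toh

    @property
    def hvt(self) -> float:
        return self.status.hvt

    @property
    def tvo(self) -> float:
        return self.status.tvo

    @property
    def hvo(self) -> float:
        return self.status.hvo

    @property
    def classification(self) -> str:
        return self.status.classification

    @property
    def nobs(self) -> int:
        return self.status.n

    # -- derived analyses ---------------------------------------------------
    def fragment(self, start: int, end: int) -> StatusReport:
        """Status of an inclusive 1-based fragment of the profiled unit."""
        return fragment_status(self.profiles, start, end, self.model.thresholds)

    def excluding(self, indices: Iterable[int]) -> StatusReport:
        """Status of the unit with the given 0-based residues removed."""
        return status_excluding(self.profiles, indices, self.model.thresholds)

    def sliding_window(self, window: int = 5) -> WindowScan:
        """Window-correlation scan (5-aa moving frame by default)."""
        return sliding_window_scan(self.profiles, window, self.model.thresholds)

    def excluding_negative_cc(self, window: int = 5) -> StatusReport:
        """Re-score after dropping residues with the amyloid window signature."""
        scan = self.sliding_window(window)
        return self.excluding(negative_cc_residues(
            scan, self.model.thresholds.window_hvo_min))

    # -- presentation ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-residue profiles as a tidy DataFrame."""
        chains, nums, aa3 = zip(*self.profiles.labels)
        local = []
        counter: dict[str, int] = {}
        for c in chains:
            counter[c] = counter.get(c, 0) + 1
            local.append(counter[c])
        return pd.DataFrame(
            {
                "chain": chains,
                "auth_resnum": nums,
                "local_index": local,
                "aa3": aa3,
                "T": self.profiles.T,
                "O": self.profiles.O,
                "H": self.profiles.H,
                "R": self.profiles.R,
            }
        )

    def summary(self) -> str:
        """Human-readable report in the style of a fitted-model summary."""
        s = self.status
        lines = [
            "Hydrophobic-core (fuzzy oil drop) status",
            "=" * 48,
            f"structure:      {self.model.structure.id}",
            f"gaussian frame: {self.profiles.gaussian_unit}",
            f"scored unit:    {self.profiles.profile_unit}  (n = {s.n})",
            f"scale:          {self.model.scale.name}",
            f"O cutoff:       {self.model.cutoff:.1f} A",
            "-" * 48,
            f"RD(T-O-R):      {s.rd_tor:8.3f}",
            f"RD(T-O-H):      {s.rd_toh:8.3f}",
            f"HvT:            {s.hvt:8.3f}",
            f"TvO:            {s.tvo:8.3f}",
            f"HvO:            {s.hvo:8.3f}",
            f"classification: {s.classification}",
            "-" * 48,
            "sigmas (A):     "
            + "  ".join(f"{x:.2f}" for x in self.capsule.sigmas),
        ]
        return "\n".join(lines)

    def plot_profiles(self, ax=None):
        """Plot T and O per residue (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        x = np.arange(len(self.profiles))
        ax.plot(x, self.profiles.T, label="T (theoretical)", color="tab:blue")
        ax.plot(x, self.profiles.O, label="O (observed)", color="tab:red")
        ax.set_xlabel("residue (local index)")
        ax.set_ylabel("normalized hydrophobicity")
        ax.set_title(self.profiles.profile_unit)
        ax.legend()
        return ax
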