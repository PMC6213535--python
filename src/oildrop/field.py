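"""The Gaussian hydrophobicity capsule and the four per-residue profiles.

The fuzzy-oil-drop picture idealizes a globular protein as a 3D Gaussian
hydrophobicity field: maximal at the molecular center, near zero at the
surface (taken to lie at 3 sigma along each principal axis). Four aligned
per-residue distributions are compared:

T  theoretical: Gaussian field sampled at each effective point,
O  observed: distance-weighted sums of intrinsic hydrophobicities,
H  intrinsic: sequence-only hydrophobicity, normalized,
R  uniform: 1/N per residue.

Each profile is normalized to sum to 1 so they are comparable as
probability distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, ProfileError, SelectionError
from .io import EffectivePointSet, ResidueSelection, effective_points
from .scales import HydrophobicityScale, default_scale

#: Surface of the capsule sits at 3 sigma from the center.
SIGMA_SURFACE_FACTOR = 3.0
#: Floor for sigma on flat or collinear point clouds (Angstrom).
SIGMA_FLOOR = 1.0
#: Default interaction cutoff of the observed-hydrophobicity kernel (Angstrom).
DEFAULT_CUTOFF = 9.0


@dataclass(frozen=True)
class GaussianCapsule:
    """Center, principal axes and (sigma_x, sigma_y, sigma_z) of the field."""

    center: np.ndarray  # (3,)
    axes: np.ndarray  # (3, 3), rows are unit axes, det +1
    sigmas: np.ndarray  # (3,), strictly positive, descending

    def __post_init__(self) -> None:
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be strictly positive")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be a proper rotation (det +1)")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates into the capsule frame."""
        return (np.atleast_2d(points) - self.center) @ self.axes.T


def fit_gaussian_capsule(points: EffectivePointSet) -> GaussianCapsule:
    """Fit center, principal axes and 3-sigma extents to the point cloud.

    center: unweighted geometric mean; axes: covariance eigenvectors with
    eigenvalues in descending order mapped to x, y, z; sigma_axis: largest
    absolute extent along that axis divided by 3, floored at 1 Angstrom for
    degenerate (flat/collinear) clouds.
    """
    xyz = points.points
    if len(xyz) < 2:
        raise DegenerateGeometryError("need at least 2 residues to fit a capsule")
    center = xyz.mean(axis=0)
    centered = xyz - center
    if np.allclose(centered, 0.0, atol=1e-9):
        raise DegenerateGeometryError("all effective points coincide")

    cov = np.cov(centered.T, bias=True).reshape(3, 3)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    axes = evecs[:, ::-1].T  # rows, descending eigenvalue

    # deterministic sign: largest-|component| of each axis positive
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]

    local = centered @ axes.T
    extents = np.abs(local).max(axis=0)
    sigmas = np.maximum(extents / SIGMA_SURFACE_FACTOR, SIGMA_FLOOR)
    return GaussianCapsule(center=center, axes=axes, sigmas=sigmas)


def _normalize(raw: np.ndarray, what: str) -> np.ndarray:
    total = raw.sum()
    if not np.isfinite(total) or total <= 0:
        raise ProfileError(f"cannot normalize {what}: total = {total}")
    return raw / total


def theoretical_profile(
    capsule: GaussianCapsule, points: EffectivePointSet
) -> np.ndarray:
    """Gaussian field at each effective point, normalized to sum 1."""
    local = capsule.to_local(points.points)
    raw = np.exp(-np.sum(local**2 / (2.0 * capsule.sigmas**2), axis=1))
    return _normalize(raw, "theoretical profile")


def distance_kernel(r: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Polynomial contact weight: 1 at r=0, 0 at and beyond the cutoff.

    g(r) = 1 - 1/2 (7 s^2 - 9 s^4 + 5 s^6 - s^8), s = r / cutoff, for
    r <= cutoff, else 0.
    """
    r = np.asarray(r, dtype=float)
    s2 = (r / cutoff) ** 2
    g = 1.0 - 0.5 * (7.0 * s2 - 9.0 * s2**2 + 5.0 * s2**3 - s2**4)
    return np.where(r <= cutoff, g, 0.0)


def observed_profile(
    points: EffectivePointSet,
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
    method: Literal["auto", "dense", "tree"] = "auto",
) -> np.ndarray:
    """Pairwise distance-weighted observed hydrophobicity, normalized.

    raw_i = sum_j (h_i + h_j) g(r_ij) over residues j within the cutoff
    (including j = i when ``include_self``, contributing 2 h_i).
    """
    xyz, h = points.points, points.intrinsic
    n = len(h)
    if method == "auto":
        method = "dense" if n <= 400 else "tree"

    if method == "dense":
        diff = xyz[:, None, :] - xyz[None, :, :]
        g = distance_kernel(np.sqrt((diff**2).sum(-1)), cutoff)
        if not include_self:
            np.fill_diagonal(g, 0.0)
        raw = h * g.sum(axis=1) + g @ h
    else:
        tree = cKDTree(xyz)
        raw = np.zeros(n)
        if include_self:
            raw += 2.0 * h  # g(0) = 1
        for i, j in tree.query_pairs(cutoff, output_type="ndarray"):
            gij = distance_kernel(np.linalg.norm(xyz[i] - xyz[j]), cutoff)
            contrib = h[i] + h[j]
            raw[i] += contrib * gij
            raw[j] += contrib * gij
    return _normalize(raw, "observed profile")


def intrinsic_profile(points: EffectivePointSet) -> np.ndarray:
    """Sequence-only hydrophobicity, h_i / sum_j h_j."""
    return _normalize(points.intrinsic.astype(float), "intrinsic profile")


def uniform_profile(n: int) -> np.ndarray:
    """The no-structure reference: 1/n everywhere."""
    if n < 1:
        raise ProfileError("uniform profile needs n >= 1")
    return np.full(n, 1.0 / n)


@dataclass(frozen=True)
class ProfileSet:
    """Aligned per-residue T, O, H, R distributions for one structural unit."""

    T: np.ndarray
    O: np.ndarray
    H: np.ndarray
    R: np.ndarray
    labels: tuple[tuple[str, str, str], ...]
    gaussian_unit: str
    profile_unit: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("T", "O", "H", "R"):
            v = getattr(self, name)
            if len(v) != n:
                raise ProfileError(f"{name} length {len(v)} != {n} labels")
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ProfileError(f"{name} is not a distribution (sum {v.sum()})")

    def __len__(self) -> int:
        return len(self.labels)

    def restricted(self, indices, label: str | None = None) -> "ProfileSet":
        """Restrict to a residue subset; T, O, H renormalized, R rebuilt."""
        idx = np.asarray(indices, dtype=int)
        if len(idx) < 1:
            raise ProfileError("restriction must keep at least one residue")
        if np.array_equal(idx, np.arange(len(self))):
            # identity restriction: bit-identical, no renormalization noise
            import dataclasses

            return dataclasses.replace(
                self, profile_unit=label or self.profile_unit)
        return ProfileSet(
            T=_normalize(self.T[idx], "restricted T"),
            O=_normalize(self.O[idx], "restricted O"),
            H=_normalize(self.H[idx], "restricted H"),
            R=uniform_profile(len(idx)),
            labels=tuple(self.labels[i] for i in idx),
            gaussian_unit=self.gaussian_unit,
            profile_unit=label or f"{self.profile_unit}[subset n={len(idx)}]",
        )


def profiles_from_points(
    gaussian_points: EffectivePointSet,
    profile_indices: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
    gaussian_unit: str = "unit",
    profile_unit: str | None = None,
) -> ProfileSet:
    """Build a ProfileSet directly from effective points.

    T and O are evaluated in the context of ``gaussian_points`` (capsule fit
    and pairwise summation), then restricted to ``profile_indices`` and
    renormalized; H and R are built on the restricted residues alone.
    """
    capsule = fit_gaussian_capsule(gaussian_points)
    t_full = theoretical_profile(capsule, gaussian_points)
    o_full = observed_profile(gaussian_points, cutoff=cutoff, include_self=include_self)

    if profile_indices is None:
        idx = np.arange(len(gaussian_points))
    else:
        idx = np.asarray(profile_indices, dtype=int)
    sub = gaussian_points.subset(idx)
    return ProfileSet(
        T=_normalize(t_full[idx], "T"),
        O=_normalize(o_full[idx], "O"),
        H=intrinsic_profile(sub),
        R=uniform_profile(len(idx)),
        labels=sub.labels,
        gaussian_unit=gaussian_unit,
        profile_unit=profile_unit or gaussian_unit,
    )


def build_profiles(
    gaussian_from: ResidueSelection,
    profile_over: ResidueSelection | None = None,
    scale: HydrophobicityScale | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    include_self: bool = True,
) -> ProfileSet:
    """Build T, O, H, R for ``profile_over`` in the frame of ``gaussian_from``.

    ``gaussian_from`` defines both the capsule and the pairwise context of
    the observed profile (e.g. a whole superfibril); ``profile_over`` is the
    unit being scored (e.g. one chain) and must be a subset of it. With
    ``profile_over=None`` the unit is scored in its own frame.
    """
    scale = scale or default_scale()
    if profile_over is None:
        profile_over = gaussian_from
    if profile_over.model is not gaussian_from.model:
        raise SelectionError("profile_over must come from the same structure")
    if not profile_over.is_subset_of(gaussian_from):
        raise SelectionError(
            f"profile_over ({profile_over.label}) is not a subset of "
            f"gaussian_from ({gaussian_from.label})"
        )
    g_points = effective_points(gaussian_from, scale)
    key_to_pos = {lab[:2]: i for i, lab in enumerate(g_points.labels)}
    idx = np.array([key_to_pos[k] for k in profile_over.keys()], dtype=int)
    return profiles_from_points(
        g_points,
        profile_indices=idx,
        cutoff=cutoff,
        include_self=include_self,
        gaussian_unit=gaussian_from.label,
        profile_unit=profile_over.label,
    )
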