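"""Divergence statistics, relative distance, correlations and classification.

The headline statistic is the relative distance

    RD = D(O||T) / (D(O||T) + D(O||REF)),

where D is the Kullback-Leibler divergence. With REF = R (uniform) this is
RD(T-O-R); with REF = H (intrinsic) it is RD(T-O-H). RD < 0.5 means the
observed hydrophobicity is closer to the monocentric Gaussian ideal than to
the structure-free reference. RD is independent of chain length and of the
logarithm base, which makes units comparable across proteins.

The amyloid-like signature combines high RD in both frames with low (often
negative) H-vs-T and T-vs-O correlations and a high H-vs-O correlation:
intrinsic residue properties dominate over a shared hydrophobic core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DivergenceUndefinedError, IndeterminateRDError, ProfileError
from .field import ProfileSet, uniform_profile

CLASS_CORE_ACCORDANT = "core_accordant"
CLASS_AMYLOID_LIKE = "amyloid_like"
CLASS_DISCORDANT = "discordant"
CLASS_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs; defaults are documented heuristics."""

    rd_cut: float = 0.5
    hvt_max: float = 0.1
    tvo_max: float = 0.35
    hvo_min: float = 0.5
    window_hvo_min: float = 0.5


@dataclass(frozen=True)
class StatusReport:
    """RD in both reference frames plus the three profile correlations."""

    rd_tor: float
    rd_toh: float
    hvt: float  # NaN when undefined (constant profile)
    tvo: float
    hvo: float
    n: int
    unit_label: str
    classification: str

    def correlations_defined(self) -> bool:
        return not any(math.isnan(v) for v in (self.hvt, self.tvo, self.hvo))

    def as_dict(self) -> dict:
        return {
            "unit_label": self.unit_label,
            "n": self.n,
            "rd_tor": self.rd_tor,
            "rd_toh": self.rd_toh,
            "hvt": self.hvt,
            "tvo": self.tvo,
            "hvo": self.hvo,
            "classification": self.classification,
        }


@dataclass(frozen=True)
class WindowScan:
    """Sliding-window profile correlations assigned to central residues."""

    window: int
    centers: tuple[int, ...]  # indices into the profile's residue list
    hvt: np.ndarray
    tvo: np.ndarray
    hvo: np.ndarray
    defined: np.ndarray  # bool; False where any window vector was constant
    flags: np.ndarray  # bool; amyloid-like mark
    labels: tuple[tuple[str, str, str], ...]

    def flagged_indices(self) -> list[int]:
        return [c for c, f in zip(self.centers, self.flags) if f]


# ---------------------------------------------------------------------------
# primitives


def kl_divergence(p: Sequence[float], q: Sequence[float], base: float = 2.0) -> float:
    """Kullback-Leibler divergence sum_i p_i log(p_i/q_i), 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise DivergenceUndefinedError("distributions differ in length")
    support = p > 0
    if np.any(q[support] <= 0):
        raise DivergenceUndefinedError("q vanishes where p is positive")
    val = float(np.sum(p[support] * np.log(p[support] / q[support])))
    return val / math.log(base)


def relative_distance(
    o: Sequence[float], t: Sequence[float], ref: Sequence[float]
) -> float:
    """RD = D(O||T) / (D(O||T) + D(O||REF)), in [0, 1]."""
    d_ot = kl_divergence(o, t)
    d_oref = kl_divergence(o, ref)
    denom = d_ot + d_oref
    if denom == 0.0:
        raise IndeterminateRDError("O coincides with both references")
    return d_ot / denom


def correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson r; NaN when either vector is constant (undefined, not zero)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("correlation needs two equal-length vectors, n >= 2")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float("nan")
    return float(sps.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# statuses


def classify(report: StatusReport, thresholds: Thresholds | None = None) -> str:
    """Label a unit from its RD values and profile correlations."""
    th = thresholds or Thresholds()
    if math.isnan(report.rd_tor):
        return CLASS_INDETERMINATE
    if report.rd_tor < th.rd_cut:
        return CLASS_CORE_ACCORDANT
    if not report.correlations_defined():
        return CLASS_INDETERMINATE
    if (
        report.rd_toh >= th.rd_cut
        and report.hvt < th.hvt_max
        and report.tvo < th.tvo_max
        and report.hvo > th.hvo_min
    ):
        return CLASS_AMYLOID_LIKE
    return CLASS_DISCORDANT


def unit_status(
    profiles: ProfileSet, thresholds: Thresholds | None = None
) -> StatusReport:
    """Compute RD(T-O-R), RD(T-O-H) and the three correlations for a unit."""
    rd_tor = relative_distance(profiles.O, profiles.T, profiles.R)
    rd_toh = relative_distance(profiles.O, profiles.T, profiles.H)
    n = len(profiles)
    if n >= 3:
        hvt = correlation(profiles.H, profiles.T)
        tvo = correlation(profiles.T, profiles.O)
        hvo = correlation(profiles.H, profiles.O)
    else:
        hvt = tvo = hvo = float("nan")
    report = StatusReport(
        rd_tor=rd_tor, rd_toh=rd_toh, hvt=hvt, tvo=tvo, hvo=hvo,
        n=n, unit_label=profiles.profile_unit, classification="",
    )
    return replace(report, classification=classify(report, thresholds))


def fragment_status(
    profiles: ProfileSet,
    start: int,
    end: int,
    thresholds: Thresholds | None = None,
) -> StatusReport:
    """Status of an inclusive 1-based local fragment of the profiled unit.

    T, O, H are restricted to the fragment and renormalized; R is rebuilt as
    1/n_fragment.
    """
    n = len(profiles)
    if not (1 <= start <= end <= n):
        raise ProfileError(f"fragment {start}-{end} outside 1..{n}")
    idx = np.arange(start - 1, end)
    label = f"{profiles.profile_unit} fragment {start}-{end}"
    return unit_status(profiles.restricted(idx, label=label), thresholds)


def status_excluding(
    profiles: ProfileSet,
    excluded: Iterable[int],
    thresholds: Thresholds | None = None,
) -> StatusReport:
    """Status of the unit with the given residue indices (0-based) removed."""
    excluded = set(int(i) for i in excluded)
    keep = [i for i in range(len(profiles)) if i not in excluded]
    if len(keep) < 3:
        raise ProfileError("fewer than 3 residues remain after exclusion")
    label = f"{profiles.profile_unit} excluding {len(excluded)} residues"
    return unit_status(profiles.restricted(keep, label=label), thresholds)


def sliding_window_scan(
    profiles: ProfileSet,
    window: int = 5,
    thresholds: Thresholds | None = None,
) -> WindowScan:
    """Correlations over successive residue windows, e.g. a 5-aa moving frame.

    Raw (un-renormalized) windowed profile values are correlated —
    correlations are scale-invariant so renormalization is unnecessary.
    A position is flagged amyloid-like when HvT < 0, TvO < 0 and
    HvO > ``thresholds.window_hvo_min`` in its window. Windows containing a
    constant vector are flagged undefined, never silently zeroed.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    th = thresholds or Thresholds()
    n = len(profiles)
    if n < window:
        import warnings

        warnings.warn(f"profile length {n} < window {window}; empty scan")
        empty = np.array([])
        return WindowScan(
            window=window, centers=(), hvt=empty, tvo=empty, hvo=empty,
            defined=np.array([], dtype=bool), flags=np.array([], dtype=bool),
            labels=(),
        )
    half = window // 2
    centers, hvts, tvos, hvos, defined = [], [], [], [], []
    for c in range(half, n - half):
        sl = slice(c - half, c + half + 1)
        t, o, h = profiles.T[sl], profiles.O[sl], profiles.H[sl]
        ok = np.ptp(t) > 0 and np.ptp(o) > 0 and np.ptp(h) > 0
        centers.append(c)
        defined.append(ok)
        if ok:
            hvts.append(correlation(h, t))
            tvos.append(correlation(t, o))
            hvos.append(correlation(h, o))
        else:
            hvts.append(float("nan"))
            tvos.append(float("nan"))
            hvos.append(float("nan"))
    hvt = np.array(hvts)
    tvo = np.array(tvos)
    hvo = np.array(hvos)
    defined_arr = np.array(defined, dtype=bool)
    with np.errstate(invalid="ignore"):
        flags = defined_arr & (hvt < 0) & (tvo < 0) & (hvo > th.window_hvo_min)
    return WindowScan(
        window=window,
        centers=tuple(centers),
        hvt=hvt, tvo=tvo, hvo=hvo,
        defined=defined_arr,
        flags=flags,
        labels=tuple(profiles.labels[c] for c in centers),
    )


def negative_cc_residues(scan: WindowScan, hvo_min: float = 0.5) -> set[int]:
    """Indices of residues whose window shows the amyloid-like signature.

    Mirrors the "No neg CC" recomputation: drop residues with negative HvT
    and TvO window coefficients coupled with high HvO, then re-score.
    """
    return {c for c, f in zip(scan.centers, scan.flags) if f}
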