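"""Vessel centreline geometry: profiles, I/O, resampling, and the healthy envelope.

A reconstructed coronary artery is represented as an arclength-sampled lumen
diameter curve (mm).  The *healthy envelope* is the minimal non-increasing
curve dominating the diameter profile; it bridges every region where the
diameter recovers downstream, so atherosclerotic narrowing is not mistaken
for branch-related taper when side-branch flow is inferred from taper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class ProfileValidationError(ValueError):
    """Raised when a vessel profile violates its structural invariants."""


@dataclass(frozen=True)
class VesselProfile:
    """Arclength-sampled lumen diameter curve for one reconstructed artery.

    Parameters
    ----------
    s : array of float
        Arclength samples in mm, strictly increasing, ``s[0] == 0`` (the
        inlet sits at the proximal pressure measurement site).
    d : array of float
        Lumen diameter in mm at each sample; strictly positive.
    label : str
        Free-text identifier.
    """

    s: np.ndarray
    d: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "d", d)
        if s.ndim != 1 or d.ndim != 1 or s.shape != d.shape:
            raise ProfileValidationError("s and d must be 1-D arrays of equal length")
        if s.size < 2:
            raise ProfileValidationError("profile needs at least 2 samples")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(d)):
            raise ProfileValidationError("profile contains non-finite values")
        if abs(s[0]) > 1e-12:
            raise ProfileValidationError(f"arclength must start at 0, got s[0]={s[0]}")
        bad = np.flatnonzero(np.diff(s) <= 0)
        if bad.size:
            raise ProfileValidationError(
                f"arclength not strictly increasing at row {bad[0] + 1} "
                f"(s={s[bad[0] + 1]:g} after s={s[bad[0]]:g})"
            )
        bad = np.flatnonzero(d <= 0)
        if bad.size:
            raise ProfileValidationError(
                f"non-positive diameter at row {bad[0]} (d={d[bad[0]]:g})"
            )

    @property
    def length(self) -> float:
        """Total vessel arclength in mm."""
        return float(self.s[-1])

    @property
    def n_samples(self) -> int:
        return int(self.s.size)

    def diameter_at(self, s_query) -> np.ndarray:
        """Linearly interpolated diameter (mm) at arbitrary arclength(s)."""
        return np.interp(s_query, self.s, self.d)


@dataclass(frozen=True)
class HealthyEnvelope:
    """Healthy-taper diameter envelope on a profile's sample grid.

    ``h`` is non-increasing, dominates the raw diameters, and equals the raw
    diameter at the outlet.  Flat stretches of ``h`` above ``d`` mark
    stenoses (regions with downstream diameter recovery) where no
    branch-related taper, hence no porous-wall leak, is credited.
    """

    h: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))


def read_profile(path) -> VesselProfile:
    """Read a vessel profile from CSV with header columns ``s_mm,d_mm``.

    Raises
    ------
    ProfileValidationError
        On a malformed header, fewer than 2 rows, non-monotone arclength or
        non-positive diameter (naming the offending row).
    """
    path = Path(path)
    # header + 2 float columns: cheap enough to parse directly and keeps the
    # row-numbered error messages exact
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols[:2] != ["s_mm", "d_mm"]:
            raise ProfileValidationError(
                f"{path}: expected header 's_mm,d_mm', got {header!r}"
            )
        s, d = [], []
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                s.append(float(parts[0]))
                d.append(float(parts[1]))
            except (ValueError, IndexError) as exc:
                raise ProfileValidationError(f"{path}: bad row {ln}: {line!r}") from exc
    if len(s) < 2:
        raise ProfileValidationError(f"{path}: needs at least 2 data rows, got {len(s)}")
    for i in range(len(s)):
        if d[i] <= 0:
            raise ProfileValidationError(
                f"{path}: non-positive diameter {d[i]:g} at data row {i + 1}"
            )
        if i and s[i] <= s[i - 1]:
            raise ProfileValidationError(
                f"{path}: non-increasing arclength at data row {i + 1} "
                f"(s={s[i]:g} after s={s[i - 1]:g})"
            )
    return VesselProfile(np.array(s), np.array(d), label=path.stem)


def write_profile(profile: VesselProfile, path) -> None:
    """Write a vessel profile as ``s_mm,d_mm`` CSV (17 significant digits)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("s_mm,d_mm\n")
        for si, di in zip(profile.s, profile.d):
            fh.write(f"{float(si)!r},{float(di)!r}\n")


def resample(profile: VesselProfile, step: float = 0.1) -> VesselProfile:
    """Resample onto a uniform grid of spacing ``step`` mm (both endpoints kept).

    Linear interpolation; the grid divides the vessel length into
    ``ceil(L/step)`` equal segments so the actual spacing never exceeds
    ``step`` and the endpoint diameters are untouched.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    L = profile.length
    if step >= L:
        raise ValueError(f"step {step} mm must be smaller than vessel length {L} mm")
    n_seg = int(np.ceil(L / step))
    s_new = np.linspace(0.0, L, n_seg + 1)
    d_new = np.interp(s_new, profile.s, profile.d)
    return VesselProfile(s_new, d_new, label=profile.label)


def healthy_envelope(profile: VesselProfile) -> HealthyEnvelope:
    """Healthy-diameter envelope: running maximum taken from the outlet backwards.

    ``h[i] = max(d[j] for j >= i)``.  This is the minimal non-increasing
    curve that dominates ``d``; it is flat across any stenosis with
    downstream diameter recovery, so such regions contribute no taper.
    """
    h = np.maximum.accumulate(profile.d[::-1])[::-1]
    return HealthyEnvelope(h=h)


def stenosis_zones(profile: VesselProfile, tol: float = 0.05) -> list[tuple[float, float]]:
    """Contiguous arclength zones where the lumen falls below the envelope.

    A sample is stenotic when ``d < (1 - tol) * h``; maximal runs of stenotic
    samples are reported as ``(s_start, s_end)`` pairs in mm.
    """
    if not 0 < tol < 1:
        raise ValueError(f"tol must be in (0, 1), got {tol}")
    h = healthy_envelope(profile).h
    mask = profile.d < (1.0 - tol) * h
    zones: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            zones.append((float(profile.s[start]), float(profile.s[i - 1])))
            start = None
    if start is not None:
        zones.append((float(profile.s[start]), float(profile.s[-1])))
    return zones
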