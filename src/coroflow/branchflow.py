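"""Side-branch flow magnitude and spatial distribution (porous-wall leak).

Murray's law, ``D_parent^x = sum(D_daughter^x)`` with exponent ``x`` between
2 and 3, links vessel calibre to the flow it carries.  Applied to the main
vessel alone, a healthy taper from diameter ``d_in`` to ``d_out`` implies
that the fraction ``(d_out/d_in)^x`` of the inlet flow remains in the main
lumen at the outlet; the rest has left through side branches.  Two schemes
distribute that loss along the artery:

* **homogeneous** — leak uniform per unit arclength, agnostic to where the
  branches actually are;
* **regional** — leak proportional to local *healthy* taper, so flow leaves
  the lumen where the envelope diameter actually drops (branch points) and
  nowhere across a stenosis.

Both schemes shed the same total side-branch flow by construction, because
the total is fixed by the envelope's endpoint diameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VesselProfile, healthy_envelope

MURRAY_EXPONENT_RANGE = (2.0, 3.0)
DEFAULT_EXPONENT = 3.0  # classical Murray value; override via MurrayConfig


@dataclass(frozen=True)
class MurrayConfig:
    """Bifurcation exponent and leak-distribution method.

    Parameters
    ----------
    exponent : float
        Murray exponent ``x``; validated to [2, 3] unless
        ``allow_any_exponent`` is set (then any positive value).
    method : {"regional", "homogeneous"}
    allow_any_exponent : bool
        Escape hatch for sensitivity studies outside the physiological range.
    """

    exponent: float = DEFAULT_EXPONENT
    method: str = "regional"
    allow_any_exponent: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("regional", "homogeneous"):
            raise ValueError(f"method must be 'regional' or 'homogeneous', got {self.method!r}")
        lo, hi = MURRAY_EXPONENT_RANGE
        if self.allow_any_exponent:
            if self.exponent <= 0:
                raise ValueError(f"exponent must be positive, got {self.exponent}")
        elif not lo <= self.exponent <= hi:
            raise ValueError(
                f"exponent {self.exponent} outside [{lo}, {hi}]; "
                "set allow_any_exponent=True to override"
            )


@dataclass(frozen=True)
class LeakProfile:
    """Fraction of inlet flow remaining in the main lumen along the vessel.

    Attributes
    ----------
    s : array
        Arclength grid (mm), copied from the profile.
    g : array
        Flow fraction at each sample: ``g[0] == 1``, non-increasing,
        ``g > 0``.  Main-lumen flow at arclength s is ``g(s) * q_in``.
    leak_density : array, length ``len(s) - 1``
        Per-segment fractional leak per unit length (1/mm); the exact
        discrete derivative ``-(g[i+1] - g[i]) / (s[i+1] - s[i])`` so that
        its arclength integral equals ``1 - g[-1]`` identically.
    """

    s: np.ndarray
    g: np.ndarray
    leak_density: np.ndarray

    def fraction_at(self, s_query) -> np.ndarray:
        """Linearly interpolated flow fraction g at arbitrary arclength(s)."""
        return np.interp(s_query, self.s, self.g)


def side_branch_fraction(d_in: float, d_out: float, x: float = DEFAULT_EXPONENT) -> float:
    """Fraction of inlet flow leaving via side branches over a healthy taper.

    ``1 - (d_out / d_in)^x``.  Requires ``d_in >= d_out > 0`` — callers must
    pass healthy (envelope) diameters so a stenosed sample cannot invert the
    taper.
    """
    if x <= 0:
        raise ValueError(f"exponent must be positive, got {x}")
    if d_out <= 0:
        raise ValueError(f"diameters must be positive, got d_out={d_out}")
    if d_out > d_in:
        raise ValueError(
            f"d_out={d_out} exceeds d_in={d_in}: use healthy-envelope diameters"
        )
    return 1.0 - (d_out / d_in) ** x


def flow_fraction_profile(profile: VesselProfile, cfg: MurrayConfig) -> LeakProfile:
    """Distribute the Murray-law side-branch loss along the vessel.

    regional
        ``g(s) = (h(s) / h(0))^x`` with ``h`` the healthy envelope: flow
        leaves exactly where the healthy calibre drops, and none across a
        stenosis (where ``h`` is flat).
    homogeneous
        ``g(s)`` linear in arclength from 1 at the inlet to
        ``(h(L)/h(0))^x`` at the outlet: constant leak density everywhere.

    Both methods share the same endpoint values of ``g``, hence identical
    total side-branch flow.
    """
    h = healthy_envelope(profile).h
    x = cfg.exponent
    g_end = (h[-1] / h[0]) ** x
    if cfg.method == "regional":
        g = (h / h[0]) ** x
    else:
        g = 1.0 + (g_end - 1.0) * profile.s / profile.length
    g[0] = 1.0
    g[-1] = g_end
    ds = np.diff(profile.s)
    density = -np.diff(g) / ds
    # clip tiny negative round-off so the non-increasing invariant is exact
    density = np.maximum(density, 0.0)
    g = np.concatenate(([1.0], 1.0 - np.cumsum(density * ds)))
    return LeakProfile(s=profile.s.copy(), g=g, leak_density=density)


def leak_between(leak: LeakProfile, s_a: float, s_b: float, q_in: float) -> float:
    """Side-branch flow (same unit as ``q_in``) shed over ``[s_a, s_b]``.

    ``q_in * (g(s_a) - g(s_b))``; additive over adjacent intervals and zero
    across any envelope-flat (stenotic) zone under the regional method.
    """
    L = float(leak.s[-1])
    if not (0.0 <= s_a < s_b <= L + 1e-12):
        raise ValueError(f"need 0 <= s_a < s_b <= {L}, got [{s_a}, {s_b}]")
    g_a, g_b = leak.fraction_at([s_a, min(s_b, L)])
    return float(q_in * (g_a - g_b))
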