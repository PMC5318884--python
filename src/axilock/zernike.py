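"""Zernike polynomials on the unit pupil, OSA/ANSI single indexing, pupil phase maps.

Polynomials are unit-RMS normalized over the unit disk ("Noll normalization"),
so a coefficient of ``c`` radians on any single mode produces a pupil phase
with RMS exactly ``c`` rad.  The single index ``j`` follows the OSA/ANSI
ordering (OEIS A176988): ``j = (n (n + 2) + m) / 2`` with azimuthal frequency
``m`` running from ``-n`` to ``n`` in steps of 2 within each radial order
``n``; negative ``m`` are sine modes, positive ``m`` cosine modes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CONVENTION",
    "DEFAULT_MODE_SET",
    "WavefrontCoeffs",
    "PupilGrid",
    "osa_to_nm",
    "nm_to_osa",
    "noll_to_osa",
    "osa_to_noll",
    "zernike_value",
    "phase_map",
    "pupil_inner_products",
    "mode_name",
]

CONVENTION = "OSA-A176988"

#: Default mode set for modal optimization (N = 8): oblique/vertical
#: astigmatism, defocus, both trefoils, both comas, primary spherical.
#: Tip and tilt are always excluded; defocus is deliberately included.
DEFAULT_MODE_SET = (3, 4, 5, 6, 7, 8, 9, 12)

_MODE_NAMES = {
    0: "piston",
    1: "vertical tilt",
    2: "horizontal tilt",
    3: "oblique astigmatism",
    4: "defocus",
    5: "vertical astigmatism",
    6: "vertical trefoil",
    7: "vertical coma",
    8: "horizontal coma",
    9: "oblique trefoil",
    10: "oblique quadrafoil",
    11: "oblique secondary astigmatism",
    12: "primary spherical",
    13: "vertical secondary astigmatism",
    14: "vertical quadrafoil",
}


def osa_to_nm(j: int) -> tuple[int, int]:
    """Radial order ``n`` and azimuthal frequency ``m`` for OSA index ``j``."""
    if j < 0:
        raise ValueError(f"single index must be >= 0, got {j}")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return n, m


def nm_to_osa(n: int, m: int) -> int:
    """OSA single index for radial order ``n``, azimuthal frequency ``m``."""
    if n < 0 or abs(m) > n or (n - m) % 2:
        raise ValueError(f"invalid Zernike orders (n={n}, m={m})")
    return (n * (n + 2) + m) // 2


def _nm_to_noll(n: int, m: int) -> int:
    j = n * (n + 1) // 2 + abs(m)
    if m == 0 or (m > 0 and n % 4 in (2, 3)) or (m < 0 and n % 4 in (0, 1)):
        j += 1
    return j


def osa_to_noll(j: int) -> int:
    """Convert an OSA/ANSI single index to the Noll single index (1-based)."""
    return _nm_to_noll(*osa_to_nm(j))


def noll_to_osa(j_noll: int) -> int:
    """Convert a Noll single index (1-based) to the OSA/ANSI single index."""
    if j_noll < 1:
        raise ValueError(f"Noll index must be >= 1, got {j_noll}")
    # Noll index j lives in radial order n with n(n+1)/2 < j <= (n+1)(n+2)/2.
    n = 0
    while (n + 1) * (n + 2) // 2 < j_noll:
        n += 1
    for m in range(-n, n + 1, 2):
        if _nm_to_noll(n, m) == j_noll:
            return nm_to_osa(n, m)
    raise ValueError(f"no Zernike mode with Noll index {j_noll}")


def mode_name(j: int) -> str:
    """Human-readable aberration name for OSA index ``j``."""
    if j < 0:
        raise ValueError(f"single index must be >= 0, got {j}")
    if j in _MODE_NAMES:
        return _MODE_NAMES[j]
    n, m = osa_to_nm(j)
    return f"Z(n={n}, m={m})"


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_value(j: int, rho, theta):
    """Evaluate the unit-RMS Zernike mode ``j`` at polar pupil coordinates.

    Parameters
    ----------
    j : int
        OSA/ANSI single index (>= 0).
    rho : array_like
        Normalized radial coordinate in [0, 1].
    theta : array_like
        Azimuth in radians.
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    n, m = osa_to_nm(j)
    radial = _radial_poly(n, abs(m), rho)
    if m == 0:
        return math.sqrt(n + 1) * radial * np.ones_like(theta)
    norm = math.sqrt(2 * (n + 1))
    if m > 0:
        return norm * radial * np.cos(m * theta)
    return norm * radial * np.sin(-m * theta)


@dataclass(frozen=True)
class WavefrontCoeffs:
    """Zernike coefficient vector in RMS radians, OSA/ANSI indexed.

    ``coeffs`` maps single index ``j`` to amplitude; absent modes are zero.
    Supports index-wise addition/subtraction and JSON round-tripping.
    """

    coeffs: Mapping[int, float] = field(default_factory=dict)
    convention: str = CONVENTION

    def __post_init__(self):
        clean = {}
        for j, a in dict(self.coeffs).items():
            j = int(j)
            a = float(a)
            if j < 0:
                raise ValueError(f"mode index must be >= 0, got {j}")
            if not math.isfinite(a):
                raise ValueError(f"amplitude for mode {j} is not finite")
            if a != 0.0:
                clean[j] = a
        object.__setattr__(self, "coeffs", clean)

    def __getitem__(self, j: int) -> float:
        return self.coeffs.get(int(j), 0.0)

    def __add__(self, other: "WavefrontCoeffs") -> "WavefrontCoeffs":
        keys = set(self.coeffs) | set(other.coeffs)
        return WavefrontCoeffs({j: self[j] + other[j] for j in keys})

    def __sub__(self, other: "WavefrontCoeffs") -> "WavefrontCoeffs":
        keys = set(self.coeffs) | set(other.coeffs)
        return WavefrontCoeffs({j: self[j] - other[j] for j in keys})

    def with_mode(self, j: int, amplitude: float) -> "WavefrontCoeffs":
        """Return a copy with mode ``j`` set to ``amplitude``."""
        d = dict(self.coeffs)
        d[int(j)] = float(amplitude)
        return WavefrontCoeffs(d)

    def rms(self, exclude: Iterable[int] = (0,)) -> float:
        """Euclidean norm of the coefficients, excluding ``exclude`` (piston)."""
        skip = set(exclude)
        return math.sqrt(sum(a * a for j, a in self.coeffs.items() if j not in skip))

    def as_vector(self, modes: Iterable[int]) -> np.ndarray:
        return np.array([self[j] for j in modes], dtype=float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "convention": self.convention,
                "unit": "rad-RMS",
                "coeffs": {str(j): a for j, a in sorted(self.coeffs.items())},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "WavefrontCoeffs":
        d = json.loads(text)
        conv = d.get("convention", CONVENTION)
        if conv != CONVENTION:
            raise ValueError(f"unsupported coefficient convention {conv!r}")
        return cls({int(j): float(a) for j, a in d["coeffs"].items()})

    @classmethod
    def zero(cls) -> "WavefrontCoeffs":
        return cls({})


@dataclass(frozen=True)
class PupilGrid:
    """Discretization of the unit pupil: radial/azimuthal coordinates + mask.

    ``regular(n)`` builds the canonical centered square grid with ``n``
    samples per side spanning [-1, 1]; the mask is exactly {rho <= 1}.
    ``weights`` (optional) are per-sample quadrature weights — subpixel disk
    coverage for the regular grid, so that pupil averages integrate the disk
    accurately despite the jagged mask edge.  Arbitrary (rho, theta) sample
    sets (e.g. an FFT frequency grid) can be wrapped directly.
    """

    rho: np.ndarray
    theta: np.ndarray
    mask: np.ndarray
    weights: np.ndarray | None = None

    @classmethod
    def regular(cls, n_samples: int, antialias: bool = True) -> "PupilGrid":
        if n_samples < 2:
            raise ValueError("need at least 2 samples per side")
        x = np.linspace(-1.0, 1.0, n_samples)
        xx, yy = np.meshgrid(x, x, indexing="xy")
        rho = np.hypot(xx, yy)
        theta = np.arctan2(yy, xx)
        weights = None
        if antialias:
            # 4x4 subpixel coverage of the disk boundary
            h = x[1] - x[0]
            off = ((np.arange(4) + 0.5) / 4.0 - 0.5) * h
            weights = np.zeros_like(rho)
            for ox in off:
                for oy in off:
                    weights += np.hypot(xx + ox, yy + oy) <= 1.0
            weights /= 16.0
        return cls(rho=rho, theta=theta, mask=rho <= 1.0, weights=weights)

    def pupil_average(self, values: np.ndarray) -> float:
        """Quadrature average of a field over the pupil disk."""
        if self.weights is not None:
            return float(np.sum(self.weights * values) / np.sum(self.weights))
        return float(np.mean(values[self.mask]))

    @classmethod
    def from_frequencies(cls, fx: np.ndarray, fy: np.ndarray, cutoff: float) -> "PupilGrid":
        """Pupil coordinates from spatial-frequency axes; ``cutoff`` maps to rho=1."""
        fxx, fyy = np.meshgrid(fx, fy, indexing="xy")
        rho = np.hypot(fxx, fyy) / cutoff
        theta = np.arctan2(fyy, fxx)
        return cls(rho=rho, theta=theta, mask=rho <= 1.0)


def pupil_inner_products(modes, grid: PupilGrid) -> np.ndarray:
    """Gram matrix of Zernike modes under the grid's pupil quadrature.

    Orthonormality means this approaches the identity as sampling refines.
    """
    modes = list(modes)
    if grid.weights is not None:
        region = grid.weights > 0
        w = grid.weights[region]
    else:
        region = grid.mask
        w = np.ones(int(region.sum()))
    rho = np.clip(grid.rho[region], 0.0, 1.0)
    theta = grid.theta[region]
    vals = np.stack([zernike_value(j, rho, theta) for j in modes])
    return (vals * w) @ vals.T / w.sum()


def phase_map(coeffs: WavefrontCoeffs, grid: PupilGrid) -> np.ndarray:
    """Pupil phase (rad) on ``grid``: sum of coefficient-weighted Zernikes.

    Values outside the pupil mask are zero.  With unit-RMS modes, the
    standard deviation of the phase over the mask equals the Euclidean norm
    of the non-piston coefficients (up to discretization error).
    """
    phi = np.zeros_like(grid.rho, dtype=float)
    if not coeffs.coeffs:
        return phi
    rho_in = np.clip(grid.rho[grid.mask], 0.0, 1.0)
    theta_in = grid.theta[grid.mask]
    acc = np.zeros_like(rho_in)
    for j, a in coeffs.coeffs.items():
        acc += a * zernike_value(j, rho_in, theta_in)
    phi[grid.mask] = acc
    return phi
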