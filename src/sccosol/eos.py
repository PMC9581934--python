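"""Cubic equations of state with Kwak-Mansoori (KM) mixing rules.

Supported variants (tag):

* ``RK``   - Redlich-Kwong, P = RT/(v-b) - a/(sqrt(T) v(v+b)); a, b constant.
* ``PR``   - Peng-Robinson with the KM decomposition of a(T) into the
  temperature-independent constants (a, b, c):
  a(T) = a + cRT - 2 sqrt(acRT), a = a(Tc)(1+m)^2, c = a(Tc) m^2/(R Tc).
* ``SRK3`` - Soave-Redlich-Kwong with the same three-constant decomposition
  (m from the 1972 alpha function).
* ``SRK4`` - SRK with the 1993 two-parameter alpha function, decomposed into
  four constants: a(T) = a + cRT - d R sqrt(T), a = a(Tc)(1+m+n),
  c = a(Tc)(n-m)/(R Tc), d = 2 n a(Tc)/(R sqrt(Tc)).

The KM rules mix these *constants* quadratically in composition with
geometric-mean cross attraction a_ij = (1-k_ij) sqrt(a_ii a_jj) and
cube-root-mean covolume-type cross terms
b_ij = (1-l_ij) ((b_ii^(1/3)+b_jj^(1/3))/2)^3 (likewise c_ij with m_ij and
d_ij with n_ij), so all binary interaction parameters are
temperature-independent.  The RK attraction constant uses the KM
conformal-solution form

    a = (sum_ij x_i x_j a_ij^(2/3) b_ij^(1/3))^(3/2) / b^(1/2).

Everything here is SI: T [K], P [Pa], v [m3/mol], R = 8.314 J/(mol K).
The hot paths are plain-float (``math``) code: the EoS regression evaluates
these functions millions of times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dataset import GAS_CONSTANT as R
from .dataset import ComponentProperties

__all__ = [
    "EOS_VARIANTS",
    "INTERACTION_NAMES",
    "PureKMConstants",
    "KMInteraction",
    "MixtureConstants",
    "pure_constants",
    "cross_terms",
    "km_mix",
    "attraction_E",
    "solve_Z",
    "RootError",
]

EOS_VARIANTS = ("RK", "PR", "SRK3", "SRK4")

#: interaction parameters per variant, in optimizer order
INTERACTION_NAMES = {
    "RK": ("k_ij", "l_ij"),
    "PR": ("k_ij", "l_ij", "m_ij"),
    "SRK3": ("k_ij", "l_ij", "m_ij"),
    "SRK4": ("k_ij", "l_ij", "m_ij", "n_ij"),
}


class RootError(RuntimeError):
    """No physically acceptable fluid root (v > b) exists."""


@dataclass(frozen=True)
class PureKMConstants:
    """Temperature-independent EoS constants of one component.

    Units: a in Pa m6/mol2 (RK: Pa m6 K^0.5/mol2), b and c in m3/mol,
    d in m3 K^0.5/mol.  c is zero/absent for RK; d only for SRK4.
    """

    a: float
    b: float
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be positive")


@dataclass(frozen=True)
class KMInteraction:
    """Binary interaction set; the count used depends on the variant
    (RK: k,l; PR/SRK3: k,l,m; SRK4: k,l,m,n)."""

    k_ij: float = 0.0
    l_ij: float = 0.0
    m_ij: float = 0.0
    n_ij: float = 0.0

    @classmethod
    def from_vector(cls, variant: str, values) -> "KMInteraction":
        names = INTERACTION_NAMES[variant]
        if len(values) != len(names):
            raise ValueError(
                f"{variant} takes {len(names)} interaction parameters "
                f"{names}, got {len(values)}"
            )
        return cls(**dict(zip(names, map(float, values))))

    def to_vector(self, variant: str) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in INTERACTION_NAMES[variant])


@dataclass(frozen=True)
class MixtureConstants:
    variant: str
    a: float
    b: float
    c: float = 0.0
    d: float = 0.0


def pure_constants(variant: str, props: ComponentProperties) -> PureKMConstants:
    """KM-decomposed constants of a pure component from (Tc, Pc, omega)."""
    tc, pc, w = props.tc, props.pc, props.omega
    if variant == "RK":
        return PureKMConstants(
            a=0.42748 * R**2 * tc**2.5 / pc,
            b=0.08664 * R * tc / pc,
        )
    if variant == "PR":
        a_tc = 0.45724 * R**2 * tc**2 / pc
        b = 0.07780 * R * tc / pc
        m = 0.37464 + 1.5422 * w - 0.26992 * w**2
        return PureKMConstants(
            a=a_tc * (1.0 + m) ** 2, b=b, c=a_tc * m**2 / (R * tc)
        )
    if variant == "SRK3":
        a_tc = 0.42748 * R**2 * tc**2 / pc
        b = 0.08664 * R * tc / pc
        m = 0.48 + 1.574 * w - 0.176 * w**2
        return PureKMConstants(
            a=a_tc * (1.0 + m) ** 2, b=b, c=a_tc * m**2 / (R * tc)
        )
    if variant == "SRK4":
        a_tc = 0.42748 * R**2 * tc**2 / pc
        b = 0.08664 * R * tc / pc
        m = 0.484 + 1.515 * w - 0.044 * w**2
        n = 2.756 * m - 0.7
        return PureKMConstants(
            a=a_tc * (1.0 + m + n),
            b=b,
            c=a_tc * (n - m) / (R * tc),
            d=2.0 * n * a_tc / (R * math.sqrt(tc)),
        )
    raise ValueError(f"unknown EoS variant {variant!r}")


def _cbrt_mean(x: float, y: float) -> float:
    """((x^(1/3)+y^(1/3))/2)^3; cube-root mean used for covolume-type terms."""
    return ((x ** (1.0 / 3.0) + y ** (1.0 / 3.0)) / 2.0) ** 3


def cross_terms(
    variant: str,
    pure: tuple[PureKMConstants, PureKMConstants],
    inter: KMInteraction,
):
    """Matrices (nested tuples) of a_ij, b_ij, c_ij, d_ij for a binary."""
    p1, p2 = pure
    prod = p1.a * p2.a
    if prod < 0:
        raise ValueError("negative product under attraction square root")
    a12 = (1.0 - inter.k_ij) * math.sqrt(prod)
    b12 = (1.0 - inter.l_ij) * _cbrt_mean(p1.b, p2.b)
    a = ((p1.a, a12), (a12, p2.a))
    b = ((p1.b, b12), (b12, p2.b))
    if variant == "RK":
        return a, b, None, None
    c12 = (1.0 - inter.m_ij) * _cbrt_mean(p1.c, p2.c)
    c = ((p1.c, c12), (c12, p2.c))
    if variant in ("PR", "SRK3"):
        return a, b, c, None
    d12 = (1.0 - inter.n_ij) * _cbrt_mean(p1.d, p2.d)
    d = ((p1.d, d12), (d12, p2.d))
    return a, b, c, d


def _quad(x, mat) -> float:
    return sum(
        x[i] * x[j] * mat[i][j] for i in range(len(x)) for j in range(len(x))
    )


def km_mix(
    variant: str,
    x,
    pure: tuple[PureKMConstants, PureKMConstants],
    inter: KMInteraction,
) -> MixtureConstants:
    """Mixture constants at composition ``x`` (must sum to 1)."""
    x = tuple(float(v) for v in x)
    if abs(sum(x) - 1.0) > 1e-12:
        raise ValueError("composition must sum to 1")
    if any(v < 0 for v in x):
        raise ValueError("composition entries must be >= 0")
    amat, bmat, cmat, dmat = cross_terms(variant, pure, inter)
    b = _quad(x, bmat)
    if variant == "RK":
        s1 = sum(
            x[i] * x[j] * amat[i][j] ** (2.0 / 3.0) * bmat[i][j] ** (1.0 / 3.0)
            for i in range(2) for j in range(2)
        )
        a = s1**1.5 / math.sqrt(b)
        return MixtureConstants("RK", a=a, b=b)
    a = _quad(x, amat)
    c = _quad(x, cmat)
    if variant in ("PR", "SRK3"):
        return MixtureConstants(variant, a=a, b=b, c=c)
    d = _quad(x, dmat)
    return MixtureConstants("SRK4", a=a, b=b, c=c, d=d)


def attraction_E(mix: MixtureConstants, T: float) -> float:
    """Effective temperature-dependent attraction a(T) of the mixture.

    PR/SRK3: E = a + cRT - 2 sqrt(acRT);  SRK4: E = a + cRT - d R sqrt(T);
    RK: a/sqrt(T) (the RK attraction already carries its T dependence).
    """
    if mix.variant == "RK":
        return mix.a / math.sqrt(T)
    if mix.variant in ("PR", "SRK3"):
        return mix.a + mix.c * R * T - 2.0 * math.sqrt(mix.a * mix.c * R * T)
    return mix.a + mix.c * R * T - mix.d * R * math.sqrt(T)


def _cubic_coeffs(variant: str, A: float, B: float):
    if variant == "PR":
        return (
            1.0,
            -(1.0 - B),
            A - 3.0 * B**2 - 2.0 * B,
            -(A * B - B**2 - B**3),
        )
    # RK / SRK share the Z-cubic of the v(v+b) attraction denominator
    return (1.0, -1.0, A - B - B**2, -A * B)


def _real_cubic_roots(p: float, q: float, r: float) -> list[float]:
    """Real roots of z^3 + p z^2 + q z + r (Cardano/trigonometric)."""
    a = q - p * p / 3.0
    b = 2.0 * p**3 / 27.0 - p * q / 3.0 + r
    shift = p / 3.0
    disc = (b / 2.0) ** 2 + (a / 3.0) ** 3
    if disc > 0.0:
        s = math.sqrt(disc)
        t = math.copysign(abs(-b / 2.0 + s) ** (1.0 / 3.0), -b / 2.0 + s) + \
            math.copysign(abs(-b / 2.0 - s) ** (1.0 / 3.0), -b / 2.0 - s)
        return [t - shift]
    if a == 0.0:  # triple root
        return [-shift]
    m = 2.0 * math.sqrt(-a / 3.0)
    arg = 3.0 * b / (a * m)
    arg = min(1.0, max(-1.0, arg))
    theta = math.acos(arg) / 3.0
    return [
        m * math.cos(theta - 2.0 * math.pi * k / 3.0) - shift for k in range(3)
    ]


def solve_Z(
    variant: str, mix: MixtureConstants, T: float, P: float
) -> tuple[float, float]:
    """Compressibility factor and molar volume of the fluid phase.

    Solves the variant's cubic in Z analytically and returns the largest real
    root with v > b (the single supercritical fluid phase), Newton-polished;
    a residual check of the pressure-explicit EoS guards against
    root-selection bugs.

    Returns ``(Z, v)`` with v in m3/mol.
    """
    if not (T > 0 and P > 0):
        raise ValueError("T and P must be > 0")
    E = attraction_E(mix, T)
    A = E * P / (R * T) ** 2
    B = mix.b * P / (R * T)
    _, c1, c2, c3 = _cubic_coeffs(variant, A, B)
    candidates = [z for z in _real_cubic_roots(c1, c2, c3) if z > B]
    if not candidates:
        raise RootError(
            f"{variant}: no real root with v > b at T={T}, P={P:.4g}"
        )
    z = max(candidates)
    # two Newton polish steps on the cubic
    for _ in range(2):
        f = ((z + c1) * z + c2) * z + c3
        df = (3.0 * z + 2.0 * c1) * z + c2
        if df == 0.0:
            break
        z -= f / df
    v = z * R * T / P
    p_calc = R * T / (v - mix.b) - E / _attr_denominator(variant, v, mix.b)
    if abs(p_calc - P) > 1e-8 * P:
        raise RootError(
            f"{variant}: root residual {abs(p_calc - P) / P:.2e} at "
            f"T={T}, P={P:.4g}"
        )
    return z, v


def _attr_denominator(variant: str, v: float, b: float) -> float:
    if variant == "PR":
        return v * (v + b) + b * (v - b)
    return v * (v + b)
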