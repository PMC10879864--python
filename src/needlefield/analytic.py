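"""Analytic potentials for point current injection in multilayer spheres.

Validation oracle for the boundary-element solver: a piecewise-homogeneous
concentric-sphere conductor (radii strictly decreasing outside-in) with point
current sources either exactly on the outer surface or at a given radius
inside the outermost layer.  The solution is the axisymmetric Legendre series

    V(r, gamma) = sum_n R_n(r) P_n(cos gamma)

per source, with the radial factors obtained from per-degree 2x2 transfer
across the interfaces (continuity of V and of sigma dV/dr) and the outer
boundary condition sigma_1 dV/dr = applied current density.  For a source
strictly inside the outer layer the free-space monopole term is added as a
particular solution and the insulating outer boundary carries a uniform
compensating outflow; for zero-net source sets the compensation cancels and
the evaluator is exactly linear in the injected currents.

Truncation note: on the source radius itself the series converges slowly;
evaluate at points at least a fraction of a layer away from the sources
(the solver comparisons evaluate on mesh surfaces away from the injection
radius or use interior sources).

Geometry in mm, currents in uA, potentials in volts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphereInjection", "analytic_sphere", "homogeneous_sphere_surface_potential"]


@dataclass
class SphereInjection:
    """One point current source: direction (unit-normalised), current (uA),
    and the radius fraction (1.0 = exactly on the outer sphere)."""

    direction: np.ndarray
    current: float
    radius_fraction: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("injection direction must be non-zero")
        self.direction = d / n
        if not 0.0 < self.radius_fraction <= 1.0:
            raise ValueError("radius_fraction must be in (0, 1]")


def _legendre_sum(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """sum_n coeffs[n] * P_n(x) via the three-term recurrence (n from 0)."""
    p_prev = np.ones_like(x)
    total = coeffs[0] * p_prev
    if len(coeffs) == 1:
        return total
    p_cur = x.copy()
    total = total + coeffs[1] * p_cur
    for n in range(1, len(coeffs) - 1):
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        total += coeffs[n + 1] * p_next
        p_prev, p_cur = p_cur, p_next
    return total


class MultilayerSphereModel:
    """Evaluator for the layered-sphere potential; linear in the currents."""

    def __init__(
        self,
        radii: list[float],
        conductivities: list[float],
        injections: list[SphereInjection],
        order: int = 100,
    ) -> None:
        radii = [float(r) for r in radii]
        sigmas = [float(s) for s in conductivities]
        if len(radii) != len(sigmas):
            raise ValueError("need one conductivity per layer radius")
        if any(b >= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly decreasing outside-in")
        if any(s <= 0 for s in sigmas):
            raise ValueError("conductivities must be positive")
        if order < 1:
            raise ValueError("order must be >= 1")
        self.radii = radii
        self.sigmas = sigmas
        self.injections = injections
        self.order = order
        # Per source: coefficients (A_i[n], B_i[n]) for every layer i.
        self._coeffs = [self._solve_source(s) for s in injections]

    # -- per-degree radial solutions -------------------------------------
    def _transfer_inner_coeffs(self, n: int) -> np.ndarray:
        """(A_i, B_i) per layer for the regular interior solution, scaled so
        the innermost layer has A = 1, B = 0 (units of R1^-n)."""
        L = len(self.radii)
        R1 = self.radii[0]
        coeffs = np.zeros((L, 2))
        coeffs[L - 1] = (1.0, 0.0)
        for i in range(L - 2, -1, -1):
            rho = self.radii[i + 1] / R1  # normalised interface radius
            a_in, b_in = coeffs[i + 1]
            s_in, s_out = self.sigmas[i + 1], self.sigmas[i]
            # continuity of V and sigma * dV/dr at rho
            v = a_in * rho**n + b_in * rho ** -(n + 1)
            f = s_in * (n * a_in * rho ** (n - 1) - (n + 1) * b_in * rho ** -(n + 2))
            M = np.array(
                [
                    [rho**n, rho ** -(n + 1)],
                    [s_out * n * rho ** (n - 1), -s_out * (n + 1) * rho ** -(n + 2)],
                ]
            )
            coeffs[i] = np.linalg.solve(M, np.array([v, f]))
        return coeffs

    def _solve_source(self, src: SphereInjection) -> dict:
        R1 = self.radii[0]
        s1 = self.sigmas[0]
        I = src.current
        c = src.radius_fraction  # normalised source radius
        L = len(self.radii)
        surface = src.radius_fraction >= 1.0 - 1e-12

        per_degree = np.zeros((self.order + 1, L, 2))
        for n in range(1, self.order + 1):
            base = self._transfer_inner_coeffs(n)
            if surface:
                # sigma_1 dV/dr(R1) = I (2n+1) / (4 pi R1^2), homogeneous elsewhere
                a1, b1 = base[0]
                flux = s1 * (n * a1 - (n + 1) * b1) / R1  # at r = R1 (x = 1)
                target = I * (2 * n + 1) / (4.0 * np.pi * R1**2)
                if flux == 0:
                    raise ArithmeticError("degenerate radial system")
                per_degree[n] = base * (target / flux)
            else:
                # Interior monopole in layer 1 at normalised radius c:
                # particular solution q * x^n / c^(n+1) (x < c) or
                # q * c^n / x^(n+1) (x > c), with q = I / (4 pi sigma_1 R1).
                q = I / (4.0 * np.pi * s1 * R1)
                if L == 1:
                    # one unknown alpha (regularity kills the B term):
                    # outer BC: d/dx [alpha x^n + q c^n x^-(n+1)] = 0 at x=1
                    alpha = q * c**n * (n + 1) / n
                    per_degree[n, 0] = (alpha, 0.0)
                else:
                    # unknowns: alpha, beta (layer-1 homogeneous part), t (inner scale)
                    rho = self.radii[1] / R1
                    a2, b2 = base[1]
                    s2 = self.sigmas[1]
                    A = np.zeros((3, 3))
                    rhs = np.zeros(3)
                    # outer BC at x=1 (r > c branch of the particular solution)
                    A[0] = (n, -(n + 1), 0.0)
                    rhs[0] = q * c**n * (n + 1)
                    # continuity of V at rho (r < c branch)
                    A[1] = (
                        rho**n,
                        rho ** -(n + 1),
                        -(a2 * rho**n + b2 * rho ** -(n + 1)),
                    )
                    rhs[1] = -q * rho**n / c ** (n + 1)
                    # continuity of sigma dV/dr at rho
                    A[2] = (
                        s1 * n * rho ** (n - 1),
                        -s1 * (n + 1) * rho ** -(n + 2),
                        -s2 * (n * a2 * rho ** (n - 1) - (n + 1) * b2 * rho ** -(n + 2)),
                    )
                    rhs[2] = -s1 * q * n * rho ** (n - 1) / c ** (n + 1)
                    alpha, beta, t = np.linalg.solve(A, rhs)
                    per_degree[n, 0] = (alpha, beta)
                    per_degree[n, 1:] = base[1:] * t
        return {"per_degree": per_degree, "source": src, "surface": surface}

    # -- evaluation -------------------------------------------------------
    def _layer_of(self, r: np.ndarray) -> np.ndarray:
        layer = np.zeros(len(r), dtype=int)
        for i, R in enumerate(self.radii[1:], start=1):
            layer[r < R + 1e-12] = i
        return layer

    def potential(self, points: np.ndarray) -> np.ndarray:
        """Potential (volts) at (n, 3) points in mm; gauge: series terms only
        (constant n=0 offsets from each source included analytically)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        R1 = self.radii[0]
        r = np.linalg.norm(pts, axis=1)
        if (r > R1 * (1 + 1e-9)).any():
            raise ValueError("evaluation points must lie inside the outer sphere")
        x = r / R1
        layer = self._layer_of(r)
        s1 = self.sigmas[0]
        out = np.zeros(len(pts))
        uA_mm_to_V = 1e-3  # uA / (S/m * mm) -> V

        for sol in self._coeffs:
            src: SphereInjection = sol["source"]
            I = src.current
            c = src.radius_fraction
            with np.errstate(invalid="ignore", divide="ignore"):
                cosg = np.where(r > 0, pts @ src.direction / np.where(r > 0, r, 1.0), 1.0)
            cosg = np.clip(cosg, -1.0, 1.0)

            # radial factors per point
            contrib = np.zeros(len(pts))
            per_degree = sol["per_degree"]
            # accumulate sum_n R_n(x) P_n(cos gamma) with a joint recurrence
            p_prev = np.ones(len(pts))
            p_cur = cosg.copy()
            for n in range(1, self.order + 1):
                A = per_degree[n, layer, 0]
                B = per_degree[n, layer, 1]
                xs = np.where(x > 0, x, 1.0)
                with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                    term_b = np.where(B == 0.0, 0.0, B * xs ** -(n + 1.0))
                radial = A * x**n + term_b
                if not sol["surface"]:
                    # free-space monopole term, present only in the source layer
                    q = I / (4.0 * np.pi * s1 * R1)
                    lt = x <= c
                    part = np.zeros_like(x)
                    part[lt] = q * x[lt] ** n / c ** (n + 1)
                    part[~lt] = q * c**n / xs[~lt] ** (n + 1.0)
                    radial = radial + np.where(layer == 0, part, 0.0)
                contrib += radial * p_cur
                p_next = ((2 * n + 1) * cosg * p_cur - n * p_prev) / (n + 1)
                p_prev, p_cur = p_cur, p_next
            # n = 0 term: I/(4 pi s1 max(x, c) R1), constant inside radius c
            n0 = I / (4.0 * np.pi * s1 * R1 * np.maximum(x, c))
            contrib += n0
            out += contrib
        return out * uA_mm_to_V

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.potential(points)


def analytic_sphere(
    radii: list[float],
    conductivities: list[float],
    surface_injection: list,
    order: int = 100,
) -> MultilayerSphereModel:
    """Build the layered-sphere evaluator.

    ``surface_injection`` items are ``(direction, current)`` or
    ``(direction, current, radius_fraction)``; directions are unit-normalised,
    currents in uA.
    """
    injections = []
    for item in surface_injection:
        if isinstance(item, SphereInjection):
            injections.append(item)
        else:
            injections.append(SphereInjection(*item))
    return MultilayerSphereModel(radii, conductivities, injections, order=order)


def homogeneous_sphere_surface_potential(
    radius: float,
    sigma: float,
    points: np.ndarray,
    injections: list[tuple[np.ndarray, float]],
) -> np.ndarray:
    """Closed form for surface point injection into a homogeneous sphere.

    V(r) = I/(4 pi sigma R) * [2 R/d - ln(1 - (r/R) cos g + d/R) + ln 2 + 1],
    the last constant being the n = 0 monopole offset; valid for r < R.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    r = np.linalg.norm(pts, axis=1)
    out = np.zeros(len(pts))
    for direction, current in injections:
        d_hat = np.asarray(direction, dtype=np.float64)
        d_hat = d_hat / np.linalg.norm(d_hat)
        a = radius * d_hat
        d = np.linalg.norm(pts - a, axis=1)
        cosg = np.where(r > 0, pts @ d_hat / np.where(r > 0, r, 1.0), 1.0)
        t = r / radius
        series = 2.0 * radius / d - np.log(1.0 - t * cosg + d / radius) + np.log(2.0)
        out += current / (4.0 * np.pi * sigma * radius) * (series - 2.0 + 1.0)
        # "-2" removes the n=0 part of 2R/d's expansion... see note below.
    return out * 1e-3


# Note on the closed form: expanding 2R/d = 2 sum_n t^n P_n includes an n=0
# term equal to 2, and -ln(1 - t cos g + d/R) + ln 2 = sum_{n>=1} t^n P_n / n
# has none; the series solution keeps only n >= 1 plus the monopole constant
# I/(4 pi sigma R).  Hence the (-2 + 1) adjustment above.
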