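"""Structural identifiability of the compliance-feedback model.

The vessel ODEs are control-affine in the inputs (dP, PI, dPI/dt) once the
ReLU clamps and the endothelial delay are dropped (the analysis runs in the
activated regime, where both stimuli exceed their references and the clamps
are inactive):

    dx/dt = f(x, p) + sum_i g_i(x, p) * u_i(t),      y = h(x) = 2R.

The generating-series approach takes iterated Lie derivatives of the
observable along the drift field f and the input fields g_i; the series
coefficients are functions of the parameters, and the rank of their Jacobian
with respect to the tested parameters (tau_m, tau_e, Sm, Se, T0, tau0, G)
bounds how many parameters the input-output behaviour pins down.  Ranks are
evaluated numerically at random generic positive points (symbolic ranks are
brittle); identifiability tableaus record which coefficients depend on which
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

__all__ = [
    "TESTED_PARAMETERS",
    "AffineControlSystem",
    "IdentifiabilityReport",
    "build_system",
    "series_coefficients",
    "jacobian_rank",
    "tableau",
    "classify",
    "analyze",
]

TESTED_PARAMETERS = ("tau_m", "tau_e", "Sm", "Se", "T0", "tau0", "G")


@dataclass
class AffineControlSystem:
    """Symbolic drift f, input fields g = [g_dP, g_PI, g_dPIdt], observable
    h = 2R, with states (xe, xm, R) and the tested/fixed parameter symbols."""

    states: tuple[sp.Symbol, ...]
    f: sp.Matrix
    g: list[sp.Matrix]
    h: sp.Expr
    tested: tuple[sp.Symbol, ...]
    fixed: tuple[sp.Symbol, ...]

    def rhs(self, inputs: tuple[sp.Expr, sp.Expr, sp.Expr]) -> sp.Matrix:
        """Full right-hand side f + sum_i g_i * u_i for given input values."""
        out = self.f
        for gi, ui in zip(self.g, inputs):
            out = out + gi * ui
        return sp.Matrix(out)


def build_system() -> AffineControlSystem:
    """The control-affine form of the vessel model (ReLU and delay omitted).

    Inputs are ordered (dP, PI, dPI/dt); dPI/dt enters as its own input to
    keep the system affine in the controls.  The drift carries the
    homogeneous activation decay and the compliance-feedback coupling; the
    input matrix carries the tension/shear forcing and the passive-compliance
    term.  Entries match the simulated model's right-hand side exactly in the
    activated regime.
    """
    xe, xm, R = sp.symbols("xe xm R", positive=True)
    tau_m, tau_e, Sm, Se, T0, tau0, G = sp.symbols(
        "tau_m tau_e Sm Se T0 tau0 G", positive=True)
    Cb, dC, Pv = sp.symbols("Cb DeltaC Pv", positive=True)

    u = xe - xm
    sech2 = sp.sech(u / (G * dC)) ** 2
    c_rel = 1 + dC * sp.tanh(u / (G * dC))
    K = Pv * Cb * sech2 / (2 * sp.pi * R * G)

    # activated-regime activation equations, inputs separated out:
    #   dxe/dt = -(xe + Se)/tau_e + [Se*R/(2*tau_e*tau0)] * dP
    #   dxm/dt = -(xm + Sm)/tau_m + [Sm*R/(2*tau_m*T0)] * PI
    a11 = Se * R / (2 * tau_e * tau0)
    a22 = Sm * R / (2 * tau_m * T0)
    a31 = K * a11
    a32 = -K * a22
    a33 = Cb * c_rel / (2 * sp.pi * R)

    f = sp.Matrix([
        -(xe + Se) / tau_e,
        -(xm + Sm) / tau_m,
        K * ((xm + Sm) / tau_m - (xe + Se) / tau_e),
    ])
    g = [sp.Matrix([a11, 0, a31]),
         sp.Matrix([0, a22, a32]),
         sp.Matrix([0, 0, a33])]
    h = 2 * R
    return AffineControlSystem(states=(xe, xm, R), f=f, g=g, h=h,
                               tested=(tau_m, tau_e, Sm, Se, T0, tau0, G),
                               fixed=(Cb, dC, Pv))


def _lie(system: AffineControlSystem, expr: sp.Expr, fld: sp.Matrix) -> sp.Expr:
    grad = sp.Matrix([[sp.diff(expr, s) for s in system.states]])
    return sp.cancel((grad * fld)[0, 0])


def series_coefficients(system: AffineControlSystem, max_order: int = 2,
                        ) -> list[sp.Expr]:
    """The observable plus all iterated Lie derivatives up to ``max_order``,
    with zero and duplicate coefficients pruned."""
    if max_order not in (1, 2):
        raise ValueError("max_order must be 1 or 2")
    fields = [system.f] + system.g
    coeffs: list[sp.Expr] = [system.h]
    level = [(system.h, ())]
    for _ in range(max_order):
        new_level = []
        for expr, path in level:
            for i, fld in enumerate(fields):
                d = _lie(system, expr, fld)
                new_level.append((d, path + (i,)))
        coeffs.extend(e for e, _ in new_level)
        level = new_level
    pruned: list[sp.Expr] = []
    seen: set[str] = set()
    for c in coeffs:
        c = sp.cancel(sp.expand(c))
        if c == 0:
            continue
        key = sp.srepr(c)
        if key in seen:
            continue
        seen.add(key)
        pruned.append(c)
    return pruned


def _parameter_jacobian(coefficients, params):
    return sp.Matrix([[sp.diff(c, p) for p in params] for c in coefficients])


def _random_point(system: AffineControlSystem, rng: np.random.Generator) -> dict:
    subs = {}
    for s in system.states + system.tested + system.fixed:
        subs[s] = float(rng.uniform(0.5, 2.0))
    return subs


def jacobian_rank(coefficients: list[sp.Expr],
                  params: tuple[sp.Symbol, ...],
                  system: AffineControlSystem,
                  n_points: int = 5, seed: int = 0,
                  rel_tol: float = 1e-8) -> int:
    """Numerical rank of the coefficient/parameter Jacobian.

    The symbolic Jacobian is evaluated at ``n_points`` random generic
    positive points; the rank (singular values above ``rel_tol`` times the
    largest) is maximised over points, which is robust against accidental
    cancellations at any single point.
    """
    jac = _parameter_jacobian(coefficients, params)
    syms = list(system.states + system.tested + system.fixed)
    fn = sp.lambdify(syms, jac, modules="numpy")
    rng = np.random.default_rng(seed)
    best = 0
    degenerate = 0
    for _ in range(n_points):
        subs = _random_point(system, rng)
        vals = np.asarray(fn(*[subs[s] for s in syms]), dtype=float)
        if not np.all(np.isfinite(vals)):
            degenerate += 1
            continue
        s = np.linalg.svd(vals, compute_uv=False)
        if s.size and s[0] > 0:
            best = max(best, int(np.sum(s > rel_tol * s[0])))
    if degenerate == n_points:
        raise ValueError("all evaluation points were degenerate")
    return best


def tableau(coefficients: list[sp.Expr], params: tuple[sp.Symbol, ...],
            system: AffineControlSystem | None = None,
            reduced: bool = True, seed: int = 0) -> np.ndarray:
    """Binary dependence matrix: entry (i, j) is 1 iff coefficient i depends
    on parameter j.  The reduced form drops all-zero rows."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in coefficients:
        row = []
        for p in params:
            d = sp.cancel(sp.diff(c, p))
            row.append(0 if d == 0 else 1)
        rows.append(row)
    mat = np.asarray(rows, dtype=int)
    if reduced:
        mat = mat[mat.any(axis=1)]
    return mat


@dataclass
class IdentifiabilityReport:
    """Ranks, tableaus and per-parameter classifications."""

    coefficients_by_order: dict[int, int]
    ranks: dict[int, int]
    tableaus: dict[int, np.ndarray]
    classifications: dict[str, str]


def classify(system: AffineControlSystem, coefficients: list[sp.Expr],
             rank: int, solve_timeout: float = 10.0) -> dict[str, str]:
    """Per-parameter classification from the series coefficients.

    A parameter that is the *only* tested unknown a nonzero coefficient
    depends on, and for which that coefficient equation has a unique symbolic
    solution, is globally identifiable; this is applied as an elimination
    cascade (solved parameters are treated as known).  With full Jacobian
    rank the remaining parameters are at least locally identifiable; an
    all-zero tableau column marks non-identifiability.  Parameters whose
    symbolic solve does not succeed are reported as locally identifiable when
    the rank supports it, otherwise undetermined.
    """
    import time
    tab = tableau(coefficients, system.tested)
    col_any = tab.any(axis=0) if tab.size else np.zeros(len(system.tested), bool)
    known: set[sp.Symbol] = set()
    global_ids: set[sp.Symbol] = set()
    deadline = time.monotonic() + solve_timeout
    progress = True
    while progress and time.monotonic() < deadline:
        progress = False
        for c in coefficients:
            free = [p for p in system.tested
                    if p not in known and sp.diff(c, p) != 0]
            if len(free) != 1:
                continue
            p = free[0]
            try:
                sols = sp.solve(sp.Eq(c, sp.Symbol("_obs", positive=True)), p,
                                dict=False)
            except Exception:
                continue
            if len(sols) == 1:
                known.add(p)
                global_ids.add(p)
                progress = True
    out: dict[str, str] = {}
    full = rank >= len(system.tested)
    for j, p in enumerate(system.tested):
        if not col_any[j]:
            out[str(p)] = "non-identifiable"
        elif p in global_ids:
            out[str(p)] = "globally identifiable"
        elif full:
            out[str(p)] = "locally identifiable"
        else:
            out[str(p)] = "undetermined"
    return out


def analyze(max_order: int = 2, seed: int = 0) -> IdentifiabilityReport:
    """Full analysis: coefficients, ranks and tableaus at orders 1..max_order,
    plus the classification at the highest order."""
    system = build_system()
    ranks: dict[int, int] = {}
    tabs: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    coeffs = []
    for order in range(1, max_order + 1):
        coeffs = series_coefficients(system, max_order=order)
        counts[order] = len(coeffs)
        ranks[order] = jacobian_rank(coeffs, system.tested, system, seed=seed)
        tabs[order] = tableau(coeffs, system.tested)
    cls = classify(system, coeffs, ranks[max_order])
    return IdentifiabilityReport(coefficients_by_order=counts, ranks=ranks,
                                 tableaus=tabs, classifications=cls)
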