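"""Free-energy estimators and energy-series summaries.

Two estimators consume per-window alchemical-decoupling samples, in which a
coupling parameter lambda switches the guest-environment interactions from
fully on (lambda = 0) to fully off (lambda = 1):

* thermodynamic integration (TI): ``dG = integral of <dH/dlambda> dlambda``
  by trapezoidal quadrature over the (possibly nonuniform) lambda grid;
* the Bennett acceptance ratio (BAR), the maximum-likelihood two-state
  estimator, solved per adjacent window pair from forward/reverse
  cross-evaluated energy differences and summed over windows.

The binding free energy follows from a thermodynamic cycle over two
decoupling legs (guest in water, guest in the host complex).  All standard
errors are seeded bootstrap estimates (200 resamples by default).  Energies
are kJ/mol throughout; ``kT = 2.577 kJ/mol`` corresponds to 310 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

__all__ = [
    "KB_KJ_PER_MOL_K",
    "E_NM_TO_DEBYE",
    "LambdaWindowSamples",
    "FreeEnergyResult",
    "ti_integrate",
    "bar_estimate",
    "bar_from_lambda_samples",
    "exp_estimate",
    "binding_cycle",
    "block_average",
    "dipole_moment",
]

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/mol/K
E_NM_TO_DEBYE = 48.0321           # 1 e*nm in Debye

DEFAULT_N_BOOT = 200


class OverlapError(RuntimeError):
    """Forward/reverse work distributions overlap too poorly to solve BAR."""


@dataclass
class LambdaWindowSamples:
    """Per-lambda samples of dH/dlambda plus adjacent-window energy differences.

    ``forward[i]`` holds U(lambda[i+1]) - U(lambda[i]) evaluated on samples
    from window i; ``reverse[i]`` holds U(lambda[i]) - U(lambda[i+1])
    evaluated on samples from window i+1.  Soft-core and schedule settings
    travel in ``metadata`` but are never used in computation.
    """

    lambdas: np.ndarray                    # ascending, in [0, 1]
    dhdl: list                             # per-lambda arrays, kJ/mol
    forward: list = field(default_factory=list)   # n_lambda - 1 arrays
    reverse: list = field(default_factory=list)   # n_lambda - 1 arrays
    temperature_K: float = 310.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(self.lambdas < 0) or np.any(self.lambdas > 1):
            raise ValueError("lambda values must lie in [0, 1]")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda values must be strictly ascending")
        if len(self.dhdl) != len(self.lambdas):
            raise ValueError("one dhdl sample array required per lambda")
        n = len(self.lambdas)
        if self.forward and len(self.forward) != n - 1:
            raise ValueError("forward needs one array per adjacent lambda pair")
        if self.reverse and len(self.reverse) != n - 1:
            raise ValueError("reverse needs one array per adjacent lambda pair")

    @property
    def kT(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature_K

    def discard_equilibration(self, fraction: float) -> "LambdaWindowSamples":
        """Drop the leading ``fraction`` of samples in every window."""
        if not 0 <= fraction < 1:
            raise ValueError("discard fraction must be in [0, 1)")

        def cut(a):
            a = np.asarray(a)
            return a[int(np.floor(fraction * len(a))):]

        return LambdaWindowSamples(
            lambdas=self.lambdas,
            dhdl=[cut(a) for a in self.dhdl],
            forward=[cut(a) for a in self.forward],
            reverse=[cut(a) for a in self.reverse],
            temperature_K=self.temperature_K,
            metadata=dict(self.metadata),
        )


@dataclass
class FreeEnergyResult:
    """A free-energy estimate with its bootstrap standard error.

    ``windows`` carries per-window contributions; for BAR the total is their
    exact sum.  ``convention`` records the sign convention of the estimate.
    """

    delta_g: float                 # kJ/mol
    se: float                      # kJ/mol, bootstrap
    method: str                    # "TI" | "BAR" | "EXP" | "cycle"
    windows: pd.DataFrame | None = None
    convention: str = "work to annihilate guest-environment interactions"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FreeEnergyResult(method={self.method}, "
                f"delta_g={self.delta_g:.3f} kJ/mol, se={self.se:.3f})")


# ---------------------------------------------------------------------------
# thermodynamic integration
# ---------------------------------------------------------------------------

def ti_integrate(samples: LambdaWindowSamples, n_boot: int = DEFAULT_N_BOOT,
                 seed: int = 0, rule: str = "trapezoid") -> FreeEnergyResult:
    """Integrate ``<dH/dlambda>`` over the lambda grid.

    Trapezoidal quadrature by default (exact for integrands affine in
    lambda); Simpson is available for uniform odd-length grids.  The
    bootstrap resamples within each window independently.
    """
    lams = samples.lambdas
    if len(lams) < 2:
        raise ValueError("TI needs at least 2 lambda points")
    groups = [np.asarray(a, dtype=float) for a in samples.dhdl]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every lambda window needs at least one dhdl sample")
    means = np.array([g.mean() for g in groups])
    value = _quadrature(lams, means, rule)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bm = np.array([rng.choice(g, size=len(g), replace=True).mean() for g in groups])
        boots[b] = _quadrature(lams, bm, rule)
    se = float(boots.std(ddof=1)) if n_boot > 1 else 0.0

    windows = pd.DataFrame({
        "lambda": lams,
        "mean_dhdl": means,
        "n_samples": [len(g) for g in groups],
    })
    return FreeEnergyResult(delta_g=float(value), se=se, method="TI", windows=windows)


def _quadrature(x: np.ndarray, y: np.ndarray, rule: str) -> float:
    if rule == "trapezoid":
        return float(np.trapezoid(y, x))
    if rule == "simpson":
        from scipy.integrate import simpson
        if len(x) % 2 == 0 or not np.allclose(np.diff(x), x[1] - x[0]):
            raise ValueError("Simpson rule needs a uniform odd-length grid")
        return float(simpson(y, x=x))
    raise ValueError(f"unknown quadrature rule: {rule!r}")


# ---------------------------------------------------------------------------
# Bennett acceptance ratio
# ---------------------------------------------------------------------------

def _bar_residual(x, w_f, w_r, beta, m):
    """BAR self-consistency residual; strictly increasing in x.

    With the logistic f(u) = 1/(1+e^u):
        sum_F f(beta*(W_F - x) + m) - sum_R f(beta*(W_R + x) - m)
    runs from -n_R (x -> -inf) to +n_F (x -> +inf).
    """
    return (expit(-(beta * (w_f - x) + m)).sum()
            - expit(-(beta * (w_r + x) - m)).sum())


def _bar_solve(w_f: np.ndarray, w_r: np.ndarray, kT: float,
               xtol: float = 1e-12) -> float:
    beta = 1.0 / kT
    m = np.log(len(w_f) / len(w_r))
    lo = min(w_f.min(), -w_r.max()) - 10 * kT
    hi = max(w_f.max(), -w_r.min()) + 10 * kT
    span = max(hi - lo, kT)
    for _ in range(80):
        if _bar_residual(lo, w_f, w_r, beta, m) < 0 < _bar_residual(hi, w_f, w_r, beta, m):
            break
        lo -= span
        hi += span
        span *= 2
    else:
        raise OverlapError(
            "BAR root not bracketed: forward/reverse work distributions "
            "overlap too poorly")
    return float(brentq(_bar_residual, lo, hi, args=(w_f, w_r, beta, m),
                        xtol=xtol, rtol=8.9e-16))


def _bar_bootstrap(w_f: np.ndarray, w_r: np.ndarray, kT: float, x0: float,
                   n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised damped-Newton BAR over bootstrap resamples.

    The residual is strictly increasing with derivative
    beta * sum f(1-f) > 0, so Newton from the full-sample root with a
    step clamp converges for every resample.
    """
    beta = 1.0 / kT
    m = np.log(len(w_f) / len(w_r))
    bf = w_f[rng.integers(0, len(w_f), size=(n_boot, len(w_f)))]
    br = w_r[rng.integers(0, len(w_r), size=(n_boot, len(w_r)))]
    x = np.full(n_boot, x0)
    clamp = 20 * kT
    for _ in range(200):
        pf = expit(-(beta * (bf - x[:, None]) + m))
        pr = expit(-(beta * (br + x[:, None]) - m))
        g = pf.sum(axis=1) - pr.sum(axis=1)
        dg = beta * ((pf * (1 - pf)).sum(axis=1) + (pr * (1 - pr)).sum(axis=1))
        step = -g / np.maximum(dg, 1e-300)
        np.clip(step, -clamp, clamp, out=step)
        x += step
        if np.max(np.abs(g)) < 1e-9:
            break
    return x


def bar_estimate(forward_work: np.ndarray, reverse_work: np.ndarray, kT: float,
                 n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> FreeEnergyResult:
    """Bennett-acceptance-ratio estimate of the free-energy difference.

    ``forward_work`` are energy differences U1-U0 on samples from state 0;
    ``reverse_work`` are U0-U1 on samples from state 1.  The estimate
    solves the maximum-likelihood condition

        sum_F f(beta*(W_F - dG) + M) = sum_R f(beta*(W_R + dG) - M),

    with f the logistic function and M = ln(n_F/n_R), by bracketed
    root-finding.  Swapping the two sample sets negates the estimate
    (label-swap antisymmetry).
    """
    w_f = np.asarray(forward_work, dtype=float).ravel()
    w_r = np.asarray(reverse_work, dtype=float).ravel()
    if len(w_f) == 0 or len(w_r) == 0:
        raise ValueError("both forward and reverse sample sets must be non-empty")
    if kT <= 0:
        raise ValueError("kT must be positive")
    x = _bar_solve(w_f, w_r, kT)
    se = 0.0
    if n_boot > 1:
        rng = np.random.default_rng(seed)
        boots = _bar_bootstrap(w_f, w_r, kT, x, n_boot, rng)
        se = float(boots.std(ddof=1))
    windows = pd.DataFrame({
        "lambda_from": [0.0], "lambda_to": [1.0],
        "delta_g": [x], "se": [se],
        "n_forward": [len(w_f)], "n_reverse": [len(w_r)],
    })
    return FreeEnergyResult(delta_g=x, se=se, method="BAR", windows=windows)


def bar_from_lambda_samples(samples: LambdaWindowSamples,
                            n_boot: int = DEFAULT_N_BOOT,
                            seed: int = 0) -> FreeEnergyResult:
    """BAR summed over adjacent lambda windows; total = exact sum of windows."""
    n = len(samples.lambdas)
    if n < 2:
        raise ValueError("BAR needs at least 2 lambda windows")
    if not samples.forward or not samples.reverse:
        raise ValueError("forward/reverse energy differences are required for BAR")
    rows = []
    total = 0.0
    var = 0.0
    for i in range(n - 1):
        res = bar_estimate(samples.forward[i], samples.reverse[i], samples.kT,
                           n_boot=n_boot, seed=seed + i)
        rows.append({
            "lambda_from": samples.lambdas[i], "lambda_to": samples.lambdas[i + 1],
            "delta_g": res.delta_g, "se": res.se,
            "n_forward": len(samples.forward[i]),
            "n_reverse": len(samples.reverse[i]),
        })
        total += res.delta_g
        var += res.se ** 2
    return FreeEnergyResult(delta_g=total, se=float(np.sqrt(var)), method="BAR",
                            windows=pd.DataFrame(rows))


def exp_estimate(forward_work: np.ndarray, kT: float) -> float:
    """One-sided exponential-averaging estimate -kT ln<exp(-W/kT)>.

    The limit BAR approaches as the reverse sample set becomes empty.
    """
    w = np.asarray(forward_work, dtype=float).ravel()
    if len(w) == 0:
        raise ValueError("empty sample set")
    return float(-kT * (logsumexp(-w / kT) - np.log(len(w))))


# ---------------------------------------------------------------------------
# thermodynamic cycle, block averages, dipole
# ---------------------------------------------------------------------------

def binding_cycle(decouple_in_water: FreeEnergyResult | float,
                  decouple_in_complex: FreeEnergyResult | float) -> FreeEnergyResult:
    """Compose the binding free energy from two decoupling legs.

    Binding then decoupling from the complex must equal decoupling from
    water, so ``dG_bind = dG_decouple(water) - dG_decouple(complex)``:
    when annihilating the guest costs more inside the host cavity than in
    water, binding is favourable and dG_bind is negative.
    """
    gw, sw = _value_se(decouple_in_water)
    gc, sc = _value_se(decouple_in_complex)
    dg = gw - gc
    se = float(np.hypot(sw, sc))
    windows = pd.DataFrame({
        "leg": ["decouple_in_water", "decouple_in_complex"],
        "delta_g": [gw, gc], "se": [sw, sc],
    })
    res = FreeEnergyResult(delta_g=float(dg), se=se, method="cycle", windows=windows)
    res.convention = ("dG_bind = dG_decouple(water) - dG_decouple(complex); "
                      "favourable binding is negative")
    return res


def _value_se(x) -> tuple[float, float]:
    if isinstance(x, FreeEnergyResult):
        return x.delta_g, x.se
    return float(x), 0.0


def block_average(series: np.ndarray, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and standard error of a (possibly correlated) series by block averaging.

    The series is split into ``n_blocks`` equal-length contiguous blocks
    (discarding the oldest remainder); SE is the standard deviation of the
    block means over sqrt(n_blocks).
    """
    s = np.asarray(series, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(s) < n_blocks:
        raise ValueError(f"series of length {len(s)} shorter than {n_blocks} blocks")
    blk = len(s) // n_blocks
    s = s[len(s) - n_blocks * blk:]
    means = s.reshape(n_blocks, blk).mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks))


def dipole_moment(positions: np.ndarray, charges: np.ndarray) -> float:
    """Magnitude of the electric dipole |sum q_i r_i| in Debye.

    Positions in nm, charges in e.  For a net-charged group the dipole is
    origin-dependent; the origin is then taken at the |q|-weighted centroid
    and this choice is part of the reported value.
    """
    r = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    if q.size == 0:
        raise ValueError("no charges supplied")
    if r.shape != (q.size, 3):
        raise ValueError("positions must be (n, 3) matching charges")
    if abs(q.sum()) > 1e-9 and np.abs(q).sum() > 0:
        origin = (np.abs(q)[:, None] * r).sum(axis=0) / np.abs(q).sum()
        r = r - origin
    mu = (q[:, None] * r).sum(axis=0)
    return float(np.linalg.norm(mu) * E_NM_TO_DEBYE)
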