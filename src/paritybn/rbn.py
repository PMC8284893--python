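"""Kauffman N-K random Boolean ensembles and attractor-count scaling.

Each of N nodes receives K edges from regulators drawn uniformly without
replacement (self-inputs allowed by default; a flag excludes them), and a
quenched update function mapping each of the 2^K regulator states to 1 with
probability p, independently.  Degenerate functions (constants, or functions
not actually depending on a listed regulator) are kept as generated.  The
ensemble sits at the order-chaos boundary when 2 K p (1 - p) = 1; K = 2,
p = 0.5 is the classic critical point.

The scaling study fits <A> = a + b N^c by nonlinear least squares to the
mean attractor count per network size, with a bootstrap over networks within
each size for confidence intervals.  Networks whose enumeration exceeds the
budget contribute bounds instead of exact counts (lower bound: number of
maximal stable modules, at least 1; upper bound: deletion-projection count,
or the per-size fallback of 10% above the most attractor-rich network of
the same size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import warnings

from scipy.optimize import OptimizeWarning, curve_fit

from .expressions import BoolFunc
from .succession import Budget, enumerate_attractors
from .system import BooleanSystem

__all__ = [
    "RBNSpec",
    "EnsembleRecord",
    "ScalingFit",
    "criticality_parameter",
    "classify_regime",
    "generate_rbn",
    "count_attractors_with_bounds",
    "run_ensemble",
    "ensemble_table",
    "fit_scaling",
]


def criticality_parameter(K: int, p: float) -> float:
    """2 K p (1 - p); the ensemble is critical when this equals 1."""
    return 2.0 * K * p * (1.0 - p)


def classify_regime(K: int, p: float, tol: float = 1e-12) -> str:
    s = criticality_parameter(K, p)
    if abs(s - 1.0) <= tol:
        return "critical"
    return "ordered" if s < 1.0 else "chaotic"


@dataclass(frozen=True)
class RBNSpec:
    n: int
    k: int = 2
    p: float = 0.5
    seed: int = 0
    allow_self_inputs: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("N must be at least 1")
        if not (1 <= self.k <= self.n):
            raise ValueError("K must satisfy 1 <= K <= N")
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie strictly between 0 and 1")


def generate_rbn(spec: RBNSpec) -> BooleanSystem:
    """A quenched Kauffman network, fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"n{i}" for i in range(spec.n))
    funcs = {}
    for i, name in enumerate(names):
        if spec.allow_self_inputs:
            pool = np.arange(spec.n)
        else:
            if spec.k > spec.n - 1:
                raise ValueError("K > N-1 with self-inputs excluded")
            pool = np.delete(np.arange(spec.n), i)
        regs = np.sort(rng.choice(pool, size=spec.k, replace=False))
        bits = rng.random(1 << spec.k) < spec.p
        table = 0
        for idx, b in enumerate(bits):
            if b:
                table |= 1 << idx
        # from_table sorts inputs; n-index order and lexicographic order agree
        # only up to 10 nodes, so build sorted-by-name explicitly
        reg_names = [names[r] for r in regs]
        order = sorted(range(spec.k), key=lambda j: reg_names[j])
        sorted_table = 0
        for idx in range(1 << spec.k):
            new_idx = 0
            for new_j, old_j in enumerate(order):
                if (idx >> old_j) & 1:
                    new_idx |= 1 << new_j
            if (table >> idx) & 1:
                sorted_table |= 1 << new_idx
        funcs[name] = BoolFunc(tuple(reg_names[j] for j in order), sorted_table)
    return BooleanSystem(names, funcs)


@dataclass(frozen=True)
class EnsembleRecord:
    spec: RBNSpec
    exact: bool
    count: int | None  # exact attractor count when available
    lower: int
    upper: int | None  # None: needs the per-size ensemble fallback
    n_point: int | None = None
    n_maximal_modules: int | None = None
    flags: tuple[str, ...] = ()


def count_attractors_with_bounds(
    sys: BooleanSystem, budget: Budget = Budget(), spec: RBNSpec | None = None
) -> EnsembleRecord:
    """Exact count via the succession pipeline, or (lower, upper) bounds."""
    spec = spec or RBNSpec(n=sys.n)
    report = enumerate_attractors(sys, budget)
    if report.exact:
        count = report.count
        sd = report.diagram
        leaf_sets = {
            frozenset(sd.nodes[k].fixed.items()) for k in sd.leaves() if k in sd.nodes
        } - {frozenset()}
        return EnsembleRecord(
            spec, True, count, count, count,
            n_point=report.n_point(),
            n_maximal_modules=len(leaf_sets),
            flags=report.flags,
        )
    return EnsembleRecord(
        spec, False, None, max(1, report.lower), report.upper, flags=report.flags
    )


def run_ensemble(
    sizes: "list[int]",
    reps: int = 100,
    k: int = 2,
    p: float = 0.5,
    seed: int = 0,
    budget: Budget = Budget(
        motif_branches=50_000, space_bits=17, succession_nodes=512, time_limit=5.0
    ),
    allow_self_inputs: bool = True,
    progress: bool = False,
) -> list[EnsembleRecord]:
    """Generate and analyze ``reps`` networks per size; reproducible by seed."""
    records: list[EnsembleRecord] = []
    master = np.random.default_rng(seed)
    for n in sizes:
        # the 10%-above-richest fallback for irreducibly hard networks
        size_records: list[EnsembleRecord] = []
        for r in range(reps):
            net_seed = int(master.integers(0, 2**31 - 1))
            spec = RBNSpec(n=n, k=k, p=p, seed=net_seed, allow_self_inputs=allow_self_inputs)
            sys = generate_rbn(spec)
            size_records.append(count_attractors_with_bounds(sys, budget, spec))
            if progress and (r + 1) % 25 == 0:
                print(f"  N={n}: {r + 1}/{reps}", flush=True)
        richest = max(
            (rec.count for rec in size_records if rec.exact), default=1
        )
        fallback_upper = int(np.ceil(1.1 * richest))
        for rec in size_records:
            if rec.upper is None:
                rec = EnsembleRecord(
                    rec.spec, rec.exact, rec.count, rec.lower,
                    max(fallback_upper, rec.lower),
                    rec.n_point, rec.n_maximal_modules,
                    rec.flags + ("fallback-upper",),
                )
            records.append(rec)
    return records


def ensemble_table(records: list[EnsembleRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "N": rec.spec.n,
                "K": rec.spec.k,
                "p": rec.spec.p,
                "seed": rec.spec.seed,
                "exact": rec.exact,
                "count": rec.count,
                "lower": rec.lower,
                "upper": rec.upper,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScalingFit:
    a: float
    b: float
    c: float
    sd: tuple[float, float, float]  # bootstrap standard deviations
    ci_c: tuple[float, float]  # bootstrap percentile 95% CI for the exponent
    mode: str
    sizes: tuple[int, ...]
    means: tuple[float, ...]
    n_networks: int
    n_boot: int
    seed: int
    fraction_exact: float = float("nan")


def _power_law(n, a, b, c):
    return a + b * np.power(n, c)


def _fit(sizes: np.ndarray, means: np.ndarray) -> tuple[float, float, float]:
    """Bounded multistart nonlinear least squares for a + b N^c.

    The three parameters trade off strongly at small exponents, so several
    initial guesses are tried and the lowest-residual solution kept.
    """
    x = sizes.astype(float)
    bounds = ([-10.0, 1e-6, 1e-4], [10.0, 100.0, 1.5])
    best, best_ssr = None, np.inf
    for c0 in (0.05, 0.1, 0.2, 0.5):
        try:
            with warnings.catch_warnings():
                # the covariance is unused; flat-ridge fits cannot estimate it
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _power_law, x, means, p0=(0.0, 1.0, c0), bounds=bounds,
                    maxfev=20_000,
                )
        except RuntimeError:
            continue
        ssr = float(np.sum((_power_law(x, *popt) - means) ** 2))
        if ssr < best_ssr - 1e-12:
            best, best_ssr = popt, ssr
    if best is None:
        raise RuntimeError("power-law fit did not converge from any start")
    return tuple(float(v) for v in best)


def fit_scaling(
    records: list[EnsembleRecord],
    mode: str = "exact",
    n_boot: int = 1000,
    seed: int = 0,
) -> ScalingFit:
    """Nonlinear least squares of <A> = a + b N^c to per-size mean counts.

    mode "exact" uses only exactly enumerated networks; "lower"/"upper" use
    the corresponding bound for every network.  Bootstrap resamples networks
    within each size and refits; the CI is the 2.5/97.5 percentile interval.
    """
    if mode not in ("exact", "lower", "upper"):
        raise ValueError("mode must be exact, lower, or upper")
    by_size: dict[int, list[float]] = {}
    total = 0
    n_exact = 0
    for rec in records:
        total += 1
        n_exact += rec.exact
        if mode == "exact":
            if rec.exact:
                by_size.setdefault(rec.spec.n, []).append(float(rec.count))
        elif mode == "lower":
            by_size.setdefault(rec.spec.n, []).append(float(rec.lower))
        else:
            if rec.upper is None:
                raise ValueError("upper bound missing; run through run_ensemble")
            by_size.setdefault(rec.spec.n, []).append(float(rec.upper))
    sizes = np.array(sorted(by_size), dtype=np.int64)
    if sizes.size < 3:
        raise ValueError("need at least 3 distinct sizes to fit a + b N^c")
    # sorted within size: the fit and bootstrap are then invariant to the
    # ordering of networks in the input
    samples = [np.sort(np.array(by_size[n])) for n in sizes]
    means = np.array([s.mean() for s in samples])
    a, b, c = _fit(sizes, means)
    rng = np.random.default_rng(seed)
    # bootstrap refits start from the point estimate (single start)
    bounds = ([-10.0, 1e-6, 1e-4], [10.0, 100.0, 1.5])
    p0 = (np.clip(a, -10, 10), np.clip(b, 1e-6, 100), np.clip(c, 1e-4, 1.5))
    boots = []
    for _ in range(n_boot):
        bm = np.array(
            [s[rng.integers(0, s.size, s.size)].mean() for s in samples]
        )
        try:
            with warnings.catch_warnings():
                # degenerate resamples (e.g. all-equal means) fit fine but
                # carry no curvature information
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _power_law, sizes.astype(float), bm, p0=p0, bounds=bounds,
                    maxfev=5_000,
                )
            boots.append(tuple(float(v) for v in popt))
        except RuntimeError:
            continue
    boots = np.array(boots) if boots else np.array([[a, b, c]])
    sd = tuple(float(x) for x in boots.std(axis=0, ddof=1)) if len(boots) > 1 else (0.0, 0.0, 0.0)
    lo, hi = np.percentile(boots[:, 2], [2.5, 97.5])
    return ScalingFit(
        a, b, c, sd, (float(lo), float(hi)), mode,
        tuple(int(n) for n in sizes), tuple(float(m) for m in means),
        n_networks=sum(s.size for s in samples), n_boot=len(boots), seed=seed,
        fraction_exact=n_exact / total if total else float("nan"),
    )
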