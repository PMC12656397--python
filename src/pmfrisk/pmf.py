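"""Uncertainty-weighted positive matrix factorization (receptor model).

Decomposes a concentration matrix ``x`` (n samples x m species) into
non-negative factor contributions ``g`` (n x p) and factor profiles ``f``
(p x m) by minimizing the uncertainty-scaled objective

    Q = sum_ij ( (x_ij - (g f)_ij) / u_ij )^2

where ``u_ij`` is the per-cell measurement uncertainty. The uncertainty is
built from the species' error fraction and method detection limit (MDL): for
values above the MDL, u = sqrt((error_fraction * conc)^2 + (0.5 * MDL)^2);
at or below the MDL the value is replaced by MDL/2 with the fixed
uncertainty u = (5/6) * MDL, the standard receptor-model convention.

The optimizer is a weighted variant of the multiplicative non-negative
matrix-factorization updates (weights 1/u^2), which are monotone in Q and
preserve non-negativity by construction; the best of ``n_starts`` random
initializations is kept. A robust mode iteratively inflates the uncertainty
of cells with |scaled residual| > 4, mirroring the robust-Q concept of the
published receptor-model tools. Factor order and scale are not identifiable,
so comparisons against a reference must go through :func:`align_factors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

from .core_data import ELEMENT_ORDER, ElementMeta, SampleTable

#: Default species error fraction used in the uncertainty equation.
DEFAULT_ERROR_FRACTION: float = 0.10

#: |scaled residual| threshold above which robust mode downweights a cell.
ROBUST_ALPHA: float = 4.0

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Uncertainty construction
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyMatrix:
    """Per-cell uncertainties plus the working concentration matrix.

    ``substituted`` marks below-detection cells whose working value is MDL/2
    with fixed uncertainty (5/6)*MDL.
    """

    u: np.ndarray
    working_conc: np.ndarray
    substituted: np.ndarray
    error_fraction: float

    def __post_init__(self) -> None:
        if not (np.asarray(self.u) > 0).all():
            raise ValueError("uncertainties must be strictly positive")


def compute_uncertainty(conc, mdl, error_fraction: float = DEFAULT_ERROR_FRACTION):
    """Uncertainty, working concentration and substitution flag for one species.

    Vectorized over ``conc``. For conc strictly greater than the MDL:
    u = sqrt((error_fraction*conc)^2 + (0.5*mdl)^2) and the concentration is
    used as-is; otherwise (including equality) u = (5/6)*mdl and the working
    concentration is mdl/2.
    """
    conc = np.asarray(conc, dtype=float)
    if not mdl > 0:
        raise ValueError(f"MDL must be > 0, got {mdl}")
    if not 0 < error_fraction < 1:
        raise ValueError(f"error fraction must be in (0, 1), got {error_fraction}")
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    above = conc > mdl
    u = np.where(
        above,
        np.sqrt((error_fraction * conc) ** 2 + (0.5 * mdl) ** 2),
        (5.0 / 6.0) * mdl,
    )
    working = np.where(above, conc, mdl / 2.0)
    if conc.ndim == 0:
        return float(u), float(working), bool(~above)
    return u, working, ~above


def build_uncertainty(
    table: SampleTable,
    registry: Mapping[str, ElementMeta],
    error_fraction: float = DEFAULT_ERROR_FRACTION,
) -> UncertaintyMatrix:
    """Uncertainty matrix for a whole survey table (column-wise MDLs)."""
    conc = table.conc.to_numpy(dtype=float)
    u = np.empty_like(conc)
    working = np.empty_like(conc)
    substituted = np.empty(conc.shape, dtype=bool)
    for j, elem in enumerate(table.elements):
        u[:, j], working[:, j], substituted[:, j] = compute_uncertainty(
            conc[:, j], registry[elem].mdl, error_fraction
        )
    return UncertaintyMatrix(u=u, working_conc=working,
                             substituted=substituted, error_fraction=error_fraction)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class PMFModel:
    """A fitted factorization with its objective values and diagnostics."""

    g: np.ndarray
    f: np.ndarray
    q_true: float
    q_robust: float
    q_theoretical: float
    scaled_residuals: np.ndarray
    converged: bool
    n_starts: int
    seed: int
    q_history: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    @property
    def n_factors(self) -> int:
        return self.g.shape[1]


def q_theoretical(n: int, m: int, p: int) -> int:
    """Degrees-of-freedom approximation of the expected Q: n*m - p*(n+m)."""
    value = n * m - p * (n + m)
    if value <= 0:
        raise ValueError(
            f"n*m - p*(n+m) = {value} <= 0: too many factors for the data size; "
            "use a smaller p"
        )
    return value


def _q_value(x: np.ndarray, u: np.ndarray, g: np.ndarray, f: np.ndarray) -> float:
    r = (x - g @ f) / u
    return float(np.sum(r * r))


def _fit_single(
    x: np.ndarray,
    u: np.ndarray,
    p: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    patience: int = 20,
    g0: np.ndarray | None = None,
    f0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """One run of the weighted multiplicative updates from one start."""
    n, m = x.shape
    w = 1.0 / (u * u)
    wx = w * x
    if g0 is None:
        g = rng.uniform(1e-3, 1.0, size=(n, p))
        f = rng.uniform(1e-3, 1.0, size=(p, m)) * np.maximum(x.mean(axis=0), _EPS)
    else:
        g = np.maximum(g0, _EPS).copy()
        f = np.maximum(f0, _EPS).copy()
    q_hist = np.empty(max_iter + 1)
    q_hist[0] = _q_value(x, u, g, f)
    still = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wgf = w * (g @ f)
        g *= (wx @ f.T) / (wgf @ f.T + _EPS)
        wgf = w * (g @ f)
        f *= (g.T @ wx) / (g.T @ wgf + _EPS)
        q = _q_value(x, u, g, f)
        q_hist[it] = q
        rel = abs(q_hist[it - 1] - q) / max(q, _EPS)
        still = still + 1 if rel < tol else 0
        if still >= patience or q <= 1e-12:
            converged = True
            break
    return g, f, q_hist[: it + 1], converged


def _als_polish(
    x: np.ndarray,
    u: np.ndarray,
    g: np.ndarray,
    f: np.ndarray,
    max_sweeps: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact alternating weighted-NNLS sweeps from a warm start.

    Each half-sweep solves the weighted non-negative least-squares problem
    for every row of g (or column of f) exactly, so Q is non-increasing
    sweep to sweep; used to polish the winning multiplicative-update run,
    whose tail convergence is slow on (near-)exact-rank data.
    """
    g = g.copy()
    f = f.copy()
    sqw = 1.0 / u
    q_hist = [_q_value(x, u, g, f)]
    for _ in range(max_sweeps):
        for i in range(x.shape[0]):
            a = f.T * sqw[i][:, None]
            g[i], _ = nnls(a, x[i] * sqw[i])
        for j in range(x.shape[1]):
            a = g * sqw[:, j][:, None]
            f[:, j], _ = nnls(a, x[:, j] * sqw[:, j])
        q = _q_value(x, u, g, f)
        q_hist.append(q)
        if abs(q_hist[-2] - q) / max(q, _EPS) < tol or q <= 1e-14:
            break
    return g, f, np.asarray(q_hist)


def fit_pmf(
    x: np.ndarray,
    u: UncertaintyMatrix | np.ndarray,
    p: int,
    n_starts: int = 20,
    seed: int = 0,
    robust: bool = False,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> PMFModel:
    """Best-of-``n_starts`` uncertainty-weighted factorization.

    ``x`` is the working concentration matrix (below-detection values already
    substituted if ``u`` is an :class:`UncertaintyMatrix`, in which case its
    ``working_conc`` is used and ``x`` may be None). Ties between equally
    good starts go to the lowest start index.
    """
    if isinstance(u, UncertaintyMatrix):
        u_arr = u.u
        if x is None:
            x = u.working_conc
    else:
        u_arr = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if p > min(n, m):
        raise ValueError(f"p={p} exceeds min(n, m)={min(n, m)}")
    if not (np.isfinite(x).all() and np.isfinite(u_arr).all()):
        raise ValueError("non-finite values in inputs")
    if (u_arr <= 0).any():
        raise ValueError("uncertainties must be strictly positive")

    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    best = None
    for k in range(n_starts):
        rng = np.random.default_rng(seeds[k])
        g, f, q_hist, conv = _fit_single(x, u_arr, p, rng, max_iter, tol)
        if best is None or q_hist[-1] < best[2][-1]:
            best = (g, f, q_hist, conv)
    g, f, q_hist, conv = best
    g, f, q_polish = _als_polish(x, u_arr, g, f)
    q_hist = np.concatenate([q_hist, q_polish[1:]])

    u_eff = u_arr
    if robust:
        for _ in range(10):
            r = (x - g @ f) / u_eff
            flagged = np.abs(r) > ROBUST_ALPHA
            u_new = np.where(
                flagged, u_eff * np.sqrt(np.abs(r) / ROBUST_ALPHA), u_eff
            )
            if not flagged.any():
                break
            g, f, q_hist2, conv = _fit_single(
                x, u_new, p, np.random.default_rng(seeds[0]),
                max_iter, tol, g0=g, f0=f,
            )
            new_flagged = np.abs((x - g @ f) / u_eff) > ROBUST_ALPHA
            u_eff = u_new
            if (new_flagged == flagged).all():
                break

    residuals = (x - g @ f) / u_arr
    q_true = float(np.sum(residuals**2))
    try:
        q_theo = float(q_theoretical(n, m, p))
    except ValueError:
        q_theo = float("nan")  # dof formula undefined on tiny matrices
    # robust Q caps each cell's squared scaled residual at alpha*|r|
    q_robust = float(
        np.sum(np.where(np.abs(residuals) > ROBUST_ALPHA,
                        ROBUST_ALPHA * np.abs(residuals), residuals**2))
    )
    return PMFModel(
        g=g, f=f, q_true=q_true, q_robust=q_robust,
        q_theoretical=q_theo,
        scaled_residuals=residuals, converged=conv,
        n_starts=n_starts, seed=seed, q_history=np.asarray(q_hist),
    )


# ---------------------------------------------------------------------------
# Model selection and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class FactorScan:
    """Q-vs-number-of-factors report; ``suggested_p`` is advisory only."""

    report: pd.DataFrame
    suggested_p: int | None


def scan_factors(
    x: np.ndarray,
    u: UncertaintyMatrix | np.ndarray,
    p_range: Sequence[int] = range(2, 7),
    n_starts: int = 20,
    seed: int = 0,
    robust: bool = False,
    max_iter: int = 5000,
) -> FactorScan:
    """Fit every p in ``p_range`` and report Q statistics per factor count.

    The suggested p is the smallest one where the relative Q drop to the next
    p falls below 10% (Q has stabilized) — advisory, never auto-selected.
    """
    rows = []
    for p in p_range:
        model = fit_pmf(x, u, p, n_starts=n_starts, seed=seed,
                        robust=robust, max_iter=max_iter)
        frac = float(np.mean(np.abs(model.scaled_residuals) <= 3.0))
        rows.append(
            {
                "p": p,
                "q_true": model.q_true,
                "q_robust": model.q_robust,
                "q_theoretical": model.q_theoretical,
                "q_ratio": model.q_true / model.q_theoretical,
                "resid_frac_within_3": frac,
            }
        )
    report = pd.DataFrame(rows).set_index("p")
    suggested = None
    qs = report["q_true"].to_numpy()
    ps = list(p_range)
    for i in range(len(ps) - 1):
        drop = (qs[i] - qs[i + 1]) / max(qs[i], _EPS)
        if drop < 0.10:
            suggested = ps[i]
            break
    return FactorScan(report=report, suggested_p=suggested)


def diagnostics(model: PMFModel, elements: Sequence[str] | None = None,
                n_worst: int = 10) -> dict:
    """Residual summary: fractions within [-3, 3] and the worst cells."""
    r = model.scaled_residuals
    elements = list(elements) if elements is not None else [
        f"e{j}" for j in range(r.shape[1])
    ]
    within = np.abs(r) <= 3.0
    flat = np.argsort(np.abs(r), axis=None)[::-1][:n_worst]
    worst = [
        {"sample": int(i), "element": elements[j], "scaled_residual": float(r[i, j])}
        for i, j in zip(*np.unravel_index(flat, r.shape))
    ]
    return {
        "overall_fraction_within_3": float(within.mean()),
        "per_element_fraction_within_3": pd.Series(
            within.mean(axis=0), index=elements
        ),
        "worst_cells": worst,
    }


def profile_percentages(model: PMFModel) -> np.ndarray:
    """Element shares across factors, percent: columns sum to 100.

    share(k, j) = f_kj / sum_k f_kj * 100. All-zero species columns yield
    NaN (share undefined).
    """
    col = model.f.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(col > 0, model.f / col * 100.0, np.nan)
    return shares


def contribution_shares(model: PMFModel) -> np.ndarray:
    """Factor shares of total reconstructed mass, percent (sums to 100)."""
    mass = model.g.sum(axis=0) * model.f.sum(axis=1)
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total reconstructed mass")
    return 100.0 * mass / total


def align_factors(
    f_est: np.ndarray, f_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of estimated to reference profiles.

    Profiles are row-normalized (L2), so the match is scale-invariant.
    Returns ``(perm, cosines)`` where ``perm[k]`` is the estimated-factor
    index assigned to reference factor k and ``cosines[k]`` its cosine
    similarity.
    """
    f_est = np.asarray(f_est, dtype=float)
    f_true = np.asarray(f_true, dtype=float)
    if f_est.shape != f_true.shape:
        raise ValueError(f"shape mismatch: {f_est.shape} vs {f_true.shape}")

    def _norm(a):
        nrm = np.linalg.norm(a, axis=1, keepdims=True)
        return a / np.maximum(nrm, _EPS)

    cos = _norm(f_true) @ _norm(f_est).T  # true x est
    row, col = linear_sum_assignment(-cos)
    return col, cos[row, col]


def bootstrap_stability(
    x: np.ndarray,
    u: UncertaintyMatrix | np.ndarray,
    model: PMFModel,
    n_boot: int = 20,
    seed: int = 0,
    cosine_threshold: float = 0.6,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Row-resampling bootstrap mapping rate per base factor.

    Each replicate resamples samples with replacement, refits from the base
    solution (warm start), and maps bootstrap factors onto base factors by
    best cosine. The mapping rate of base factor k is the fraction of
    replicates whose matched cosine is at least ``cosine_threshold``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    u_arr = u.u if isinstance(u, UncertaintyMatrix) else np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    p = model.n_factors
    rng = np.random.default_rng(seed)
    hits = np.zeros(p)
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        g, f, _, _ = _fit_single(
            x[rows], u_arr[rows], p, rng, max_iter, tol,
            g0=model.g[rows], f0=model.f,
        )
        _, cosines = align_factors(f, model.f)
        hits += cosines >= cosine_threshold
    return hits / n_boot
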