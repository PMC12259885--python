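"""Defense/adaptive-trait trade-off: upper envelope and sigmoid fit.

The inverse relationship between defense-system counts and adaptive traits
(ARG/MRG/VFG) is quantified by extracting the *upper envelope* — the maximum
trait count among genomes at each distinct defense-system count x — and
fitting the logistic decline

    y = a / (1 + exp(b * (x - c)))

by nonlinear least squares.  The curve is symmetric about (c, a/2); b sets
the steepness at the inflection.  Goodness of fit is the classical

    R^2 = 1 - sum (y_obs - y_fit)^2 / sum (y_obs - mean(y_obs))^2

computed on the envelope points.  The least-squares surface has local
minima, so the fitter is multi-start with seeded jitter and the best SSE
wins; determinism is preserved by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError
from .io import GenomeAnnotation
from .metrics import spearman


@dataclass(slots=True)
class TradeoffEnvelope:
    x: np.ndarray        # distinct defense-system counts, strictly increasing
    y_max: np.ndarray    # max trait count among genomes at each x
    n_at_x: np.ndarray   # genomes per bin
    trait_name: str
    category: str

    @property
    def n_points(self) -> int:
        return int(self.x.size)


@dataclass(slots=True)
class SigmoidFit:
    a: float
    b: float
    c: float
    r_squared: float
    sse: float
    converged: bool
    n_points: int
    seed: int
    message: str = ""


def _category_count(genome: GenomeAnnotation, category: str,
                    first_line: set[str] | frozenset[str] | None) -> int:
    if category == "all":
        return len(genome.systems)
    if category in ("first_line", "accessory"):
        if first_line is None:
            raise DataError(f"category {category!r} needs a first_line set")
        n_fl = sum(1 for s in genome.systems if s.family in first_line)
        return n_fl if category == "first_line" else len(genome.systems) - n_fl
    if category.startswith("family:"):
        fam = category.split(":", 1)[1]
        return sum(1 for s in genome.systems if s.family == fam)
    raise DataError(f"unknown category {category!r}")


def build_envelope(cohort: list[GenomeAnnotation], trait_name: str,
                   category: str = "all",
                   first_line: set[str] | frozenset[str] | None = None,
                   min_bin: int = 1) -> TradeoffEnvelope:
    """Per-x maximum trait count; bins with fewer than min_bin genomes drop."""
    xs, ys = [], []
    for ga in cohort:
        if trait_name not in ga.traits:
            raise DataError(f"{ga.genome_id}: trait {trait_name!r} missing")
        xs.append(_category_count(ga, category, first_line))
        ys.append(ga.traits[trait_name])
    df = pd.DataFrame({"x": xs, "y": ys})
    g = df.groupby("x")["y"].agg(["max", "size"]).reset_index()
    g = g[g["size"] >= min_bin]
    if g.empty:
        raise DataError("empty envelope")
    return TradeoffEnvelope(
        x=g["x"].to_numpy(dtype=float),
        y_max=g["max"].to_numpy(dtype=float),
        n_at_x=g["size"].to_numpy(dtype=int),
        trait_name=trait_name, category=category)


def sigmoid(x, a: float, b: float, c: float):
    z = np.clip(b * (np.asarray(x, dtype=float) - c), -500, 500)
    return a / (1.0 + np.exp(z))


def r_squared(y_obs, y_fit) -> float:
    """R^2 = 1 - SSE/SST on the given points; undefined for constant y_obs."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y_obs.shape != y_fit.shape:
        raise DataError("r_squared: length mismatch")
    if y_obs.size < 2:
        raise DataError("r_squared: need >= 2 points")
    sst = np.sum((y_obs - y_obs.mean()) ** 2)
    if sst == 0:
        raise DataError("r_squared undefined for constant observations")
    return float(1.0 - np.sum((y_obs - y_fit) ** 2) / sst)


def fit_sigmoid(env: TradeoffEnvelope, n_starts: int = 16, seed: int = 0,
                weight_by_n: bool = False) -> SigmoidFit:
    """Multi-start least-squares fit of the logistic decline to an envelope.

    Starts: a0 = max(y_max); c0 spread over the x range; b0 in
    {+-0.1, +-1}, each jittered by the seeded RNG.  The fit with the lowest
    SSE wins.  Degenerate envelopes (constant y_max, < 4 points) return
    ``converged=False`` with a diagnostic message instead of raising.
    """
    x, y = env.x, env.y_max
    if env.n_points < 4:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                          env.n_points, seed, "need >= 4 envelope points")
    if np.all(y == y[0]):
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                          env.n_points, seed,
                          "constant envelope: b unidentifiable")
    w = np.sqrt(env.n_at_x.astype(float)) if weight_by_n else np.ones_like(y)

    def residuals(theta):
        a, b, c = theta
        return w * (y - sigmoid(x, a, b, c))

    rng = np.random.default_rng(seed)
    a0 = float(y.max())
    c_grid = np.linspace(x.min(), x.max(), 4)
    b_grid = [0.1, 1.0, -0.1, -1.0]
    starts = [(a0, b0, c0) for c0 in c_grid for b0 in b_grid]
    while len(starts) < n_starts:
        starts.append((a0 * rng.uniform(0.5, 1.5),
                       rng.uniform(-2, 2),
                       rng.uniform(x.min(), x.max())))
    starts = starts[:n_starts]
    # deterministic small jitter decorrelates duplicated grid starts
    jitter = rng.normal(scale=1e-3, size=(len(starts), 3))

    best = None
    for s, j in zip(starts, jitter):
        theta0 = np.array(s, dtype=float) + j
        try:
            res = least_squares(residuals, theta0, method="lm",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=5000)
        except Exception:
            continue
        sse = float(np.sum((y - sigmoid(x, *res.x)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                          env.n_points, seed, "all starts failed")
    sse, (a, b, c) = best
    if a < 0:  # mirror-image solution a<0,b flipped: reject as non-physical
        return SigmoidFit(a, b, c, np.nan, sse, False, env.n_points, seed,
                          "fitted ceiling a is negative")
    r2 = r_squared(y, sigmoid(x, a, b, c))
    return SigmoidFit(float(a), float(b), float(c), r2, sse, True,
                      env.n_points, seed)


def category_correlations(cohort: list[GenomeAnnotation], trait_name: str,
                          first_line: set[str] | frozenset[str]
                          ) -> pd.DataFrame:
    """Spearman of trait count vs per-category defense-system count.

    Categories: all, first_line, accessory, and one row per first-line
    family.  Rows where the correlation is undefined (constant counts) get
    NaN instead of raising.
    """
    cats = ["all", "first_line", "accessory"] + \
           [f"family:{f}" for f in sorted(first_line)]
    ys = [ga.traits[trait_name] for ga in cohort]
    rows = []
    for cat in cats:
        xs = [_category_count(ga, cat, first_line) for ga in cohort]
        try:
            rho, p = spearman(xs, ys)
        except DataError:
            rho, p = np.nan, np.nan
        rows.append({"category": cat, "rho": rho, "pvalue": p})
    return pd.DataFrame(rows, columns=["category", "rho", "pvalue"])
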