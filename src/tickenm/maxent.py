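"""Regularized maximum-entropy presence-background niche model.

The model estimates a probability density ``q(x) = exp(lambda . f(x)) / Z``
over the background cells of the calibration region, where ``f`` are
feature transformations of the environmental variables and ``Z``
normalizes over the background. Fitting maximizes the L1-penalized
log-likelihood of the presence records

    sum_i log q(x_i) - sum_j beta_j |lambda_j|,

with per-feature penalties ``beta_j = multiplier * base(class, n) * s_j / sqrt(n)``
(``s_j`` = feature sd over presences, ``n`` = presence count, ``base``
the published class-specific defaults interpolated by presence count).
The optimum of this convex objective — not any particular sequential
update scheme — defines the model; we solve it by splitting each
coefficient into its positive and negative parts (``lambda = u - v``,
``u, v >= 0``), which turns the L1 penalty into a smooth bound-
constrained problem handled by L-BFGS-B. Coefficients pinned at the
bound come out exactly zero, so the parameter count ``k`` used by AICc
is well defined; a KKT residual check on the original subdifferential
confirms convergence.

Five feature classes are supported (linear, quadratic, product,
threshold, hinge), all computed on variables min-max scaled to [0, 1]
over the background. Predictions can be *raw* (the density itself,
summing to 1 over background) or *cloglog*
(``1 - exp(-exp(H) * raw)`` with ``H`` the entropy of the fitted
background distribution), the bounded suitability scale used for all
downstream thresholding. Projection onto new conditions optionally
*clamps* each variable into its training range first, limiting
extrapolated responses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .envstack import EnvStack

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product", "threshold", "hinge")

#: class-specific base penalties interpolated by presence count
#: (published MaxEnt defaults)
_BASE_PENALTY = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 1.3, 0.8, 0.5, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 2.6, 1.6, 1.0, 0.05]),
    "threshold": ([0, 100], [2.0, 1.0]),
    "hinge": ([0, 1], [0.5, 0.5]),
}

_MIN_FEATURE_SD = 1e-2  # floor on presence sd so absent features stay penalized
# Coefficients below this magnitude are pruned to exact zero after fitting.
# With [0,1]-scaled features and per-presence penalties as small as ~1e-6,
# the active set is numerically undetermined below this scale: solver dust
# and genuine coefficients cannot be told apart, and a 1e-3 coefficient
# moves the linear predictor by at most 0.1%.
_ZERO_TOL = 1e-3


def base_penalty(feature_class: str, n_presences: int) -> float:
    xs, ys = _BASE_PENALTY[feature_class]
    return float(np.interp(n_presences, xs, ys))


@dataclass
class FeatureSpec:
    """Feature-expansion recipe tied to a calibration dataset.

    Stores the background min/max used for [0,1] scaling and the knot
    locations for threshold and hinge features, so the identical
    expansion can be replayed on any projection data.
    """

    classes: tuple[str, ...]
    var_names: list[str]
    var_min: np.ndarray
    var_max: np.ndarray
    threshold_knots: dict[str, np.ndarray] = field(default_factory=dict)
    hinge_knots: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.classes:
            raise ValueError("feature class set must be non-empty")
        bad = [c for c in self.classes if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(f"unknown feature class(es): {bad}")
        self.classes = tuple(c for c in FEATURE_CLASSES if c in self.classes)

    def scale(self, values: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Min-max scale columns to [0,1]; returns (scaled, out_of_range row mask)."""
        values = np.asarray(values, dtype=float)
        rng = self.var_max - self.var_min
        out = (values < self.var_min) | (values > self.var_max)
        if clamp:
            values = np.clip(values, self.var_min, self.var_max)
        return (values - self.var_min) / rng, out.any(axis=1)


def build_feature_spec(
    classes: Sequence[str],
    var_names: Sequence[str],
    background: np.ndarray,
    presences: np.ndarray | None = None,
    n_hinge_knots: int = 15,
    n_threshold_knots: int = 10,
) -> FeatureSpec:
    """Construct a FeatureSpec from calibration data.

    Scaling bounds come from the background sample; hinge knots sit at
    presence quantiles (falling back to evenly spaced when no presences
    are given) and threshold knots are evenly spaced, both strictly
    inside (0, 1) in scaled coordinates. Constant variables (zero
    background range) are excluded with a warning.
    """
    var_names = list(var_names)
    background = np.asarray(background, dtype=float)
    lo = background.min(axis=0)
    hi = background.max(axis=0)
    keep = hi > lo
    if not keep.all():
        dropped = [v for v, k in zip(var_names, keep) if not k]
        log.warning("excluding constant variable(s): %s", dropped)
        var_names = [v for v, k in zip(var_names, keep) if k]
        background = background[:, keep]
        if presences is not None:
            presences = np.asarray(presences, dtype=float)[:, keep]
        lo, hi = lo[keep], hi[keep]
    if not var_names:
        raise ValueError("no non-constant variables remain")
    spec = FeatureSpec(classes=tuple(classes), var_names=var_names, var_min=lo, var_max=hi)
    if "threshold" in spec.classes:
        knots = np.linspace(0.0, 1.0, n_threshold_knots + 2)[1:-1]
        spec.threshold_knots = {v: knots.copy() for v in var_names}
    if "hinge" in spec.classes:
        for j, v in enumerate(var_names):
            if presences is not None and len(presences) >= 2:
                x = (np.asarray(presences, dtype=float)[:, j] - lo[j]) / (hi[j] - lo[j])
                qs = np.quantile(x, np.linspace(0.0, 1.0, n_hinge_knots + 2)[1:-1])
            else:
                qs = np.linspace(0.0, 1.0, n_hinge_knots + 2)[1:-1]
            qs = np.unique(np.clip(qs, 1e-6, 1.0 - 1e-6))
            spec.hinge_knots[v] = qs
    return spec


def expand_features(values: np.ndarray, spec: FeatureSpec, clamp: bool = False):
    """Expand raw variable values into the model's design matrix.

    Returns ``(design, feature_names, feature_classes, out_of_range)``.
    Columns per class on [0,1]-scaled variables ``x``:
    linear ``x``; quadratic ``x^2``; product ``x_i x_j (i<j)``;
    threshold ``1[x > knot]``; hinge forward ``max(0, x-knot)/(1-knot)``
    and reverse ``max(0, knot-x)/knot`` (both rescaled to [0,1]).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(spec.var_names):
        raise ValueError(
            f"expected {len(spec.var_names)} variable column(s), got {values.shape[1]}"
        )
    x, oor = spec.scale(values, clamp=clamp)
    cols: list[np.ndarray] = []
    names: list[str] = []
    klass: list[str] = []
    p = len(spec.var_names)
    if "linear" in spec.classes:
        for j, v in enumerate(spec.var_names):
            cols.append(x[:, j])
            names.append(f"linear({v})")
            klass.append("linear")
    if "quadratic" in spec.classes:
        for j, v in enumerate(spec.var_names):
            cols.append(x[:, j] ** 2)
            names.append(f"quadratic({v})")
            klass.append("quadratic")
    if "product" in spec.classes:
        for i in range(p):
            for j in range(i + 1, p):
                cols.append(x[:, i] * x[:, j])
                names.append(f"product({spec.var_names[i]},{spec.var_names[j]})")
                klass.append("product")
    if "threshold" in spec.classes:
        for j, v in enumerate(spec.var_names):
            for t in spec.threshold_knots[v]:
                cols.append((x[:, j] > t).astype(float))
                names.append(f"threshold({v},{t:.6g})")
                klass.append("threshold")
    if "hinge" in spec.classes:
        for j, v in enumerate(spec.var_names):
            for t in spec.hinge_knots[v]:
                cols.append(np.maximum(0.0, x[:, j] - t) / (1.0 - t))
                names.append(f"hinge({v},{t:.6g})")
                klass.append("hinge")
                cols.append(np.maximum(0.0, t - x[:, j]) / t)
                names.append(f"revhinge({v},{t:.6g})")
                klass.append("hinge")
    design = np.column_stack(cols) if cols else np.empty((len(x), 0))
    return design, names, klass, oor


@dataclass
class MaxentModel:
    """Fitted maximum-entropy model: feature recipe + sparse coefficients."""

    feature_spec: FeatureSpec
    lambdas: np.ndarray
    feature_names: list[str]
    feature_classes: list[str]
    betas: np.ndarray
    log_density_normalizer: float  # log Z over the training background
    entropy: float  # H of the fitted background distribution
    beta_multiplier: float
    n_presences: int
    n_background: int
    converged: bool = True
    # unpruned solver solution, kept only to warm-start path refits
    raw_lambdas: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def k(self) -> int:
        """Number of nonzero coefficients (the AICc parameter count)."""
        return int(np.sum(np.abs(self.lambdas) > _ZERO_TOL))

    # -- prediction on value matrices -----------------------------------
    def raw(self, values: np.ndarray, clamp: bool = True):
        """Raw density (normalized over training background) per row; also out-of-range mask."""
        F, _, _, oor = expand_features(values, self.feature_spec, clamp=clamp)
        eta = F @ self.lambdas
        return np.exp(eta - self.log_density_normalizer), oor

    def cloglog(self, values: np.ndarray, clamp: bool = True):
        raw, oor = self.raw(values, clamp=clamp)
        return 1.0 - np.exp(-np.exp(self.entropy) * raw), oor

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        spec = self.feature_spec
        payload = {
            "classes": list(spec.classes),
            "var_names": spec.var_names,
            "var_min": spec.var_min.tolist(),
            "var_max": spec.var_max.tolist(),
            "threshold_knots": {v: k.tolist() for v, k in spec.threshold_knots.items()},
            "hinge_knots": {v: k.tolist() for v, k in spec.hinge_knots.items()},
            "lambdas": self.lambdas.tolist(),
            "feature_names": self.feature_names,
            "feature_classes": self.feature_classes,
            "betas": self.betas.tolist(),
            "log_density_normalizer": self.log_density_normalizer,
            "entropy": self.entropy,
            "beta_multiplier": self.beta_multiplier,
            "n_presences": self.n_presences,
            "n_background": self.n_background,
            "converged": self.converged,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        spec = FeatureSpec(
            classes=tuple(d["classes"]),
            var_names=list(d["var_names"]),
            var_min=np.asarray(d["var_min"], dtype=float),
            var_max=np.asarray(d["var_max"], dtype=float),
            threshold_knots={v: np.asarray(k, dtype=float) for v, k in d["threshold_knots"].items()},
            hinge_knots={v: np.asarray(k, dtype=float) for v, k in d["hinge_knots"].items()},
        )
        return cls(
            feature_spec=spec,
            lambdas=np.asarray(d["lambdas"], dtype=float),
            feature_names=list(d["feature_names"]),
            feature_classes=list(d["feature_classes"]),
            betas=np.asarray(d["betas"], dtype=float),
            log_density_normalizer=float(d["log_density_normalizer"]),
            entropy=float(d["entropy"]),
            beta_multiplier=float(d["beta_multiplier"]),
            n_presences=int(d["n_presences"]),
            n_background=int(d["n_background"]),
            converged=bool(d["converged"]),
        )


@dataclass
class SuitabilityGrid:
    """Model prediction over a raster grid (raw or cloglog scale)."""

    values: np.ndarray
    output_scale: str
    clamped_mask: np.ndarray
    valid_mask: np.ndarray


def fit_maxent(
    presences: np.ndarray,
    background: np.ndarray,
    feature_spec: FeatureSpec,
    beta_multiplier: float = 1.0,
    max_iter: int = 4000,
    tol: float = 1e-5,
    init_lambdas: np.ndarray | None = None,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model (positive/negative-part split + L-BFGS-B).

    ``presences`` and ``background`` are value matrices over the
    variables in ``feature_spec`` (background should be a representative
    sample of the calibration-region cells). Convergence is declared
    when the KKT residual of the L1 subdifferential falls below
    ``tol`` (scaled by the presence count); non-convergence flags the
    model but still returns it.
    """
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n = len(presences)
    if n < 1:
        raise ValueError("need at least one presence")
    Fp, names, klass, _ = expand_features(presences, feature_spec)
    Fb, _, _, _ = expand_features(background, feature_spec)
    m = Fp.shape[1]
    # per-feature penalties
    s = Fp.std(axis=0, ddof=0) if n > 1 else np.zeros(m)
    s = np.maximum(s, _MIN_FEATURE_SD)
    base = np.array([base_penalty(c, n) for c in klass])
    betas = beta_multiplier * base * s / np.sqrt(n)

    mean_pres = Fp.mean(axis=0)  # sufficient statistics
    betas_n = betas / n  # per-presence scale keeps the objective O(1)

    def smooth_val_grad(lam):
        eta = Fb @ lam
        mx = eta.max()
        w = np.exp(eta - mx)
        se = w.sum()
        w /= se
        lse = float(mx + np.log(se))
        val = -float(mean_pres @ lam) + lse
        grad = -mean_pres + (Fb.T @ w)
        return val, grad

    # split lambda = u - v (u, v >= 0): the L1 penalty becomes the
    # linear term beta . (u + v) under bound constraints
    def objective(z):
        u, v = z[:m], z[m:]
        val, grad = smooth_val_grad(u - v)
        val += float(betas_n @ (u + v))
        return val, np.concatenate([grad + betas_n, -grad + betas_n])

    from scipy.optimize import minimize

    if init_lambdas is not None and len(init_lambdas) == m:
        z0 = np.concatenate([np.maximum(init_lambdas, 0.0), np.maximum(-init_lambdas, 0.0)])
    else:
        z0 = np.zeros(2 * m)
    res = minimize(
        objective,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * m),
        options={"maxiter": max_iter, "maxfun": 4 * max_iter, "ftol": 1e-15, "gtol": 1e-8},
    )
    z = res.x
    lam = z[:m] - z[m:]
    lam_raw = lam.copy()
    # KKT residual of the original (per-presence) L1 subdifferential,
    # evaluated on the raw solution before pruning
    _, g = smooth_val_grad(lam)
    active = np.abs(lam) > 1e-12
    kkt = np.zeros(m)
    kkt[active] = np.abs(g[active] + betas_n[active] * np.sign(lam[active]))
    kkt[~active] = np.maximum(np.abs(g[~active]) - betas_n[~active], 0.0)
    converged = bool(kkt.max(initial=0.0) <= tol)
    if not converged:
        log.warning(
            "fit_maxent: KKT residual %.3g above tolerance (%s)", kkt.max(initial=0.0), res.message
        )
    lam[np.abs(lam) <= _ZERO_TOL] = 0.0
    eta_b = Fb @ lam
    log_z = float(logsumexp(eta_b))
    w = np.exp(eta_b - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(np.where(w > 0, w * np.log(w), 0.0)))
    return MaxentModel(
        feature_spec=feature_spec,
        lambdas=lam,
        feature_names=names,
        feature_classes=klass,
        betas=betas,
        log_density_normalizer=log_z,
        entropy=entropy,
        beta_multiplier=beta_multiplier,
        n_presences=n,
        n_background=len(background),
        converged=converged,
        raw_lambdas=lam_raw,
    )


def regularization_path(
    presences: np.ndarray,
    background: np.ndarray,
    feature_spec: FeatureSpec,
    multipliers: Sequence[float],
    **fit_kwargs,
) -> list[MaxentModel]:
    """Fit one model per regularization multiplier with warm starts.

    Models are fitted in descending-penalty order, each initialized
    from the previous optimum (the solutions vary continuously along
    the path, so warm starts cut iteration counts sharply and keep
    weakly-penalized fits well converged). Results are returned in the
    order of ``multipliers``.
    """
    fit_kwargs.setdefault("max_iter", 10_000)
    order = np.argsort(multipliers)[::-1]
    models: dict[int, MaxentModel] = {}
    init = None
    for i in order:
        models[i] = fit_maxent(
            presences, background, feature_spec, float(multipliers[i]),
            init_lambdas=init, **fit_kwargs,
        )
        init = models[i].raw_lambdas
    return [models[i] for i in range(len(multipliers))]


def predict(
    model: MaxentModel,
    env: EnvStack,
    region_mask: np.ndarray | None = None,
    clamp: bool = True,
    output_scale: str = "cloglog",
) -> SuitabilityGrid:
    """Apply a fitted model over a raster stack.

    With ``clamp=True`` variable values outside the training min/max
    are pinned to the boundary before feature expansion, and
    ``clamped_mask`` marks the affected cells. Raw output stays
    normalized against the *training* background (so projecting onto
    the training region reproduces a density summing to 1); cloglog is
    ``1 - exp(-exp(H) * raw)``.
    """
    missing = [v for v in model.feature_spec.var_names if v not in env.layers]
    if missing:
        raise KeyError(f"stack lacks model variable(s): {missing}")
    if output_scale not in ("raw", "cloglog"):
        raise ValueError("output_scale must be 'raw' or 'cloglog'")
    mask = env.mask if region_mask is None else (np.asarray(region_mask, dtype=bool) & env.mask)
    values = env.table(model.feature_spec.var_names, mask=mask)
    if output_scale == "raw":
        pred, oor = model.raw(values, clamp=clamp)
    else:
        pred, oor = model.cloglog(values, clamp=clamp)
    grid = np.full(env.shape, np.nan)
    grid[mask] = pred
    cl = np.zeros(env.shape, dtype=bool)
    cl[mask] = oor if clamp else False
    return SuitabilityGrid(values=grid, output_scale=output_scale, clamped_mask=cl, valid_mask=mask)


def sample_background(env: EnvStack, region_mask: np.ndarray | None = None, max_cells: int = 10_000, seed: int = 0):
    """Background value matrix: all valid region cells, subsampled above ``max_cells``."""
    mask = env.mask if region_mask is None else (np.asarray(region_mask, dtype=bool) & env.mask)
    table = env.table(mask=mask)
    if len(table) > max_cells:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(table), size=max_cells, replace=False))
        table = table[idx]
    return table


def fit_replicates(
    presences: np.ndarray,
    background: np.ndarray,
    feature_spec: FeatureSpec,
    beta_multiplier: float = 1.0,
    n_replicates: int = 10,
    seed: int = 0,
    bootstrap: bool = True,
) -> list[MaxentModel]:
    """Fit ``n_replicates`` models on bootstrap resamples of the presences.

    Replicate seeds derive deterministically from the master seed. With
    ``bootstrap=False`` every replicate refits the full presence set
    (useful only for determinism checks). Individual fit failures are
    logged and skipped; at least one replicate must succeed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    n = len(presences)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    models: list[MaxentModel] = []
    for r in range(n_replicates):
        if bootstrap:
            rng = np.random.default_rng(seeds[r])
            idx = rng.integers(0, n, size=n)
            sample = presences[idx]
        else:
            sample = presences
        try:
            models.append(fit_maxent(sample, background, feature_spec, beta_multiplier))
        except Exception as exc:  # propagate nothing; log and continue
            log.warning("replicate %d failed: %s", r, exc)
    if not models:
        raise RuntimeError("all replicates failed to fit")
    return models


def median_and_range(grids: Sequence[SuitabilityGrid]) -> tuple[SuitabilityGrid, np.ndarray]:
    """Cellwise median suitability and max-minus-min uncertainty surface."""
    if not grids:
        raise ValueError("need at least one grid")
    shapes = {g.values.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError("grids are not co-registered")
    stack = np.stack([g.values for g in grids])
    med = np.nanmedian(stack, axis=0) if len(grids) > 1 else stack[0].copy()
    rng = np.nanmax(stack, axis=0) - np.nanmin(stack, axis=0)
    mask = grids[0].valid_mask
    clamped = np.zeros_like(mask)
    for g in grids:
        clamped |= g.clamped_mask
    med_grid = SuitabilityGrid(
        values=med, output_scale=grids[0].output_scale, clamped_mask=clamped, valid_mask=mask
    )
    return med_grid, rng
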