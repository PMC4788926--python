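"""Measurement-error model of ddCT biological variance.

The replicate-to-replicate variance of ddCT is modelled as a flexible
function of the signal magnitude,

    sigma2(x) = alpha + beta * |x| ** gamma,

fitted by weighted least squares to bin-averaged (|ddCT|, sample variance)
points. Four nested variants are supported:

=========  ===========================  ==============
variant    free parameters              constraint
=========  ===========================  ==============
constant   alpha                        beta = 0
linear     alpha, beta                  gamma = 1
power      beta, gamma                  alpha = 0
full       alpha, beta, gamma
=========  ===========================  ==============

Model choice follows a precision screen (coefficient of variation of each
free parameter) followed by the smallest weighted residual sum of squares
(WRSS), with parsimony as the tie-break. The selected model supplies the
variance used by the significance test downstream; per-cell sample
variances are only used here and for the variance filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import BinningError, FitError, InsufficientReplicationError

VARIANTS = ("constant", "linear", "power", "full")

#: free parameter names per variant, in optimisation order
FREE_PARAMS = {
    "constant": ("alpha",),
    "linear": ("alpha", "beta"),
    "power": ("beta", "gamma"),
    "full": ("alpha", "beta", "gamma"),
}


@dataclass(frozen=True)
class ErrorModel:
    """A fitted variance model sigma2(x) = alpha + beta * |x| ** gamma."""

    variant: str
    alpha: float
    beta: float
    gamma: float
    se: dict = field(default_factory=dict)  # standard error per free parameter
    wrss: float = float("nan")
    n_points: int = 0
    converged: bool = True
    degraded: bool = False  # set when selection fell back past the precision screen

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")

    @property
    def free_params(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.variant]

    def predict(self, ddct):
        """Predicted ddCT variance at (arrays of) ddCT values."""
        x = np.abs(np.asarray(ddct, dtype=float))
        if self.variant == "constant":
            out = np.full_like(x, self.alpha)
        else:
            out = self.alpha + self.beta * x**self.gamma
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "se": dict(self.se),
            "wrss": self.wrss,
            "n_points": self.n_points,
            "converged": self.converged,
            "degraded": self.degraded,
        }


def predict_variance(model: ErrorModel, ddct) -> float:
    """Variance predicted by a converged model at the given ddCT."""
    if not model.converged:
        raise FitError("model did not converge; cannot predict", model=model)
    return model.predict(ddct)


@dataclass
class BinnedVariance:
    """Equal-count bins of (|mean ddCT|, mean replicate variance) points."""

    bins: pd.DataFrame  # columns mean_abs_ddct, mean_var, n; sorted ascending

    def __post_init__(self):
        x = self.bins["mean_abs_ddct"].to_numpy()
        if np.any(np.diff(x) < 0):
            raise ValueError("bins must be ordered by increasing mean_abs_ddct")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def total_n(self) -> int:
        return int(self.bins["n"].sum())

    def write_csv(self, path) -> None:
        self.bins.to_csv(path, index=False)


def collect_replicate_stats(
    ddct, perturbations: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Pool per-cell (|mean ddCT|, sample variance, K) records for fitting.

    One record per (perturbation, gene, time point) summary cell, pooled
    across the requested silencing experiments (all by default). Cells with
    K < 2 carry no variance estimate; they are excluded and counted in the
    diagnostics dict.
    """
    summary = ddct.summary
    if perturbations is not None:
        summary = summary[summary["perturbation"].isin(perturbations)]
    usable = summary[summary["K"] >= 2]
    diagnostics = {
        "n_cells": int(len(summary)),
        "n_excluded_k_lt_2": int(len(summary) - len(usable)),
    }
    if usable.empty:
        raise InsufficientReplicationError(
            "no (perturbation, gene, time point) cell has K >= 2 replicates"
        )
    stats = pd.DataFrame(
        {
            "abs_mean_ddct": usable["mean_ddct"].abs().to_numpy(),
            "sample_variance": usable["var_ddct"].to_numpy(),
            "K": usable["K"].to_numpy(),
        }
    )
    return stats.reset_index(drop=True), diagnostics


def bin_variances(stats: pd.DataFrame, n_bins: int = 10, min_bin_size: int = 3) -> BinnedVariance:
    """Sort records by |mean ddCT| and average them in equal-count bins.

    The remainder of an uneven split goes to the leftmost bins, so bin
    counts differ by at most one.
    """
    n = len(stats)
    if n_bins < 1 or min_bin_size < 1:
        raise ValueError("n_bins and min_bin_size must be positive")
    if n < n_bins * min_bin_size:
        raise BinningError(
            f"{n} records cannot fill {n_bins} bins of >= {min_bin_size}; "
            f"reduce n_bins (max {n // min_bin_size})"
        )
    order = np.argsort(stats["abs_mean_ddct"].to_numpy(), kind="stable")
    x = stats["abs_mean_ddct"].to_numpy()[order]
    v = stats["sample_variance"].to_numpy()[order]
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    rows, start = [], 0
    for size in sizes:
        sl = slice(start, start + size)
        rows.append((float(x[sl].mean()), float(v[sl].mean()), size))
        start += size
    return BinnedVariance(pd.DataFrame(rows, columns=["mean_abs_ddct", "mean_var", "n"]))


def _variant_pack(variant: str, alpha, beta, gamma):
    # map a full (alpha, beta, gamma) vector to the variant's free vector
    if variant == "constant":
        return [alpha]
    if variant == "linear":
        return [alpha, beta]
    if variant == "power":
        return [beta, gamma]
    return [alpha, beta, gamma]


def _variant_unpack(variant: str, theta):
    if variant == "constant":
        return float(theta[0]), 0.0, 0.0
    if variant == "linear":
        return float(theta[0]), float(theta[1]), 1.0
    if variant == "power":
        return 0.0, float(theta[0]), float(theta[1])
    return float(theta[0]), float(theta[1]), float(theta[2])


def fit_error_model(
    binned: BinnedVariance,
    variant: str = "constant",
    gamma_bounds: tuple[float, float] = (0.0, 4.0),
) -> ErrorModel:
    """Weighted least squares of bin variance on bin |ddCT|.

    Weights are the bin counts. The constant variant has the closed form
    alpha = sum(n * var) / sum(n); the others use bounded nonlinear least
    squares with alpha, beta >= 0 and gamma in ``gamma_bounds``. Standard
    errors are the usual asymptotic ones from the weighted Jacobian.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    df = binned.bins
    x = df["mean_abs_ddct"].to_numpy(dtype=float)
    v = df["mean_var"].to_numpy(dtype=float)
    w = df["n"].to_numpy(dtype=float)
    if np.any(v < 0):
        raise ValueError("negative bin variance")
    n_free = len(FREE_PARAMS[variant])
    if len(df) < n_free + 1:
        raise BinningError(f"{variant!r} fit needs >= {n_free + 1} bins, got {len(df)}")

    if variant == "constant":
        alpha = float(np.sum(w * v) / np.sum(w))
        resid = np.sqrt(w) * (v - alpha)
        wrss = float(np.sum(resid**2))
        dof = len(df) - 1
        se_alpha = float(np.sqrt(wrss / dof / np.sum(w))) if dof > 0 else float("nan")
        return ErrorModel(
            variant="constant", alpha=alpha, beta=0.0, gamma=0.0,
            se={"alpha": se_alpha}, wrss=wrss, n_points=len(df),
        )

    def residuals(theta):
        a, b, g = _variant_unpack(variant, theta)
        return np.sqrt(w) * (v - (a + b * np.where(x > 0, x, 0.0) ** g))

    a0 = max(float(v.min()), 1e-6)
    slope = (v[-1] - v[0]) / (x[-1] - x[0]) if x[-1] > x[0] else 0.0
    b0 = max(slope, 1e-3)
    lo = np.array(_variant_pack(variant, 0.0, 0.0, gamma_bounds[0]))
    hi = np.array(_variant_pack(variant, np.inf, np.inf, gamma_bounds[1]))
    theta0 = np.clip(np.array(_variant_pack(variant, a0, b0, 1.0)), lo, hi)

    res = least_squares(
        residuals, theta0, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    alpha, beta, gamma = _variant_unpack(variant, res.x)
    wrss = float(np.sum(res.fun**2))
    dof = max(len(df) - n_free, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * (wrss / dof)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(n_free, np.nan)
    se = dict(zip(FREE_PARAMS[variant], (float(s) for s in ses)))
    model = ErrorModel(
        variant=variant, alpha=alpha, beta=beta, gamma=gamma,
        se=se, wrss=wrss, n_points=len(df), converged=bool(res.success),
    )
    if not res.success:
        raise FitError(f"{variant!r} fit did not converge: {res.message}", model=model)
    return model


def fit_all_variants(
    binned: BinnedVariance, variants: tuple[str, ...] = VARIANTS
) -> list[ErrorModel]:
    """Fit every requested variant, skipping those with too few bins or
    failed convergence (non-convergent best iterates are dropped)."""
    fits = []
    for variant in variants:
        try:
            fits.append(fit_error_model(binned, variant))
        except (FitError, BinningError):
            continue
    return fits


def select_error_model(fits: list[ErrorModel], cv_max: float = 0.5) -> ErrorModel:
    """Pick the best variance model: precision screen, then WRSS, then parsimony.

    A fit passes the precision screen when every free parameter has
    coefficient of variation se/|estimate| <= ``cv_max``. Among passing
    fits the smallest WRSS wins; equal WRSS goes to the fewer-parameter
    model. If nothing passes, the converged fit with fewest free parameters
    is returned flagged ``degraded``.

    The selected model feeds the null-hypothesis test downstream, so it
    must predict positive variance at ddCT = 0; fits that collapse to zero
    there (the zero-offset power law with a positive exponent) are
    compared but never selected.
    """
    converged = [f for f in fits if f.converged and f.predict(0.0) > 0]
    if not converged:
        raise ValueError(
            "no converged fit predicts positive variance at the null"
        )

    def cv_ok(fit: ErrorModel) -> bool:
        for name in fit.free_params:
            est = getattr(fit, name)
            se = fit.se.get(name, float("nan"))
            if not np.isfinite(se):
                return False
            if est == 0:
                if se > 0:
                    return False
            elif se / abs(est) > cv_max:
                return False
        return True

    precise = [f for f in converged if cv_ok(f)]
    if precise:
        return min(precise, key=lambda f: (f.wrss, len(f.free_params)))
    fallback = min(converged, key=lambda f: (len(f.free_params), f.wrss))
    return replace(fallback, degraded=True)


def write_report(model: ErrorModel, binned: BinnedVariance, path_json, path_txt=None) -> None:
    """Write the fitted-model report (JSON, optional human-readable text)."""
    payload = {"model": model.to_dict(), "bins": binned.bins.to_dict(orient="records")}
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2)
    if path_txt is not None:
        lines = [
            f"variance model: {model.variant}",
            f"  sigma2(x) = alpha + beta * |x|**gamma",
        ]
        for name in model.free_params:
            lines.append(f"  {name} = {getattr(model, name):.6g} "
                         f"(se {model.se.get(name, float('nan')):.3g})")
        lines.append(f"  WRSS = {model.wrss:.6g} over {model.n_points} bins")
        if model.degraded:
            lines.append("  note: no variant passed the precision screen; "
                         "fell back to the most parsimonious fit")
        with open(path_txt, "w") as fh:
            fh.write("\n".join(lines) + "\n")
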