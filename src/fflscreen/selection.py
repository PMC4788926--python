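"""Two-stage significance selection for knockdown screens.

Stage one filters out, within each silencing experiment, the cells whose
replicate sample variance exceeds the 95th percentile of the observed
variance distribution (unstable measurements). Stage two tests every
remaining (gene, time point) cell for H0: ddCT = 0: under the null the
replicate-averaged ddCT is taken as N(0, sigma2/K), where sigma2 comes
from the fitted measurement-error model — never from the cell's own sample
variance — and K is the number of biological replicates. Two-sided
p-values are Bonferroni-corrected with m = number of tests actually
performed in that experiment, and calls are made at an adjusted-p cutoff
(default 0.05).

Directions follow the CT convention: a significant positive mean ddCT is a
down-regulation under silencing (the silenced gene activated the target),
a negative one an up-regulation (the silenced gene repressed it).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ModelError
from .error_model import ErrorModel, predict_variance

#: columns of the calls table
CALL_COLUMNS = (
    "perturbation", "gene", "time_h", "phase", "mean_ddct", "var_ddct", "K",
    "fold_change", "filtered", "z", "p", "p_adj", "significant", "direction",
)

MIN_CELLS_FOR_FILTER = 20


class FilterSkippedWarning(UserWarning):
    """Raised when too few variances exist for a meaningful percentile."""


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the value at ascending rank ceil(q/100 * n)."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("empty variance set")
    rank = math.ceil(percentile / 100.0 * n)
    return float(v[rank - 1])


def variance_filter(
    variances, percentile: float = 95.0
) -> tuple[np.ndarray, float, bool]:
    """Flag cells whose variance strictly exceeds the percentile threshold.

    Returns (filtered mask, threshold, skipped). With fewer than
    ``MIN_CELLS_FOR_FILTER`` defined variances the filter is skipped (no
    cell flagged) and a :class:`FilterSkippedWarning` is emitted. NaN
    variances (K < 2 cells) are never flagged. Ties at the threshold are
    retained ("strictly exceeds").
    """
    v = np.asarray(variances, dtype=float)
    defined = v[~np.isnan(v)]
    if len(defined) < MIN_CELLS_FOR_FILTER:
        warnings.warn(
            f"only {len(defined)} defined variances (< {MIN_CELLS_FOR_FILTER}); "
            "variance filter skipped",
            FilterSkippedWarning,
            stacklevel=2,
        )
        return np.zeros(v.shape, dtype=bool), float("nan"), True
    threshold = nearest_rank_percentile(defined, percentile)
    mask = np.zeros(v.shape, dtype=bool)
    ok = ~np.isnan(v)
    mask[ok] = v[ok] > threshold
    return mask, threshold, False


def test_modulation(mean_ddct, model: ErrorModel, K):
    """z-test of H0: ddCT = 0 with model-predicted variance.

    z = mean_ddct / sqrt(sigma2 / K); p is the two-sided standard-normal
    tail 2 * (1 - Phi(|z|)). Accepts scalars or arrays.
    """
    mean = np.asarray(mean_ddct, dtype=float)
    k = np.asarray(K, dtype=float)
    if np.any(k < 1):
        raise ValueError("K must be >= 1")
    sigma2 = np.asarray(predict_variance(model, mean), dtype=float)
    if np.any(sigma2 <= 0):
        raise ModelError("model predicts non-positive variance")
    z = mean / np.sqrt(sigma2 / k)
    p = 2.0 * norm.sf(np.abs(z))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


test_modulation.__test__ = False  # keep pytest from collecting the operation


def bonferroni_adjust(pvals, m: int):
    """Bonferroni correction p_adj = min(1, m * p) for m tests."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


@dataclass
class SelectionResult:
    """Calls for every tested cell plus per-experiment bookkeeping."""

    calls: pd.DataFrame  # CALL_COLUMNS, one row per tested or filtered cell
    experiments: dict  # perturbation -> {m, threshold, n_filtered, filter_skipped}
    knockdown: pd.DataFrame  # the silenced genes' own cells (efficiency check)
    alpha_level: float
    percentile: float
    m_policy: str

    def significant(self) -> pd.DataFrame:
        return self.calls[self.calls["significant"]].reset_index(drop=True)

    def write_calls(self, path) -> None:
        self.calls.to_csv(path, index=False)

    def write_summary(self, path) -> None:
        payload = {
            "alpha_level": self.alpha_level,
            "percentile": self.percentile,
            "m_policy": self.m_policy,
            "experiments": self.experiments,
            "knockdown_efficiency": self.knockdown.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def run_selection(
    ddct,
    model: ErrorModel,
    alpha_level: float = 0.05,
    percentile: float = 95.0,
    include_time0: bool = False,
    m_policy: str = "post_filter",
) -> SelectionResult:
    """Run the full two-stage procedure per silencing experiment.

    The silenced gene's own cells trivially reflect the knockdown itself;
    they are excluded from target calls and reported separately as a
    knockdown-efficiency diagnostic. Time 0 h (pre-stimulus) is excluded
    from testing unless ``include_time0``. ``m_policy`` chooses whether the
    Bonferroni m counts tests actually performed after filtering
    ("post_filter", default) or all candidate cells ("pre_filter").
    """
    if m_policy not in ("post_filter", "pre_filter"):
        raise ValueError(f"unknown m_policy {m_policy!r}")
    summary = ddct.summary
    if not include_time0:
        summary = summary[summary["time_h"] > 0]

    kd_rows = summary[summary["gene"] == summary["perturbation"]].copy()
    targets = summary[summary["gene"] != summary["perturbation"]]

    call_frames = []
    experiments = {}
    for pert, cells in targets.groupby("perturbation", sort=False):
        cells = cells.copy()
        mask, threshold, skipped = variance_filter(
            cells["var_ddct"].to_numpy(), percentile
        )
        cells["filtered"] = mask
        m = int(len(cells)) if m_policy == "pre_filter" else int((~mask).sum())
        tested = cells[~mask]
        z = np.full(len(cells), np.nan)
        p = np.full(len(cells), np.nan)
        p_adj = np.full(len(cells), np.nan)
        if len(tested):
            zt, pt = test_modulation(tested["mean_ddct"].to_numpy(), model,
                                     tested["K"].to_numpy())
            z[~mask], p[~mask] = zt, pt
            p_adj[~mask] = bonferroni_adjust(pt, m)
        cells["z"], cells["p"], cells["p_adj"] = z, p, p_adj
        cells["significant"] = ~mask & (p_adj <= alpha_level)
        cells["direction"] = np.where(
            ~cells["significant"], "none",
            np.where(cells["mean_ddct"] > 0, "down", "up"),
        )
        call_frames.append(cells)
        experiments[pert] = {
            "m": m,
            "threshold": threshold,
            "n_filtered": int(mask.sum()),
            "filter_skipped": skipped,
            "n_significant": int(cells["significant"].sum()),
        }

    calls = (
        pd.concat(call_frames, ignore_index=True)[list(CALL_COLUMNS)]
        if call_frames
        else pd.DataFrame(columns=list(CALL_COLUMNS))
    )
    return SelectionResult(
        calls=calls,
        experiments=experiments,
        knockdown=kd_rows.reset_index(drop=True),
        alpha_level=alpha_level,
        percentile=percentile,
        m_policy=m_policy,
    )


@dataclass
class ModulatorSummary:
    """Strength, sign and timing of one silenced candidate modulator."""

    perturbation: str
    strength: int  # distinct genes with >= 1 significant call
    sign: str  # positive / negative / mixed
    down_fraction: float  # of gene-level directions, NaN when strength = 0
    timing: dict = field(default_factory=dict)  # {"by_time": {...}, "by_phase": {...}}

    def to_dict(self) -> dict:
        return {
            "perturbation": self.perturbation,
            "strength": self.strength,
            "sign": self.sign,
            "down_fraction": self.down_fraction,
            "timing": self.timing,
        }


def _gene_level_direction(calls: pd.DataFrame) -> str:
    """Direction of one gene across its significant calls.

    Only stimulation-phase calls carry an interpretable sign (after the
    stimulus is withdrawn the regulation may have relaxed); the earliest
    significant stimulation time point decides. Wash-out-only genes are
    "unspecified".
    """
    stim = calls[calls["phase"] == "stimulation"]
    if not len(stim):
        return "unspecified"
    return str(stim.sort_values("time_h", kind="stable").iloc[0]["direction"])


def summarize_modulator(calls: pd.DataFrame, perturbation: str) -> ModulatorSummary:
    """Summarise one silencing experiment's significant regulations.

    A modulator is a *positive* regulator when more than half of its
    significantly regulated genes go down upon silencing, *negative* when
    fewer than half do, and *mixed* at exactly half. Genes regulated only
    in the wash-out phase count toward strength and timing but carry no
    sign, so they never count as down-regulations.
    """
    sig = calls[(calls["perturbation"] == perturbation) & calls["significant"]]
    strength = int(sig["gene"].nunique())
    if strength == 0:
        return ModulatorSummary(perturbation, 0, "mixed", float("nan"), {})
    directions = sig.groupby("gene", sort=False).apply(
        _gene_level_direction, include_groups=False
    )
    down_fraction = float((directions == "down").sum() / strength)
    if down_fraction > 0.5:
        sign = "positive"
    elif down_fraction < 0.5:
        sign = "negative"
    else:
        sign = "mixed"
    timing = {
        "by_time": {str(t): int(c) for t, c in sig.groupby("time_h").size().items()},
        "by_phase": {str(ph): int(c) for ph, c in sig.groupby("phase").size().items()},
    }
    return ModulatorSummary(perturbation, strength, sign, down_fraction, timing)
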