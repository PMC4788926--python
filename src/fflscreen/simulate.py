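"""Synthetic knockdown screens with known ground truth.

Emulates a small-scale qRT-PCR perturbation screen: a 96-gene panel with a
few housekeeping genes, knockdown (KD) and calibrator-control conditions,
a short time series spanning a stimulation phase (0, 2, 8 h) and a
wash-out phase (12 h), K biological replicates, and replicate noise drawn
so that the ddCT variance follows the measurement-error model family
sigma2 = alpha + beta * |ddCT| ** gamma.

Planted regulations are expressed as ddCT shifts (cycles) of a target gene
under a given knockdown at given time points: a positive shift raises the
target's CT under KD, i.e. the silenced gene was activating the target.
The generator guarantees that, after comparative-CT processing against the
designated reference gene, the per-cell true mean ddCT equals the planted
shift and the replicate ddCT variance equals the model prediction at that
shift.

Noise placement: the four CT terms entering ddCT cannot carry equal noise
shares because the reference (housekeeping) terms must stay near-noiseless,
so the gene-CT noise variance is v(0)/2 in control samples and
v(shift) - v(0)/2 in KD samples, which sums to the target v(shift) exactly
for any monotone variant of the model family.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .error_model import ErrorModel
from .qpcr import CONTROL, CtTable, PhaseSchedule, SampleMeta
from . import selection as _selection


@dataclass(frozen=True)
class PlantedEffect:
    """One planted regulation: silencing ``source`` shifts ``target``'s ddCT."""

    source: str
    target: str
    shift: float  # cycles; > 0 = down-regulation under silencing (activation)
    times_h: tuple = (2.0, 8.0)


@dataclass(frozen=True)
class ScreenConfig:
    """Study-design parameters of one synthetic screen.

    Defaults mirror the emulated screen: 96 genes of which 3 are
    housekeeping candidates, two silenced candidate modulators, samples at
    0/2/8/12 h (wash-out after 8 h), two biological replicates, and
    constant ddCT replicate variance 0.3975 cycles^2.
    """

    n_genes: int = 96
    n_housekeeping: int = 3
    perturbed: tuple = ("G01", "G02")
    time_points_h: tuple = (0.0, 2.0, 8.0, 12.0)
    washout_after_h: float = 8.0
    K: int = 2
    noise: ErrorModel = field(
        default_factory=lambda: ErrorModel("constant", alpha=0.3975, beta=0.0, gamma=0.0)
    )
    effects: tuple = ()
    kd_self_shift: float = 4.0  # the knockdown's effect on its own transcript
    baseline_ct_range: tuple = (18.0, 30.0)
    housekeeping_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2 or self.n_housekeeping < 1 or self.K < 1:
            raise ConfigError("counts must be positive (and n_genes >= 2)")
        if self.n_housekeeping >= self.n_genes:
            raise ConfigError("housekeeping genes must leave room for targets")
        genes = set(self.gene_panel())
        if not set(self.perturbed) <= genes:
            raise ConfigError("perturbed genes must belong to the panel")
        if set(self.perturbed) & set(self.housekeeping_genes()):
            raise ConfigError("housekeeping genes cannot be perturbed")
        for e in self.effects:
            if e.source not in self.perturbed:
                raise ConfigError(f"effect source {e.source!r} is not perturbed")
            if e.target not in genes:
                raise ConfigError(f"effect target {e.target!r} not in panel")
            if e.target in self.housekeeping_genes():
                raise ConfigError("housekeeping genes cannot receive effects")

    def gene_panel(self) -> list[str]:
        n_targets = self.n_genes - self.n_housekeeping
        width = len(str(n_targets))
        genes = [f"G{i + 1:0{width}d}" for i in range(n_targets)]
        genes += self.housekeeping_genes()
        return genes

    def housekeeping_genes(self) -> list[str]:
        return [f"HK{i + 1}" for i in range(self.n_housekeeping)]

    @property
    def reference_gene(self) -> str:
        return self.housekeeping_genes()[0]

    def schedule(self) -> PhaseSchedule:
        return PhaseSchedule(self.washout_after_h)

    def shift_of(self, perturbation: str, gene: str, time_h: float) -> float:
        total = 0.0
        if gene == perturbation:
            total += self.kd_self_shift
        for e in self.effects:
            if e.source == perturbation and e.target == gene and time_h in e.times_h:
                total += e.shift
        return total

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["noise"] = {
            "variant": self.noise.variant, "alpha": self.noise.alpha,
            "beta": self.noise.beta, "gamma": self.noise.gamma,
        }
        payload["effects"] = [dataclasses.asdict(e) for e in self.effects]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        noise = payload.pop("noise", None)
        effects = payload.pop("effects", [])
        kwargs = dict(payload)
        for key in ("perturbed", "time_points_h", "baseline_ct_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if noise is not None:
            kwargs["noise"] = ErrorModel(
                noise["variant"], alpha=noise["alpha"],
                beta=noise.get("beta", 0.0), gamma=noise.get("gamma", 0.0),
            )
        kwargs["effects"] = tuple(
            PlantedEffect(e["source"], e["target"], e["shift"],
                          tuple(e.get("times_h", (2.0, 8.0))))
            for e in effects
        )
        return cls(**kwargs)


def plant_ffl(
    config: ScreenConfig,
    x: str,
    y: str,
    targets: list[str],
    signs: dict | None = None,
    shift: float = 3.0,
    times_h: tuple = (2.0, 8.0),
) -> ScreenConfig:
    """Add effects so the noiseless pipeline recovers one multi-output FFL.

    ``signs`` maps edges (source, target) to "activation" (positive ddCT
    shift: silencing lowers the target) or "repression" (negative shift);
    unlisted edges default to activation. X and Y must be perturbed genes;
    targets must not be perturbed.
    """
    if x not in config.perturbed or y not in config.perturbed:
        raise ConfigError("FFL regulators must be perturbed genes")
    overlap = set(targets) & set(config.perturbed)
    if overlap:
        raise ConfigError(f"targets overlap the perturbed set: {sorted(overlap)}")
    signs = signs or {}

    def signed(source, target):
        return shift if signs.get((source, target), "activation") == "activation" else -shift

    effects = list(config.effects)
    effects.append(PlantedEffect(x, y, signed(x, y), times_h))
    for z in targets:
        effects.append(PlantedEffect(x, z, signed(x, z), times_h))
        effects.append(PlantedEffect(y, z, signed(y, z), times_h))
    return dataclasses.replace(config, effects=tuple(effects))


@dataclass
class GroundTruth:
    """What the generator planted, plus the modules those effects imply."""

    true_effects: tuple
    true_modules: list  # dicts: {p1, p2, targets, edges {(s, t): (sign, phase)}}

    def write_json(self, path) -> None:
        payload = {
            "effects": [dataclasses.asdict(e) for e in self.true_effects],
            "modules": [
                {
                    "p1": m["p1"], "p2": m["p2"], "targets": m["targets"],
                    "edges": [
                        {"source": s, "target": t, "sign": sg, "phase": ph}
                        for (s, t), (sg, ph) in m["edges"].items()
                    ],
                }
                for m in self.true_modules
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _true_modules(config: ScreenConfig) -> list:
    """Enumerate the modules implied by the planted effects (noiseless truth).

    Tests validate the analysis pipeline against a separate exhaustive
    oracle; this enumerator only defines the generator's ground truth.
    """
    schedule = config.schedule()

    def regulation(source, target):
        # (sign, phase) per the stimulation-precedence rule, or None
        hits = sorted(
            (t, config.shift_of(source, target, t))
            for e in config.effects
            if e.source == source and e.target == target
            for t in e.times_h
            if config.shift_of(source, target, t) != 0 and t > 0
        )
        if not hits:
            return None
        stim = [(t, s) for t, s in hits if schedule.phase_of(t) == "stimulation"]
        if stim:
            t, s = stim[0]
            return ("activation" if s > 0 else "repression", "stimulation")
        return ("unspecified", "washout")

    genes = config.gene_panel()
    modules = []
    for p1 in config.perturbed:
        for p2 in config.perturbed:
            if p1 == p2 or regulation(p1, p2) is None:
                continue
            targets = [
                z for z in genes
                if z not in (p1, p2)
                and regulation(p1, z) is not None
                and regulation(p2, z) is not None
            ]
            if not targets:
                continue
            edges = {(p1, p2): regulation(p1, p2)}
            for z in targets:
                edges[(p1, z)] = regulation(p1, z)
                edges[(p2, z)] = regulation(p2, z)
            modules.append({"p1": p1, "p2": p2, "targets": targets, "edges": edges})
    return modules


def generate_screen(config: ScreenConfig) -> tuple[CtTable, GroundTruth]:
    """Simulate one screen: a validated CT table plus its ground truth.

    Reproducible: identical configs (including seed) yield identical
    tables. Control and KD samples are emitted for every time point and
    replicate; the reference housekeeping gene is noiseless so ddCT noise
    comes entirely from the gene terms.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_panel()
    hk = set(config.housekeeping_genes())
    schedule = config.schedule()
    lo, hi = config.baseline_ct_range
    baseline = pd.Series(rng.uniform(lo, hi, size=len(genes)), index=genes)

    v0 = float(config.noise.predict(0.0))
    is_hk = np.array([g in hk for g in genes])
    gene_index = {g: i for i, g in enumerate(genes)}
    conditions = [CONTROL, *config.perturbed]
    samples, columns = [], {}
    for cond in conditions:
        for t in config.time_points_h:
            shifts = np.zeros(len(genes))
            if cond != CONTROL:
                shifts[gene_index[cond]] = config.kd_self_shift
                for e in config.effects:
                    if e.source == cond and t in e.times_h:
                        shifts[gene_index[e.target]] += e.shift
            if cond == CONTROL:
                var = np.full(len(genes), v0 / 2.0)
            else:
                var = np.asarray(config.noise.predict(shifts), dtype=float) - v0 / 2.0
                if var.min() < -1e-12:
                    raise ConfigError(
                        "noise model must be non-decreasing in |ddCT| "
                        "for the variance decomposition to be valid"
                    )
            var[is_hk] = config.housekeeping_noise_sd**2
            sd = np.sqrt(np.clip(var, 0.0, None))
            for r in range(1, config.K + 1):
                sid = f"{cond}_t{t:g}_r{r}"
                samples.append(SampleMeta(sid, cond, t, schedule.phase_of(t), r))
                col = baseline.to_numpy() + shifts + rng.normal(size=len(genes)) * sd
                columns[sid] = col
    values = pd.DataFrame(columns, index=genes).clip(lower=0.0, upper=40.0)
    values.index.name = "gene"
    ct = CtTable(
        values=values,
        samples=samples,
        housekeeping_candidates=sorted(hk),
        schedule=schedule,
    )
    truth = GroundTruth(true_effects=tuple(config.effects),
                        true_modules=_true_modules(config))
    return ct, truth


def simulate_null_fwer(
    model: ErrorModel,
    n_screens: int = 1000,
    n_genes: int = 96,
    n_timepoints: int = 3,
    K: int = 2,
    alpha_level: float = 0.05,
    percentile: float = 95.0,
    seed: int = 0,
) -> dict:
    """Family-wise error rate of the selection procedure under the global null.

    Each simulated screen draws K replicate ddCT values per (gene, time
    point) cell from N(0, sigma2) with sigma2 = model variance at 0, then
    runs the actual two-stage procedure (variance filter, model-based
    z-test, per-screen Bonferroni). Returns the fraction of screens with at
    least one significant call and its Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(float(model.predict(0.0)))
    n_cells = n_genes * n_timepoints
    hits = 0
    for _ in range(n_screens):
        reps = rng.normal(0.0, sigma, size=(n_cells, K))
        means = reps.mean(axis=1)
        variances = reps.var(axis=1, ddof=1)
        mask, _, _ = _selection.variance_filter(variances, percentile)
        m = int((~mask).sum())
        if m == 0:
            continue
        _, p = _selection.test_modulation(means[~mask], model, K)
        p_adj = _selection.bonferroni_adjust(p, m)
        if np.any(p_adj <= alpha_level):
            hits += 1
    fwer = hits / n_screens
    mc_se = float(np.sqrt(max(fwer * (1 - fwer), 1e-12) / n_screens))
    return {"fwer": fwer, "n_screens": n_screens, "mc_se": mc_se,
            "alpha_level": alpha_level}
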