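"""Comparative cycle-threshold (CT) processing for perturbation screens.

A screen measures a panel of genes on qRT-PCR array cards under siRNA
knockdown (KD) of candidate modulators and under a non-targeting calibrator
siRNA (control), over a short time series spanning a stimulation phase and a
wash-out phase. This module reads and validates the raw CT tables, selects
the most stable housekeeping gene as the normalisation reference, and
computes relative expression by the comparative-CT method:

    dCT  = CT_gene - CT_reference            (within one sample)
    ddCT = dCT_knockdown - dCT_control       (matched control sample)
    fold change = 2 ** (-mean ddCT)

Positive ddCT means lower expression under knockdown (down-regulation);
higher CT always means fewer transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    InsufficientDataError,
    NormalizationError,
    PairingError,
    RangeError,
    SchemaError,
)

CONTROL = "CONTROL"

#: canonical long-dialect column names
LONG_COLUMNS = ("sample_id", "perturbation", "time_h", "phase", "replicate", "gene", "ct")

MISSING_TOKENS = {"", "na", "nan", "undetermined", "undet", "missing", "null"}


@dataclass(frozen=True)
class PhaseSchedule:
    """Maps sampling time to experiment phase.

    The default mirrors a double-stimulation design: the agent is added at
    0 h and removed at ``washout_after_h``; samples taken strictly after the
    removal time belong to the wash-out phase.
    """

    washout_after_h: float = 8.0

    def phase_of(self, time_h: float) -> str:
        return "washout" if time_h > self.washout_after_h else "stimulation"


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample (one card column)."""

    sample_id: str
    perturbation: str  # silenced gene, or CONTROL for the calibrator siRNA
    time_h: float
    phase: str
    replicate: int

    def __post_init__(self):
        if self.time_h < 0:
            raise ValueError(f"negative time for sample {self.sample_id!r}")
        if self.phase not in ("stimulation", "washout"):
            raise ValueError(f"unknown phase {self.phase!r} for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1 for sample {self.sample_id!r}")


@dataclass
class CtTable:
    """Validated raw CT measurements: genes x samples, NaN marks MISSING."""

    values: pd.DataFrame  # index = genes, columns = sample_id, float with NaN
    samples: list[SampleMeta]
    housekeeping_candidates: list[str] = field(default_factory=list)
    ct_max: float = 40.0
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)

    def __post_init__(self):
        self.validate()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta(self, sample_id: str) -> SampleMeta:
        return self._meta_index[sample_id]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "perturbation": [s.perturbation for s in self.samples],
                "time_h": [s.time_h for s in self.samples],
                "phase": [s.phase for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def validate(self) -> None:
        if list(self.values.columns) != self.sample_ids:
            raise SchemaError("CT matrix columns do not match sample metadata")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DuplicateRecordError(f"duplicate gene rows: {dupes}")
        vals = self.values.to_numpy(dtype=float)
        bad = np.where(~np.isnan(vals) & ((vals < 0) | (vals > self.ct_max)))
        if bad[0].size:
            g = self.values.index[bad[0][0]]
            s = self.values.columns[bad[1][0]]
            raise RangeError(
                f"CT {vals[bad[0][0], bad[1][0]]} outside [0, {self.ct_max}] "
                f"at gene {g!r}, sample {s!r}"
            )
        missing_hk = set(self.housekeeping_candidates) - set(self.genes)
        if missing_hk:
            raise SchemaError(f"housekeeping candidates not in gene panel: {sorted(missing_hk)}")
        seen: dict[tuple, set[int]] = {}
        for s in self.samples:
            expected = self.schedule.phase_of(s.time_h)
            if s.phase != expected:
                raise SchemaError(
                    f"sample {s.sample_id!r}: phase {s.phase!r} inconsistent with "
                    f"time {s.time_h} h (schedule says {expected!r})"
                )
            key = (s.perturbation, s.time_h)
            reps = seen.setdefault(key, set())
            if s.replicate in reps:
                raise DuplicateRecordError(
                    f"duplicate replicate {s.replicate} in stratum {key}"
                )
            reps.add(s.replicate)
        self._meta_index = {s.sample_id: s for s in self.samples}


@dataclass(frozen=True)
class FormatConfig:
    """Table-dialect description for :func:`read_ct_table`.

    ``dialect`` is ``"long"`` (one row per gene x sample) or ``"wide"``
    (genes x samples matrix plus a separate metadata table). Column names
    can be remapped via ``columns``; values matching ``missing_tokens``
    (case-insensitive) become MISSING.
    """

    dialect: str = "long"
    sep: str | None = None  # None: infer from extension (.tsv -> tab)
    columns: dict[str, str] = field(default_factory=dict)
    missing_tokens: frozenset = frozenset(MISSING_TOKENS)
    ct_max: float = 40.0
    washout_after_h: float = 8.0
    metadata_path: str | None = None  # wide dialect only
    housekeeping: tuple[str, ...] = ()


def _sep_for(path: str, cfg: FormatConfig) -> str:
    if cfg.sep is not None:
        return cfg.sep
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _parse_ct(value, tokens) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    text = str(value).strip()
    if text.lower() in tokens:
        return math.nan
    try:
        return float(text)
    except ValueError:
        return math.nan


def _samples_from_meta(meta: pd.DataFrame, schedule: PhaseSchedule) -> list[SampleMeta]:
    samples = []
    for row in meta.itertuples(index=False):
        time_h = float(row.time_h)
        phase = getattr(row, "phase", None)
        if phase is None or (isinstance(phase, float) and math.isnan(phase)):
            phase = schedule.phase_of(time_h)
        samples.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                perturbation=str(row.perturbation),
                time_h=time_h,
                phase=str(phase),
                replicate=int(row.replicate),
            )
        )
    return samples


def read_ct_table(path, format_config: FormatConfig | None = None) -> CtTable:
    """Read a CT table in the long or wide dialect and validate it.

    Non-numeric CT entries (e.g. the instrument's "Undetermined") become
    MISSING cells; structural problems raise :class:`SchemaError`,
    :class:`DuplicateRecordError` or :class:`RangeError`.
    """
    cfg = format_config or FormatConfig()
    schedule = PhaseSchedule(cfg.washout_after_h)
    sep = _sep_for(path, cfg)
    if cfg.dialect == "long":
        raw = pd.read_csv(path, sep=sep, dtype=str)
        colmap = {cfg.columns.get(c, c): c for c in LONG_COLUMNS}
        missing = [src for src in colmap if src not in raw.columns]
        # phase may be derived from time; everything else is mandatory
        missing = [c for c in missing if colmap[c] != "phase"]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        df = raw.rename(columns={src: dst for src, dst in colmap.items() if src in raw.columns})
        dup = df.duplicated(subset=["gene", "sample_id"])
        if dup.any():
            first = df.loc[dup, ["gene", "sample_id"]].iloc[0]
            raise DuplicateRecordError(
                f"duplicate record for gene {first['gene']!r}, sample {first['sample_id']!r}"
            )
        df["ct"] = [_parse_ct(v, cfg.missing_tokens) for v in df["ct"]]
        meta = df.drop_duplicates("sample_id")[
            [c for c in ("sample_id", "perturbation", "time_h", "phase", "replicate") if c in df.columns]
        ]
        samples = _samples_from_meta(meta, schedule)
        genes = list(dict.fromkeys(df["gene"]))
        values = (
            df.pivot(index="gene", columns="sample_id", values="ct")
            .reindex(index=genes, columns=[s.sample_id for s in samples])
        )
        values.columns.name = None
        values.index.name = "gene"
    elif cfg.dialect == "wide":
        if cfg.metadata_path is None:
            raise SchemaError("wide dialect requires format_config.metadata_path")
        matrix = pd.read_csv(path, sep=sep, dtype=str)
        gene_col = cfg.columns.get("gene", "gene")
        if gene_col not in matrix.columns:
            raise SchemaError(f"missing mandatory column(s): ['{gene_col}']")
        matrix = matrix.set_index(gene_col)
        if matrix.index.has_duplicates:
            raise DuplicateRecordError("duplicate gene rows in wide matrix")
        meta = pd.read_csv(cfg.metadata_path, sep=_sep_for(cfg.metadata_path, cfg), dtype=str)
        needed = [c for c in ("sample_id", "perturbation", "time_h", "replicate") if c not in meta.columns]
        if needed:
            raise SchemaError(f"missing mandatory column(s): {needed}")
        samples = _samples_from_meta(meta, schedule)
        values = matrix.map(lambda v: _parse_ct(v, cfg.missing_tokens))
        values = values.reindex(columns=[s.sample_id for s in samples])
        values.index.name = "gene"
    else:
        raise SchemaError(f"unknown dialect {cfg.dialect!r}")
    return CtTable(
        values=values.astype(float),
        samples=samples,
        housekeeping_candidates=list(cfg.housekeeping),
        ct_max=cfg.ct_max,
        schedule=schedule,
    )


def write_ct_table(ct: CtTable, path) -> None:
    """Write the canonical long-dialect CSV (round-trips non-MISSING cells)."""
    rows = []
    for s in ct.samples:
        col = ct.values[s.sample_id]
        for gene, value in col.items():
            rows.append(
                (s.sample_id, s.perturbation, repr(s.time_h), s.phase, s.replicate, gene,
                 "" if math.isnan(value) else repr(value))
            )
    out = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    out.to_csv(path, index=False)


def select_reference_gene(
    ct: CtTable, candidates: list[str] | None = None
) -> tuple[str, pd.Series]:
    """Pick the most stable housekeeping candidate as normalisation reference.

    Stability is the pooled standard deviation of raw CT across all samples
    (every condition, time point and replicate together); the candidate with
    the smallest SD wins, ties broken by candidate-list order. Returns the
    winner and the full score table for reporting.
    """
    if candidates is None:
        candidates = ct.housekeeping_candidates
    if not candidates:
        raise ValueError("empty candidate list")
    unknown = [c for c in candidates if c not in ct.genes]
    if unknown:
        raise ValueError(f"candidates not in gene panel: {unknown}")
    scores = {}
    for cand in candidates:
        obs = ct.values.loc[cand].dropna()
        if len(obs) < 2:
            raise InsufficientDataError(
                f"candidate {cand!r} has {len(obs)} observation(s); need >= 2"
            )
        scores[cand] = float(obs.std(ddof=1))
    table = pd.Series(scores, name="ct_sd")
    best = min(candidates, key=lambda c: scores[c])  # min is stable: first wins ties
    return best, table


@dataclass
class DdctTable:
    """Per-replicate ddCT values plus per-cell summaries.

    ``cells`` has one row per (perturbation, gene, time_h, replicate) with
    the paired ddCT (NaN where a required CT was MISSING). ``summary`` has
    one row per (perturbation, gene, time_h) with the replicate mean,
    sample variance (K-1 denominator, NaN when K < 2), the replicate count
    K actually used, and the fold change 2**(-mean_ddct). Cells whose every
    replicate was MISSING (K = 0) are dropped and counted in ``n_dropped``.
    """

    cells: pd.DataFrame
    summary: pd.DataFrame
    reference: str
    control_label: str = CONTROL
    pairing: str = "paired"
    n_dropped: int = 0

    def write_summary(self, path) -> None:
        cols = ["perturbation", "gene", "time_h", "phase",
                "mean_ddct", "var_ddct", "K", "fold_change"]
        self.summary[cols].to_csv(path, index=False)


def compute_ddct(
    ct: CtTable,
    reference: str,
    control_label: str = CONTROL,
    pairing: str = "paired",
) -> DdctTable:
    """Comparative-CT quantification against the calibrator condition.

    ``pairing="paired"`` subtracts the control dCT of the same
    (time point, replicate index); ``pairing="mean_control"`` subtracts the
    control-stratum mean dCT at that time point. A MISSING CT in any
    required term propagates to a MISSING replicate ddCT and reduces K.
    """
    if reference not in ct.genes:
        raise ValueError(f"reference gene {reference!r} not in panel")
    if pairing not in ("paired", "mean_control"):
        raise ValueError(f"unknown pairing policy {pairing!r}")

    ref_ct = ct.values.loc[reference]
    has_data = ct.values.notna().any(axis=0)
    ref_missing = ref_ct.isna() & has_data
    if ref_missing.any():
        raise NormalizationError(
            f"reference gene {reference!r} is MISSING in sample(s) "
            f"{list(ct.values.columns[ref_missing])} that carry other data"
        )

    dct = ct.values.sub(ref_ct, axis=1)  # genes x samples
    meta = ct.meta_frame()
    control_meta = meta[meta["perturbation"] == control_label]
    pert_meta = meta[meta["perturbation"] != control_label]
    if pert_meta.empty:
        raise PairingError("no perturbed samples in table")

    # control dCT lookup per (time_h, replicate) and per-time mean
    ctrl_by_tr = {
        (row.time_h, row.replicate): dct[row.sample_id]
        for row in control_meta.itertuples(index=False)
    }
    ctrl_mean_by_t = {
        t: pd.concat(
            [dct[r.sample_id] for r in control_meta.itertuples(index=False) if r.time_h == t],
            axis=1,
        ).mean(axis=1)
        for t in control_meta["time_h"].unique()
    }

    frames = []
    for row in pert_meta.itertuples(index=False):
        if pairing == "paired":
            ctrl = ctrl_by_tr.get((row.time_h, row.replicate))
            if ctrl is None:
                raise PairingError(
                    f"no control sample for time {row.time_h} h, replicate {row.replicate}"
                )
        else:
            ctrl = ctrl_mean_by_t.get(row.time_h)
            if ctrl is None:
                raise PairingError(f"no control samples at time {row.time_h} h")
        ddct = dct[row.sample_id] - ctrl
        frames.append(
            pd.DataFrame(
                {
                    "perturbation": row.perturbation,
                    "gene": ddct.index,
                    "time_h": row.time_h,
                    "phase": row.phase,
                    "replicate": row.replicate,
                    "ddct": ddct.to_numpy(),
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)

    grouped = cells.groupby(["perturbation", "gene", "time_h", "phase"], sort=False)["ddct"]
    summary = grouped.agg(
        mean_ddct="mean", var_ddct=lambda v: v.var(ddof=1), K="count"
    ).reset_index()
    n_dropped = int((summary["K"] == 0).sum())
    summary = summary[summary["K"] >= 1].copy()
    summary.loc[summary["K"] < 2, "var_ddct"] = np.nan
    summary["fold_change"] = 2.0 ** (-summary["mean_ddct"])
    summary = summary[
        ["perturbation", "gene", "time_h", "phase", "mean_ddct", "var_ddct", "K", "fold_change"]
    ].reset_index(drop=True)

    return DdctTable(
        cells=cells,
        summary=summary,
        reference=reference,
        control_label=control_label,
        pairing=pairing,
        n_dropped=n_dropped,
    )


def with_schedule(ct: CtTable, washout_after_h: float) -> CtTable:
    """Return a copy of the table under a different phase schedule."""
    schedule = PhaseSchedule(washout_after_h)
    samples = [replace(s, phase=schedule.phase_of(s.time_h)) for s in ct.samples]
    return CtTable(
        values=ct.values.copy(),
        samples=samples,
        housekeeping_candidates=list(ct.housekeeping_candidates),
        ct_max=ct.ct_max,
        schedule=schedule,
    )
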