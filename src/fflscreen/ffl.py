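"""Signed multi-output feed-forward-loop (FFL) module inference.

An FFL is a closed unidirectional three-node motif: an upstream regulator X
controls a downstream regulator Y and both control a common target Z. When
two silenced candidate modulators P1 and P2 regulate one another and share
several significant targets, the component FFLs merge into a single
multi-output module: P1, P2 and their common targets.

Edges inherit sign and phase from the significance calls that back them. A
significant down-regulation under silencing means the silenced gene was
activating its target; up-regulation means repression. When a target is
regulated both during stimulation and wash-out, only the stimulation-phase
regulation is annotated; wash-out-only edges carry an unspecified sign
(transcription may have relaxed by then, so the direction is not
interpreted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import InconsistentCallError


@dataclass(frozen=True)
class RegulationEdge:
    """One signed, phase-annotated regulation between two genes."""

    source: str
    target: str
    sign: str  # activation / repression / unspecified
    phase: str  # stimulation / washout
    evidence: tuple = ()  # significance-call records (dicts) backing the edge
    conflict: bool = False  # stimulation-phase calls disagreed in direction

    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


def annotate_phase(evidence: pd.DataFrame) -> tuple[str, str, bool]:
    """Derive (phase, sign, conflict) for an edge from its significant calls.

    Stimulation-phase evidence takes precedence over wash-out evidence; the
    earliest significant stimulation time point fixes the sign, and a
    direction disagreement across stimulation time points is flagged as a
    conflict. Wash-out-only edges have unspecified sign.
    """
    sig = evidence[evidence["significant"]]
    if sig.empty:
        raise ValueError("no significant call backing the edge")
    stim = sig[sig["phase"] == "stimulation"].sort_values("time_h", kind="stable")
    if len(stim):
        direction = str(stim.iloc[0]["direction"])
        sign = "activation" if direction == "down" else "repression"
        conflict = stim["direction"].nunique() > 1
        return "stimulation", sign, conflict
    return "washout", "unspecified", False


def _edge(calls: pd.DataFrame, source: str, target: str) -> RegulationEdge:
    evidence = calls[
        (calls["perturbation"] == source) & (calls["gene"] == target) & calls["significant"]
    ]
    if evidence.empty:
        raise InconsistentCallError(
            f"no significant regulation of {target!r} by {source!r}"
        )
    phase, sign, conflict = annotate_phase(evidence)
    return RegulationEdge(
        source=source,
        target=target,
        sign=sign,
        phase=phase,
        evidence=tuple(evidence.to_dict(orient="records")),
        conflict=conflict,
    )


def find_regulating_pairs(
    calls: pd.DataFrame, perturbed: list[str]
) -> list[tuple[str, str]]:
    """Ordered pairs (P1, P2) where silencing P1 significantly regulates P2.

    P1 takes the upstream role. Mutual regulation emits both orientations.
    Pair order follows the ``perturbed`` list for reproducibility.
    """
    sig = calls[calls["significant"]]
    pairs = []
    for p1 in perturbed:
        for p2 in perturbed:
            if p1 == p2:
                continue
            hit = sig[(sig["perturbation"] == p1) & (sig["gene"] == p2)]
            if len(hit):
                pairs.append((p1, p2))
    return pairs


def common_targets(
    calls: pd.DataFrame, p1: str, p2: str, gene_order: list[str] | None = None
) -> list[str]:
    """Genes significantly regulated by both silenced modulators.

    The two modulators themselves are excluded; the result follows the gene
    panel order (or first-appearance order in the calls table).
    """
    sig = calls[calls["significant"]]
    l1 = set(sig[sig["perturbation"] == p1]["gene"])
    l2 = set(sig[sig["perturbation"] == p2]["gene"])
    shared = (l1 & l2) - {p1, p2}
    if gene_order is None:
        gene_order = list(dict.fromkeys(calls["gene"]))
    return [g for g in gene_order if g in shared]


@dataclass(frozen=True)
class FflTriple:
    """One component FFL: X regulates Y, and both regulate Z."""

    x: str
    y: str
    z: str
    edges: tuple  # (X->Y, X->Z, Y->Z) RegulationEdges


def build_ffl(calls: pd.DataFrame, x: str, y: str, z: str) -> FflTriple:
    """Reconstruct a single FFL from the calls; every leg must be significant."""
    return FflTriple(x=x, y=y, z=z, edges=(
        _edge(calls, x, y), _edge(calls, x, z), _edge(calls, y, z),
    ))


@dataclass
class FflModule:
    """A merged multi-output FFL: two regulators and their common targets."""

    p1: str  # upstream regulator X
    p2: str  # downstream regulator Y
    orientation: str  # "p1->p2" (or "p2->p1" for the mirrored module)
    common_targets: list[str]
    ffls: list[FflTriple]
    merged_edges: list[RegulationEdge] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return [self.p1, self.p2, *self.common_targets]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(p1=self.p1, p2=self.p2)
        for node in self.nodes:
            g.add_node(node, role="regulator" if node in (self.p1, self.p2) else "target")
        for e in self.merged_edges:
            attrs = {"sign": e.sign, "phase": e.phase, "conflict": e.conflict}
            best = min(
                (c for c in e.evidence), default=None,
                key=lambda c: (c.get("p_adj", 1.0)),
            )
            if best is not None:
                attrs["p_adj"] = float(best.get("p_adj", float("nan")))
                attrs["fold_change"] = float(best.get("fold_change", float("nan")))
            g.add_edge(e.source, e.target, **attrs)
        return g

    def to_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "orientation": self.orientation,
            "common_targets": list(self.common_targets),
            "n_ffls": len(self.ffls),
            "edges": [
                {
                    "source": e.source, "target": e.target, "sign": e.sign,
                    "phase": e.phase, "conflict": e.conflict,
                    "evidence": [
                        {k: c.get(k) for k in
                         ("time_h", "phase", "mean_ddct", "fold_change", "p_adj", "direction")}
                        for c in e.evidence
                    ],
                }
                for e in self.merged_edges
            ],
        }


def merge_ffls(ffls: list[FflTriple]) -> FflModule:
    """Merge component FFLs sharing the same (X, Y) into one module."""
    if not ffls:
        raise ValueError("cannot merge an empty FFL list")
    pairs = {(f.x, f.y) for f in ffls}
    if len(pairs) > 1:
        raise ValueError(f"FFLs span multiple regulator pairs: {sorted(pairs)}")
    x, y = next(iter(pairs))
    targets = list(dict.fromkeys(f.z for f in ffls))
    edges: dict[tuple[str, str], RegulationEdge] = {}
    for f in ffls:
        for e in f.edges:
            edges.setdefault(e.key(), e)
    module = FflModule(
        p1=x, p2=y, orientation="p1->p2",
        common_targets=targets, ffls=list(ffls),
        merged_edges=list(edges.values()),
    )
    assert len(module.merged_edges) == 1 + 2 * len(targets)
    return module


def infer_modules(
    calls: pd.DataFrame,
    perturbed: list[str],
    gene_order: list[str] | None = None,
) -> list[FflModule]:
    """Full inference: pairs -> common targets -> FFLs -> merged modules.

    Pairs with no common target yield no module (they appear in
    :func:`inference_report` instead). Deterministic: module order follows
    the perturbed-gene list, target order the gene panel.
    """
    modules = []
    for p1, p2 in find_regulating_pairs(calls, perturbed):
        targets = common_targets(calls, p1, p2, gene_order)
        if not targets:
            continue
        ffls = [build_ffl(calls, p1, p2, z) for z in targets]
        modules.append(merge_ffls(ffls))
    return modules


def inference_report(
    calls: pd.DataFrame,
    perturbed: list[str],
    gene_order: list[str] | None = None,
) -> dict:
    """Modules plus the bare regulating pairs that had no shared target."""
    pairs = find_regulating_pairs(calls, perturbed)
    modules = infer_modules(calls, perturbed, gene_order)
    with_targets = {(m.p1, m.p2) for m in modules}
    return {
        "pairs": [{"p1": a, "p2": b} for a, b in pairs],
        "bare_pairs": [{"p1": a, "p2": b} for a, b in pairs if (a, b) not in with_targets],
        "modules": [m.to_dict() for m in modules],
    }


# ---------------------------------------------------------------------------
# exports

_SIF_RELATION = {"activation": "activates", "repression": "represses",
                 "unspecified": "regulates"}


def write_sif(module: FflModule, path) -> None:
    """Simple-interaction-format export: source <TAB> relation <TAB> target."""
    lines = [
        f"{e.source}\t{_SIF_RELATION[e.sign]}\t{e.target}"
        for e in sorted(module.merged_edges, key=lambda e: e.key())
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_graphml(module: FflModule, path) -> None:
    nx.write_graphml(module.to_networkx(), path)


_DOT_ARROW = {"activation": "normal", "repression": "tee", "unspecified": "dot"}


def write_dot(module: FflModule, path) -> None:
    """Graphviz export: solid = stimulation phase, dashed = wash-out."""
    lines = ["digraph ffl_module {"]
    for node in module.nodes:
        shape = "box" if node in (module.p1, module.p2) else "ellipse"
        lines.append(f'  "{node}" [shape={shape}];')
    for e in sorted(module.merged_edges, key=lambda e: e.key()):
        style = "solid" if e.phase == "stimulation" else "dashed"
        lines.append(
            f'  "{e.source}" -> "{e.target}" '
            f'[style={style}, arrowhead={_DOT_ARROW[e.sign]}];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_module_report(modules: list[FflModule], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in modules], fh, indent=2, default=float)
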