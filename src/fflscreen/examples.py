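"""Worked example: an interferon-alpha knockdown screen of STAT1 and IFIH1.

A fully synthetic significance-call table for a screen in which two
candidate modulators of the IFN-alpha transcriptional response, the
transcription factor STAT1 and the RNA helicase IFIH1, were silenced in
endothelial cells sampled at 2 h and 8 h of stimulation and 12 h
(wash-out). The table is *constructed*, not measured: it encodes a
plausible call pattern with 21 genes significantly regulated by STAT1
silencing (17 down-regulated in the early stimulation phase, 4
up-regulated at 8 h) and 12 by IFIH1 silencing (8 down: 3 early and
5 late; SAMD9 affected only in the wash-out phase), such that the two
experiments share the six targets IDO1, DDX60, FAM46A, CXCL10, SAMD9 and
IFNAR1 and both modulators repress IFNAR1. Running the inference step on
it yields one six-output feed-forward-loop module with 8 nodes.

Numeric columns (mean ddCT, p-values) are invented placeholders with the
right signs and magnitudes; only the significance pattern matters here.
"""

from __future__ import annotations

import pandas as pd

from .qpcr import PhaseSchedule
from .selection import CALL_COLUMNS

PERTURBED = ["STAT1", "IFIH1"]

#: six targets shared by the two silencing experiments, in panel order
COMMON_TARGETS = ["IDO1", "DDX60", "FAM46A", "CXCL10", "SAMD9", "IFNAR1"]

# STAT1 silencing: 17 genes down at 2 h (early stimulation), 4 up at 8 h
_STAT1_DOWN_2H = [
    "IFIH1", "IDO1", "DDX60", "FAM46A", "CXCL10",
    "MX1", "OAS1", "IFIT1", "IFIT3", "ISG15", "IRF7",
    "IFI6", "IFI44", "RSAD2", "BST2", "USP18", "IFITM1",
]
_STAT1_UP_8H = ["IFNA1", "ZC3HAV1", "SAMD9", "IFNAR1"]

# IFIH1 silencing: 8 down (3 early, 5 late), 3 up at 8 h, SAMD9 wash-out only
_IFIH1_DOWN_2H = ["IDO1", "DDX60", "CXCL10"]
_IFIH1_DOWN_8H = ["FAM46A", "OASL", "HERC5", "SOCS1", "PARP9"]
_IFIH1_UP_8H = ["IFNAR1", "XAF1", "STAT2"]
_IFIH1_WASHOUT_12H = ["SAMD9"]


def gene_panel() -> list[str]:
    """Deterministic panel order for the example (regulators first)."""
    seen: dict[str, None] = {}
    for name in (
        PERTURBED
        + COMMON_TARGETS
        + _STAT1_DOWN_2H
        + _STAT1_UP_8H
        + _IFIH1_DOWN_8H
        + _IFIH1_UP_8H
    ):
        seen.setdefault(name)
    return list(seen)


def _call(perturbation, gene, time_h, mean_ddct, significant=True):
    schedule = PhaseSchedule(8.0)
    direction = "none"
    if significant:
        direction = "down" if mean_ddct > 0 else "up"
    return {
        "perturbation": perturbation,
        "gene": gene,
        "time_h": float(time_h),
        "phase": schedule.phase_of(time_h),
        "mean_ddct": float(mean_ddct),
        "var_ddct": 0.35,
        "K": 2,
        "fold_change": 2.0 ** (-mean_ddct),
        "filtered": False,
        "z": 0.0,
        "p": 1e-4 if significant else 0.5,
        "p_adj": 0.01 if significant else 1.0,
        "significant": bool(significant),
        "direction": direction,
    }


def example_calls() -> pd.DataFrame:
    """Significance-call table of the worked IFN-alpha example."""
    rows = []
    for i, gene in enumerate(_STAT1_DOWN_2H):
        rows.append(_call("STAT1", gene, 2.0, 1.5 + 0.1 * i))
    for i, gene in enumerate(_STAT1_UP_8H):
        rows.append(_call("STAT1", gene, 8.0, -(1.0 + 0.1 * i)))
    # FAM46A is regulated in both phases; the stimulation call must win
    rows.append(_call("STAT1", "FAM46A", 12.0, 1.2))
    for i, gene in enumerate(_IFIH1_DOWN_2H):
        rows.append(_call("IFIH1", gene, 2.0, 1.4 + 0.1 * i))
    for i, gene in enumerate(_IFIH1_DOWN_8H):
        rows.append(_call("IFIH1", gene, 8.0, 1.6 + 0.1 * i))
    for i, gene in enumerate(_IFIH1_UP_8H):
        rows.append(_call("IFIH1", gene, 8.0, -(1.1 + 0.1 * i)))
    for gene in _IFIH1_WASHOUT_12H:
        rows.append(_call("IFIH1", gene, 12.0, 1.3))
    # a few non-significant background cells so the table is not all hits
    rows.append(_call("STAT1", "OASL", 2.0, 0.2, significant=False))
    rows.append(_call("IFIH1", "MX1", 8.0, -0.1, significant=False))
    calls = pd.DataFrame(rows, columns=list(CALL_COLUMNS))
    return calls
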