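"""Report helpers: heatmap-ready matrices and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def make_heatmap_table(calls: pd.DataFrame, perturbation: str | None = None) -> pd.DataFrame:
    """Genes x time-points matrix of fold changes, significant cells only.

    Non-significant cells are blank (NaN). Rows are ordered by increasing
    fold change in the stimulation phase (a gene's smallest significant
    stimulation-phase FC); genes significant only in the wash-out phase
    follow, ordered by their wash-out FC. Fold changes below 1 are
    down-regulations, above 1 up-regulations.
    """
    if perturbation is not None:
        calls = calls[calls["perturbation"] == perturbation]
    sig = calls[calls["significant"]]
    times = sorted(calls["time_h"].unique())
    genes = list(dict.fromkeys(calls["gene"]))
    matrix = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"), columns=times)
    for row in sig.itertuples(index=False):
        matrix.loc[row.gene, row.time_h] = row.fold_change

    stim_fc, washout_fc = {}, {}
    for gene, grp in sig.groupby("gene", sort=False):
        stim = grp[grp["phase"] == "stimulation"]
        if len(stim):
            stim_fc[gene] = float(stim["fold_change"].min())
        else:
            washout_fc[gene] = float(grp["fold_change"].min())

    def sort_key(gene):
        if gene in stim_fc:
            return (0, stim_fc[gene])
        if gene in washout_fc:
            return (1, washout_fc[gene])
        return (2, 0.0)  # never significant: keep panel order at the bottom

    order = sorted(genes, key=lambda g: (*sort_key(g), genes.index(g)))
    return matrix.loc[order]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, settings: dict, artifacts: list[str], path=None) -> dict:
    """Record every artifact with a content hash for provenance."""
    outdir = Path(outdir)
    manifest = {
        "settings": settings,
        "artifacts": {
            name: file_sha256(outdir / name)
            for name in sorted(artifacts)
            if (outdir / name).exists()
        },
    }
    target = Path(path) if path else outdir / "manifest.json"
    with open(target, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
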