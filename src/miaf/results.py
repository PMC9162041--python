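"""Result serialization: JSON hierarchy, TSV summaries, annotated Newick."""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional

import pandas as pd

from . import __version__
from .pipeline import MiAFResult
from .tree_abundance import PhyloTree

__all__ = ["result_to_dict", "write_results"]


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def result_to_dict(result: MiAFResult, config: Optional[dict] = None) -> dict:
    """Serializable hierarchy of component p-values and selections.

    Deterministic for fixed inputs and seed (no timestamps), so a re-run
    with the echoed config reproduces the file byte-identically.
    """
    config = dict(config or {})
    return {
        "version": __version__,
        "B": result.B,
        "seed": result.seed,
        "n_samples": result.n,
        "alpha": result.alpha,
        "measures": list(result.measures),
        "config": config,
        "config_hash": _config_hash(config),
        "p_values": {k: float(v) for k, v in result.p_values.items()},
        "P_MiAF": float(result.p_final),
        "significant": bool(result.significant),
        "minimizer_h": result.h,
        "selected_taxa": result.selected,
        "selection_note": "heuristic taxon selection; exploratory only",
        "removed_taxa": result.removed,
    }


def write_results(
    result: MiAFResult,
    config: dict,
    out_json,
    summary_tsv=None,
    taxa_tsv=None,
    tree: Optional[PhyloTree] = None,
    annotated_tree=None,
) -> None:
    """Write the JSON hierarchy plus TSV summaries.

    Files are written atomically (temp file + rename) so a failure never
    leaves a partial result behind.  ``annotated_tree`` exports the
    phylogeny with upper/lower-tail-selected node labels tagged.
    """
    doc = result_to_dict(result, config)

    def _atomic_write(path, text):
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)

    _atomic_write(out_json, json.dumps(doc, indent=2, sort_keys=True) + "\n")

    if summary_tsv is not None:
        rows = [{"test": k, "p_value": v} for k, v in result.p_values.items()]
        pd.DataFrame(rows).to_csv(summary_tsv, sep="\t", index=False)

    if taxa_tsv is not None:
        rows = []
        for key, taxa in result.selected.items():
            measure, tail = key.split(":")
            for rec in taxa:
                rows.append({
                    "taxon": rec["taxon"], "tail": tail, "measure": measure,
                    "W": rec["W"], "rank": rec["rank"],
                })
        cols = ["taxon", "tail", "measure", "W", "rank"]
        pd.DataFrame(rows, columns=cols).to_csv(taxa_tsv, sep="\t", index=False)

    if annotated_tree is not None:
        if tree is None:
            raise ValueError("annotated Newick export needs the tree")
        tags: dict = {}
        for key, taxa in result.selected.items():
            tag = "_selU" if key.endswith("upper") else "_selL"
            for rec in taxa:
                tags.setdefault(rec["taxon"], set()).add(tag)
        suffix = {taxon: "".join(sorted(ts)) for taxon, ts in tags.items()}
        _atomic_write(annotated_tree, tree.to_newick(label_suffix=suffix) + "\n")
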