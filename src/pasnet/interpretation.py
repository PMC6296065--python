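"""Biological readout of a trained model.

Interpretation rests on two ingredients: group-mean node activations
(how strongly each pathway/hidden/output node responds in each outcome
group) and absolute masked weights (how strongly a gene feeds its
pathway, or a pathway the hidden layer).  Raw node values between the
pathway and output layers lie in (0, 1); output-node values are
additionally reported as −log2 for display, which spreads the scale for
probabilities near zero.  Group-mean values summarize the model's
response, not biological activation per se.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkState, forward

__all__ = [
    "NodeValueSummary",
    "RankedPathways",
    "node_values",
    "rank_pathways",
    "rank_genes",
    "export_heatmaps",
]

_LOG_EPS = 1e-12


@dataclass
class NodeValueSummary:
    """Per-group mean node activations at each layer.

    Each frame is groups × nodes; ``output_neglog2`` is −log2 of the
    output group means.
    """

    pathway: pd.DataFrame
    hidden: pd.DataFrame
    output: pd.DataFrame
    output_neglog2: pd.DataFrame


@dataclass
class RankedPathways:
    """Pathways ordered by importance (non-increasing scores)."""

    table: pd.DataFrame  # columns: pathway, score

    def top(self, k: int) -> list[str]:
        return self.table["pathway"].head(k).tolist()


def node_values(state: NetworkState, X, group_labels) -> NodeValueSummary:
    """Group-mean activations of every node (dropout-free forward pass)."""
    groups = pd.Series(list(group_labels))
    if groups.empty:
        raise ValueError("group_labels is empty")
    trace = forward(np.asarray(X, dtype=float), state)
    _, h1, h2, post = trace.layer_outputs
    p_names = state.pathway_names or list(range(state.n_pathways))

    def by_group(values, columns):
        df = pd.DataFrame(values, columns=columns)
        df["__g"] = groups.to_numpy()
        return df.groupby("__g").mean().rename_axis("group")

    pw = by_group(h1, p_names)
    hid = by_group(h2, list(range(state.hidden_size)))
    out = by_group(post, list(range(state.n_classes)))
    neglog = -np.log2(np.clip(out, _LOG_EPS, None))
    return NodeValueSummary(pw, hid, out, neglog)


def rank_pathways(state: NetworkState, aggregate: str = "sum") -> RankedPathways:
    """Rank pathways by absolute masked pathway→hidden weight.

    A pathway's score aggregates |W(1) ⋆ M(1)| over all hidden nodes it
    feeds (``sum`` by default, ``max`` as alternative); only unmasked
    connections contribute.  Ties break by pathway name so the order is
    deterministic.
    """
    absW = np.abs(state.weights[1] * state.masks[1])
    if aggregate == "sum":
        scores = absW.sum(axis=0)
    elif aggregate == "max":
        scores = absW.max(axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    names = state.pathway_names or [str(i) for i in range(state.n_pathways)]
    table = (
        pd.DataFrame({"pathway": names, "score": scores})
        .sort_values(["score", "pathway"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return RankedPathways(table)


def rank_genes(state: NetworkState, pathway_name: str, top_k: int | None = None) -> pd.DataFrame:
    """Genes of one pathway ordered by absolute gene→pathway weight.

    Only the pathway's member genes can appear: the biadjacency mask
    zeroes every other weight.  Returns a frame with gene and weight
    columns, at most ``top_k`` rows.
    """
    names = state.pathway_names
    if pathway_name not in names:
        raise KeyError(f"pathway {pathway_name!r} not in the model")
    i = names.index(pathway_name)
    row = state.weights[0][i] * state.masks[0][i]
    member = np.flatnonzero(state.masks[0][i] > 0)
    order = member[np.argsort(-np.abs(row[member]), kind="stable")]
    genes = [state.gene_names[j] for j in order]
    out = pd.DataFrame({"gene": genes, "weight": row[order]})
    return out if top_k is None else out.head(top_k)


def export_heatmaps(
    state: NetworkState, X, group_labels, out_dir: str | PathLike
) -> list[Path]:
    """Write heatmap-ready matrices as TSV files.

    Exports, with row/column labels: per-sample output node values
    (rows sorted by group), hidden→output weights, per-sample hidden
    node values, pathway→hidden absolute weights, and gene→pathway
    weights.  Masked entries are exact zeros; weights keep their sign
    (split positive/negative when plotting), except the pathway→hidden
    export which is absolute.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(list(group_labels))
    order = np.argsort(groups, kind="stable")
    trace = forward(X, state)
    _, h1, h2, post = trace.layer_outputs
    p_names = state.pathway_names or [str(i) for i in range(state.n_pathways)]
    sample_ids = [f"sample_{i}" for i in range(len(X))]
    srt = [sample_ids[i] for i in order]

    frames = {
        "output_node_values.tsv": pd.DataFrame(
            post[order], index=pd.Index(srt, name="sample"),
            columns=[f"class_{k}" for k in range(state.n_classes)],
        ).assign(group=groups[order]),
        "hidden_output_weights.tsv": pd.DataFrame(
            state.weights[2] * state.masks[2],
            index=[f"class_{k}" for k in range(state.n_classes)],
            columns=[f"hidden_{j}" for j in range(state.hidden_size)],
        ),
        "hidden_node_values.tsv": pd.DataFrame(
            h2[order], index=pd.Index(srt, name="sample"),
            columns=[f"hidden_{j}" for j in range(state.hidden_size)],
        ),
        "pathway_hidden_weights.tsv": pd.DataFrame(
            np.abs(state.weights[1] * state.masks[1]),
            index=pd.Index([f"hidden_{j}" for j in range(state.hidden_size)],
                           name="hidden"),
            columns=p_names,
        ),
        "gene_pathway_weights.tsv": pd.DataFrame(
            state.weights[0] * state.masks[0],
            index=pd.Index(p_names, name="pathway"),
            columns=state.gene_names or None,
        ),
    }
    written = []
    for name, df in frames.items():
        path = out_dir / name
        df.to_csv(path, sep="\t", float_format="%.10g")
        written.append(path)
    return written
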