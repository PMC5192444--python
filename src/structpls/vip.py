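"""Variable Importance in Projection (VIP) scores and block summaries.

For a fitted PLS2 model, each Y column k gets its own VIP vector over the p
predictors (the standard Wold/Chong-Jun definition):

    VIP_jk = sqrt( p * sum_a SS_ak (w_ja / ||w_a||)^2 / sum_a SS_ak ),
    SS_ak = q_ak^2 * (t_a . t_a)

where SS_ak is the Y-variance of column k explained by component a.  By
construction the mean of VIP^2 over the p variables equals 1 for every
column, so VIP > 1 marks above-average contributors.

With a structured Y, the per-column scores are summarised per factor block by
taking, for each variable, the maximum VIP over the block's columns; a
single-column ordinal block's summary is that column itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coding import CodingScheme
from .pls import PLSModel

__all__ = ["vip_scores", "summarize_vip_by_block", "top_k_variables", "vip_table"]


def vip_scores(model: PLSModel) -> np.ndarray:
    """Per-column VIP matrix, shape (p, q)."""
    if model.n_components < 1:
        raise ValueError("VIP needs a model with at least one component")
    W = model.weights  # (p, A), columns unit norm
    Q = model.y_loadings  # (q, A)
    T = model.scores  # (n, A)
    p = W.shape[0]
    # ss[a, k]: variance of Y column k captured by component a
    tt = np.einsum("na,na->a", T, T)
    ss = (Q.T**2) * tt[:, None]  # (A, q)
    denom = ss.sum(axis=0)  # (q,)
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(
            f"model explains zero variance for Y column(s) {bad.tolist()}; "
            "VIP undefined there"
        )
    wsq = W**2  # ||w_a|| = 1 by construction
    return np.sqrt(p * (wsq @ ss) / denom)


def summarize_vip_by_block(vip: np.ndarray, scheme: CodingScheme) -> np.ndarray:
    """Column-wise max of VIP within each block; shape (p, B)."""
    vip = np.asarray(vip, dtype=float)
    if vip.ndim != 2 or vip.shape[1] != scheme.width:
        raise ValueError(
            f"VIP matrix has {vip.shape[1] if vip.ndim == 2 else '?'} columns, "
            f"scheme width is {scheme.width}"
        )
    out = np.empty((vip.shape[0], len(scheme.blocks)))
    for i, b in enumerate(scheme.blocks):
        lo, hi = scheme.column_range(b.name)
        out[:, i] = vip[:, lo:hi].max(axis=1)
    return out


def top_k_variables(block_vip, block: str, k: int, variable_names=None) -> list:
    """Names of the k highest-VIP variables for one block.

    ``block_vip`` is a DataFrame (columns = block names) or an array paired
    with an ordered block-name list via a dict-like interface.  Ties are
    broken by ascending variable index.
    """
    if isinstance(block_vip, pd.DataFrame):
        if block not in block_vip.columns:
            raise KeyError(
                f"unknown block {block!r}; have {list(block_vip.columns)}"
            )
        values = block_vip[block].to_numpy(dtype=float)
        names = list(block_vip.index)
    else:
        raise TypeError("block_vip must be a DataFrame (see vip_table)")
    p = len(values)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}, got {k}")
    # stable sort on descending value keeps the original order among ties
    order = np.argsort(-values, kind="stable")
    return [names[i] for i in order[:k]]


def vip_table(
    model: PLSModel, scheme: CodingScheme, variable_names=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-column and per-block VIP as labelled DataFrames.

    Column labels for the per-column table are ``block[level]`` for
    categorical blocks and the block name for ordinal blocks.
    """
    vip = vip_scores(model)
    if variable_names is None:
        variable_names = [f"var_{j + 1}" for j in range(vip.shape[0])]
    col_labels = []
    for b in scheme.blocks:
        if b.width == 1:
            col_labels.append(b.name)
        else:
            col_labels.extend(f"{b.name}[{lev}]" for lev in b.levels)
    per_col = pd.DataFrame(vip, index=variable_names, columns=col_labels)
    per_block = pd.DataFrame(
        summarize_vip_by_block(vip, scheme),
        index=variable_names,
        columns=scheme.block_names,
    )
    return per_col, per_block


def plot_block_vip(per_block: pd.DataFrame, path=None):
    """Stem plot of block VIP vs variable index (one panel per block)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    B = per_block.shape[1]
    fig, axes = plt.subplots(B, 1, figsize=(8, 2.4 * B), sharex=True)
    if B == 1:
        axes = [axes]
    x = np.arange(1, per_block.shape[0] + 1)
    for ax, name in zip(axes, per_block.columns):
        ax.vlines(x, 0, per_block[name].to_numpy(), lw=0.8)
        ax.axhline(1.0, color="red", lw=0.8, ls="--")
        ax.set_ylabel(f"VIP ({name})")
    axes[-1].set_xlabel("variable index")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
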