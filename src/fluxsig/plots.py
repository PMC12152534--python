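"""Figure helpers mirroring the standard presentation of the analysis:
PCA scatter of high-producing solutions, subsystem-proportion dot plot,
and the paired-bar amino-acid transport signature chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .signatures import PCAResult

__all__ = ["pca_scatter", "enrichment_dotplot", "signature_bars"]


def pca_scatter(pca: PCAResult, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pca.scores[:, 0], pca.scores[:, 1], s=8, alpha=0.5)
    ax.set_xlabel(f"PC1 ({pca.explained_variance_pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pca.explained_variance_pct[1]:.1f}%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enrichment_dotplot(enrichment: pd.DataFrame, path: str | Path) -> None:
    """Proportion of each subsystem's reactions skewed down (left) / up
    (right) in the high-producing solutions."""
    frame = enrichment.sort_values("subsystem")
    y = np.arange(len(frame))
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(frame), 4) + 1))
    ax.scatter(-frame["prop_down"], y, label="decreased", color="tab:blue")
    ax.scatter(frame["prop_up"], y, label="increased", color="tab:red")
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_yticks(y, frame["subsystem"])
    ax.set_xlabel("proportion of subsystem reactions")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def signature_bars(signature: pd.DataFrame, path: str | Path) -> None:
    """Mean flux per transport reaction: darker bar = high-producing
    selection, paler bar = general pool; imports positive, exports
    negative."""
    frame = signature.sort_values(["amino_acid", "reaction"]).reset_index(drop=True)
    sign = np.where(frame["transport_direction"] == "import", 1.0, -1.0)
    y = np.arange(len(frame))
    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(frame), 3) + 1))
    ax.barh(y + 0.2, sign * frame["mean_flux_high"], height=0.4,
            color="tab:purple", label="high producers")
    ax.barh(y - 0.2, sign * frame["mean_flux_pool"], height=0.4,
            color="thistle", label="general pool")
    ax.axvline(0, color="grey", lw=0.5)
    labels = [f"{r} ({aa})" for r, aa in zip(frame["reaction"], frame["amino_acid"])]
    ax.set_yticks(y, labels)
    ax.set_xlabel("mean flux (mmol/gDW/h); import > 0, export < 0")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
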