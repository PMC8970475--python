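"""Basic fingerprint heat map for visual inspection (not publication-grade)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .stats import CohortMatrix

__all__ = ["cu_heatmap"]


def cu_heatmap(matrix: CohortMatrix, path, cmap: str = "RdYlBu_r") -> None:
    """Render the genes x codons CU matrix to an image file.

    Masked (absent-family) cells plot at 0, the lowest-value color, matching
    how they enter the clustering distances.
    """
    n_rows, n_cols = matrix.values.shape
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.18 * n_cols), max(3.0, 0.25 * n_rows))
    )
    im = ax.imshow(matrix.values, aspect="auto", cmap=cmap, vmin=0.0, vmax=1.0)
    ax.set_xticks(range(n_cols), labels=matrix.col_ids, rotation=90, fontsize=5)
    ax.set_yticks(range(n_rows), labels=matrix.row_ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="CU value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
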