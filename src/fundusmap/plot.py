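"""Manhattan and score-distribution figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from fundusmap.pedigree import _CHROM_LENGTH_MB


def manhattan_plot(manhattan: pd.DataFrame, threshold: float, path: str | Path) -> Path:
    """-log10 best p against genomic position with the Bonferroni line."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(9, 3.5))
    if "chromosome" in manhattan.columns:
        offsets = {}
        run = 0.0
        for c, mb in _CHROM_LENGTH_MB.items():
            offsets[c] = run
            run += mb * 1e6
        xs = [
            offsets.get(str(r.chromosome), 0.0) + r.position_bp
            for r in manhattan.itertuples()
        ]
        colors = [
            "tab:blue" if int(str(r.chromosome)) % 2 else "tab:orange"
            for r in manhattan.itertuples()
        ]
        ax.set_xlabel("genomic position")
    else:
        xs = np.arange(len(manhattan))
        colors = "tab:blue"
        ax.set_xlabel("site index")
    ax.scatter(xs, manhattan["neglog10p"], c=colors, s=14)
    ax.axhline(-np.log10(threshold), color="red", ls="--", lw=1, label="Bonferroni 0.05")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def score_distribution_plot(phenotypes: pd.DataFrame, path: str | Path) -> Path:
    """Histogram of the 0-8 per-mouse fundus-spot scores."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(phenotypes["mouse_score"], bins=np.arange(-0.5, 9.5, 1), rwidth=0.85)
    ax.set_xlabel("per-mouse fundus spot score (0-8)")
    ax.set_ylabel("mice")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
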