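"""Manhattan and QQ plots for association scans."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gwas_scan import ScanResult, Thresholds


def manhattan_plot(scan: ScanResult, thresholds: Thresholds, path: str | Path) -> None:
    """Per-SNP -log10 p by cumulative genome position; every tested SNP drawn."""
    tab = scan.table
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(
        tab.groupby("chrom", sort=False)
    ):
        x = offset + sub["pos"].to_numpy()
        y = -np.log10(np.clip(sub["p"].to_numpy(dtype=float), 1e-300, None))
        ax.scatter(x, y, s=4, color="C0" if i % 2 == 0 else "C1", rasterized=True)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max()
    ax.axhline(-np.log10(thresholds.significant), ls="--", color="red", lw=0.8)
    ax.axhline(-np.log10(thresholds.suggestive), ls=":", color="gray", lw=0.8)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"{scan.engine} / {scan.coding} / {scan.response_label}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq_plot(scan: ScanResult, path: str | Path) -> None:
    """Observed vs expected -log10 p under the uniform null."""
    p = scan.table["p"].dropna().to_numpy(dtype=float)
    p = np.sort(np.clip(p, 1e-300, 1.0))
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(exp, -np.log10(p), s=5)
    lim = max(exp.max(), -np.log10(p[0]))
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
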