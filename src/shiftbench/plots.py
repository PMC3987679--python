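"""Figure generation: cumulative match curves, accuracy plane, heatmaps."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .benchmark import BenchmarkReport, SimilarityMatrix


def plot_cumulative_curves(
    reports: Mapping[str, BenchmarkReport], path: str | Path
) -> None:
    """Overlay the fraction of correct matches within the n best hits per
    predictor, with each predictor's MRR in the legend."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, rep in reports.items():
        n = np.arange(1, len(rep.cumulative) + 1)
        ax.plot(n, rep.cumulative, marker="o", ms=3, label=f"{name} (MRR={rep.mrr:.3f})")
    ax.set_xlabel("n highest-ranking hits")
    ax.set_ylabel("fraction of correct matches")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_accuracy_plane(
    reports: Mapping[str, BenchmarkReport], path: str | Path
) -> None:
    """Scatter of (best-match, correct-match) similarity per query; the
    identity diagonal marks queries whose correct match is the best match."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        best = [o.s_best for o in rep.outcomes]
        correct = [o.s_correct for o in rep.outcomes]
        ax.scatter(best, correct, s=8, alpha=0.5,
                   label=f"{name} (mean rel={rep.mean_relative_accuracy:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("best-match similarity")
    ax.set_ylabel("correct-match similarity")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_similarity_heatmap(m: SimilarityMatrix, path: str | Path) -> None:
    """Heatmap of the experimental x simulated similarity matrix; an accurate
    predictor shows a bright diagonal."""
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(m.values, cmap="gray_r", vmin=0, vmax=1)
    ax.set_xlabel("simulated spectra")
    ax.set_ylabel("experimental spectra")
    fig.colorbar(im, ax=ax, label="similarity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_shift_error_histogram(
    reports: Mapping[str, BenchmarkReport], path: str | Path
) -> None:
    """Cumulative fraction of predicted shifts within each deviation bound."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, rep in reports.items():
        if rep.shift_errors is None:
            continue
        sh = rep.shift_errors
        edges = list(sh.edges[1:]) + [sh.edges[-1] + 0.05]
        ax.plot(edges, sh.cumulative, marker="s", ms=3, label=name)
    ax.set_xlabel("deviation from observed shift (ppm)")
    ax.set_ylabel("fraction of predictions within deviation")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
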