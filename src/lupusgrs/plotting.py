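"""Basic plot exports: risk-score histogram and expression box plot.

matplotlib is an optional dependency (the ``plot`` extra); it is imported
lazily so the analysis modules work without it.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_score_histogram", "plot_expression_groups"]


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - environment guard
        raise ImportError("plotting requires matplotlib (install the 'plot' extra)") from exc
    return plt


def plot_score_histogram(hist: pd.DataFrame, path) -> None:
    """Side-by-side per-arm frequency bars over rounded risk scores."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 4))
    x = hist.index.to_numpy(dtype=float)
    width = 0.4
    ax.bar(x - width / 2, hist["case"], width=width, label="SLE", color="#c0392b")
    ax.bar(x + width / 2, hist["control"], width=width, label="controls", color="#2980b9")
    ax.set_xlabel("rounded weighted genetic risk score")
    ax.set_ylabel("within-arm frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_expression_groups(samples: pd.DataFrame, path, group_by: str = "genotype_class") -> None:
    """Box plot of per-sample relative expression by group."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = list(samples.groupby(group_by)["rel_expr"])
    ax.boxplot([g.to_numpy() for _, g in groups], tick_labels=[str(k) for k, _ in groups])
    ax.set_ylabel("relative expression (2^-ddCt)")
    ax.set_xlabel(group_by)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
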