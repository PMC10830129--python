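"""Plot helpers for fitted results and validation curves."""

from __future__ import annotations

import pandas as pd


def plot_error_rates(curve: pd.DataFrame, fdr_cutoff: float = 0.1, ax=None):
    """FPR/FNR against the FDR threshold (the error-rate curve)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["threshold"], curve["fpr"], color="tab:red", label="FPR")
    ax.plot(curve["threshold"], curve["fnr"], color="tab:orange", label="FNR")
    ax.axvline(fdr_cutoff, ls="--", color="grey")
    ax.set_xlabel("FDR threshold")
    ax.set_ylabel("rate")
    ax.legend()
    return ax


def plot_score_distribution(results, ax=None, bins: int = 50):
    """Histogram of disease scores across all evaluated associations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scores = results.table["score"].dropna()
    ax.hist(scores, bins=bins, color="tab:blue")
    ax.set_xlabel("disease score")
    ax.set_ylabel("associations")
    return ax
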