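"""Forest- and funnel-plot data frames and simple renderings."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .meta import MetaResult


def forest_frame(effects: Sequence, result: MetaResult) -> pd.DataFrame:
    """Per-study rows (label, OR, CI, weight %) plus a summary row.

    Weights are the random-effects weights 1/(se^2 + tau2), normalised to
    percent.
    """
    ys = np.array([e.log_or for e in effects])
    ses = np.array([e.se for e in effects])
    w = 1.0 / (ses**2 + result.tau2)
    w = 100.0 * w / w.sum()
    rows = [
        {
            "label": getattr(e, "study_id", "") or f"study {i + 1}",
            "or": float(np.exp(y)),
            "ci_low": float(np.exp(y - 1.96 * s)),
            "ci_high": float(np.exp(y + 1.96 * s)),
            "weight_percent": float(wi),
            "summary": False,
        }
        for i, (e, y, s, wi) in enumerate(zip(effects, ys, ses, w))
    ]
    rows.append(
        {
            "label": "RE summary",
            "or": result.or_value,
            "ci_low": result.or_ci[0],
            "ci_high": result.or_ci[1],
            "weight_percent": 100.0,
            "summary": True,
        }
    )
    return pd.DataFrame(rows)


def funnel_frame(effects: Sequence) -> pd.DataFrame:
    """Effect-versus-precision coordinates for a funnel plot."""
    return pd.DataFrame(
        {
            "label": [getattr(e, "study_id", "") for e in effects],
            "log_or": [e.log_or for e in effects],
            "se": [e.se for e in effects],
        }
    )


def save_forest_plot(frame: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render a forest_frame to SVG/PNG (by file extension)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(frame)
    fig, ax = plt.subplots(figsize=(6, 0.4 * n + 1.2))
    ypos = np.arange(n)[::-1]
    for y, (_, row) in zip(ypos, frame.iterrows()):
        color = "tab:red" if row["summary"] else "black"
        marker = "D" if row["summary"] else "s"
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], color=color, lw=1.2)
        ax.plot(
            [row["or"]], [y], marker=marker, color=color,
            markersize=4 + 6 * row["weight_percent"] / 100.0,
        )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks(ypos)
    ax.set_yticklabels(frame["label"])
    ax.set_xlabel("odds ratio (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
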