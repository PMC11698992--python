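"""Bar-chart helpers for summaries (the only plotting this package does)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence


def bar_chart(
    values: Mapping[str, float],
    title: str = "",
    ylabel: str = "%",
    out: str | Path | None = None,
):
    """One bar per key; writes a PNG when ``out`` is given, returns the axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    keys = list(values)
    ax.bar(range(len(keys)), [values[k] for k in keys], color="steelblue")
    ax.set_xticks(range(len(keys)), keys, rotation=30, ha="right")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return ax
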