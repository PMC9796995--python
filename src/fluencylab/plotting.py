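"""Chain-diagram plots of per-participant angle sequences."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from fluencylab.semantic import AngleSequence, build_chain

__all__ = ["plot_chain", "save_chain_plot"]


def plot_chain(angles: AngleSequence, ax=None, sign_rule: str = "random",
               seed: Optional[int] = 0, title: str = ""):
    """Draw the unit-segment chain for one angle sequence."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    chain = build_chain(angles, sign_rule=sign_rule, seed=seed)
    xs, ys = chain.vertices[:, 0], chain.vertices[:, 1]
    ax.plot(xs, ys, "-", color="0.3", lw=1.5)
    ax.plot(xs[0], ys[0], "o", color="red", ms=6)    # start
    ax.plot(xs[-1], ys[-1], "o", color="green", ms=6)  # end
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.axis("off")
    return ax


def save_chain_plot(angles: AngleSequence, path: str | Path,
                    sign_rule: str = "random", seed: Optional[int] = 0,
                    title: str = "") -> Path:
    fig, ax = plt.subplots(figsize=(4, 4))
    plot_chain(angles, ax=ax, sign_rule=sign_rule, seed=seed, title=title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
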