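"""Optional rendering of dot plots and identity profiles (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_dotplot(matches: pd.DataFrame, path, title: str = "", triangular: bool = False) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    for strand, color in (("+", "black"), ("-", "red")):
        sel = matches[matches["strand"] == strand]
        ax.plot(sel["i"], sel["j"], ".", ms=1, color=color, rasterized=True)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("position (bp)")
    if title:
        ax.set_title(title)
    if triangular:
        ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_identity_profile(profile: pd.DataFrame, path, pab: int | None = None) -> None:
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(profile["window_start"], profile["identity"], lw=0.8)
    if pab is not None:
        ax.axvline(pab, ls="--", color="red", label="PAB")
        ax.legend()
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("% identity")
    ax.set_ylim(None, 100.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
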