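"""Simple static figures for the three analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_sweep(table: pd.DataFrame, path: str | Path) -> None:
    """Toughness enhancement versus s/2a, one line per pattern orientation."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for orient, g in table[table.orientation != "none"].groupby("orientation"):
        g = g.sort_values("s_over_2a")
        ax.plot(g.s_over_2a, g.enhancement_factor, "o-", label=f"{orient}-nanocracks")
    ax.axhline(1.0, color="0.6", lw=0.8, ls="--")
    ax.set_xlabel("s / 2a")
    ax.set_ylabel("toughness enhancement")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_j_curves(tables: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Fracture energy versus crack extension for each material class."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, df in tables.items():
        ax.plot(df.crack_extension_nm, df.J_J_per_m2, "o-", label=label)
    ax.set_xlabel("crack extension (nm)")
    ax.set_ylabel(r"J (J m$^{-2}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_amplification(table: pd.DataFrame, path: str | Path) -> None:
    """Overall-toughness amplification versus level-0 enhancement factor."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(table.scale, table.amplification, "o-")
    ax.plot(table.scale, table.scale, "--", color="0.6", label="linear")
    ax.set_xlabel("level-0 enhancement factor")
    ax.set_ylabel("overall toughness amplification")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
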