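"""Optional matplotlib renderings of pipeline outputs (PNG files)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_signal_bars(screen_table, path: Path, top: int = 20) -> None:
    """Horizontal log10(ROR) bars for the top drugs of a screen table."""
    df = screen_table.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(df) + 1.5))
    ax.barh(df["entity"], df["log10_ror"],
            color=np.where(df["consensus"], "#c0392b", "#7f8c8d"))
    ax.set_xlabel("log10 ROR")
    ax.axvline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tto_hist(bins_records, path: Path) -> None:
    """Bar chart of onset-time bins."""
    labels = [r["bin"] for r in bins_records]
    counts = [r["count"] for r in bins_records]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, counts, color="#2980b9")
    ax.set_xlabel("days to onset")
    ax.set_ylabel("reports")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_survival(curves, path: Path) -> None:
    """Product-limit curves of onset by drug class."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in curves.items():
        ax.step(df["days"], df["survival"], where="post", label=label)
    ax.set_xlabel("days to onset")
    ax.set_ylabel("fraction without onset")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_weibull_density(days, shape: float, scale: float, path: Path) -> None:
    """Onset histogram with the fitted Weibull density overlaid."""
    from scipy import stats

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(days, bins=30, density=True, alpha=0.5, color="#27ae60")
    x = np.linspace(1, max(days), 300)
    ax.plot(x, stats.weibull_min.pdf(x, shape, scale=scale), "k-",
            label=f"Weibull(k={shape:.2f}, λ={scale:.0f}d)")
    ax.set_xlabel("days to onset")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_all(result, outdir: Path) -> None:
    outdir = Path(outdir)
    for mode, tbl in result.screens.items():
        plot_signal_bars(tbl, outdir / f"signals_{mode}.png")
    tto = result.tto_summary
    if "bins" in tto:
        plot_tto_hist(tto["bins"], outdir / "tto_bins.png")
    wb = tto.get("weibull", {})
    if "shape" in wb:
        days = result.dataset.loc[
            result.dataset["tto_reason"] == "ok", "tto_days"
        ].dropna()
        plot_weibull_density(days, wb["shape"], wb["scale_days"],
                             outdir / "tto_weibull.png")
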