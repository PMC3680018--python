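"""Minimal per-chromosome graphical output: LRR, BAF and detected regions."""

from __future__ import annotations

from pathlib import Path

from .trio_data import Region, TrioDataset

PARENT_COLOR = {"father": "tab:blue", "mother": "tab:red"}


def plot_chromosome(data: TrioDataset, regions: list[Region], chrom: str,
                    out_path, member: str = "child"):
    """Three-panel plot (LRR, BAF, calls) for one chromosome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arms = data.arms_of_chrom(chrom)
    if not arms:
        raise ValueError(f"no arms for chromosome {chrom}")
    lo = min(data.arms[a][0] for a in arms)
    hi = max(data.arms[a][1] for a in arms)
    pos = data.pos[lo:hi] / 1e6

    fig, axes = plt.subplots(3, 1, figsize=(10, 6), sharex=True,
                             height_ratios=[2, 2, 1])
    axes[0].plot(pos, data.lrr(member)[lo:hi], ".", ms=1, color="0.4")
    axes[0].set_ylabel("LRR")
    axes[0].set_ylim(-2.5, 1.5)
    axes[1].plot(pos, data.baf(member)[lo:hi], ".", ms=1, color="0.4")
    axes[1].set_ylabel("BAF")
    axes[1].set_ylim(-0.02, 1.02)
    axes[2].set_ylabel("calls")
    axes[2].set_yticks([])
    axes[2].set_xlabel(f"chr{chrom} position (Mb)")
    for r in regions:
        if r.chrom != chrom:
            continue
        color = PARENT_COLOR.get(r.parent, "black")
        x0, x1 = data.pos[r.start_idx] / 1e6, data.pos[r.end_idx] / 1e6
        axes[2].axvspan(x0, x1, color=color, alpha=0.7)
        axes[2].text((x0 + x1) / 2, 0.5, f"{r.abn_type}:{r.parent_code()}",
                     ha="center", va="center", fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
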