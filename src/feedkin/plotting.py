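"""Optional QC plots (per-trial speed profiles)."""

from __future__ import annotations

from pathlib import Path

from .hand_metrics import SpeedProfile


def plot_speed_profile(sp: SpeedProfile, path: str | Path,
                       title: str = "hand speed") -> Path:
    """Save a PNG of one speed profile for visual QC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(sp.time - sp.time[0], sp.speed, lw=1.2)
    ax.set_xlabel("time in window (s)")
    ax.set_ylabel("speed (m/s)")
    ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
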