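"""Convenience plots (tornado diagram, CEAC).  Never load-bearing."""

from __future__ import annotations

from typing import Sequence

from .sensitivity import CEACPoint, TornadoEntry

__all__ = ["plot_tornado", "plot_ceac"]


def plot_tornado(entries: Sequence[TornadoEntry], base_icer: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)[::-1]  # widest on top
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo = e.icer_low if e.icer_low is not None else base_icer
        hi = e.icer_high if e.icer_high is not None else base_icer
        left, width = min(lo, hi), abs(hi - lo)
        ax.barh(i, width, left=left, color="#4878a8" if not e.flagged else "#c44e52")
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(entries)), [e.name for e in entries])
    ax.set_xlabel("ICER (USD/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(points: Sequence[CEACPoint], wtp_threshold: float, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in points], [p.probability for p in points])
    ax.axvline(wtp_threshold, color="k", ls="--", lw=1, label="WTP threshold")
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
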