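"""Optional rendering layer: hydropathy curves with TMS and domain bars.

Figures are a visual aid for manual review of alignments (criterion 2 of
the decision scheme is ultimately a human call); nothing in the analysis
pipeline depends on them.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core_io import DomainHit, TopologyAnnotation
from .topology import HydropathyProfile


def plot_hydropathy(
    profile: HydropathyProfile,
    topology: TopologyAnnotation | None = None,
    domains: Sequence[DomainHit] = (),
    aligned_span: tuple[int, int] | None = None,
    path: str | None = None,
):
    """Hydropathy curve with TMS bars, domain bars and an alignment wedge."""
    fig, ax = plt.subplots(figsize=(8, 2.5))
    positions = range(1, len(profile.values) + 1)
    ax.plot(positions, profile.values, color="crimson", lw=1.0)
    ax.axhline(0, color="gray", lw=0.5)
    if topology:
        for start, end in topology.tms:
            ax.axvspan(start, end, color="orange", alpha=0.25, lw=0)
    for i, hit in enumerate(domains):
        y = ax.get_ylim()[0] + 0.3 * (i + 1)
        color = "steelblue" if hit.origin == "direct" else "mediumpurple"
        ax.plot([hit.env_start, hit.env_end], [y, y], color=color, lw=3,
                solid_capstyle="butt")
    if aligned_span:
        ax.axvspan(*aligned_span, color="green", alpha=0.10, lw=0)
    ax.set_xlabel("residue")
    ax.set_ylabel(f"hydropathy ({profile.scale}, w={profile.window})")
    ax.set_title(profile.protein, fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
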