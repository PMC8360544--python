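"""Optional figure rendering: cost-effectiveness plane and CEAC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def ce_plane(psa_output, path: Path, title: str = "Cost-effectiveness plane"):
    """Scatter of (pneumonia reduction, incremental cost) PSA draws."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa_output.delta_effect, psa_output.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("Reduction in proportion of pneumonia patients")
    ax.set_ylabel("Incremental cost (2020 intl $)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ceac_curve(points, path: Path, title: str = "Cost-effectiveness acceptability curve"):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in points], [p.probability_cost_effective for p in points])
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay per unit pneumonia reduction ($)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
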