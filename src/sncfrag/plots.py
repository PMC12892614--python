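"""Optional figure helpers (PNG/SVG via matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def cv_auc_histogram(report, path) -> None:
    """Histogram of round-mean AUCs from cross-validation."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for vals, label in ((report.round_auc_uc, "HC vs UC"),
                        (report.round_auc_cd, "HC vs CD")):
        vals = vals[~np.isnan(vals)]
        if len(vals):
            ax.hist(vals, bins=30, alpha=0.6, label=label)
    ax.set_xlabel("round-mean AUC")
    ax.set_ylabel("rounds")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cleavage_profile_plot(profile, path) -> None:
    """Per-group mean coverage with +/- SEM shading along one parent."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(profile.length)
    for g, mean in profile.mean.items():
        sem = profile.sem[g]
        ax.plot(x, mean, label=g)
        ax.fill_between(x, mean - sem, mean + sem, alpha=0.25)
    ax.set_xlabel(f"position along {profile.parent_id} (nt)")
    ax.set_ylabel("mean coverage (RPM)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
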