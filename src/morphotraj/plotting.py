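"""Small plotting helpers: scree plot, morphospace scatter with
trajectory arrows, and consensus wireframe export."""

from __future__ import annotations

import numpy as np
import pandas as pd


def scree_plot(pca_result, ax=None, n: int = 10):
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    m = min(n, pca_result.variance_fractions.size)
    ax.bar(np.arange(1, m + 1), 100 * pca_result.variance_fractions[:m], color="0.4")
    ax.axvline(pca_result.n_significant + 0.5, ls="--", color="firebrick",
               label="broken-stick cutoff")
    ax.set_xlabel("principal component")
    ax.set_ylabel("% variance")
    ax.legend(frameon=False)
    return ax


def trajectory_scatter(pca_result, specimen_ids, trajectories, axes=(0, 1), ax=None):
    """Morphospace scatter with juvenile-to-adult arrows per trajectory."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    i, j = axes
    s = pca_result.scores
    ax.scatter(s[:, i], s[:, j], s=18, color="0.2")
    pos = {sid: idx for idx, sid in enumerate(specimen_ids)}
    for lab in trajectories:
        jid, aid = f"{lab}/juvenile", f"{lab}/adult"
        if jid in pos and aid in pos:
            p0, p1 = s[pos[jid], [i, j]], s[pos[aid], [i, j]]
            ax.annotate("", xy=p1, xytext=p0,
                        arrowprops=dict(arrowstyle="->", color="firebrick"))
            ax.text(*p1, lab, fontsize=8)
    ax.set_xlabel(f"PC{i + 1}")
    ax.set_ylabel(f"PC{j + 1}")
    return ax


def wireframe_csv(path, shape_flat, links=None) -> None:
    """Write a consensus (or any) shape as a wireframe point/segment CSV
    that external plotting tools can consume."""
    xy = np.asarray(shape_flat).reshape(-1, 2)
    df = pd.DataFrame(xy, columns=["x", "y"])
    df.index.name = "landmark"
    df.to_csv(path)
    if links is not None:
        pd.DataFrame(links, columns=["from", "to"]).to_csv(
            str(path) + ".links.csv", index=False)
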