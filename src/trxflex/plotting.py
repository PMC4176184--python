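"""Envelope track plots (observed/min/max/synonymous-mean flexibility)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .protein_space import FlexEnvelope


def plot_envelope(env: FlexEnvelope, path) -> None:
    """Smoothed per-codon flexibility tracks for one gene.

    Observed in red, greedy min/max bounds in green/blue, synonymous-
    randomization mean in black with its 95% CI band; codons whose
    observed score falls outside the CI are ticked along the x axis.
    """
    fig, ax = plt.subplots(figsize=(9, 4))
    x = range(1, env.observed_trx.size + 1)
    lo = env.ci_low_smoothed if env.ci_low_smoothed is not None else env.smoothed("ci_low")
    hi = env.ci_high_smoothed if env.ci_high_smoothed is not None else env.smoothed("ci_high")
    ax.fill_between(x, lo, hi, color="0.8", label="95% CI (synonymous)")
    ax.plot(x, env.smoothed("syn_mean"), "k-", lw=1, label="synonymous mean")
    ax.plot(x, env.smoothed("min_trx"), "g-", lw=1, label="min")
    ax.plot(x, env.smoothed("max_trx"), "b-", lw=1, label="max")
    ax.plot(x, env.smoothed("observed_trx"), "r-", lw=1.2, label="observed")
    flags = (
        env.outside_ci_smoothed
        if env.outside_ci_smoothed is not None
        else env.outside_ci
    )
    flagged = [i + 1 for i, out in enumerate(flags) if out]
    if flagged:
        ax.plot(flagged, [ax.get_ylim()[0]] * len(flagged), "|",
                color="saddlebrown", ms=6, label="outside CI")
    ax.set_xlabel("codon")
    ax.set_ylabel("TRX$_{cdn}$")
    ax.set_title(f"{env.gene_id}  (mean devTRX = {env.gene_mean_dev:.3f})")
    ax.legend(fontsize=8, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
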