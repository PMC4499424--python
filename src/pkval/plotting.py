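"""Concentration–time plotting helpers (matplotlib is imported lazily)."""

from __future__ import annotations


def plot_cohort(profiles, ax=None, semilog: bool = True, show_blq: bool = True):
    """Plot a cohort's concentration–time profiles on a (semi-log) axis.

    BLQ samples are shown as open markers at their recorded value so censoring
    is visible. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for p in profiles:
        usable = p.usable
        ax.plot(p.times[usable], p.concentrations[usable], "o-", label=p.subject_id)
        if show_blq and (~usable).any():
            ax.plot(p.times[~usable], p.concentrations[~usable], "o", mfc="none", color="grey")
    if semilog:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.legend(fontsize="small")
    return ax
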