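"""Quick-look plots for simulated runs and calibration fits."""

from __future__ import annotations

import numpy as np


def plot_run(run, ax=None):
    """Probe channels, true OD and (if present) inline predictions vs time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    t = run.records["time_h"]
    ax.plot(t, run.records["transmission"], lw=0.5, alpha=0.5, label="transmission")
    ax.plot(t, run.records["reflection"], lw=0.5, alpha=0.5, label="reflection")
    ax.plot(t, run.records["do_pct"], lw=0.8, label="DO (%)")
    ax2 = ax.twinx()
    ax2.plot(run.truth["time_h"], run.truth["od600"], "k-", lw=1.5, label="true OD600")
    if run.predictions is not None:
        ax2.plot(t, run.predictions, "r--", lw=1.0, label="inline OD")
    if len(run.offline):
        ax2.plot(run.offline["time_h"], run.offline["od600"], "ko", ms=4,
                 mfc="none", label="offline OD")
    for e in run.events:
        ax.axvline(e.time, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("detector units / % sat")
    ax2.set_ylabel("OD600")
    h1, l1 = ax.get_legend_handles_labels()
    h2, l2 = ax2.get_legend_handles_labels()
    ax.legend(h1 + h2, l1 + l2, fontsize=7, loc="upper left")
    return ax


def plot_calibration(results, ax=None):
    """Predicted vs observed OD for the pooled calibration data."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    data = results.model.data
    pred = results.predict(data)
    obs = data[results.model.target].to_numpy()
    ax.scatter(obs, pred, s=10, alpha=0.6)
    lim = [0, max(float(np.max(obs)), float(np.max(pred))) * 1.05]
    ax.plot(lim, lim, "k--", lw=0.8)
    ax.set_xlabel("offline OD600")
    ax.set_ylabel("inline (predicted) OD600")
    m = results.metrics_test
    ax.set_title(f"test RMSE {m.rmse:.2f}, R$^2$ {m.r2:.4f}", fontsize=9)
    return ax
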