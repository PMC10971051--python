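"""Optional matplotlib renderings of tornado, CE-plane and CEAC results."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_tornado(tornado: pd.DataFrame, out: str | Path) -> Path:
    plt = _axes()
    base = float(tornado.loc[tornado["scenario"] == "base_case", "icer"].iloc[0])
    rows = tornado[tornado["scenario"] != "base_case"].iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(rows) + 1.5))
    ax.barh(rows["scenario"], rows["icer"] - base, left=base, color="#4878a8")
    ax.axvline(base, color="black", lw=1)
    ax.set_xlabel("ICER (AUD per QALY gained)")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_ce_plane(psa: pd.DataFrame, wtp: float, out: str | Path) -> Path:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa["incremental_qalys"], psa["incremental_cost"], s=6, alpha=0.4)
    qmax = float(psa["incremental_qalys"].abs().max()) * 1.05
    ax.plot([-qmax, qmax], [-wtp * qmax, wtp * qmax], "r--", lw=1, label=f"WTP {wtp:,.0f}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (AUD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_ceac(curve: pd.DataFrame, out: str | Path) -> Path:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["probability"], marker="o", ms=3)
    ax.set_xlabel("Willingness to pay (AUD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)
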