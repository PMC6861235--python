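"""Optional figures for a pipeline report bundle (time series, ratios, composites)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_annual_series(annual: "pd.DataFrame", variable: str, region: str, ax=None):
    """Observed vs precipitation-adjusted annual series for one variable/region."""
    if ax is None:
        _, ax = plt.subplots()
    sub = annual[(annual["variable"] == variable) & (annual["region"] == region)]
    for kind, style in (("full", "o-"), ("PA", "s--")):
        s = sub[sub["data"] == kind]
        ax.plot(s["fire_year"], s["value"], style, label=kind)
    ax.set_xlabel("fire year")
    ax.set_ylabel(variable)
    ax.set_title(f"{variable} — {region}")
    ax.legend()
    return ax


def plot_report(bundle: dict, outdir) -> list[Path]:
    """Write one annual-series figure per variable for the first region."""
    outdir = Path(outdir)
    annual = bundle["annual_series"]
    written = []
    region = annual["region"].iloc[0]
    for variable in annual["variable"].unique():
        fig, ax = plt.subplots(figsize=(6, 4))
        plot_annual_series(annual, variable, region, ax=ax)
        path = outdir / f"series_{variable}_{region}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
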