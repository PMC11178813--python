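#!/usr/bin/env python
"""Plot P and v against the adhesion strength (the sweep's summary figure).

Reads results/sweep.tsv (written by 02_adhesion_sweep.py), averages over
seeds, and draws the ordering indicator and mean velocity as functions of
Gamma_R into scratch/fig_sweep.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from chainpotts import sweep_summary

ROOT = Path(__file__).resolve().parent.parent
SWEEP = ROOT / "results" / "sweep.tsv"
OUT = ROOT / "scratch" / "fig_sweep.png"


def main() -> None:
    df = pd.read_csv(SWEEP, sep="\t")
    summary = sweep_summary(df)
    OUT.parent.mkdir(exist_ok=True)

    fig, ax1 = plt.subplots(figsize=(5, 3.2))
    ax1.plot(summary["Gamma_R"], summary["P"], "k-o", label="P")
    ax1.set_xlabel(r"adhesion strength $\Gamma_R$")
    ax1.set_ylabel("ordering indicator $P$")
    ax1.set_ylim(bottom=0)
    ax2 = ax1.twinx()
    ax2.plot(summary["Gamma_R"], summary["v"], "r--s", label="v")
    ax2.set_ylabel("mean velocity $v$ (lattice units / window)", color="r")
    ax2.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(OUT, dpi=150)
    print(summary.to_string(index=False))
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
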