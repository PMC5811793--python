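"""Deterministic figure generation from pipeline CSV outputs.

Line-plot convention: solid lines for fixed-b0 curves, dashed for
fixed-q0, a bold black line for the true (b0 = 0) reference.  SVG output
is made byte-reproducible by pinning the hash salt and stripping the
creation date.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["make_figures"]

_STYLE = {"b0_zero": ("k", "-", 2.5), "fixed_b0": ("C0", "-", 1.5), "fixed_q0": ("C1", "--", 1.5)}


def _savefig(fig, path: Path) -> None:
    plt.rcParams["svg.hashsalt"] = "steamref"
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _plot_curves(df: pd.DataFrame, outdir: Path) -> list[Path]:
    out = []
    for label, sub in df.groupby("label"):
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for key, grp in sub.groupby(["scheme", "b0_fraction"]):
            scheme, frac = key
            color, ls, lw = _STYLE.get(scheme, ("C2", ":", 1.0))
            ax.plot(
                grp["Delta_ms"],
                grp["adc"],
                ls,
                color=color,
                lw=lw,
                alpha=0.4 + 0.6 * float(frac) / max(df["b0_fraction"].max(), 1e-9)
                if scheme != "b0_zero"
                else 1.0,
                label=f"{scheme} b0/b={frac:g}",
            )
        ax.set_xlabel(r"diffusion time $\Delta$ (ms)")
        ax.set_ylabel(r"ADC ($\mu$m$^2$/ms)")
        ax.set_title(str(label))
        ax.legend(fontsize=5, ncol=2)
        fig.tight_layout()
        path = outdir / f"curves_{str(label).replace(' ', '_')}.svg"
        _savefig(fig, path)
        out.append(path)
    return out


def _plot_contours(df: pd.DataFrame, outdir: Path) -> list[Path]:
    piv = df.pivot_table(index="Delta_ms", columns="b", values="diff_pct")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    cs = ax.contourf(piv.columns.values, piv.index.values, piv.values, levels=12)
    fig.colorbar(cs, ax=ax, label="ADC difference (% of true ADC)")
    ax.set_xlabel(r"b (ms$\cdot\mu$m$^{-2}$)")
    ax.set_ylabel(r"$\Delta$ (ms)")
    fig.tight_layout()
    path = outdir / "contours.svg"
    _savefig(fig, path)
    return [path]


def _plot_seqcheck(df: pd.DataFrame, outdir: Path) -> list[Path]:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for variant, grp in df.groupby("variant"):
        ls = "-" if variant == "modified" else "--"
        ax.plot(grp["Delta_ms"], grp["imaging_b"], ls, marker="o", label=variant)
    ax.set_xlabel(r"$\Delta$ (ms)")
    ax.set_ylabel(r"imaging-gradient b (ms$\cdot\mu$m$^{-2}$)")
    ax.legend()
    fig.tight_layout()
    path = outdir / "seqcheck.svg"
    _savefig(fig, path)
    return [path]


def _plot_analysis(df: pd.DataFrame, outdir: Path) -> list[Path]:
    out = []
    for (tissue, metric) in [(t, m) for t in df["tissue"].unique()
                             for m in ("longitudinal", "radial")]:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for scheme, grp in df[df.tissue == tissue].groupby("scheme"):
            color, ls, lw = _STYLE.get(scheme, ("C2", ":", 1.0))
            ax.plot(grp["Delta_ms"], grp[metric], ls, color=color, lw=lw, marker="o",
                    label=scheme)
        ax.set_xlabel(r"$\Delta$ (ms)")
        ax.set_ylabel(f"{metric} diffusivity " + r"($\mu$m$^2$/ms)")
        ax.set_title(f"{tissue} {metric}")
        ax.legend()
        fig.tight_layout()
        path = outdir / f"analysis_{tissue}_{metric}.svg"
        _savefig(fig, path)
        out.append(path)
    return out


def make_figures(results_dir: str | Path, outdir: str | Path | None = None) -> list[Path]:
    """Regenerate all figures found in a results directory.

    Looks for curves.csv, contours.csv, seqcheck.csv and analysis_curves.csv;
    raises FileNotFoundError naming the missing inputs when none is present.
    """
    results_dir = Path(results_dir)
    outdir = Path(outdir) if outdir else results_dir
    outdir.mkdir(parents=True, exist_ok=True)

    known = {
        "curves.csv": _plot_curves,
        "contours.csv": _plot_contours,
        "seqcheck.csv": _plot_seqcheck,
        "analysis_curves.csv": _plot_analysis,
    }
    present = {n: f for n, f in known.items() if (results_dir / n).exists()}
    if not present:
        raise FileNotFoundError(
            "no figure inputs found; expected at least one of: " + ", ".join(known)
        )
    made: list[Path] = []
    for name, plot in present.items():
        df = pd.read_csv(results_dir / name, comment="#")
        made.extend(plot(df, outdir))
    return made
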