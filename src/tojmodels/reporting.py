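"""Run orchestration and human-readable reports.

``run_comparison`` executes the full pipeline for a set of response tables:
fit every requested (table, model, family) cell, write per-fit JSON, the
comparison table, NMI tables, and fitted-vs-observed curve tables, and record
a manifest with seed, configuration hash, and package version.
``render_report`` turns a completed run directory into a single markdown
document with psychometric-function plots.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import ResponseTable, read_response_table
from .fitting import FitConfig, FitResult, fit_model
from .models import response_probs
from .selection import compare_models, nmi_report

__all__ = ["RunConfig", "run_comparison", "render_report"]


@dataclass(frozen=True)
class RunConfig:
    """What to fit and where to put it."""

    inputs: tuple[str, ...]  # paths to response-table TSVs
    models: tuple[str, ...] = ("rem", "tsm", "ttm")
    families: tuple[str, ...] = ("normal",)
    out_dir: str = "toj_run"
    seed: int = 0
    expected_floor: float = 0.1
    verbosity: int = 1

    def fit_config(self) -> FitConfig:
        return FitConfig(expected_floor=self.expected_floor)

    def to_dict(self) -> dict:
        return {
            "inputs": list(self.inputs),
            "models": list(self.models),
            "families": list(self.families),
            "out_dir": self.out_dir,
            "seed": self.seed,
            "expected_floor": self.expected_floor,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config whose YAML keys mirror the RunConfig field names."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("inputs", "models", "families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _curve_table(table: ResponseTable, fits: dict[str, FitResult]) -> pd.DataFrame:
    out = table.to_frame()
    props = table.proportions()
    for resp, col in zip(("xy", "si", "yx"), range(3)):
        out[f"obs_p_{resp}"] = props[:, col]
    for name, fit in fits.items():
        probs = response_probs(fit.params, table.soa_ms)
        for resp, col in zip(("xy", "si", "yx"), range(3)):
            out[f"{name}_p_{resp}"] = probs[:, col]
    return out


def run_comparison(config: RunConfig, tables: list[ResponseTable] | None = None):
    """Fit every requested cell and write all artifacts under ``out_dir``.

    ``tables`` may be passed directly (e.g. simulated); otherwise the TSV
    paths in the config are loaded.  Returns the ComparisonTable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if tables is None:
        for p in config.inputs:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        tables = [read_response_table(p) for p in config.inputs]
    if not tables:
        raise ValueError("no input tables")

    fit_cfg = config.fit_config()
    all_fits: list[FitResult] = []
    failures: list[dict] = []
    nmi_rows: list[dict] = []
    for table in tables:
        per_table: dict[str, FitResult] = {}
        for family in config.families:
            for model in config.models:
                try:
                    fit = fit_model(table, model, family, fit_cfg)
                except RuntimeError as exc:
                    failures.append(
                        {"label": table.label, "model": model,
                         "family": family, "error": str(exc)}
                    )
                    continue
                all_fits.append(fit)
                per_table[f"{model}_{family}"] = fit
                with open(out / f"fit_{table.label}_{model}_{family}.json", "w") as fh:
                    json.dump(fit.to_dict(), fh, indent=2)
        if per_table:
            _curve_table(table, per_table).to_csv(
                out / f"curves_{table.label}.tsv", sep="\t", index=False
            )
            row = {"label": table.label}
            row.update(nmi_report(table, per_table))
            nmi_rows.append(row)

    comparison = compare_models(all_fits)
    comparison.to_tsv(out / "comparison.tsv")
    comparison.to_json(out / "comparison.json")
    pd.DataFrame(nmi_rows).to_csv(out / "nmi.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "n_fits": len(all_fits),
        "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    if failures:
        raise RuntimeError(f"{len(failures)} fit cell(s) failed; see manifest.json")
    return comparison


def render_report(run_dir: str | Path, plot: bool = True) -> Path:
    """Render a completed run directory into ``report.md`` (plus PNG plots).

    A pure function of the artifacts on disk: regenerating from the same
    directory yields the same document.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    comparison = json.loads((run_dir / "comparison.json").read_text())
    nmi_df = pd.read_csv(run_dir / "nmi.tsv", sep="\t")

    lines = [
        "# Model comparison report",
        "",
        f"Package version {manifest['version']}, seed {manifest['seed']}, "
        f"config hash {manifest['config_hash']}.",
        "",
        "## Summed G² and BIC per model",
        "",
        pd.DataFrame(comparison["summary"]).to_markdown(index=False),
        "",
        "## Per-table fits",
        "",
        pd.DataFrame(comparison["rows"]).to_markdown(index=False),
        "",
        "## Non-monotonicity index (observed vs fitted)",
        "",
        nmi_df.to_markdown(index=False),
        "",
        "## Best-fitting parameters",
        "",
    ]
    for fit_file in sorted(run_dir.glob("fit_*.json")):
        fit = json.loads(fit_file.read_text())
        lines.append(
            f"- **{fit['label']} / {fit['model']} / {fit['family']}**: "
            f"G²={fit['g_squared']:.2f}, k={fit['k']}, n={fit['n']}, "
            f"params={json.dumps(fit['params'])}"
        )
    if plot:
        figs = _plot_curves(run_dir)
        if figs:
            lines += ["", "## Psychometric functions", ""]
            lines += [f"![{f.stem}]({f.name})" for f in figs]
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _plot_curves(run_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    for curve_file in sorted(run_dir.glob("curves_*.tsv")):
        df = pd.read_csv(curve_file, sep="\t")
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        d = df["soa_ms"]
        fitted = sorted(
            {c.rsplit("_p_", 1)[0] for c in df.columns if "_p_" in c} - {"obs"}
        )
        for resp, color in zip(("xy", "si", "yx"), ("C0", "C1", "C2")):
            axes[0].plot(d, df[f"obs_p_{resp}"], "o", color=color, label=f"obs R_{resp}")
            for i, name in enumerate(fitted):
                axes[0].plot(d, df[f"{name}_p_{resp}"], ["-", "--", ":"][i % 3],
                             color=color, alpha=0.8)
        axes[0].set(xlabel="d (ms)", ylabel="P(R|d)", title=curve_file.stem)
        axes[0].legend(fontsize=7)
        axes[1].plot(d, df["obs_p_xy"], "o", color="C0", label="P(R_xy|d)")
        axes[1].plot(d, df["obs_p_xy"] + df["obs_p_si"], "s", color="C3",
                     label="1 - P(R_yx|d)")
        for i, name in enumerate(fitted):
            axes[1].plot(d, df[f"{name}_p_xy"], ["-", "--", ":"][i % 3], color="C0")
            axes[1].plot(d, df[f"{name}_p_xy"] + df[f"{name}_p_si"],
                         ["-", "--", ":"][i % 3], color="C3")
        axes[1].set(xlabel="d (ms)", ylabel="P", title="cumulative curves")
        axes[1].legend(fontsize=7)
        fig.tight_layout()
        png = run_dir / f"{curve_file.stem}.png"
        fig.savefig(png, dpi=110)
        plt.close(fig)
        out.append(png)
    return out
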