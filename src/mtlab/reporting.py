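"""Run configuration, tidy outputs, optional figures and run manifests.

All acceptance-grade numbers live in the CSVs; figures are conveniences
and a missing plotting backend only costs a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .registry import METHOD_REGISTRY, STUDY_METHODS
from .replication import ScreenReport
from .simulation import GRID_BETA, GRID_M, GRID_PI0

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated study configuration; defaults are the standard grid at alpha 0.05."""

    alpha: float = 0.05
    seed: int = 0
    reps: int = 100
    methods: tuple[str, ...] = STUDY_METHODS
    ms: tuple[int, ...] = GRID_M
    pi0s: tuple[float, ...] = GRID_PI0
    betas: tuple[float, ...] = GRID_BETA
    out_dir: str = "results"
    figures: bool = False
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a JSON/YAML config; an empty or absent file yields the full defaults."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    unknown = sorted(set(data) - known)
    cfg_kwargs = {}
    errors = []
    for key in known & set(data):
        val = data[key]
        if key in ("methods", "ms", "pi0s", "betas"):
            val = tuple(val)
        cfg_kwargs[key] = val
    if "methods" in cfg_kwargs:
        bad = [m for m in cfg_kwargs["methods"] if m not in METHOD_REGISTRY]
        if bad:
            errors.append(
                f"unknown methods {bad}; valid ids: {sorted(METHOD_REGISTRY)}"
            )
    if "alpha" in cfg_kwargs and not (0 < cfg_kwargs["alpha"] < 1):
        errors.append(f"alpha must lie in (0, 1), got {cfg_kwargs['alpha']}")
    if errors:
        raise ValueError("; ".join(errors))
    cfg = RunConfig(**cfg_kwargs)
    cfg.extra = {k: data[k] for k in unknown}
    if unknown:
        logger.warning("ignoring unknown config keys: %s", unknown)
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, cfg: RunConfig, files: list[Path]) -> Path:
    """Record config, seed, package version and per-file checksums."""
    manifest = {
        "package": "mtlab",
        "version": __version__,
        "config": {**asdict(cfg), "methods": list(cfg.methods), "ms": list(cfg.ms),
                   "pi0s": list(cfg.pi0s), "betas": list(cfg.betas)},
        "files": {f.name: _checksum(f) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def render_simulation(
    summaries: pd.DataFrame,
    pi0_estimates: pd.DataFrame,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    figures: bool = False,
) -> list[Path]:
    """Write the tidy scenario and pi0 CSVs (and optional panels)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    f1 = out / "scenario_summaries.csv"
    summaries.to_csv(f1, index=False)
    files.append(f1)
    f2 = out / "pi0_estimates.csv"
    pi0_estimates.to_csv(f2, index=False)
    files.append(f2)
    if figures:
        files += _simulation_figures(summaries, pi0_estimates, out)
    write_manifest(out, cfg or RunConfig(), files)
    return files


def render_screen(report: ScreenReport, out_dir: str | Path,
                  cfg: RunConfig | None = None, figures: bool = False) -> list[Path]:
    """Write the per-method significance-count report (and optional bar chart)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    files = [out / "screen_report.csv"]
    frame.to_csv(files[0], index=False)
    if figures:
        files += _screen_figure(frame, out)
    write_manifest(out, cfg or RunConfig(), files)
    return files


def _simulation_figures(summaries, pi0_estimates, out: Path) -> list[Path]:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - backend trouble only costs the figure
        logger.warning("matplotlib unavailable; CSVs written, figures skipped")
        return []
    files = []
    for metric in ("power", "specificity"):
        fig, axes = plt.subplots(
            1, len(sorted(summaries["pi0"].unique())), figsize=(14, 4), sharey=True
        )
        for ax, pi0 in zip(
            (axes if hasattr(axes, "__len__") else [axes]),
            sorted(summaries["pi0"].unique()),
        ):
            sub = summaries[(summaries["pi0"] == pi0) & (summaries["beta"] == 2.5)]
            for method, g in sub.groupby("method"):
                ax.plot(g["m"], g[metric], marker="o", label=method)
            ax.set_xscale("log")
            ax.set_title(f"pi0={pi0:g}")
            ax.set_xlabel("m")
        (axes[0] if hasattr(axes, "__len__") else axes).set_ylabel(metric)
        (axes[-1] if hasattr(axes, "__len__") else axes).legend(fontsize=6)
        f = out / f"{metric}_panels.png"
        fig.savefig(f, dpi=120, bbox_inches="tight")
        plt.close(fig)
        files.append(f)
    if len(pi0_estimates):
        fig, ax = plt.subplots(figsize=(8, 4))
        data = [
            g["pi0_hat"].values
            for _, g in pi0_estimates.groupby(["estimator", "m"], sort=True)
        ]
        labels = [
            f"{est}\nm={m}" for (est, m), _ in pi0_estimates.groupby(["estimator", "m"], sort=True)
        ]
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("estimated pi0")
        f = out / "pi0_boxplots.png"
        fig.savefig(f, dpi=120, bbox_inches="tight")
        plt.close(fig)
        files.append(f)
    return files


def _screen_figure(frame: pd.DataFrame, out: Path) -> list[Path]:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover
        logger.warning("matplotlib unavailable; CSVs written, figures skipped")
        return []
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(frame["method"], frame["n_significant"], color="gray")
    ax.set_ylabel("significant features in replication")
    ax.tick_params(axis="x", rotation=45)
    f = out / "screen_counts.png"
    fig.savefig(f, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return [f]
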