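"""Report assembly: provenance blocks and on-disk serialization."""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

from .bias import ComparisonReport
from .io import write_json, write_table

log = logging.getLogger("weartime")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def provenance_block(config: dict, seed: int | None = None) -> dict:
    from . import __version__

    return {
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def write_comparison_report(report: ComparisonReport, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a comparison report as JSON plus three CSV tables.

    ``effects.csv`` (method × estimate), ``retention.csv`` (method × group)
    and ``adaptive_scan.csv`` (threshold rows) are the machine-readable
    analogs of a methods-comparison figure and retention table.
    """
    out = Path(out_dir)
    paths = {
        "json": write_json(report.to_dict(), out / "comparison.json"),
        "effects": write_table(report.effects_frame(), out / "effects.csv"),
        "retention": write_table(report.retention_frame(), out / "retention.csv"),
        "scan": write_table(report.scan_frame(), out / "adaptive_scan.csv"),
    }
    for name, p in paths.items():
        log.info("wrote output=%s path=%s", name, p)
    return paths


def plot_comparison(report: ComparisonReport, out_dir: str | Path) -> list[Path]:
    """Optional static figures: effect-by-method and retention-by-threshold.

    Requires matplotlib (the ``plot`` extra); imported lazily so the core
    pipeline has no plotting dependency.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    effects = report.effects_frame()
    if len(effects):
        fig, ax = plt.subplots(figsize=(6, 4))
        y = range(len(effects))
        ax.errorbar(
            effects["estimate"], y,
            xerr=[effects["estimate"] - effects["ci_low"], effects["ci_high"] - effects["estimate"]],
            fmt="o", capsize=3,
        )
        ax.set_yticks(list(y), effects["method"])
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_xlabel(f"group difference ({effects['sign_convention'].iloc[0]})")
        fig.tight_layout()
        p = out / "effects_by_method.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)

    scan = report.scan_frame()
    pct_cols = [c for c in scan.columns if c.startswith("retained_pct_")]
    if len(scan) and pct_cols:
        fig, ax = plt.subplots(figsize=(6, 4))
        for c in pct_cols:
            ax.plot(scan["threshold"], scan[c], marker="o", label=c.removeprefix("retained_pct_"))
        ax.set_xlabel("minimum wear-hours threshold")
        ax.set_ylabel("% person-days retained")
        ax.legend()
        fig.tight_layout()
        p = out / "retention_by_threshold.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)

    for p in paths:
        log.info("wrote figure path=%s", p)
    return paths


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="ts=%(asctime)s level=%(levelname)s module=%(name)s %(message)s",
        force=True,
    )
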