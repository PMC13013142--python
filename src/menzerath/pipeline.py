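"""Full-analysis orchestration and structured reporting.

``run_full_analysis`` runs, per context table: the duration model with
and without single-call sequences, both Monte-Carlo null models, the
first/last correlations, and the final-lengthening test; then every
pairwise context interaction model.  The report is a plain JSON-able
dict with seed/config provenance; figures are optional renderings of the
report and never a data source.  Identical config and seeds give an
identical report payload.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from importlib.metadata import version as _pkg_version

from .boundary import final_lengthening_test, first_last_correlation
from .data_io import CallTable, read_call_table
from .lmm import LmmSpec, fit_group_interaction, fit_menzerath
from .null_models import production_constraint_null, shuffle_null

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Inputs and settings for one full run.

    ``inputs`` maps context name -> call-table CSV path.  ``null_models``
    selects which chance models to run (subset of {"shuffle",
    "production_constraint"}).
    """

    inputs: dict[str, str]
    include_singles: bool = True
    null_models: tuple[str, ...] = ("shuffle", "production_constraint")
    n_iter: int = 1000
    seed: int = 0
    interactions: bool = True

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("config lists no input tables")
        unknown = set(self.null_models) - {"shuffle", "production_constraint"}
        if unknown:
            raise ValueError(f"unknown null models: {sorted(unknown)}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        missing = [p for p in self.inputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input paths do not exist: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "null_models" in raw:
            raw["null_models"] = tuple(raw["null_models"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "inputs": dict(self.inputs),
            "include_singles": self.include_singles,
            "null_models": list(self.null_models),
            "n_iter": self.n_iter,
            "seed": self.seed,
            "interactions": self.interactions,
        }


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(report_block: dict, name: str, func, *args, **kwargs):
    """Run one stage; on failure mark it and keep going."""
    t0 = time.perf_counter()
    try:
        out = func(*args, **kwargs)
        report_block[name] = out.to_dict() if hasattr(out, "to_dict") else out
        ok = True
    except Exception as exc:  # noqa: BLE001 - independent stages must continue
        logger.exception("stage %s failed", name)
        report_block[name] = {"failed": True, "error": f"{type(exc).__name__}: {exc}"}
        ok = False
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    return ok


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute all stages deterministically and return the report dict.

    The report has one block per context, pairwise interaction blocks,
    and provenance (package version, seeds, config hash).  Failed stages
    are marked ``{"failed": true, ...}`` and independent stages still
    run; ``report["any_failed"]`` summarizes.
    """
    config.validate()
    tables: dict[str, CallTable] = {
        name: read_call_table(path) for name, path in config.inputs.items()
    }
    report: dict = {
        "provenance": {
            "package_version": _pkg_version("menzerath"),
            "seed": config.seed,
            "n_iter": config.n_iter,
            "config_hash": _config_hash(config),
            "config": config.to_dict(),
        },
        "contexts": {},
        "interactions": {},
    }
    all_ok = True
    spec = LmmSpec(include_singles=True)
    spec_nosingles = LmmSpec(include_singles=False)

    for name, table in tables.items():
        block: dict = {}
        all_ok &= _stage(block, "lmm", fit_menzerath, table, spec)
        all_ok &= _stage(block, "lmm_excluding_singles", fit_menzerath, table, spec_nosingles)
        if "shuffle" in config.null_models:
            all_ok &= _stage(block, "shuffle_null", shuffle_null, table,
                             n_iter=config.n_iter, seed=config.seed, spec=spec)
        if "production_constraint" in config.null_models:
            all_ok &= _stage(block, "production_constraint_null", production_constraint_null,
                             table, n_iter=config.n_iter, seed=config.seed, spec=spec)
        all_ok &= _stage(block, "boundary", first_last_correlation, table)
        all_ok &= _stage(block, "final_lengthening", final_lengthening_test, table)
        report["contexts"][name] = block

    if config.interactions:
        names = list(tables)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                key = f"{names[i]}_vs_{names[j]}"
                all_ok &= _stage(report["interactions"], key, fit_group_interaction,
                                 tables[names[i]], tables[names[j]], "group")

    report["any_failed"] = not all_ok
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def render_figures(report: dict, out_dir: str | Path) -> list[Path]:
    """Render violin plots of the null slope distributions per context.

    Purely a view of the report JSON; computes nothing new.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, block in report.get("contexts", {}).items():
        nulls = [
            (label, block[key])
            for label, key in (("shuffle", "shuffle_null"),
                               ("production constraint", "production_constraint_null"))
            if key in block and not block[key].get("failed")
        ]
        if not nulls:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        for ax, slope_key, obs_key, title in (
            (axes[0], "slopes_size", "observed_size", "size slope"),
            (axes[1], "slopes_position", "observed_position", "position slope"),
        ):
            data = [nd[slope_key] for _, nd in nulls]
            ax.violinplot(data, showextrema=False)
            ax.scatter([1] * len(nulls[:1]), [nulls[0][1][obs_key]], color="k", zorder=3)
            ax.axhline(nulls[0][1][obs_key], color="k", lw=0.8, ls="--")
            ax.set_xticks(range(1, len(nulls) + 1), [lbl for lbl, _ in nulls])
            ax.set_title(f"{name}: {title}")
        fig.tight_layout()
        path = out_dir / f"nulls_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
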