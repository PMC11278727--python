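"""End-to-end orchestration: many exposures against one outcome.

Each exposure is analyzed marginally and independently (no multivariable
modelling): select instruments, harmonize against the outcome, estimate.
Exposures with no surviving instruments are reported with status
``no_instruments`` rather than silently dropped, and a failure in one
exposure never aborts the rest of the run.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import instruments as instr
from . import harmonize as harm
from .errors import MicroMRError
from .estimate import MRResult, estimate_exposure
from .sumstats_io import read_ld, read_sumstats, write_results

__all__ = ["RunConfig", "run", "significant_results", "forest_data"]


@dataclass
class RunConfig:
    """All knobs of one analysis run; defaults mirror the reference analysis."""

    exposure_paths: list[str] = field(default_factory=list)
    outcome_path: str = ""
    ld_dir: str = ""
    p_threshold: float = 1e-8
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    min_f: float = 10.0
    maf_threshold: float = 0.01
    ci_level: float = 0.95
    alpha: float = 0.05
    wald_se_order: int = 1
    steiger_effective_n: bool = False
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise MicroMRError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


def run(config: RunConfig) -> tuple[list[MRResult], dict]:
    """Execute the full pipeline; returns (results, run report).

    The report carries per-exposure stage counts (candidates, post-clump,
    post-F, post-harmonization) and the total instrument tallies before and
    after harmonization, so the instrument audit is reproducible. When
    ``config.output_dir`` is set, results and logs are written there.
    """
    outcome = read_sumstats(config.outcome_path, trait_type="binary")
    ld = read_ld(config.ld_dir)

    results: list[MRResult] = []
    report: dict = {"exposures": {}, "config": asdict(config)}
    selection_rows: list[tuple[str, str, str]] = []
    exclusion_rows: list[tuple[str, str, str]] = []
    total_selected = 0
    total_harmonized = 0

    for path in config.exposure_paths:
        exposure = read_sumstats(path, trait_type="quantitative")
        eid = exposure.trait_id
        entry: dict = {"path": path}
        try:
            selected = instr.select_instruments(
                exposure,
                ld,
                p_threshold=config.p_threshold,
                f_min=config.min_f,
                r2_threshold=config.clump_r2,
                window_bp=config.clump_window_bp,
            )
            log = selected.selection_log
            entry["n_candidates"] = sum(
                1 for d in log.values() if d != "dropped_p"
            )
            entry["n_post_clump"] = sum(
                1 for d in log.values() if d in ("kept", "dropped_F")
            )
            entry["n_post_f"] = len(selected)
            for vid, disposition in sorted(log.items()):
                selection_rows.append((eid, vid, disposition))
            if not selected.members:
                entry["status"] = "no_instruments"
                entry["n_harmonized"] = 0
                report["exposures"][eid] = entry
                continue
            total_selected += len(selected)
            harmonized, excluded = harm.harmonize_set(
                selected, outcome, maf_threshold=config.maf_threshold
            )
            entry["n_harmonized"] = len(harmonized)
            for exc in excluded:
                exclusion_rows.append((eid, exc.variant_id, exc.reason))
            if not harmonized:
                entry["status"] = "no_instruments"
                report["exposures"][eid] = entry
                continue
            total_harmonized += len(harmonized)
            result = estimate_exposure(
                harmonized,
                eid,
                se_order=config.wald_se_order,
                ci_level=config.ci_level,
                steiger_effective_n=config.steiger_effective_n,
            )
            results.append(result)
            entry["status"] = "ok"
        except MicroMRError as exc:  # isolate per-exposure failures
            entry["status"] = f"error: {exc}"
        report["exposures"][eid] = entry

    report["total_ivs_selected"] = total_selected
    report["total_ivs_harmonized"] = total_harmonized

    if config.output_dir:
        _emit(config, results, report, selection_rows, exclusion_rows)
    return results, report


def _emit(config, results, report, selection_rows, exclusion_rows) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    if results:
        write_results(results, os.path.join(out, "results.tsv"))
    significant_results(results, config.alpha).to_csv(
        os.path.join(out, "significant.tsv"), sep="\t", index=False
    )
    forest_data(results, config.alpha).to_csv(
        os.path.join(out, "forest.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        selection_rows, columns=["exposure_id", "variant_id", "disposition"]
    ).to_csv(os.path.join(out, "selection_log.tsv"), sep="\t", index=False)
    pd.DataFrame(
        exclusion_rows, columns=["exposure_id", "variant_id", "reason"]
    ).to_csv(os.path.join(out, "exclusion_log.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "run_report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def significant_results(results, alpha: float = 0.05) -> pd.DataFrame:
    """Rows with p < alpha, annotated protective (OR < 1) or risk (OR > 1),
    sorted by OR."""
    rows = []
    for res in results:
        if res.pvalue < alpha:
            rows.append(
                {
                    "exposure_id": res.exposure_id,
                    "method": res.method,
                    "n_iv": res.n_iv,
                    "or": res.or_,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "pvalue": res.pvalue,
                    "class": "protective" if res.or_ < 1 else "risk",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "exposure_id", "method", "n_iv", "or",
            "ci_low", "ci_high", "pvalue", "class",
        ],
    )
    return df.sort_values(["or", "exposure_id"], kind="stable").reset_index(drop=True)


def forest_data(results, alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready forest table (label, OR, CI bounds, class), ordered by OR."""
    sig = significant_results(results, alpha)
    return sig.rename(columns={"exposure_id": "label"})[
        ["label", "or", "ci_low", "ci_high", "class"]
    ]
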