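"""Configuration-driven end-to-end analysis: one exposure, many outcomes.

``run_analysis`` executes the full pipeline for each outcome — instrument
selection, harmonization, IVW / weighted-median / MR-Egger estimation and
MR-PRESSO diagnostics — and writes per-outcome TSVs plus one combined
forest table.  Outputs are deterministic: the same configuration and seed
produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import estimators, instruments, presso, summary_data
from .summary_data import ConfigurationError, EffectWithCI, HarmonizedDataset

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class AnalysisConfig:
    """Everything one run needs; loadable from a YAML mapping."""

    exposure_path: str
    outcome_paths: dict[str, str]  # label -> path
    p_threshold: float = 5e-8
    ld_matrix_path: str | None = None
    r2_threshold: float = 0.05
    exclusion_list_path: str | None = None
    ivw_model: str = "multiplicative_random"
    palindromic_policy: str = "flag"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_sig_threshold: float = 0.05
    seed: int = 0
    alpha: float = 0.05
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.outcome_paths:
            raise ConfigurationError("at least one outcome is required")
        if self.ivw_model not in estimators.IVW_MODELS:
            raise ConfigurationError(f"unknown ivw_model {self.ivw_model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "AnalysisConfig":
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        unknown = set(merged) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**merged)


@dataclass
class OutcomeResult:
    label: str
    dataset: HarmonizedDataset
    effects: list[EffectWithCI]
    egger: estimators.EggerResult
    presso: presso.PressoResult


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    outcomes: dict[str, OutcomeResult] = field(default_factory=dict)
    n_candidates: int = 0
    n_instruments: int = 0

    @property
    def forest_table(self) -> pd.DataFrame:
        rows = []
        for label, res in self.outcomes.items():
            for eff in res.effects:
                rows.append(
                    {
                        "outcome": label,
                        "method": eff.method,
                        "n_snps": eff.n_snps,
                        "estimate_log": eff.estimate_log,
                        "se_log": eff.se_log,
                        "or": eff.or_scale,
                        "ci_low": eff.ci_low,
                        "ci_high": eff.ci_high,
                        "pvalue": eff.pvalue,
                    }
                )
        return pd.DataFrame(rows)


def _select_instruments(
    config: AnalysisConfig, exposure: list[summary_data.SNPAssociation]
) -> list[summary_data.SNPAssociation]:
    selected = instruments.select_by_pvalue(exposure, config.p_threshold)
    log.info("p < %.3g retained %d of %d candidates", config.p_threshold, len(selected), len(exposure))
    if config.ld_matrix_path:
        ld = instruments.LDMatrix.from_tsv(config.ld_matrix_path)
        selected = instruments.ld_prune(selected, ld, config.r2_threshold)
        log.info("LD pruning (r2 < %g) retained %d", config.r2_threshold, len(selected))
    if config.exclusion_list_path:
        excluded = instruments.read_exclusion_list(config.exclusion_list_path)
        selected = instruments.exclude_rsids(selected, excluded, reason="exclusion list")
        log.info("exclusion list retained %d", len(selected))
    return selected


def _analyse_outcome(
    config: AnalysisConfig,
    label: str,
    exposure: list[summary_data.SNPAssociation],
    outcome: list[summary_data.SNPAssociation],
) -> OutcomeResult:
    ds = summary_data.harmonize(
        exposure,
        outcome,
        policy=config.palindromic_policy,
        exposure_label="exposure",
        outcome_label=label,
    )
    if ds.flip_log:
        log.info("%s: flipped alleles for %s", label, ", ".join(ds.flip_log))
    if ds.dropped:
        log.info("%s: dropped %d SNP(s): %s", label, len(ds.dropped), ", ".join(ds.dropped))
    effects = [
        estimators.ivw(ds, model=config.ivw_model, alpha=config.alpha),
        estimators.weighted_median(ds, n_boot=config.n_boot, seed=config.seed, alpha=config.alpha),
    ]
    egger = estimators.mr_egger(ds)
    effects.append(egger.slope_effect(alpha=config.alpha))
    pres = presso.presso_outlier(
        ds,
        n_sim=config.presso_n_sim,
        seed=config.seed,
        sig_threshold=config.presso_sig_threshold,
    )
    return OutcomeResult(label=label, dataset=ds, effects=effects, egger=egger, presso=pres)


def _write_outcome(outdir: Path, res: OutcomeResult, config: AnalysisConfig) -> None:
    tag = res.label.lower()
    res.dataset.to_tsv(outdir / f"harmonized_{tag}.tsv")

    wr = estimators.wald_ratios(res.dataset)
    pd.DataFrame(
        {
            "rsid": wr.snps,
            "wald_ratio": wr.ratio,
            "se_ratio": wr.se_ratio,
            "weight": wr.weight,
        }
    ).to_csv(outdir / f"wald_ratios_{tag}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    rows = [
        {
            "method": e.method,
            "outcome": res.label,
            "n_snps": e.n_snps,
            "estimate_log": e.estimate_log,
            "se_log": e.se_log,
            "or": e.or_scale,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pvalue": e.pvalue,
        }
        for e in res.effects
    ]
    rows.append(
        {
            "method": "Egger-intercept",
            "outcome": res.label,
            "n_snps": res.egger.n_snps,
            "estimate_log": res.egger.intercept,
            "se_log": res.egger.se_intercept,
            "or": float("nan"),
            "ci_low": float("nan"),
            "ci_high": float("nan"),
            "pvalue": res.egger.intercept_pvalue,
        }
    )
    pd.DataFrame(rows).to_csv(outdir / f"estimates_{tag}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    p = res.presso
    presso_rows = [
        {
            "row": "global",
            "rsid": "",
            "statistic": p.rss_observed,
            "pvalue": p.global_pvalue,
            "outlier": "",
        }
    ]
    for s in p.snps:
        presso_rows.append(
            {
                "row": "snp",
                "rsid": s,
                "statistic": float("nan"),
                "pvalue": p.snp_pvalues.get(s, float("nan")),
                "outlier": "yes" if s in p.outliers else "no",
            }
        )
    if p.distortion_pvalue is not None:
        presso_rows.append(
            {
                "row": "distortion",
                "rsid": "",
                "statistic": p.distortion_statistic,
                "pvalue": p.distortion_pvalue,
                "outlier": "",
            }
        )
    pd.DataFrame(presso_rows).to_csv(
        outdir / f"presso_{tag}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the full multi-outcome analysis and write the report files.

    Writes, under ``config.output_dir``: per-outcome harmonized data, Wald
    ratios, estimate and MR-PRESSO tables; a combined forest table across
    outcomes; and ``run_log.txt`` recording selection counts, flips, seed
    and parameters.
    """
    for path in [config.exposure_path, *config.outcome_paths.values()] + [
        p for p in (config.ld_matrix_path, config.exclusion_list_path) if p
    ]:
        if not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")

    exposure_all = summary_data.read_summary_table(config.exposure_path)
    selected = _select_instruments(config, exposure_all)
    if not selected:
        raise ConfigurationError("no instruments survive selection")

    result = AnalysisResult(
        config=config, n_candidates=len(exposure_all), n_instruments=len(selected)
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, path in config.outcome_paths.items():
        outcome = summary_data.read_summary_table(path)
        res = _analyse_outcome(config, label, selected, outcome)
        result.outcomes[label] = res
        _write_outcome(outdir, res, config)

    result.forest_table.to_csv(
        outdir / "forest_table.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    _write_run_log(outdir / "run_log.txt", config, result)
    return result


def _write_run_log(path: Path, config: AnalysisConfig, result: AnalysisResult) -> None:
    lines = ["# analysis run log"]
    for k, v in vars(config).items():
        if k == "output_dir":  # the log's own location; not an analysis parameter
            continue
        lines.append(f"param {k} = {v}")
    lines.append(f"candidates read: {result.n_candidates}")
    lines.append(f"instruments selected: {result.n_instruments}")
    for label, res in result.outcomes.items():
        lines.append(f"[{label}] n_snps={res.dataset.n_snps}")
        lines.append(f"[{label}] flips: {', '.join(res.dataset.flip_log) or 'none'}")
        lines.append(f"[{label}] dropped: {', '.join(res.dataset.dropped) or 'none'}")
        lines.append(f"[{label}] palindromic: {', '.join(res.dataset.palindromic) or 'none'}")
        lines.append(f"[{label}] presso outliers: {', '.join(res.presso.outliers) or 'none'}")
    path.write_text("\n".join(lines) + "\n")
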