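"""End-to-end analysis: pooling, cross-population comparison, burden score
and power, from two study tables and a single config.

Stages mirror a two-population comparative association analysis:

1. meta-analyse each population's studies per SNP signal (rows sharing an
   ``ld_group`` key are pooled as one signal);
2. compare pooled effects between populations with a Z test on log ORs;
3. contrast weighted genotype (population-burden) scores, both populations
   weighted by one population's ORs;
4. compute power / required pairs for a table of alternative designs;
5. log every harmonization flip and exclusion as machine-readable events.

Outputs are TSV + JSON and are byte-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .compare import compare_log_or
from .effects import EffectEstimate, estimate_from_record, weighted_raf
from .exceptions import ConfigurationError, EstimateError
from .io import StudyAssociation, harmonize_alleles, parse_study_table
from .meta import DEFAULT_I2_THRESHOLDS, MetaResult, pool
from .power import power_report
from .score import build_score, compare_scores

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Global constants and file locations for one analysis run."""

    study_table_a: Path
    study_table_b: Path
    weights_population: str = "b"
    alpha: float = 0.05
    prevalence: float = 0.10
    meta_model: str = "random"
    output_dir: Path = Path("ethnometa_output")
    i2_labels: tuple[float, float, float] = DEFAULT_I2_THRESHOLDS
    power_table: Path | None = None
    bonferroni: bool = False  # optional extension, off by default
    population_a: str = "a"
    population_b: str = "b"
    #: Decimal places of the published tables. Pooled ORs/CIs are rounded to
    #: this precision before the cross-population Z test, matching how such
    #: consortium comparisons are made from printed columns. None = exact.
    comparison_precision: int | None = 2

    def __post_init__(self) -> None:
        self.study_table_a = Path(self.study_table_a)
        self.study_table_b = Path(self.study_table_b)
        self.output_dir = Path(self.output_dir)
        if self.power_table is not None:
            self.power_table = Path(self.power_table)
        if self.weights_population not in ("a", "b"):
            raise ConfigurationError("weights_population must be 'a' or 'b'")
        if self.meta_model not in ("fixed", "random"):
            raise ConfigurationError("meta_model must be 'fixed' or 'random'")
        thresholds = tuple(self.i2_labels)
        if len(thresholds) != 3 or list(thresholds) != sorted(thresholds) or not (
            0 < thresholds[0] and thresholds[-1] < 1
        ):
            raise ConfigurationError("i2_labels must be three increasing fractions in (0,1)")
        self.i2_labels = thresholds
        if not 0 < self.alpha < 1 or not 0 < self.prevalence < 1:
            raise ConfigurationError("alpha and prevalence must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisReport:
    """In-memory results of one pipeline run plus the files written."""

    meta_a: pd.DataFrame
    meta_b: pd.DataFrame
    comparison: pd.DataFrame
    score: dict[str, Any]
    power: pd.DataFrame | None
    events: list[dict[str, Any]]
    paths: dict[str, Path]


def _signal_groups(records: Sequence[StudyAssociation]) -> dict[str, list[StudyAssociation]]:
    """Group records into signals: one per ld_group key, else per SNP."""
    groups: dict[str, list[StudyAssociation]] = {}
    for rec in records:
        groups.setdefault(rec.ld_group or rec.snp_id, []).append(rec)
    return groups


def _summary_raf(records: Sequence[StudyAssociation]) -> float | None:
    rafs, sizes = [], []
    for rec in records:
        if rec.raf is not None:
            rafs.append(rec.raf)
            sizes.append(rec.n_cases + rec.n_controls)
    return weighted_raf(rafs, sizes) if rafs else None


def _pool_population(
    records: Sequence[StudyAssociation],
    population: str,
    config: AnalysisConfig,
    events: list[dict[str, Any]],
) -> tuple[pd.DataFrame, dict[str, MetaResult], dict[str, dict[str, Any]]]:
    """Meta-analyse one population; returns (table, results, signal info)."""
    rows = []
    pooled: dict[str, MetaResult] = {}
    info: dict[str, dict[str, Any]] = {}
    for key, group in sorted(_signal_groups(records).items()):
        snp_ids = sorted({rec.snp_id for rec in group})
        if len(group) > 1:
            events.append(
                {
                    "event": "pool",
                    "population": population,
                    "signal": key,
                    "snp_ids": snp_ids,
                    "k": len(group),
                    "ld_group": group[0].ld_group,
                }
            )
        estimates = [estimate_from_record(rec) for rec in group]
        result = pool(estimates, model=config.meta_model, thresholds=config.i2_labels)
        raf = _summary_raf(group)
        pooled[key] = result
        info[key] = {
            "snp_ids": snp_ids,
            "gene": group[0].gene,
            "risk_allele": group[0].risk_allele,
            "raf": raf,
            "n_cases": sum(rec.n_cases for rec in group),
            "n_controls": sum(rec.n_controls for rec in group),
            "monomorphic": any(rec.is_monomorphic() for rec in group),
        }
        rows.append(
            {
                "population": population,
                "signal": key,
                "snp_ids": "/".join(snp_ids),
                "gene": group[0].gene,
                "risk_allele": group[0].risk_allele,
                "k": result.k,
                "raf": raf,
                "or": result.pooled_or,
                "ci_low": result.ci_low,
                "ci_high": result.ci_high,
                "p": result.p_value,
                "q": result.q_stat,
                "q_df": result.q_df,
                "q_p": result.q_p,
                "i2": result.i2,
                "tau2": result.tau2,
                "heterogeneity": result.label,
            }
        )
    frame = pd.DataFrame(rows)
    if config.bonferroni and len(frame):
        frame["p_bonferroni"] = (frame["p"] * len(frame)).clip(upper=1.0)
    return frame, pooled, info


def _comparison_estimate(
    result: MetaResult,
    snp: str,
    risk_allele: str | None,
    precision: int | None,
) -> EffectEstimate:
    """Pooled effect as fed to the cross-population Z test.

    With a reporting ``precision``, multi-study pooled ORs and CIs are
    rounded to that many decimals and the SE re-derived from the rounded
    CI — the comparison then operates on exactly the values a published
    table carries.  Single-study results pass through unrounded: their
    OR/CI already are the published numbers.
    """
    from .effects import estimate_from_ci

    if precision is None or result.k == 1:
        est = EffectEstimate(
            log_or=result.pooled_log_or, se=result.pooled_se, source="pooled"
        )
    else:
        try:
            est = estimate_from_ci(
                round(result.pooled_or, precision),
                round(result.ci_low, precision),
                round(result.ci_high, precision),
            )
        except EstimateError:
            # rounding collapsed or disordered the interval: fall back to exact
            est = EffectEstimate(
                log_or=result.pooled_log_or, se=result.pooled_se, source="pooled"
            )
        est.source = "pooled"
    est.snp_id = snp
    est.risk_allele = risk_allele
    return est


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute every stage and write the report bundle to ``output_dir``.

    On any stage error the partially written outputs are removed and the
    offending SNP/study surfaces in the exception message.
    """
    events: list[dict[str, Any]] = []
    records_a = parse_study_table(config.study_table_a)
    records_b = parse_study_table(config.study_table_b)

    reference = {}
    for rec in records_a:
        reference.setdefault(rec.snp_id, rec.risk_allele)
    for rec in records_b:
        ref = reference.get(rec.snp_id)
        if ref is not None and rec.risk_allele != ref:
            events.append(
                {"event": "flip", "population": "b", "snp_id": rec.snp_id,
                 "study_id": rec.study_id, "to_allele": ref}
            )
    records_b = harmonize_alleles(records_b, reference)

    meta_a, pooled_a, info_a = _pool_population(records_a, config.population_a, config, events)
    meta_b, pooled_b, info_b = _pool_population(records_b, config.population_b, config, events)

    # Map signals by SNP id for the cross-population join.
    by_snp_a = {snp: key for key, d in info_a.items() for snp in d["snp_ids"]}
    by_snp_b = {snp: key for key, d in info_b.items() for snp in d["snp_ids"]}

    comparison_rows = []
    score_panel = []
    for snp, key_a in sorted(by_snp_a.items()):
        key_b = by_snp_b.get(snp)
        if key_b is None:
            events.append(
                {"event": "drop", "stage": "comparison", "snp_id": snp,
                 "reason": "present only in population a"}
            )
            continue
        if info_a[key_a]["monomorphic"] or info_b[key_b]["monomorphic"]:
            events.append(
                {"event": "drop", "stage": "comparison", "snp_id": snp,
                 "reason": "monomorphic in one population"}
            )
            continue
        res_a, res_b = pooled_a[key_a], pooled_b[key_b]
        est_a = _comparison_estimate(
            res_a, snp, info_a[key_a]["risk_allele"], config.comparison_precision
        )
        est_b = _comparison_estimate(
            res_b, snp, info_b[key_b]["risk_allele"], config.comparison_precision
        )
        raf_a, raf_b = info_a[key_a]["raf"], info_b[key_b]["raf"]
        cmp = compare_log_or(est_a, est_b, raf_a=raf_a, raf_b=raf_b)
        comparison_rows.append(
            {
                "snp_id": snp,
                "gene": info_a[key_a]["gene"],
                "or_a": res_a.pooled_or,
                "or_b": res_b.pooled_or,
                "raf_a": raf_a,
                "raf_b": raf_b,
                "delta_log_or": cmp.delta_log_or,
                "z": cmp.z,
                "p_heterogeneity": cmp.p_value,
            }
        )
        if raf_a is None or raf_b is None:
            events.append(
                {"event": "drop", "stage": "score", "snp_id": snp,
                 "reason": "missing RAF in one population"}
            )
            continue
        weights = res_b if config.weights_population == "b" else res_a
        score_panel.append(
            {"snp_id": snp, "log_or_w": weights.pooled_log_or,
             "var_w": weights.pooled_se**2, "raf_a": raf_a, "raf_b": raf_b}
        )
    for snp, key_b in sorted(by_snp_b.items()):
        if snp not in by_snp_a:
            events.append(
                {"event": "drop", "stage": "comparison", "snp_id": snp,
                 "reason": "present only in population b"}
            )
    comparison = pd.DataFrame(comparison_rows)

    score_summary: dict[str, Any] = {}
    if score_panel:
        ors = [math.exp(row["log_or_w"]) for row in score_panel]
        variances = [row["var_w"] for row in score_panel]
        snp_ids = [row["snp_id"] for row in score_panel]
        weights_label = (
            config.population_b if config.weights_population == "b" else config.population_a
        )
        score_a = build_score(
            config.population_a, ors, [row["raf_a"] for row in score_panel],
            variances, weights_label, snp_ids,
        )
        score_b = build_score(
            config.population_b, ors, [row["raf_b"] for row in score_panel],
            variances, weights_label, snp_ids,
        )
        z, p = compare_scores(score_a, score_b)
        score_summary = {
            "weights_source": weights_label,
            "n_snps": score_a.n_snps,
            "snp_ids": snp_ids,
            "score_a": score_a.score,
            "variance_a": score_a.variance,
            "score_b": score_b.score,
            "variance_b": score_b.variance,
            "z": z,
            "p_value": p,
        }

    power_frame: pd.DataFrame | None = None
    if config.power_table is not None:
        specs = pd.read_csv(config.power_table)
        or_col = "or_gwas" if "or_gwas" in specs.columns else "or_alt"
        power_frame = power_report(
            specs, prevalence=config.prevalence, alpha=config.alpha, or_column=or_col
        )
    elif len(meta_a):
        specs = meta_a.loc[meta_a["raf"].notna() & (meta_a["or"] != 1.0)].copy()
        specs = specs[["signal", "snp_ids", "gene", "or", "raf"]].rename(
            columns={"or": "or_alt"}
        )
        specs["n_cases"] = [
            info_a[s]["n_cases"] for s in specs["signal"]
        ]
        power_frame = power_report(
            specs, prevalence=config.prevalence, alpha=config.alpha
        )

    paths = _write_outputs(config, meta_a, meta_b, comparison, score_summary, power_frame, events)
    return AnalysisReport(
        meta_a=meta_a, meta_b=meta_b, comparison=comparison,
        score=score_summary, power=power_frame, events=events, paths=paths,
    )


def _write_outputs(
    config: AnalysisConfig,
    meta_a: pd.DataFrame,
    meta_b: pd.DataFrame,
    comparison: pd.DataFrame,
    score_summary: dict[str, Any],
    power_frame: pd.DataFrame | None,
    events: list[dict[str, Any]],
) -> dict[str, Path]:
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    paths: dict[str, Path] = {}
    try:
        for name, frame in (
            ("meta_a", meta_a),
            ("meta_b", meta_b),
            ("comparison", comparison),
        ):
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
            paths[name] = path
        if power_frame is not None:
            path = out / "power.tsv"
            power_frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
            paths["power"] = path
        path = out / "genotype_score.json"
        path.write_text(json.dumps(score_summary, indent=2, sort_keys=True) + "\n")
        written.append(path)
        paths["score"] = path
        path = out / "analysis_log.jsonl"
        path.write_text(
            "".join(json.dumps(event, sort_keys=True) + "\n" for event in events)
        )
        written.append(path)
        paths["log"] = path
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return paths
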