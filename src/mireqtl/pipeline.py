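"""End-to-end study orchestration and report writing.

``run_study`` reads the exchange files, normalizes all arrays against a
shared 75th-percentile reference, builds the paired differential matrix,
aligns the cohort, and then for every requested (stratum, tissue) pair
re-filters probes on that stratum's own samples, runs the bootstrap-F
scan, adjusts within per-SNP families and writes one report table, plus
a run manifest and a log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationResult, BootstrapConfig, run_scan, stratum_samples
from .datamodel import (
    STRATA,
    AnalysisCohort,
    ExpressionMatrix,
    align_cohort,
    compute_paired_differential,
)
from .errors import ConfigurationError, ContractError
from .io import (
    read_covariates,
    read_expression,
    read_genotypes,
    read_snp_specs,
)
from .multitest import DecisionConfig, decide
from .normalize import FilterConfig, apply_normalization, compute_scaling_factors, filter_probes, percentile75

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "snp_id", "gene", "model", "mirna_id", "ref_group", "var_group",
    "n_ref", "n_var", "mean_ref", "mean_var", "f_obs", "p_boot",
    "fdr_adjusted_p", "q_value", "direction", "important", "q_significant",
]


@dataclass
class StudyConfig:
    """Paths, strata/tissues to run, and stage settings for one study."""

    expression_normal: str
    genotypes: str
    covariates: str
    snp_specs: str
    expression_carcinoma: str | None = None
    detection_normal: str | None = None
    detection_carcinoma: str | None = None
    strata: tuple[str, ...] = ("colorectal", "colon", "rectal")
    tissues: tuple[str, ...] = ("normal", "differential")
    filter: FilterConfig = field(default_factory=FilterConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    decision: DecisionConfig = field(default_factory=DecisionConfig)
    log2_offset: float = 1.0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.strata or not self.tissues:
            raise ConfigurationError("at least one stratum and one tissue required")
        bad = set(self.strata) - set(STRATA)
        if bad:
            raise ConfigurationError(f"unknown stratum/strata: {sorted(bad)}")
        bad = set(self.tissues) - {"normal", "differential"}
        if bad:
            raise ConfigurationError(f"unknown tissue(s): {sorted(bad)}")
        if "differential" in self.tissues and not self.expression_carcinoma:
            raise ConfigurationError(
                "differential tissue requested but no carcinoma expression file given")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key, sub in (("filter", FilterConfig), ("bootstrap", BootstrapConfig),
                         ("decision", DecisionConfig)):
            if isinstance(raw.get(key), dict):
                raw[key] = sub(**raw[key])
        for key in ("strata", "tissues"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Results as a report-shaped DataFrame sorted by SNP then adjusted p."""
    if not results:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
    frame = frame[REPORT_COLUMNS]
    sort_cols = ["snp_id", "fdr_adjusted_p", "p_boot", "mirna_id"]
    if frame["fdr_adjusted_p"].isna().all():
        sort_cols = ["snp_id", "p_boot", "mirna_id"]
    return frame.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)


def write_report(results, path: str | Path) -> None:
    """Write a results table (list of results or a DataFrame) as TSV."""
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ContractError(f"report is missing column(s): {missing}")
    frame.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _shared_reference(matrices: list[ExpressionMatrix]) -> float:
    """Median of the per-sample 75th percentiles pooled over all arrays."""
    q75 = [percentile75(mat.values[s].to_numpy())
           for mat in matrices for s in mat.sample_ids]
    return float(np.median(q75))


def prepare_cohort(config: StudyConfig) -> AnalysisCohort:
    """Read, normalize (shared reference), difference, and align the inputs."""
    normal = read_expression(config.expression_normal, "normal",
                             config.detection_normal)
    carcinoma = None
    if config.expression_carcinoma:
        carcinoma = read_expression(config.expression_carcinoma, "carcinoma",
                                    config.detection_carcinoma)
    genotypes = read_genotypes(config.genotypes)
    covariates = read_covariates(config.covariates)

    mats = [m for m in (normal, carcinoma) if m is not None]
    ref = _shared_reference(mats)
    log.info("normalization reference (pooled median Q75): %.6g", ref)
    normed = {m.tissue: apply_normalization(m, compute_scaling_factors(m, reference=ref))
              for m in mats}

    expressions: dict[str, ExpressionMatrix] = {}
    if "normal" in config.tissues:
        expressions["normal"] = normed["normal"]
    if "differential" in config.tissues:
        expressions["differential"] = compute_paired_differential(
            normed["carcinoma"], normed["normal"])
    cohort, _ = align_cohort(expressions, genotypes, covariates)
    return cohort


def run_study(config: StudyConfig) -> dict[tuple[str, str], pd.DataFrame]:
    """Run every (stratum, tissue) scan and write the report set."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "study.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mireqtl")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cohort = prepare_cohort(config)
        specs = read_snp_specs(config.snp_specs)
        tables: dict[tuple[str, str], pd.DataFrame] = {}
        manifest: dict = {
            "package": "mireqtl",
            "version": __version__,
            "master_seed": config.bootstrap.master_seed,
            "bootstrap_reps": config.bootstrap.n_reps,
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "config": config.to_dict(),
            "tables": {},
        }
        for stratum in config.strata:
            for tissue in config.tissues:
                samples = stratum_samples(cohort.covariates.frame,
                                          cohort.samples[tissue], stratum)
                name = f"{stratum}_{tissue}"
                path = out / f"results_{name}.tsv"
                if not samples:
                    log.warning("no samples for stratum %s tissue %s; empty table",
                                stratum, tissue)
                    frame = results_frame([])
                else:
                    sub = cohort.expression[tissue].subset_samples(samples)
                    filtered, dropped = filter_probes(sub, config.filter)
                    log.info("stratum %s tissue %s: %d samples, %d/%d probes retained",
                             stratum, tissue, len(samples),
                             len(filtered.probe_ids), len(sub.probe_ids))
                    results = run_scan(cohort, specs, tissue, stratum,
                                       config.bootstrap, expression=filtered,
                                       log2_offset=config.log2_offset)
                    decide(results, config.decision)
                    frame = results_frame(results)
                    manifest["tables"][name] = {
                        "n_samples": len(samples),
                        "n_probes_retained": len(filtered.probe_ids),
                        "n_probes_dropped": len(dropped),
                        "n_results": int(len(frame)),
                        "n_important": int(frame["important"].sum()) if len(frame) else 0,
                    }
                write_report(frame, path)
                tables[(stratum, tissue)] = frame
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return tables
    finally:
        root.removeHandler(handler)
        handler.close()
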