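"""Cohort data model: expression, genotype and covariate containers.

The containers wrap pandas objects (probes/SNPs as rows, samples as
columns) and enforce the invariants the downstream statistics rely on:
unique identifiers, finite signal, non-negative signal for measured
tissue, allele counts in {0, 1, 2, missing}.  ``align_cohort`` restricts
every component to a shared ordered sample list per tissue, and
``compute_paired_differential`` forms the carcinoma-minus-normal matrix
used for the paired differential analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError

log = logging.getLogger(__name__)

#: Recognised tissue labels.  "differential" holds carcinoma - normal
#: signal differences and is the only tissue allowed negative values.
TISSUES = ("normal", "carcinoma", "differential")

#: Tumor-site strata used throughout the pipeline.
STRATA = ("colorectal", "colon", "rectal")

#: Inheritance models for the genotype indicator.
MODELS = ("dominant", "recessive")

SITES = ("colon", "rectal")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ContractError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of array signal for one tissue type.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns.
    tissue
        One of ``normal``, ``carcinoma`` or ``differential``.
    detection
        Optional boolean DataFrame of identical shape; ``True`` marks a
        probe called detected/expressed in that sample.
    """

    values: pd.DataFrame
    tissue: str
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ContractError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if vals.size and not np.isfinite(vals).all():
            raise ContractError("expression values must be finite")
        if self.tissue != "differential" and vals.size and (vals < 0).any():
            raise ContractError(f"negative signal not allowed for tissue {self.tissue!r}")
        if self.detection is not None:
            if self.detection.shape != self.values.shape:
                raise ContractError("detection matrix shape differs from values")
            if not (self.detection.index.equals(self.values.index)
                    and self.detection.columns.equals(self.values.columns)):
                raise ContractError("detection matrix ids differ from values")
            self.detection = self.detection.astype(bool)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        det = self.detection[list(sample_ids)] if self.detection is not None else None
        return ExpressionMatrix(self.values[list(sample_ids)], self.tissue, det)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        det = self.detection.loc[list(probe_ids)] if self.detection is not None else None
        return ExpressionMatrix(self.values.loc[list(probe_ids)], self.tissue, det)


@dataclass
class GenotypeMatrix:
    """SNPs x samples matrix of variant-allele counts with missingness.

    Calls are stored as floats with NaN marking a missing genotype; every
    non-missing call must be 0, 1 or 2.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "SNP")
        _check_unique(self.calls.columns, "sample")
        vals = self.calls.to_numpy(dtype=float, copy=False)
        observed = vals[~np.isnan(vals)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(observed[~np.isin(observed, (0.0, 1.0, 2.0))]))
            raise ContractError(f"genotype calls outside {{0,1,2,NA}}: {bad[:5]}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[list(sample_ids)])


#: Columns every covariate table must carry.
COVARIATE_COLUMNS = ("age", "sex", "race", "site")


@dataclass
class CovariateTable:
    """Per-sample covariates: age at diagnosis, sex, race/ethnicity, site.

    ``frame`` is indexed by sample id.  An optional boolean column
    ``has_carcinoma_pair`` marks cases with a paired carcinoma array; when
    absent it is derived during cohort alignment.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")
        missing = [c for c in COVARIATE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ContractError(f"covariate table missing column(s): {missing}")
        age = self.frame["age"].to_numpy(dtype=float)
        if age.size and (not np.isfinite(age).all() or (age <= 0).any()):
            raise ContractError("age must be finite and > 0 for every sample")
        bad_site = set(self.frame["site"].astype(str)) - set(SITES)
        if bad_site:
            raise ContractError(f"unknown site level(s): {sorted(bad_site)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.frame.loc[list(sample_ids)])


@dataclass(frozen=True)
class SnpSpec:
    """Per-SNP test specification: gene, inheritance model, variant allele.

    ``model`` decides the binary indicator: dominant pools carriers of the
    variant allele (calls 1 and 2) against reference homozygotes;
    recessive pools variant homozygotes (call 2) against everyone else.
    ``variant_allele`` is annotation only.
    """

    snp_id: str
    gene: str
    model: str
    variant_allele: str = ""

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ContractError(
                f"SNP {self.snp_id}: model {self.model!r} not one of {MODELS}")


@dataclass
class AlignmentReport:
    """Retained/dropped sample counts produced by :func:`align_cohort`."""

    retained: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, dict[str, int]] = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = []
        for tissue, n in self.retained.items():
            d = self.dropped.get(tissue, {})
            parts.append(f"{tissue}: retained {n} "
                         f"(dropped from expression {d.get('expression', 0)}, "
                         f"genotypes {d.get('genotypes', 0)}, "
                         f"covariates {d.get('covariates', 0)})")
        return "; ".join(parts)


@dataclass
class AnalysisCohort:
    """Aligned study inputs: per-tissue expression plus genotypes/covariates.

    Within each tissue the expression matrix, the genotype matrix and the
    covariate table share the identical ordered sample list stored in
    ``samples``.
    """

    expression: dict[str, ExpressionMatrix]
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    samples: dict[str, list[str]]

    def genotype_calls(self, tissue: str) -> pd.DataFrame:
        return self.genotypes.calls[self.samples[tissue]]

    def covariate_frame(self, tissue: str) -> pd.DataFrame:
        return self.covariates.frame.loc[self.samples[tissue]]


def align_cohort(
    expressions: Mapping[str, ExpressionMatrix] | Iterable[ExpressionMatrix],
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
) -> tuple[AnalysisCohort, AlignmentReport]:
    """Restrict all sources to their common samples, per tissue.

    The canonical sample order is the order of the expression matrix for
    that tissue.  Samples absent from any source are dropped everywhere;
    an empty intersection is a configuration error.  For the differential
    tissue, samples flagged ``has_carcinoma_pair == False`` are excluded.
    """
    if not isinstance(expressions, Mapping):
        expressions = {m.tissue: m for m in expressions}
    if not expressions:
        raise ContractError("at least one expression matrix is required")

    geno_samples = set(genotypes.sample_ids)
    cov_samples = set(covariates.sample_ids)
    has_pair = None
    if "has_carcinoma_pair" in covariates.frame.columns:
        has_pair = covariates.frame["has_carcinoma_pair"].astype(bool)

    aligned: dict[str, ExpressionMatrix] = {}
    samples: dict[str, list[str]] = {}
    report = AlignmentReport()
    for tissue, mat in expressions.items():
        if tissue != mat.tissue:
            raise ContractError(f"expression labelled {mat.tissue!r} supplied under key {tissue!r}")
        common = [s for s in mat.sample_ids if s in geno_samples and s in cov_samples]
        if tissue == "differential" and has_pair is not None:
            common = [s for s in common if has_pair.get(s, False)]
        if not common:
            raise ConfigurationError(
                f"no common samples across expression/genotypes/covariates for tissue {tissue!r}")
        aligned[tissue] = mat.subset_samples(common)
        samples[tissue] = common
        report.retained[tissue] = len(common)
        report.dropped[tissue] = {
            "expression": len(mat.sample_ids) - len(common),
            "genotypes": len(geno_samples - set(common)),
            "covariates": len(cov_samples - set(common)),
        }

    cov_frame = covariates.frame.copy()
    if "has_carcinoma_pair" not in cov_frame.columns:
        diff_set = set(samples.get("differential", []))
        cov_frame["has_carcinoma_pair"] = [s in diff_set for s in cov_frame.index]
    cohort = AnalysisCohort(aligned, genotypes, CovariateTable(cov_frame), samples)
    log.info("aligned cohort: %s", report)
    return cohort, report


def compute_paired_differential(
    carcinoma: ExpressionMatrix, normal: ExpressionMatrix
) -> ExpressionMatrix:
    """Carcinoma-minus-normal signal for samples present in both matrices.

    Pairing is by identical sample id.  Both inputs must already sit on a
    common normalized scale and carry identical probe sets.  Detection
    flags, when both matrices carry them, are combined with a logical OR
    (a probe is informative for the difference if it was detected in
    either tissue).
    """
    if carcinoma.tissue != "carcinoma" or normal.tissue != "normal":
        raise ContractError("arguments must be (carcinoma, normal) expression matrices")
    if set(carcinoma.probe_ids) != set(normal.probe_ids):
        raise ContractError("carcinoma and normal probe sets differ")
    common = [s for s in carcinoma.sample_ids if s in set(normal.sample_ids)]
    if not common:
        raise ConfigurationError("no paired samples shared by carcinoma and normal matrices")
    norm_vals = normal.values.loc[carcinoma.probe_ids, common]
    diff = carcinoma.values[common] - norm_vals
    detection = None
    if carcinoma.detection is not None and normal.detection is not None:
        detection = (carcinoma.detection[common]
                     | normal.detection.loc[carcinoma.probe_ids, common])
    return ExpressionMatrix(diff, "differential", detection)
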