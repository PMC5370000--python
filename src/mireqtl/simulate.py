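"""Synthetic cohort generator with a planted-effect truth registry.

Emulates the statistical structure the pipeline assumes: Hardy-Weinberg
genotypes at configurable minor allele frequencies, case covariates
(age, sex, race/ethnicity, tumor site) matching the study population's
descriptive statistics, Agilent-like positive array signal with
per-sample scale distortions and detection-driven dropout, a paired
carcinoma array for a subset of cases, and SNP effects planted on a
configurable fraction of miRNAs.  The truth registry records every
planted (SNP, miRNA, tissue, effect) so calibration and recovery tests
know the null set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CovariateTable, ExpressionMatrix, GenotypeMatrix, SnpSpec
from .errors import ContractError
from . import io as mio


@dataclass
class SimulationParams:
    """Cohort-level simulation settings.

    Defaults emulate the study cohort: 1188 cases of which 1141 carry a
    paired carcinoma array, a 689:499 colon:rectal split, tagSNPs with
    MAF above 0.1, and per-site age/sex/race distributions taken from the
    cohort description.  Effect sizes are expressed in units of the
    probe's residual SD on the log2 scale.
    """

    n_samples: int = 1188
    fraction_with_carcinoma_pair: float = 1141 / 1188
    colon_fraction: float = 689 / 1188

    n_snps: int = 80
    maf_range: tuple[float, float] = (0.1, 0.5)
    dominant_fraction: float = 0.5
    genotype_missing_rate: float = 0.04

    n_mirnas: int = 1200
    baseline_log2_range: tuple[float, float] = (2.0, 10.0)
    residual_sd_range: tuple[float, float] = (0.8, 1.2)
    sample_scale_sd: float = 0.25      # SD of log array-scale distortion
    dropout_rate: float = 0.20         # mean per-probe detection dropout
    dropout_concentration: float = 2.0  # Beta concentration of per-probe rates

    effect_fraction: float = 0.10      # fraction of miRNAs given a SNP effect
    n_effects: int | None = None       # overrides effect_fraction when set
    effect_size_range: tuple[float, float] = (0.5, 1.5)
    differential_effect_fraction: float = 0.5  # planted in carcinoma only
    tumor_shift_sd: float = 1.0        # probe-specific log2 shift in carcinoma

    age_mean: dict = field(default_factory=lambda: {"colon": 65.3, "rectal": 61.8})
    age_sd: dict = field(default_factory=lambda: {"colon": 9.1, "rectal": 11.1})
    age_bounds: tuple[float, float] = (30.0, 79.0)
    male_fraction: dict = field(default_factory=lambda: {"colon": 0.556, "rectal": 0.593})
    race_levels: tuple = ("white", "hispanic", "black", "other")
    race_probs: dict = field(default_factory=lambda: {
        "colon": (0.862, 0.068, 0.067, 0.003),
        "rectal": (0.802, 0.092, 0.036, 0.070),
    })
    covariate_variance_fraction: float = 0.01

    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 0 or self.n_mirnas < 1:
            raise ContractError("n_samples and n_mirnas must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ContractError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("fraction_with_carcinoma_pair", "colon_fraction",
                     "dominant_fraction", "genotype_missing_rate",
                     "dropout_rate", "effect_fraction",
                     "differential_effect_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ContractError(f"{name} must lie in [0, 1]")
        n_eff = self.resolved_n_effects()
        if n_eff > self.n_snps * self.n_mirnas or n_eff > self.n_mirnas:
            raise ContractError("too many planted effects for the grid size")

    def resolved_n_effects(self) -> int:
        if self.n_effects is not None:
            return int(self.n_effects)
        if self.n_snps == 0:
            return 0
        return int(round(self.effect_fraction * self.n_mirnas))


@dataclass(frozen=True)
class TruthEntry:
    snp_id: str
    mirna_id: str
    tissue: str          # "normal": both tissues; "differential": carcinoma only
    effect_size: float   # signed, in residual-SD units on the log2 scale


@dataclass
class SyntheticTruth:
    """Registry of planted effects; the null set is the complement."""

    entries: list[TruthEntry] = field(default_factory=list)

    def affected_pairs(self, tissue: str) -> set[tuple[str, str]]:
        """(SNP, miRNA) pairs that are non-null for a scan of ``tissue``.

        Effects planted in "normal" shift normal and carcinoma signal
        alike (and so cancel in the paired difference); "differential"
        effects shift carcinoma only and surface in both the carcinoma
        and differential scans.
        """
        if tissue == "normal":
            keep = {"normal"}
        elif tissue == "carcinoma":
            keep = {"normal", "differential"}
        elif tissue == "differential":
            keep = {"differential"}
        else:
            raise ContractError(f"unknown tissue {tissue!r}")
        return {(e.snp_id, e.mirna_id) for e in self.entries if e.tissue in keep}


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    pd.DataFrame(
        [(e.snp_id, e.mirna_id, e.tissue, e.effect_size) for e in truth.entries],
        columns=["snp_id", "mirna_id", "tissue", "effect_size"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> SyntheticTruth:
    frame = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "mirna_id": str,
                                               "tissue": str})
    entries = [TruthEntry(r.snp_id, r.mirna_id, r.tissue, float(r.effect_size))
               for r in frame.itertuples()]
    return SyntheticTruth(entries)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _snp_ids(n: int) -> list[str]:
    return [f"snp{i + 1:03d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1:04d}" for i in range(n)]


def generate_covariates(params: SimulationParams,
                        rng: np.random.Generator) -> CovariateTable:
    """Case covariates with site-specific age, sex and race distributions."""
    n = params.n_samples
    ids = _sample_ids(n)
    site = np.array(["rectal"] * n, dtype=object)
    n_colon = int(round(n * params.colon_fraction))
    site[rng.permutation(n)[:n_colon]] = "colon"

    age = np.empty(n)
    sex = np.empty(n, dtype=object)
    race = np.empty(n, dtype=object)
    for s in ("colon", "rectal"):
        mask = site == s
        k = int(mask.sum())
        age[mask] = np.clip(rng.normal(params.age_mean[s], params.age_sd[s], k),
                            *params.age_bounds)
        sex[mask] = np.where(rng.random(k) < params.male_fraction[s],
                             "male", "female")
        race[mask] = rng.choice(params.race_levels, size=k, p=params.race_probs[s])

    n_pair = int(round(n * params.fraction_with_carcinoma_pair))
    paired = np.zeros(n, dtype=bool)
    paired[rng.choice(n, size=n_pair, replace=False)] = True

    frame = pd.DataFrame({"age": age, "sex": sex, "race": race, "site": site,
                          "has_carcinoma_pair": paired}, index=pd.Index(ids, name="sample_id"))
    return CovariateTable(frame)


def generate_genotypes(params: SimulationParams,
                       rng: np.random.Generator,
                       missing_rate: float = 0.0) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: calls ~ Binomial(2, MAF) per sample.

    Each SNP's MAF is drawn uniformly from ``maf_range``.  An optional
    missingness rate masks calls completely at random.
    """
    n_snps, n = params.n_snps, params.n_samples
    maf = rng.uniform(*params.maf_range, size=n_snps)
    calls = rng.binomial(2, maf[:, None], size=(n_snps, n)).astype(float)
    if missing_rate > 0:
        calls[rng.random((n_snps, n)) < missing_rate] = np.nan
    frame = pd.DataFrame(calls, index=pd.Index(_snp_ids(n_snps), name="snp_id"),
                         columns=_sample_ids(n))
    return GenotypeMatrix(frame)


def generate_snp_specs(params: SimulationParams,
                       rng: np.random.Generator) -> list[SnpSpec]:
    """Per-SNP inheritance models: dominant with prob ``dominant_fraction``."""
    specs = []
    for i, snp in enumerate(_snp_ids(params.n_snps)):
        model = "dominant" if rng.random() < params.dominant_fraction else "recessive"
        specs.append(SnpSpec(snp, f"gene{i % 21 + 1}", model, "A"))
    return specs


def generate_truth(params: SimulationParams,
                   rng: np.random.Generator) -> SyntheticTruth:
    """Plant signed effects on distinct miRNAs, one SNP per affected miRNA."""
    n_eff = params.resolved_n_effects()
    if n_eff == 0 or params.n_snps == 0:
        return SyntheticTruth([])
    mirnas = rng.choice(_mirna_ids(params.n_mirnas), size=n_eff, replace=False)
    snps = rng.choice(_snp_ids(params.n_snps), size=n_eff, replace=True)
    sizes = rng.uniform(*params.effect_size_range, size=n_eff)
    signs = rng.choice([-1.0, 1.0], size=n_eff)
    tissues = np.where(rng.random(n_eff) < params.differential_effect_fraction,
                       "differential", "normal")
    entries = [TruthEntry(str(s), str(m), str(t), float(sz * sg))
               for s, m, t, sz, sg in zip(snps, mirnas, tissues, sizes, signs)]
    return SyntheticTruth(entries)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_expression(params: SimulationParams,
                        genotypes: GenotypeMatrix,
                        covariates: CovariateTable,
                        snp_specs: Sequence[SnpSpec],
                        truth: SyntheticTruth,
                        rng: np.random.Generator
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix | None]:
    """Array signal for normal mucosa and (paired) carcinoma tissue.

    log2 signal = probe baseline + planted effect * genotype indicator
    + small covariate effects + Gaussian noise; raw signal is 2^log2
    scaled by a lognormal per-sample array factor, with detection-driven
    dropout zeroing a Beta-distributed per-probe fraction of samples.
    Carcinoma adds a probe-specific tumor shift and the carcinoma-only
    planted effects, for paired samples only.  Genotype calls must be
    complete (plant from true genotypes; mask missingness afterwards).
    """
    m, n = params.n_mirnas, params.n_samples
    mirnas = _mirna_ids(m)
    mirna_index = {mid: i for i, mid in enumerate(mirnas)}
    samples = covariates.sample_ids
    spec_by_id = {s.snp_id: s for s in snp_specs}

    baseline = rng.uniform(*params.baseline_log2_range, size=m)
    sd = rng.uniform(*params.residual_sd_range, size=m)

    cov = covariates.frame
    z = np.vstack([
        _standardize(cov["age"].to_numpy(dtype=float)),
        _standardize((cov["sex"] == "male").to_numpy(dtype=float)),
        _standardize((cov["race"] != "white").to_numpy(dtype=float)),
    ])
    signs = rng.choice([-1.0, 1.0], size=(m, 3))
    scale = np.sqrt(params.covariate_variance_fraction)
    mean_log2 = baseline[:, None] + (sd[:, None] * scale) * (signs @ z)

    def _indicator(entry: TruthEntry) -> np.ndarray:
        if entry.snp_id not in spec_by_id or entry.mirna_id not in mirna_index:
            raise ContractError(f"truth references unknown id {entry.snp_id}/{entry.mirna_id}")
        calls = genotypes.calls.loc[entry.snp_id, samples].to_numpy(dtype=float)
        if np.isnan(calls).any():
            raise ContractError("plant effects from complete genotype calls")
        model = spec_by_id[entry.snp_id].model
        return (calls >= 1).astype(float) if model == "dominant" else (calls == 2).astype(float)

    normal_mean = mean_log2.copy()
    carc_extra = np.zeros_like(mean_log2)
    for entry in truth.entries:
        ind = _indicator(entry)
        shift = entry.effect_size * sd[mirna_index[entry.mirna_id]] * ind
        if entry.tissue == "normal":
            normal_mean[mirna_index[entry.mirna_id]] += shift
        else:
            carc_extra[mirna_index[entry.mirna_id]] += shift

    tumor_shift = rng.normal(0.0, params.tumor_shift_sd, size=m)
    if params.dropout_rate > 0:
        a = params.dropout_rate * params.dropout_concentration
        b = (1.0 - params.dropout_rate) * params.dropout_concentration
        dropout = rng.beta(a, b, size=m)
    else:
        dropout = np.zeros(m)

    def _tissue_matrix(mean: np.ndarray, cols: list[str], tissue: str) -> ExpressionMatrix:
        k = len(cols)
        col_idx = [samples.index(c) for c in cols]
        log2sig = mean[:, col_idx] + rng.normal(0.0, 1.0, size=(m, k)) * sd[:, None]
        array_scale = np.exp(rng.normal(0.0, params.sample_scale_sd, size=k))
        signal = np.exp2(log2sig) * array_scale
        detected = rng.random((m, k)) >= dropout[:, None]
        signal = np.where(detected, signal, 0.0)
        idx = pd.Index(mirnas, name="probe_id")
        return ExpressionMatrix(pd.DataFrame(signal, index=idx, columns=cols), tissue,
                                pd.DataFrame(detected, index=idx, columns=cols))

    normal = _tissue_matrix(normal_mean, samples, "normal")
    paired = [s for s, flag in zip(samples, cov["has_carcinoma_pair"]) if flag]
    carcinoma = None
    if paired:
        carc_mean = normal_mean + carc_extra + tumor_shift[:, None]
        carcinoma = _tissue_matrix(carc_mean, paired, "carcinoma")
    return normal, carcinoma


@dataclass
class SyntheticCohort:
    """In-memory bundle of everything the generator produces."""

    normal: ExpressionMatrix
    carcinoma: ExpressionMatrix | None
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    snp_specs: list[SnpSpec]
    truth: SyntheticTruth


def generate_cohort(params: SimulationParams,
                    out_dir: str | Path | None = None
                    ) -> tuple[SyntheticCohort, SyntheticTruth]:
    """Generate a full cohort, optionally writing the exchange files.

    Fully deterministic given ``params.master_seed``: each stage draws
    from its own child stream of the master seed, so e.g. changing the
    missingness rate does not perturb the expression noise.
    """
    streams = np.random.SeedSequence(params.master_seed).spawn(6)
    r_cov, r_gen, r_spec, r_truth, r_expr, r_miss = map(np.random.default_rng, streams)

    covariates = generate_covariates(params, r_cov)
    genotypes_complete = generate_genotypes(params, r_gen, missing_rate=0.0)
    snp_specs = generate_snp_specs(params, r_spec)
    truth = generate_truth(params, r_truth)
    normal, carcinoma = generate_expression(
        params, genotypes_complete, covariates, snp_specs, truth, r_expr)

    calls = genotypes_complete.calls.to_numpy(copy=True)
    if params.genotype_missing_rate > 0:
        calls[r_miss.random(calls.shape) < params.genotype_missing_rate] = np.nan
    genotypes = GenotypeMatrix(pd.DataFrame(
        calls, index=genotypes_complete.calls.index,
        columns=genotypes_complete.calls.columns))

    cohort = SyntheticCohort(normal, carcinoma, genotypes, covariates,
                             snp_specs, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_expression(normal, out / "expression_normal.tsv",
                             out / "detection_normal.tsv")
        if carcinoma is not None:
            mio.write_expression(carcinoma, out / "expression_carcinoma.tsv",
                                 out / "detection_carcinoma.tsv")
        mio.write_genotypes(genotypes, out / "genotypes.tsv")
        mio.write_covariates(covariates, out / "covariates.tsv")
        mio.write_snp_specs(snp_specs, out / "snp_specs.tsv")
        write_truth(truth, out / "truth.tsv")
    return cohort, truth
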