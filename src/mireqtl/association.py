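"""Covariate-adjusted association tests with residual-bootstrap p-values.

For each (SNP, miRNA) pair the genotype is collapsed to a binary
indicator under the SNP's dominant or recessive model, and the miRNA
response is regressed on the indicator adjusting for age at diagnosis,
sex and race/ethnicity by least squares.  Significance comes from the
1-df nested F statistic for the indicator, referred to a null
distribution built by resampling the residuals of the covariate-only
fit (default 10,000 replicates).

The per-pair p-value uses the (1 + exceedances) / (B + 1) convention,
so its resolution is 1/(B+1) and it can never be exactly zero.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AnalysisCohort, ExpressionMatrix, SnpSpec
from .errors import (
    ConfigurationError,
    ContractError,
    DegenerateFitError,
    UntestableSnpError,
)

log = logging.getLogger(__name__)

UPREGULATED = "Upregulated"
DOWNREGULATED = "Downregulated"

_GROUP_LABELS = {
    "dominant": ("0 copies", "1-2 copies"),
    "recessive": ("0-1 copies", "2 copies"),
}


@dataclass
class GenotypeIndicator:
    """Binary genotype grouping for one SNP over its complete-case samples.

    ``g`` is an int8 Series indexed by sample id (1 = variant group);
    samples with a missing call are absent from the index.
    """

    g: pd.Series
    reference_group: str
    variant_group: str

    @property
    def n_ref(self) -> int:
        return int((self.g == 0).sum())

    @property
    def n_var(self) -> int:
        return int((self.g == 1).sum())


def encode_genotype(calls: pd.Series, model: str) -> GenotypeIndicator:
    """Collapse allele counts to the binary test indicator.

    Dominant: carriers (calls 1 or 2) form the variant group.  Recessive:
    variant homozygotes (call 2) form it.  Missing calls are excluded
    (per-SNP complete-case analysis).  A constant indicator raises
    :class:`UntestableSnpError`.
    """
    if model not in _GROUP_LABELS:
        raise ContractError(f"unknown inheritance model {model!r}")
    obs = calls.dropna().astype(float)
    bad = set(obs.unique()) - {0.0, 1.0, 2.0}
    if bad:
        raise ContractError(f"genotype calls outside {{0,1,2}}: {sorted(bad)}")
    g = (obs >= 1) if model == "dominant" else (obs == 2)
    g = g.astype(np.int8)
    ref_label, var_label = _GROUP_LABELS[model]
    name = calls.name or "SNP"
    if len(g) == 0 or g.min() == g.max():
        raise UntestableSnpError(
            f"{name}: constant {model} indicator "
            f"({int(g.sum()) if len(g) else 0} of {len(g)} in variant group)")
    return GenotypeIndicator(g, ref_label, var_label)


@dataclass
class DesignPair:
    """Null (covariate-only) and full (plus genotype) design matrices."""

    X_null: np.ndarray
    X_full: np.ndarray
    null_columns: list[str]
    sample_ids: list[str]


def _dummy_columns(series: pd.Series, prefix: str) -> dict[str, np.ndarray]:
    """Treatment-coded dummies with the largest level as reference.

    Ties on the count break by level name so the design is deterministic.
    A single observed level contributes no columns.
    """
    s = series.astype(str)
    counts = s.value_counts()
    levels = sorted(counts.index, key=lambda lv: (-counts[lv], lv))
    return {f"{prefix}[{lv}]": (s == lv).to_numpy(dtype=float) for lv in levels[1:]}


def build_design(covariates: pd.DataFrame, indicator: GenotypeIndicator) -> DesignPair:
    """Intercept + centered age + sex/race dummies; full adds the indicator.

    Covariates are taken for exactly the indicator's (complete-case)
    samples.  Columns that become linearly dependent after subsetting are
    dropped with a logged note.
    """
    samples = list(indicator.g.index)
    missing = [s for s in samples if s not in covariates.index]
    if missing:
        raise ContractError(f"covariates missing for sample(s) {missing[:5]}")
    cov = covariates.loc[samples]
    if cov[["age", "sex", "race"]].isna().any().any():
        raise ContractError("missing covariate values among analyzed samples")

    n = len(samples)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    age = cov["age"].to_numpy(dtype=float)
    cols["age"] = age - age.mean()
    cols.update(_dummy_columns(cov["sex"], "sex"))
    cols.update(_dummy_columns(cov["race"], "race"))

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    keep = _independent_columns(X)
    if len(keep) < len(names):
        dropped = [names[i] for i in range(len(names)) if i not in keep]
        log.info("dropped rank-deficient design column(s): %s", dropped)
        names = [names[i] for i in keep]
        X = X[:, keep]
    g = indicator.g.to_numpy(dtype=float)
    return DesignPair(X, np.column_stack([X, g]), names, samples)


def _independent_columns(X: np.ndarray, rtol: float = 1e-10) -> list[int]:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return []
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.count_nonzero(diag > rtol * (diag[0] if diag.size else 1.0)))
    return sorted(piv[:rank].tolist())


class NestedOLS:
    """Precomputed projections for the 1-df nested F comparison.

    Decomposes the full design into an orthonormal basis ``Q`` of the
    covariate-only column space and the unit vector ``u`` along the part
    of the genotype indicator orthogonal to it, after which each response
    costs two matrix-vector products:

        RSS_null = |y|^2 - |Q'y|^2,   RSS_full = RSS_null - (u'y)^2,
        F = (u'y)^2 / (RSS_full / (n - p_full)).
    """

    def __init__(self, designs: DesignPair):
        Xn, Xf = np.asarray(designs.X_null, float), np.asarray(designs.X_full, float)
        n = Xn.shape[0]
        if n <= Xf.shape[1]:
            raise ContractError(
                f"need more samples ({n}) than design columns ({Xf.shape[1]})")
        self.Q, _ = np.linalg.qr(Xn)
        g = Xf[:, -1]
        g_perp = g - self.Q @ (self.Q.T @ g)
        norm = float(np.linalg.norm(g_perp))
        if norm <= 1e-8 * max(1.0, float(np.linalg.norm(g))):
            raise UntestableSnpError("genotype indicator is collinear with covariates")
        self.u = g_perp / norm
        self.n = n
        self.dof = n - Xf.shape[1]

    def fitted_null(self, y: np.ndarray) -> np.ndarray:
        return self.Q @ (self.Q.T @ y)

    def null_residuals(self, y: np.ndarray) -> np.ndarray:
        return y - self.fitted_null(y)

    def leverage(self) -> np.ndarray:
        return (self.Q ** 2).sum(axis=1)

    def f_stat(self, y) -> float:
        y = np.asarray(y, dtype=float)
        qy = self.Q.T @ y
        rss_null = max(float(y @ y - qy @ qy), 0.0)
        t = float(self.u @ y)
        rss_full = max(rss_null - t * t, 0.0)
        tol = 1e-12 * max(1.0, float(y @ y))
        if rss_null <= tol:
            return 0.0  # y already explained by the covariates: no added power
        if rss_full <= tol:
            raise DegenerateFitError("full model has (numerically) zero residual variance")
        return (t * t) / (rss_full / self.dof)

    def f_stats(self, Y: np.ndarray) -> np.ndarray:
        """Vectorized F statistics for responses in the rows of ``Y``."""
        Y = np.asarray(Y, dtype=float)
        qy = Y @ self.Q
        t = Y @ self.u
        rss_null = np.maximum((Y * Y).sum(axis=1) - (qy * qy).sum(axis=1), 0.0)
        rss_full = np.maximum(rss_null - t * t, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (t * t) * self.dof / rss_full
        # a degenerate resample (constant response) counts as an exceedance
        return np.where(np.isfinite(f), f, np.inf)


def f_statistic(y, designs: DesignPair) -> float:
    """1-df nested F statistic for the genotype term."""
    return NestedOLS(designs).f_stat(y)


@dataclass
class BootstrapConfig:
    """Residual-bootstrap settings.

    ``n_reps`` replicates (default 10,000) of the null-model F statistic
    are produced by resampling the centered covariate-only residuals with
    replacement; ``residual_scheme='leverage'`` switches to
    leverage-adjusted residuals e_i / sqrt(1 - h_ii).  The tail rule is
    fixed: replicate statistics >= the observed one count as exceedances.
    """

    n_reps: int = 10_000
    master_seed: int = 0
    residual_scheme: str = "raw"
    tail_rule = "greater-or-equal"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.residual_scheme not in ("raw", "leverage"):
            raise ConfigurationError("residual_scheme must be 'raw' or 'leverage'")


def task_seed(master_seed: int, snp_id: str, mirna_id: str,
              stratum: str, tissue: str) -> np.random.SeedSequence:
    """Deterministic per-task seed independent of execution order."""
    key = f"{snp_id}\x1f{mirna_id}\x1f{stratum}\x1f{tissue}".encode()
    word = int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big")
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, word >> 32, word & 0xFFFFFFFF])


def bootstrap_null_pvalue(y, designs: DesignPair,
                          config: BootstrapConfig | None = None,
                          *, rng: np.random.Generator | None = None,
                          engine: NestedOLS | None = None) -> tuple[float, float]:
    """Residual-bootstrap p-value for the genotype F statistic.

    Fits the null (covariate-only) model, centers its residuals, and for
    each replicate forms y* = X_null b_null + resample(e) and scores its
    F statistic; p = (1 + #{F* >= F_obs}) / (B + 1).
    """
    config = config or BootstrapConfig()
    engine = engine or NestedOLS(designs)
    y = np.asarray(y, dtype=float)
    f_obs = engine.f_stat(y)
    e = engine.null_residuals(y)
    if config.residual_scheme == "leverage":
        e = e / np.sqrt(np.clip(1.0 - engine.leverage(), 1e-8, None))
    e = e - e.mean()
    if rng is None:
        rng = np.random.default_rng(config.master_seed)
    idx = rng.integers(0, engine.n, size=(config.n_reps, engine.n))
    # F ignores the column space of X_null, so adding the null fitted
    # values to each resample would change nothing: score residuals as-is.
    f_star = engine.f_stats(e[idx])
    p = (1 + int(np.count_nonzero(f_star >= f_obs))) / (config.n_reps + 1)
    return p, f_obs


def group_means(reporting_values: pd.Series,
                indicator: GenotypeIndicator) -> tuple[float, float, str]:
    """Arithmetic genotype-group means on the reporting scale, plus direction.

    Direction is Upregulated iff the variant-group mean exceeds the
    reference-group mean; exact ties are labelled Downregulated (and
    logged) so the binary label stays deterministic.
    """
    vals = reporting_values.loc[indicator.g.index]
    ref = vals[indicator.g == 0]
    var = vals[indicator.g == 1]
    if ref.empty or var.empty:
        raise ContractError("both genotype groups must be non-empty")
    mean_ref, mean_var = float(ref.mean()), float(var.mean())
    if mean_var == mean_ref:
        log.info("direction tie for %s: labelled %s", reporting_values.name, DOWNREGULATED)
    direction = UPREGULATED if mean_var > mean_ref else DOWNREGULATED
    return mean_ref, mean_var, direction


@dataclass
class AssociationResult:
    """One (SNP, miRNA, stratum, tissue) test with reporting-scale means."""

    snp_id: str
    mirna_id: str
    gene: str
    model: str
    stratum: str
    tissue: str
    n_ref: int
    n_var: int
    ref_group: str
    var_group: str
    mean_ref: float
    mean_var: float
    f_obs: float
    p_boot: float
    direction: str
    fdr_adjusted_p: float | None = None
    q_value: float | None = None
    important: bool | None = None
    q_significant: bool | None = None


def stratum_samples(covariates: pd.DataFrame, samples: list[str], stratum: str) -> list[str]:
    """Samples of ``samples`` belonging to a tumor-site stratum."""
    if stratum == "colorectal":
        return list(samples)
    if stratum not in ("colon", "rectal"):
        raise ContractError(f"unknown stratum {stratum!r}")
    site = covariates["site"].astype(str)
    return [s for s in samples if site.get(s) == stratum]


def run_scan(cohort: AnalysisCohort, snp_specs, tissue: str = "normal",
             stratum: str = "colorectal",
             config: BootstrapConfig | None = None,
             *, expression: ExpressionMatrix | None = None,
             log2_offset: float = 1.0) -> list[AssociationResult]:
    """Bootstrap-F scan of every (SNP, retained miRNA) pair.

    ``expression`` defaults to the cohort's aligned matrix for the tissue
    and is expected to be normalized and probe-filtered for this stratum.
    The response is log2(signal + log2_offset) for measured tissue and
    the raw paired difference for differential tissue; group means are
    always reported on the matrix's own (normalized or difference) scale.
    Untestable SNPs are logged and skipped; the scan never aborts on
    per-SNP degeneracies.  Deterministic given ``config.master_seed``.
    """
    config = config or BootstrapConfig()
    expr = expression if expression is not None else cohort.expression[tissue]
    samples = stratum_samples(cohort.covariates.frame,
                              [s for s in expr.sample_ids], stratum)
    results: list[AssociationResult] = []
    if not snp_specs or not expr.probe_ids or not samples:
        return results

    reporting = expr.values[samples]
    if tissue == "differential":
        response = reporting
    else:
        response = np.log2(reporting + log2_offset)
    cov = cohort.covariates.frame
    probe_ids = expr.probe_ids

    for spec in snp_specs:
        if spec.snp_id not in cohort.genotypes.calls.index:
            raise ConfigurationError(f"SNP {spec.snp_id!r} absent from genotype matrix")
        calls = cohort.genotypes.calls.loc[spec.snp_id, samples]
        calls.name = spec.snp_id
        try:
            indicator = encode_genotype(calls, spec.model)
        except UntestableSnpError as exc:
            log.warning("skipping untestable SNP: %s", exc)
            continue
        analyzed = list(indicator.g.index)
        designs = build_design(cov, indicator)
        try:
            engine = NestedOLS(designs)
        except UntestableSnpError as exc:
            log.warning("skipping SNP %s: %s", spec.snp_id, exc)
            continue
        y_mat = response[analyzed].to_numpy(dtype=float)
        rep_mat = reporting[analyzed].to_numpy(dtype=float)
        gmask = indicator.g.to_numpy(dtype=bool)
        for row, mirna in enumerate(probe_ids):
            rng = np.random.default_rng(
                task_seed(config.master_seed, spec.snp_id, mirna, stratum, tissue))
            try:
                p_boot, f_obs = bootstrap_null_pvalue(
                    y_mat[row], designs, config, rng=rng, engine=engine)
            except DegenerateFitError:
                log.warning("degenerate fit for (%s, %s); pair skipped",
                            spec.snp_id, mirna)
                continue
            rvals = rep_mat[row]
            mean_ref = float(rvals[~gmask].mean())
            mean_var = float(rvals[gmask].mean())
            direction = UPREGULATED if mean_var > mean_ref else DOWNREGULATED
            results.append(AssociationResult(
                snp_id=spec.snp_id, mirna_id=mirna, gene=spec.gene,
                model=spec.model, stratum=stratum, tissue=tissue,
                n_ref=indicator.n_ref, n_var=indicator.n_var,
                ref_group=indicator.reference_group,
                var_group=indicator.variant_group,
                mean_ref=mean_ref, mean_var=mean_var,
                f_obs=f_obs, p_boot=p_boot, direction=direction))
    return results
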