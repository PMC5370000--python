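"""Calibration experiments for the screening pipeline.

These helpers run the full pipeline (generate, normalize, filter, scan,
adjust) on replicate synthetic families and summarise error-control
quantities against the planted truth.  They back the package's
reproducibility script and its calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import BootstrapConfig, run_scan
from .datamodel import align_cohort
from .multitest import DecisionConfig, decide
from .normalize import FilterConfig, apply_normalization, compute_scaling_factors, filter_probes
from .simulate import SimulationParams, generate_cohort


@dataclass
class FdrCalibrationResult:
    """Per-family realized false-discovery proportions and summaries."""

    fdp: np.ndarray            # realized FDP per family (0 when nothing flagged)
    n_discoveries: np.ndarray  # flagged associations per family
    n_false: np.ndarray        # flagged true nulls per family
    fdr_threshold: float

    @property
    def n_families(self) -> int:
        return int(self.fdp.size)

    @property
    def mean_fdp(self) -> float:
        return float(self.fdp.mean())

    @property
    def sem_fdp(self) -> float:
        return float(self.fdp.std(ddof=1) / np.sqrt(self.fdp.size))


def scan_family(params: SimulationParams, n_boot: int,
                fdr_threshold: float = 0.09,
                filter_config: FilterConfig | None = None):
    """Full pipeline on one synthetic family.

    A family is the generated SNP set scanned against every retained
    miRNA in normal tissue of the combined colorectal stratum: generate
    the cohort, normalize the arrays, apply the expression filter, run
    the bootstrap F scan and adjust with BH within per-SNP families.
    Returns (decided results, truth registry).
    """
    cohort, truth = generate_cohort(params)
    factors = compute_scaling_factors(cohort.normal)
    normed = apply_normalization(cohort.normal, factors)
    filtered, _ = filter_probes(normed, filter_config or FilterConfig())
    aligned, _ = align_cohort({"normal": filtered}, cohort.genotypes,
                              cohort.covariates)
    results = run_scan(aligned, cohort.snp_specs, "normal", "colorectal",
                       BootstrapConfig(n_reps=n_boot,
                                       master_seed=params.master_seed))
    decide(results, DecisionConfig(fdr_threshold=fdr_threshold))
    return results, truth


def run_family(params: SimulationParams, n_boot: int,
               fdr_threshold: float = 0.09,
               filter_config: FilterConfig | None = None
               ) -> tuple[int, int]:
    """One family's (discoveries, false discoveries) at the BH threshold."""
    results, truth = scan_family(params, n_boot, fdr_threshold, filter_config)
    true_pairs = truth.affected_pairs("normal")
    flagged = [r for r in results if r.important]
    n_false = sum((r.snp_id, r.mirna_id) not in true_pairs for r in flagged)
    return len(flagged), n_false


def fdr_calibration(n_families: int = 100, *, n_samples: int = 300,
                    n_mirnas: int = 400, n_boot: int = 500,
                    maf: float = 0.3, effect_fraction: float = 0.10,
                    effect_size_range: tuple[float, float] = (0.5, 1.5),
                    dropout_rate: float = 0.20,
                    fdr_threshold: float = 0.09,
                    seed: int = 0) -> FdrCalibrationResult:
    """Realized FDP of the full pipeline over replicate synthetic families.

    Each family plants effects on ``effect_fraction`` of the miRNAs (90%
    true nulls by default) and flags associations at BH-adjusted
    p < ``fdr_threshold``; families with no discoveries contribute an
    FDP of zero, matching the quantity BH controls in expectation.
    """
    rng = np.random.default_rng(seed)
    family_seeds = rng.integers(0, 2**31 - 1, size=n_families)
    fdp = np.zeros(n_families)
    n_disc = np.zeros(n_families, dtype=int)
    n_false = np.zeros(n_families, dtype=int)
    for i, fam_seed in enumerate(family_seeds):
        params = SimulationParams(
            n_samples=n_samples, n_snps=1, n_mirnas=n_mirnas,
            fraction_with_carcinoma_pair=0.0,
            maf_range=(maf, maf), effect_fraction=effect_fraction,
            effect_size_range=effect_size_range,
            differential_effect_fraction=0.0,
            dropout_rate=dropout_rate,
            master_seed=int(fam_seed))
        d, f = run_family(params, n_boot, fdr_threshold)
        n_disc[i], n_false[i] = d, f
        fdp[i] = f / d if d else 0.0
    return FdrCalibrationResult(fdp, n_disc, n_false, fdr_threshold)
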