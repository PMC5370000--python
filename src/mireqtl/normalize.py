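"""Scaling-factor normalization and the expression-proportion probe filter.

Arrays are put on a common scale by multiplying each sample by
``m / Q75_i`` where ``Q75_i`` is that sample's 75th percentile of total
gene signal and ``m`` is the median of the per-sample 75th percentiles.
Probes are then filtered to those expressed in at least a configurable
fraction of the analyzed samples (default 20%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix
from .errors import ContractError, DegenerateSampleError

log = logging.getLogger(__name__)

DETECTION_RULES = ("auto", "flag", "positive", "threshold")


def percentile75(values) -> float:
    """75th percentile under linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ContractError("percentile75 of an empty vector")
    if not np.isfinite(arr).all():
        raise ContractError("percentile75 requires finite values")
    return float(np.percentile(arr, 75))


@dataclass
class NormalizationFactors:
    """Per-sample scaling factors and the shared reference value.

    ``factors[i] * Q75_i == reference`` for every sample i, so after
    application every sample's 75th percentile equals ``reference``.
    """

    factors: pd.Series
    reference: float

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ContractError("scaling factors must be positive and finite")


def compute_scaling_factors(matrix: ExpressionMatrix,
                            reference: float | None = None) -> NormalizationFactors:
    """Scaling factor per sample: ``median_j(Q75_j) / Q75_i``.

    ``reference`` overrides the median, which lets several matrices (e.g.
    normal and carcinoma arrays of the same cases) be normalized against
    one shared value so they land on a common scale.
    """
    if not matrix.sample_ids:
        raise ContractError("cannot normalize a matrix with no samples")
    q75 = matrix.values.apply(lambda col: percentile75(col.to_numpy()), axis=0)
    bad = q75.index[q75 <= 0]
    if len(bad):
        raise DegenerateSampleError(
            f"sample {bad[0]!r} has non-positive 75th percentile ({q75[bad[0]]}); "
            "cannot compute a scaling factor")
    ref = float(np.median(q75.to_numpy())) if reference is None else float(reference)
    return NormalizationFactors(ref / q75, ref)


def apply_normalization(matrix: ExpressionMatrix,
                        factors: NormalizationFactors) -> ExpressionMatrix:
    """Multiply each sample column by its scaling factor."""
    missing = [s for s in matrix.sample_ids if s not in factors.factors.index]
    if missing:
        raise ContractError(f"no scaling factor for sample(s) {missing[:5]}")
    scaled = matrix.values * factors.factors[matrix.sample_ids]
    return ExpressionMatrix(scaled, matrix.tissue, matrix.detection)


@dataclass
class FilterConfig:
    """Probe-retention rule: minimum expressed fraction and detection rule.

    ``detection_rule``:

    - ``auto`` (default): use the detection-flag matrix when the
      expression matrix carries one, otherwise fall back to positive
      signal;
    - ``flag``: require the detection-flag matrix;
    - ``positive``: expressed means signal > 0;
    - ``threshold``: expressed means signal > ``threshold``.
    """

    min_expressed_proportion: float = 0.20
    detection_rule: str = "auto"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.min_expressed_proportion <= 1):
            raise ContractError("min_expressed_proportion must lie in (0, 1]")
        if self.detection_rule not in DETECTION_RULES:
            raise ContractError(
                f"detection_rule {self.detection_rule!r} not one of {DETECTION_RULES}")


def _expressed(values: np.ndarray, detection: np.ndarray | None,
               config: FilterConfig) -> np.ndarray:
    rule = config.detection_rule
    if rule == "auto":
        rule = "flag" if detection is not None else "positive"
    if rule == "flag":
        if detection is None:
            raise ContractError("detection_rule='flag' but no detection matrix supplied")
        return detection.astype(bool)
    if rule == "positive":
        return values > 0
    return values > config.threshold


def expression_proportion(probe_row, detection_row=None,
                          config: FilterConfig | None = None) -> float:
    """Fraction of samples in which a probe counts as expressed."""
    config = config or FilterConfig()
    values = np.asarray(probe_row, dtype=float)
    if values.size == 0:
        raise ContractError("expression_proportion of an empty row")
    det = None if detection_row is None else np.asarray(detection_row, dtype=bool)
    return float(_expressed(values, det, config).mean())


def filter_probes(matrix: ExpressionMatrix,
                  config: FilterConfig | None = None
                  ) -> tuple[ExpressionMatrix, list[str]]:
    """Retain probes expressed in at least ``min_expressed_proportion`` of samples.

    Returns the filtered matrix and the list of dropped probe ids.  The
    proportion is computed over exactly the samples present in
    ``matrix``, so per-stratum retention uses each stratum's own samples.
    """
    config = config or FilterConfig()
    values = matrix.values.to_numpy(dtype=float)
    det = None if matrix.detection is None else matrix.detection.to_numpy()
    mask = _expressed(values, det, config)
    props = mask.mean(axis=1) if values.size else np.zeros(values.shape[0])
    keep = props >= config.min_expressed_proportion
    dropped = [p for p, k in zip(matrix.probe_ids, keep) if not k]
    if not keep.any():
        warnings.warn("probe filter dropped every probe", stacklevel=2)
        log.warning("probe filter dropped all %d probes", len(dropped))
    kept_ids = [p for p, k in zip(matrix.probe_ids, keep) if k]
    return matrix.subset_probes(kept_ids), dropped
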