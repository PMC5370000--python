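"""Benjamini-Hochberg FDR adjustment, Storey q-values, decision rule.

Adjustment families are one SNP's full scan within a stratum and tissue,
i.e. m equals the number of miRNAs retained by the expression filter for
that stratum.  Associations are declared important when the BH-adjusted
p-value falls below the FDR threshold (default 0.09); a secondary flag
marks q-values below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError

log = logging.getLogger(__name__)


def _validated(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ContractError("p-values must form a 1-d vector")
    if p.size and (not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any()):
        raise ContractError("p-values must lie in (0, 1]")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj(i) = min over j >= i (in the ascending sort) of min(1, p(j)*m/j).
    """
    p = _validated(pvalues)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def estimate_pi0(pvalues, lam: float = 0.5) -> float:
    """Storey's null-proportion estimate at a single lambda, floored at 1/m."""
    p = _validated(pvalues)
    if p.size == 0:
        raise ContractError("cannot estimate pi0 from an empty vector")
    pi0 = np.count_nonzero(p > lam) / (p.size * (1.0 - lam))
    return float(min(1.0, max(pi0, 1.0 / p.size)))


def storey_qvalues(pvalues, lam: float = 0.5) -> np.ndarray:
    """q-values: pi0-rescaled BH-adjusted p-values (single-lambda Storey)."""
    p = _validated(pvalues)
    if p.size == 0:
        return p.copy()
    return estimate_pi0(p, lam) * bh_adjust(p)


@dataclass
class DecisionConfig:
    """Significance thresholds for the screening decision."""

    fdr_threshold: float = 0.09
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "q_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ContractError(f"{name} must lie in (0, 1)")


def decide(results: Sequence, config: DecisionConfig | None = None) -> list:
    """Adjust p-values within each (SNP, stratum, tissue) family and flag.

    Mutates each AssociationResult in place, filling ``fdr_adjusted_p``,
    ``q_value``, ``important`` (BH-adjusted p < fdr_threshold) and
    ``q_significant`` (q < q_threshold); returns the same list.
    """
    config = config or DecisionConfig()
    families: dict[tuple, list[int]] = {}
    for i, r in enumerate(results):
        families.setdefault((r.snp_id, r.stratum, r.tissue), []).append(i)
    for key, idx in families.items():
        if not idx:
            log.info("empty adjustment family %s skipped", key)
            continue
        p = np.array([results[i].p_boot for i in idx])
        adj = bh_adjust(p)
        q = storey_qvalues(p)
        for j, i in enumerate(idx):
            results[i].fdr_adjusted_p = float(adj[j])
            results[i].q_value = float(q[j])
            results[i].important = bool(adj[j] < config.fdr_threshold)
            results[i].q_significant = bool(q[j] < config.q_threshold)
    return list(results)
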