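"""Tab-delimited exchange formats.

All matrices are written with the feature id (probe or SNP) in the first
column and sample ids as the header row.  Missing genotypes use the token
``NA``.  Floats are written with Python's shortest round-tripping repr,
so write-then-read reproduces values bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    SnpSpec,
)
from .errors import ParseError

_GENO_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}

SNP_SPEC_COLUMNS = ("snp_id", "gene", "model", "variant_allele")


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    # check the header ourselves: read_csv silently renames duplicates
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for col in header[1:]:
        if col in seen:
            raise ParseError(f"{what} file {path}: duplicated sample column {col!r}")
        seen.add(col)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          keep_default_na=False)
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(f"cannot parse {what} file {path}: {exc}") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{what} file {path}: duplicated row id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ParseError(f"{what} file {path}: duplicated sample column {dup!r}")
    return raw


def _to_numeric(raw: pd.DataFrame, path: str | Path, what: str) -> pd.DataFrame:
    out = {}
    for col in raw.columns:
        try:
            # numpy's parser rounds correctly, so written floats round-trip
            out[col] = raw[col].astype(float)
        except ValueError:
            probe = pd.to_numeric(raw[col], errors="coerce")
            bad = probe.index[probe.isna()]
            row = bad[0] if len(bad) else "?"
            raise ParseError(
                f"{what} file {path}: non-numeric cell at row {row!r}, column {col!r}")
    return pd.DataFrame(out, index=raw.index)


def read_expression(path: str | Path, tissue: str,
                    detection_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a probes x samples expression matrix and declare its tissue."""
    values = _to_numeric(_read_table(path, "expression"), path, "expression")
    detection = read_detection(detection_path) if detection_path else None
    return ExpressionMatrix(values, tissue, detection)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     detection_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")
    if detection_path and matrix.detection is not None:
        matrix.detection.astype(int).to_csv(detection_path, sep="\t",
                                            index_label="probe_id")


def read_detection(path: str | Path) -> pd.DataFrame:
    raw = _read_table(path, "detection")
    bad_tokens = set(raw.to_numpy().ravel()) - {"0", "1"}
    if bad_tokens:
        raise ParseError(f"detection file {path}: cells must be 0/1, got {sorted(bad_tokens)[:5]}")
    return raw.astype(int).astype(bool)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a SNPs x samples matrix of calls in {0, 1, 2, NA}."""
    raw = _read_table(path, "genotype")
    arr = raw.to_numpy()
    bad_tokens = set(arr.ravel()) - set(_GENO_TOKENS)
    if bad_tokens:
        tok = sorted(bad_tokens)[0]
        rows, cols = np.nonzero(arr == tok)
        raise ParseError(
            f"genotype file {path}: invalid call {tok!r} at row "
            f"{raw.index[rows[0]]!r}, column {raw.columns[cols[0]]!r}")
    calls = raw.apply(lambda col: col.map(_GENO_TOKENS)).astype(float)
    return GenotypeMatrix(calls)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    fmt = matrix.calls.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    fmt.to_csv(path, sep="\t", index_label="snp_id")


def read_covariates(path: str | Path) -> CovariateTable:
    """Read the per-sample covariate table (sample_id, age, sex, race, site)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    except (ValueError, KeyError) as exc:
        raise ParseError(f"covariate file {path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"covariate file {path}: duplicated sample_id {dup!r}")
    if "has_carcinoma_pair" in frame.columns:
        frame["has_carcinoma_pair"] = frame["has_carcinoma_pair"].astype(bool)
    return CovariateTable(frame)


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_snp_specs(path: str | Path) -> list[SnpSpec]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SNP_SPEC_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ParseError(f"snp-spec file {path}: missing column(s) {missing}")
    specs = []
    for _, row in frame.iterrows():
        specs.append(SnpSpec(row["snp_id"], row["gene"], row["model"],
                             row.get("variant_allele", "")))
    return specs


def write_snp_specs(specs: Sequence[SnpSpec], path: str | Path) -> None:
    pd.DataFrame(
        [(s.snp_id, s.gene, s.model, s.variant_allele) for s in specs],
        columns=list(SNP_SPEC_COLUMNS),
    ).to_csv(path, sep="\t", index=False)
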