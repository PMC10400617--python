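"""Reader-stability filtering and z-score normalization of feature tables.

The stability filter removes features whose inter-reader coefficient of
variation (CV) exceeds a threshold (default 10%), emulating the standard
radiomics practice of discarding features sensitive to manual segmentation.
The CV for a feature is the per-sample two-point CV between the two reader
values, ``sd(a, b) / |mean(a, b)|`` with ``sd(a, b) = |a - b| / sqrt(2)``,
averaged over samples. A sample pair with zero mean yields an infinite CV, so
any such feature fails a finite threshold (conservative by design). An
alternative aggregation — the CV of the two per-reader mean profiles — is
available via ``aggregate="profile_mean"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OmicsBlock, check_aligned

logger = logging.getLogger(__name__)

DEFAULT_CV_MAX = 0.10


@dataclass
class StabilityReport:
    """Per-feature inter-reader CV and the retain decision."""

    table: pd.DataFrame  # columns: cv, retained; index: feature id
    cv_max: float

    @property
    def retained_ids(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])

    @property
    def dropped_ids(self) -> list[str]:
        return list(self.table.index[~self.table["retained"]])

    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index_label="feature_id")


def stability_filter(
    reader_a: OmicsBlock,
    reader_b: OmicsBlock,
    cv_max: float = DEFAULT_CV_MAX,
    aggregate: str = "per_sample",
) -> tuple[OmicsBlock, StabilityReport]:
    """Drop features whose inter-reader CV exceeds ``cv_max``.

    Returns the filtered block (values taken from reader A by convention) and
    a report listing every feature's CV. ``retained`` is ``CV <= cv_max``.
    """
    check_aligned(reader_a, reader_b, features=True)
    a = reader_a.values
    b = reader_b.values
    if aggregate == "per_sample":
        sd = np.abs(a - b) / np.sqrt(2.0)
        mean = np.abs(a + b) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cv_pairs = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
            cv_pairs = np.where((mean == 0) & (sd == 0), 0.0, cv_pairs)
        cv = cv_pairs.mean(axis=0)
    elif aggregate == "profile_mean":
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        sd = np.abs(ma - mb) / np.sqrt(2.0)
        mean = np.abs(ma + mb) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
            cv = np.where((mean == 0) & (sd == 0), 0.0, cv)
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    retained = cv <= cv_max
    report = StabilityReport(
        pd.DataFrame({"cv": cv, "retained": retained}, index=reader_a.data.columns),
        cv_max=cv_max,
    )
    kept = [f for f, r in zip(reader_a.feature_ids, retained) if r]
    filtered = reader_a.subset_features(kept)
    logger.info(
        "stability filter: %d/%d features retained at CV <= %g",
        len(kept), reader_a.n_features, cv_max,
    )
    return filtered, report


def zscore_normalize(block: OmicsBlock, ddof: int = 1, tol: float = 1e-12) -> OmicsBlock:
    """Standardize every feature column to mean 0 and (sample) sd 1.

    Constant columns carry no information and cannot be standardized; they are
    dropped with a logged warning. Requires at least two samples.
    """
    if block.n_samples < 2:
        raise ValueError("z-score normalization needs at least 2 samples")
    values = block.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    scale = np.abs(values).max(axis=0)
    constant = sd <= tol * np.maximum(scale, 1.0)
    if constant.any():
        dropped = [f for f, c in zip(block.feature_ids, constant) if c]
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped[:10])
    keep = ~constant
    z = (values[:, keep] - mean[keep]) / sd[keep]
    cols = [f for f, k in zip(block.feature_ids, keep) if k]
    return OmicsBlock(pd.DataFrame(z, index=block.data.index, columns=cols), block.kind)
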