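"""Synthetic two-block data with planted condition-specific coupling.

The generator emulates a radiometabolomics study design: a CT-radiomics block
and a MALDI-MSI metabolite block measured on the same tumors, with a benign and
a malignant condition. Structure is planted through latent factors:

* ``shared`` features (in both blocks) load on one common factor in *both*
  conditions — cross-block coupled everywhere, hence not discriminative;
* ``discriminative`` features split into a benign-coupled and a malignant-coupled
  half; each half loads on a condition-specific factor in exactly one condition
  and is pure noise in the other;
* all remaining features are independent Gaussian noise.

The latent-factor construction makes the cross-block correlation between two
planted partner features analytically controllable: for loading ``a`` and noise
standard deviation ``s`` it equals ``a**2 / (a**2 + s**2)``.

A companion generator produces reader replicates (multiplicative log-normal
perturbation, because the inter-reader coefficient of variation is scale-free)
and a toy GMT pathway map with one pathway over-populated with the planted
discriminative metabolites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import BENIGN, MALIGNANT, METABOLITE, RADIOMICS, OmicsBlock, PathwayMap

#: log-sd of the multiplicative reader noise for features meant to fail the
#: 10% CV filter (expected mean CV ~ 0.28) and for stable features (~ 0.011).
READER_SIGMA_UNSTABLE = 0.5
READER_SIGMA_STABLE = 0.02


class InvalidSpecError(ValueError):
    """Raised when a SyntheticSpec is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the emulated cohort: 14 benign oncocytic and 19 malignant
    tumors, with 10 planted discriminative features per block (5 coupled in
    each condition) and 4 features per block coupled in both conditions.

    ``factor_mean`` is the mean of each condition-specific latent factor
    (the shared factor is always centered): coupled features then differ in
    level as well as in covariance between conditions, which is what makes
    the planted signal visible to sample clustering and to classifiers.
    Within-condition structure (and hence the association networks) is
    unaffected by it.
    """

    n_benign: int = 14
    n_malignant: int = 19
    p_radiomics: int = 60
    p_metabolites: int = 80
    n_discriminative_per_block: int = 10
    n_shared_coupled_per_block: int = 4
    latent_loading: float = 1.0
    noise_sd: float = 1.0
    factor_mean: float = 1.0
    reader_cv_unstable_fraction: float = 0.25
    seed: int = 7

    def validate(self) -> None:
        counts = (
            self.n_benign,
            self.n_malignant,
            self.p_radiomics,
            self.p_metabolites,
            self.n_discriminative_per_block,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise InvalidSpecError("all sample/feature counts must be integers >= 1")
        if self.n_shared_coupled_per_block < 0:
            raise InvalidSpecError("n_shared_coupled_per_block must be >= 0")
        budget = self.n_discriminative_per_block + self.n_shared_coupled_per_block
        if budget > min(self.p_radiomics, self.p_metabolites):
            raise InvalidSpecError(
                f"planted features per block ({budget}) exceed block size "
                f"({min(self.p_radiomics, self.p_metabolites)})"
            )
        if not self.noise_sd > 0:
            raise InvalidSpecError("noise_sd must be > 0")
        if not 0.0 <= self.reader_cv_unstable_fraction <= 1.0:
            raise InvalidSpecError("reader_cv_unstable_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of one synthetic draw."""

    discriminative_ids: frozenset[str]
    shared_ids: frozenset[str]
    enriched_pathway_id: str | None = None
    benign_coupled_ids: frozenset[str] = frozenset()
    malignant_coupled_ids: frozenset[str] = frozenset()
    radiomics_universe: tuple[str, ...] = ()
    metabolite_universe: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.discriminative_ids & self.shared_ids:
            raise ValueError("discriminative and shared feature sets overlap")

    @property
    def discriminative_metabolites(self) -> frozenset[str]:
        return self.discriminative_ids & frozenset(self.metabolite_universe)

    @property
    def discriminative_radiomics(self) -> frozenset[str]:
        return self.discriminative_ids & frozenset(self.radiomics_universe)


def _feature_ids(kind: str, p: int) -> list[str]:
    if kind == RADIOMICS:
        return [f"rf_{i:04d}" for i in range(1, p + 1)]
    return [f"C{i:05d}" for i in range(1, p + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"T{i:03d}" for i in range(1, n + 1)]


def generate_coupled_blocks(
    spec: SyntheticSpec,
) -> tuple[OmicsBlock, OmicsBlock, pd.Series, GroundTruth]:
    """Draw one synthetic study: two blocks, labels, and its ground truth.

    Feature layout per block: the first ``n_discriminative_per_block`` columns
    are discriminative (first half benign-coupled, second half malignant-coupled),
    the next ``n_shared_coupled_per_block`` load on the common factor, and the
    remainder are noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_benign + spec.n_malignant
    samples = _sample_ids(n)
    labels = pd.Series(
        [BENIGN] * spec.n_benign + [MALIGNANT] * spec.n_malignant,
        index=samples,
        name="condition",
    )
    benign_mask = (labels == BENIGN).to_numpy()

    # latent factors, one value per sample
    z_shared = rng.standard_normal(n)
    z_benign = rng.standard_normal(n) + spec.factor_mean
    z_malignant = rng.standard_normal(n) + spec.factor_mean

    n_disc = spec.n_discriminative_per_block
    n_b = n_disc // 2 + n_disc % 2  # benign-coupled half (larger on odd counts)

    def build(kind: str, p: int) -> tuple[OmicsBlock, list[str], list[str]]:
        ids = _feature_ids(kind, p)
        x = rng.normal(0.0, spec.noise_sd, size=(n, p))
        a = spec.latent_loading
        disc = ids[:n_disc]
        shared = ids[n_disc : n_disc + spec.n_shared_coupled_per_block]
        for j in range(n_b):  # benign-coupled: factor active in benign samples only
            x[benign_mask, j] += a * z_benign[benign_mask]
        for j in range(n_b, n_disc):
            x[~benign_mask, j] += a * z_malignant[~benign_mask]
        for j in range(n_disc, n_disc + spec.n_shared_coupled_per_block):
            x[:, j] += a * z_shared
        return OmicsBlock(pd.DataFrame(x, index=samples, columns=ids), kind), disc, shared

    rf_block, rf_disc, rf_shared = build(RADIOMICS, spec.p_radiomics)
    met_block, met_disc, met_shared = build(METABOLITE, spec.p_metabolites)

    truth = GroundTruth(
        discriminative_ids=frozenset(rf_disc + met_disc),
        shared_ids=frozenset(rf_shared + met_shared),
        benign_coupled_ids=frozenset(rf_disc[:n_b] + met_disc[:n_b]),
        malignant_coupled_ids=frozenset(rf_disc[n_b:] + met_disc[n_b:]),
        radiomics_universe=tuple(rf_block.feature_ids),
        metabolite_universe=tuple(met_block.feature_ids),
    )
    return rf_block, met_block, labels, truth


def generate_reader_replicates(
    block: OmicsBlock, spec: SyntheticSpec, unstable_mask: np.ndarray | None = None
) -> tuple[OmicsBlock, OmicsBlock]:
    """Emulate two readers segmenting the same tumors.

    Reader A is the block itself; reader B is perturbed with per-feature
    multiplicative log-normal noise. A feature designated unstable receives
    noise strong enough that its mean two-point CV exceeds the usual 10%
    threshold; stable features receive negligible noise. By default each
    feature is unstable independently with probability
    ``spec.reader_cv_unstable_fraction``; an explicit boolean mask (one entry
    per feature) overrides the random designation.
    """
    spec.validate()
    if not block.is_finite():
        raise ValueError("block contains non-finite values")
    rng = np.random.default_rng([int(spec.seed), 0x5EAD])
    p = block.n_features
    if unstable_mask is None:
        unstable_mask = rng.random(p) < spec.reader_cv_unstable_fraction
    else:
        unstable_mask = np.asarray(unstable_mask, dtype=bool)
        if unstable_mask.shape != (p,):
            raise ValueError("unstable_mask must have one entry per feature")
    sigma = np.where(unstable_mask, READER_SIGMA_UNSTABLE, READER_SIGMA_STABLE)
    factors = np.exp(rng.standard_normal(block.data.shape) * sigma[None, :])
    reader_a = OmicsBlock(block.data.copy(), block.kind)
    reader_b = OmicsBlock(block.data * factors, block.kind)
    return reader_a, reader_b


def generate_pathway_map(
    ground_truth: GroundTruth,
    n_pathways: int = 12,
    seed: int = 0,
    pathway_size: int = 10,
    enriched_fraction: float = 0.8,
) -> PathwayMap:
    """Toy KEGG-style pathway map with one planted enriched pathway.

    The first pathway contains ``enriched_fraction`` of the planted
    discriminative metabolites (at least one) padded with random background
    compounds up to ``pathway_size``; the remaining pathways draw members
    uniformly from the whole metabolite universe.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    disc = sorted(ground_truth.discriminative_metabolites)
    if not disc:
        raise ValueError("ground truth has no discriminative metabolites")
    universe = list(ground_truth.metabolite_universe)
    rng = np.random.default_rng(seed)

    n_core = max(1, math.ceil(enriched_fraction * len(disc)))
    core = list(rng.choice(disc, size=n_core, replace=False))
    background = [m for m in universe if m not in core]
    pad = max(0, pathway_size - n_core)
    filler = list(rng.choice(background, size=min(pad, len(background)), replace=False))

    members: dict[str, frozenset[str]] = {"map00001": frozenset(core + filler)}
    names = {"map00001": "Planted enriched pathway (synthetic)"}
    for i in range(2, n_pathways + 1):
        pid = f"map{i:05d}"
        size = min(pathway_size, len(universe))
        members[pid] = frozenset(rng.choice(universe, size=size, replace=False))
        names[pid] = f"Background pathway {i} (synthetic)"

    pmap = PathwayMap(members, names)
    return pmap


@dataclass
class StudyFixture:
    """Full synthetic input bundle at study scale.

    ``radiomics`` holds the stability-filtered reader-A block (the shape an
    analysis consumes after the CV filter); ``radiomics_reader_a`` /
    ``radiomics_reader_b`` hold the pre-filter replicate pair so the filter
    itself can be exercised.
    """

    radiomics: OmicsBlock
    metabolites: OmicsBlock
    radiomics_reader_a: OmicsBlock
    radiomics_reader_b: OmicsBlock
    labels: pd.Series
    ground_truth: GroundTruth
    pathway_map: PathwayMap
    spec: SyntheticSpec = field(default=None)  # type: ignore[assignment]


#: cohort-scale feature counts the fixture reproduces at scale=1: the raw
#: radiomics extraction, the post-filter stable subset, and the metabolite panel
_P_RF_RAW, _P_RF_STABLE, _P_MET = 944, 700, 771


def study_fixture(scale: float = 1.0, seed: int = 7) -> StudyFixture:
    """Synthetic bundle shaped like the emulated 33-tumor study.

    At ``scale=1`` the filtered radiomics block has 700 features (944 before
    reader-stability filtering) and the metabolite block 771; smaller scales
    shrink feature counts proportionally with a floor of 20 per block. Sample
    counts stay at 14 benign / 19 malignant.
    """
    if not scale > 0:
        raise ValueError("scale must be > 0")
    if scale > 1:
        raise ValueError("scale must be <= 1")
    p_rf_raw = max(20, int(round(_P_RF_RAW * scale)))
    p_rf_stable = max(20, int(round(_P_RF_STABLE * scale)))
    p_met = max(20, int(round(_P_MET * scale)))
    p_rf_stable = min(p_rf_stable, p_rf_raw)

    spec = SyntheticSpec(
        p_radiomics=p_rf_raw,
        p_metabolites=p_met,
        reader_cv_unstable_fraction=(p_rf_raw - p_rf_stable) / p_rf_raw,
        seed=seed,
    )
    rf_raw, met, labels, truth = generate_coupled_blocks(spec)

    # designate exactly p_rf_raw - p_rf_stable unplanted features as unstable so
    # the downstream CV filter reproduces the raw -> stable reduction
    planted = truth.discriminative_ids | truth.shared_ids
    ids = rf_raw.feature_ids
    candidates = np.array([i for i, f in enumerate(ids) if f not in planted])
    rng = np.random.default_rng([seed, 0xF17])
    n_unstable = p_rf_raw - p_rf_stable
    unstable_idx = rng.choice(candidates, size=n_unstable, replace=False)
    mask = np.zeros(p_rf_raw, dtype=bool)
    mask[unstable_idx] = True
    reader_a, reader_b = generate_reader_replicates(rf_raw, spec, unstable_mask=mask)

    stable_ids = [f for i, f in enumerate(ids) if not mask[i]]
    rf_stable = rf_raw.subset_features(stable_ids)

    pmap = generate_pathway_map(truth, seed=seed)
    truth = replace(truth, enriched_pathway_id="map00001")
    return StudyFixture(
        radiomics=rf_stable,
        metabolites=met,
        radiomics_reader_a=reader_a,
        radiomics_reader_b=reader_b,
        labels=labels,
        ground_truth=truth,
        pathway_map=pmap,
        spec=spec,
    )
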