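"""Synthetic cohort and peptide-quantitation generator.

Emulates the statistical structure the pipeline assumes, at desk scale and
with known ground truth: Hardy-Weinberg genotypes at one biallelic C/T SNP,
per-protein latent expression scores (one of which may carry a genotype
effect — the simulated pQTL), peptide log2 intensities that load on their
parent protein's score with multiplicative loadings plus Gaussian noise,
occasional "promiscuous" peptides that also load on a foreign protein, random
missingness, and a binary treatment outcome generated from a logistic model
with a genotype (recessive) and/or protein-score effect.

Setting ``outcome_beta_protein = 0`` with a nonzero ``outcome_beta_geno``
gives the pleiotropy scenario (the genotype affects protein and outcome
through separate paths); ``outcome_beta_geno = 0`` with a nonzero protein
effect gives full mediation.

All randomness flows from ``SimConfig.seed`` through purpose-specific
streams (genotypes, covariates, outcome, scores, loadings, noise, masking,
metadata), so e.g. changing ``missing_rate`` does not perturb the genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, DimensionError
from .tables import CohortTable, IsotopeGroupTable

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "simulate_peptides", "simulate_dataset"]

# sub-stream indices under the top-level seed
_STREAMS = {
    "genotype": 0,
    "covariates": 1,
    "outcome": 2,
    "scores": 3,
    "loadings": 4,
    "noise": 5,
    "masking": 6,
    "metadata": 7,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    Defaults emulate the 41-patient chronic-HCV serum cohort at one tenth of
    the proteome scale: 10 proteins with 5 isotope groups each, C-allele
    frequency 0.707 (so the CC "responder" genotype is ~49% of samples under
    HWE), race ~78% Caucasian, an additive genotype effect of 1.16 score
    units per C allele on the pQTL protein, and a recessive genotype effect
    of log(0.03) on the log-odds of treatment response with no direct
    protein effect (the pleiotropy scenario).
    """

    n_samples: int = 41
    allele_freq_C: float = 0.707
    n_proteins: int = 10
    peptides_per_protein: int | Sequence[int] = 5
    loading_range: tuple[float, float] = (0.8, 1.2)
    residual_sd: float = 0.5
    missing_rate: float = 0.05
    pqtl_protein_index: int | None = 0
    beta_geno: float = 1.16
    promiscuous_fraction: float = 0.02
    outcome_intercept: float = 3.0
    outcome_beta_geno: float = -3.5
    outcome_beta_protein: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ConfigError(f"n_samples must be >= 4, got {self.n_samples}")
        for name in ("allele_freq_C", "missing_rate", "promiscuous_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if min(self.peptide_counts()) < 1:
            raise ConfigError("peptides_per_protein must be >= 1")
        if self.residual_sd <= 0:
            raise ConfigError(f"residual_sd must be > 0, got {self.residual_sd}")
        if self.loading_range[0] > self.loading_range[1]:
            raise ConfigError("loading_range must be (low, high) with low <= high")
        if self.pqtl_protein_index is not None and not (
            0 <= self.pqtl_protein_index < self.n_proteins
        ):
            raise ConfigError(
                f"pqtl_protein_index {self.pqtl_protein_index} out of range for "
                f"{self.n_proteins} proteins"
            )

    def peptide_counts(self) -> list[int]:
        if isinstance(self.peptides_per_protein, int):
            return [self.peptides_per_protein] * self.n_proteins
        counts = list(self.peptides_per_protein)
        if len(counts) != self.n_proteins:
            raise ConfigError(
                f"peptides_per_protein list has {len(counts)} entries for "
                f"{self.n_proteins} proteins"
            )
        return counts

    def rng(self, purpose: str) -> np.random.Generator:
        """Deterministic purpose-specific stream under the top-level seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[purpose],))
        )

    def protein_ids(self) -> list[str]:
        return [f"PROT{g:03d}" for g in range(self.n_proteins)]

    def protein_names(self) -> list[str]:
        return [f"P{g:03d}" for g in range(self.n_proteins)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "allele_freq_C": self.allele_freq_C,
            "n_proteins": self.n_proteins,
            "peptides_per_protein": self.peptides_per_protein
            if isinstance(self.peptides_per_protein, int)
            else list(self.peptides_per_protein),
            "loading_range": list(self.loading_range),
            "residual_sd": self.residual_sd,
            "missing_rate": self.missing_rate,
            "pqtl_protein_index": self.pqtl_protein_index,
            "beta_geno": self.beta_geno,
            "promiscuous_fraction": self.promiscuous_fraction,
            "outcome_intercept": self.outcome_intercept,
            "outcome_beta_geno": self.outcome_beta_geno,
            "outcome_beta_protein": self.outcome_beta_protein,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SimConfig":
        config = cls()
        known = config.to_dict().keys()
        unknown = set(payload) - set(known)
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        kwargs = dict(payload)
        if "loading_range" in kwargs:
            kwargs["loading_range"] = tuple(kwargs["loading_range"])
        if "peptides_per_protein" in kwargs and not isinstance(
            kwargs["peptides_per_protein"], int
        ):
            kwargs["peptides_per_protein"] = list(kwargs["peptides_per_protein"])
        return replace(config, **kwargs)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``protein_scores`` are the latent per-sample factor scores (samples x
    proteins); ``peptide_membership`` maps each feature_id to the set of
    protein (factor) indices it loads on; ``loadings`` maps
    (feature_id, factor index) to the generating loading.
    """

    protein_scores: pd.DataFrame
    genotypes: np.ndarray
    outcome: np.ndarray
    peptide_membership: dict[str, set[int]] = field(default_factory=dict)
    loadings: dict[tuple[str, int], float] = field(default_factory=dict)


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, SimTruth]:
    """Draw genotypes (HWE), covariates, latent protein scores and outcome.

    The latent protein scores are drawn here (not in ``simulate_peptides``)
    because the outcome model may depend on the pQTL protein's score; they
    are carried in ``SimTruth`` and consumed by ``simulate_peptides``.
    """
    config.validate()
    n = config.n_samples

    genotypes = config.rng("genotype").binomial(2, config.allele_freq_C, size=n)

    rng_cov = config.rng("covariates")
    sex = np.where(rng_cov.random(n) < 0.61, "male", "female")
    race = np.where(rng_cov.random(n) < 0.78, "Caucasian", "African American")

    scores = config.rng("scores").standard_normal((n, config.n_proteins))
    if config.pqtl_protein_index is not None:
        g_centered = genotypes - genotypes.mean()
        scores[:, config.pqtl_protein_index] = (
            config.beta_geno * g_centered + scores[:, config.pqtl_protein_index]
        )

    non_cc = (genotypes < 2).astype(float)
    eta = config.outcome_intercept + config.outcome_beta_geno * non_cc
    if config.pqtl_protein_index is not None and config.outcome_beta_protein != 0.0:
        eta = eta + config.outcome_beta_protein * scores[:, config.pqtl_protein_index]
    outcome = (config.rng("outcome").random(n) < expit(eta)).astype(int)

    geno_label = {2: "CC", 1: "CT", 0: "TT"}
    data = pd.DataFrame(
        {
            "genotype": [geno_label[g] for g in genotypes],
            "allele_count": genotypes.astype(int),
            "sex": sex,
            "race": race,
            "outcome": np.where(outcome == 1, "SVR", "NR"),
        },
        index=pd.Index(config.sample_ids(), name="sample_id"),
    )
    truth = SimTruth(
        protein_scores=pd.DataFrame(
            scores, index=data.index, columns=config.protein_ids()
        ),
        genotypes=genotypes,
        outcome=outcome,
    )
    return CohortTable(data=data), truth


def simulate_peptides(
    config: SimConfig, cohort: CohortTable, truth: SimTruth
) -> tuple[IsotopeGroupTable, SimTruth]:
    """Generate the isotope-group intensity matrix from the latent scores.

    Each peptide j of protein g has log2 intensity
    ``x_ij = intercept_j + lambda_j * t_ig (+ lambda'_j * t_ig') + eps_ij``
    with ``eps ~ N(0, residual_sd^2)``; the optional second term is present
    for promiscuous peptides, which additionally load on a random foreign
    protein.  Entries are then masked missing independently with probability
    ``missing_rate``.  The identification metadata (m/z, charge, centroid
    times, peak-time scores) are plausible values carrying no signal.
    """
    config.validate()
    if cohort.n_samples != config.n_samples:
        raise DimensionError(
            f"cohort has {cohort.n_samples} samples, config expects {config.n_samples}"
        )
    if truth.protein_scores.shape != (config.n_samples, config.n_proteins):
        raise DimensionError("truth.protein_scores shape does not match config")

    rng_load = config.rng("loadings")
    rng_noise = config.rng("noise")
    rng_mask = config.rng("masking")
    rng_meta = config.rng("metadata")

    scores = truth.protein_scores.to_numpy()
    counts = config.peptide_counts()
    protein_ids = config.protein_ids()
    protein_names = config.protein_names()
    low, high = config.loading_range

    feature_ids: list[str] = []
    meta_records: list[dict] = []
    rows: list[np.ndarray] = []
    membership: dict[str, set[int]] = {}
    loadings: dict[tuple[str, int], float] = {}

    feature_no = 0
    for g, n_pep in enumerate(counts):
        for _ in range(n_pep):
            fid = f"F{feature_no:04d}"
            feature_no += 1
            lam = rng_load.uniform(low, high)
            intercept = rng_load.normal(20.0, 2.0)
            promiscuous = rng_load.random() < config.promiscuous_fraction
            x = intercept + lam * scores[:, g]
            membership[fid] = {g}
            loadings[(fid, g)] = lam
            if promiscuous and config.n_proteins > 1:
                foreign = int(rng_load.integers(config.n_proteins - 1))
                if foreign >= g:
                    foreign += 1
                lam2 = rng_load.uniform(low, high)
                x = x + lam2 * scores[:, foreign]
                membership[fid].add(foreign)
                loadings[(fid, foreign)] = lam2
            x = x + rng_noise.normal(0.0, config.residual_sd, size=config.n_samples)

            n_times = int(rng_meta.integers(2, 8))
            base_time = rng_meta.uniform(20.0, 80.0)
            times = np.sort(base_time + rng_meta.uniform(0.0, 0.2, size=n_times))
            meta_records.append(
                {
                    "peptide_label": protein_names[g],
                    "protein_id": protein_ids[g],
                    "monoisotopic_mz": float(rng_meta.uniform(400.0, 1500.0)),
                    "charge_state": int(rng_meta.choice([1, 2, 3], p=[0.3, 0.5, 0.2])),
                    "peak_centroid_times": [float(t) for t in times],
                    "peak_time_scores": [
                        float(s) for s in rng_meta.uniform(0.75, 0.99, size=n_times)
                    ],
                }
            )
            feature_ids.append(fid)
            rows.append(x)

    intensities = np.asarray(rows, dtype=float)
    if config.missing_rate > 0:
        mask = rng_mask.random(intensities.shape) < config.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    features = pd.DataFrame(meta_records, index=pd.Index(feature_ids, name="feature_id"))
    table = IsotopeGroupTable(
        features=features,
        intensities=pd.DataFrame(
            intensities, index=features.index, columns=cohort.sample_ids
        ),
    )
    truth.peptide_membership = membership
    truth.loadings = loadings
    return table, truth


def simulate_dataset(config: SimConfig) -> tuple[IsotopeGroupTable, CohortTable, SimTruth]:
    """Convenience wrapper: cohort then peptides, one call."""
    cohort, truth = simulate_cohort(config)
    table, truth = simulate_peptides(config, cohort, truth)
    return table, cohort, truth
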