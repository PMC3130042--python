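"""Sparse one-factor "metaprotein" model.

Peptides quantified by label-free LC-MS are noisy, partially misidentified
proxies of protein abundance.  Instead of averaging a protein's peptides, a
metaprotein is a latent factor seeded on the protein's identified isotope
groups: peptides whose expression tracks the factor stay in (including
peptides assigned to *other* proteins, or unidentified ones), peptides that
do not co-express are excluded, and the per-sample factor score is the
protein-level expression estimate.

Model, per seed protein, over candidate peptides j and samples i::

    x_ij = mu_j + rho_j * lambda_j * f_i + eps_ij,   eps_ij ~ N(0, psi_j)
    f_i ~ N(0, 1),  lambda_j ~ N(0, tau),  rho_j ~ Bernoulli(pi_j)

with a spike-and-slab inclusion prior: ``pi_j = pi_seed`` for the seed
protein's own peptides and the much smaller ``pi_other`` for everything
else.  The fit is variational EM with a factorized posterior
q(f) q(lambda, rho): the E-step computes the Gaussian posterior of the
factor scores, the Gaussian slab posterior of each loading, and the exact
inclusion probabilities from the Bernoulli-Gaussian marginal likelihood
ratio (integrating the loading out, so an uninformative peptide pays an
Occam penalty and can be excluded); the M-step updates (mu, psi) in closed
form.
Missing intensities are simply omitted from the likelihood (MAR).  The
objective tracked for convergence is the evidence lower bound, which this
coordinate scheme increases monotonically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .errors import ConfigError, DegenerateFactorError
from .tables import IsotopeGroupTable

logger = logging.getLogger(__name__)

__all__ = [
    "FactorHyperparams",
    "Metaprotein",
    "MetaproteinFit",
    "seed_factors",
    "fit_metaprotein",
    "fit_all",
    "composition_metrics",
    "peptide_correlations",
    "save_fit",
    "load_scores",
]

_PSI_FLOOR = 1e-8
_PROB_EPS = 1e-12


@dataclass(frozen=True)
class FactorHyperparams:
    """Hyperparameters of the spike-and-slab factor fit.

    ``pi_seed`` / ``pi_other`` are the prior inclusion probabilities for the
    seed protein's peptides versus all other candidates; ``tau`` the prior
    loading variance; ``membership_threshold`` the posterior-probability
    cutoff defining factor membership.
    """

    pi_seed: float = 0.95
    pi_other: float = 0.001
    tau: float = 1.0
    membership_threshold: float = 0.5
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pi_other < self.pi_seed < 1.0):
            raise ConfigError("require 0 < pi_other < pi_seed < 1")
        if self.tau <= 0:
            raise ConfigError("tau must be > 0")
        if not (0.0 < self.membership_threshold < 1.0):
            raise ConfigError("membership_threshold must be in (0, 1)")
        if self.max_iter < 1 or self.tol <= 0:
            raise ConfigError("max_iter must be >= 1 and tol > 0")

    def to_dict(self) -> dict:
        return {
            "pi_seed": self.pi_seed,
            "pi_other": self.pi_other,
            "tau": self.tau,
            "membership_threshold": self.membership_threshold,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "seed": self.seed,
        }


@dataclass
class Metaprotein:
    """One fitted factor: the seed protein's name, members and composition.

    ``members`` holds (feature_id, loading, inclusion probability) for every
    candidate whose posterior inclusion probability reached the membership
    threshold.  ``coverage_pct`` is the percentage of the seed protein's
    identified isotope groups that are in the factor; ``signature_pct`` the
    percentage of factor members that come from the seed protein.
    """

    name: str
    seed_protein: str
    members: list[tuple[str, float, float]]
    coverage_pct: float
    signature_pct: float
    inclusion_probs: pd.Series = field(repr=False, default=None)
    loadings: pd.Series = field(repr=False, default=None)

    @property
    def member_ids(self) -> list[str]:
        return [fid for fid, _, _ in self.members]


@dataclass
class _FactorFitState:
    """Internal per-factor fit output (score + diagnostics)."""

    metaprotein: Metaprotein
    score: pd.Series
    residual_variances: pd.Series
    objective_trace: np.ndarray
    n_iterations: int
    converged: bool


@dataclass
class MetaproteinFit:
    """Result of fitting one factor per seed protein.

    ``scores`` is samples x K with each column standardized (mean 0, unit
    variance) and sign-aligned so the mean seed-member loading is positive:
    a lower score means lower inferred protein level.
    """

    factors: list[Metaprotein]
    scores: pd.DataFrame
    residual_variances: dict[str, pd.Series]
    n_iterations: dict[str, int]
    converged: bool
    seed: int
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.factors)


def seed_factors(table: IsotopeGroupTable) -> list[tuple[str, list[str]]]:
    """Seed one factor per protein with >= 2 identified isotope groups.

    Unidentified features never seed a factor but remain recruitment
    candidates.  Output is ordered by protein_id for determinism.
    """
    identified = table.features.dropna(subset=["protein_id"])
    seeds = []
    for protein_id, group in identified.groupby("protein_id", sort=True):
        if len(group) >= 2:
            seeds.append((protein_id, list(group.index)))
    if not seeds:
        raise DegenerateFactorError("no protein has >= 2 identified isotope groups")
    return seeds


def _initialize(X: np.ndarray, obs: np.ndarray, n_seed: int):
    """Deterministic start: factor = first PC of the mean-imputed seed block."""
    seed_block = X[:, :n_seed].copy()
    col_mean = np.nanmean(seed_block, axis=0)
    inds = np.where(np.isnan(seed_block))
    seed_block[inds] = np.take(col_mean, inds[1])
    centered = seed_block - seed_block.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    f = u[:, 0] * s[0]
    sd = f.std()
    if sd <= 0:
        raise DegenerateFactorError("seed peptides carry no variance")
    f = (f - f.mean()) / sd

    mu = np.array([np.nanmean(X[:, j]) for j in range(X.shape[1])])
    R = np.where(obs, X - mu, 0.0)
    denom = obs.T @ (f**2)
    lam = (R.T @ f) / np.maximum(denom, 1e-12)
    if lam[:n_seed].mean() < 0:
        f, lam = -f, -lam
    resid = np.where(obs, R - f[:, None] * lam[None, :], 0.0)
    psi = np.maximum((resid**2).sum(axis=0) / np.maximum(obs.sum(axis=0), 1), 1e-4)
    return f, mu, lam, psi


def fit_metaprotein(
    table: IsotopeGroupTable,
    seed_protein: str,
    seed_feature_ids: list[str],
    candidate_ids: list[str],
    hp: FactorHyperparams,
) -> _FactorFitState:
    """Fit the sparse one-factor model for a single seed protein.

    ``candidate_ids`` are non-seed features offered for recruitment under
    prior ``pi_other``.  Seed features with fewer than 3 observed samples are
    dropped; fewer than 2 usable seed features is an error.
    """
    n_obs_per = table.intensities.loc[seed_feature_ids].notna().sum(axis=1)
    usable_seed = [fid for fid in seed_feature_ids if n_obs_per[fid] >= 3]
    if len(usable_seed) < 2:
        raise DegenerateFactorError(
            f"{seed_protein}: fewer than 2 seed peptides with >= 3 observed samples"
        )
    candidate_ids = [fid for fid in candidate_ids if fid not in set(usable_seed)]
    cols = usable_seed + candidate_ids
    n_seed = len(usable_seed)

    X = table.intensities.loc[cols].to_numpy().T  # samples x features
    obs = ~np.isnan(X)
    keep = obs.sum(axis=0) >= 3
    keep[:n_seed] = True
    cols = [c for c, k in zip(cols, keep) if k]
    X, obs = X[:, keep], obs[:, keep]
    n, J = X.shape
    n_j = obs.sum(axis=0)

    pi = np.full(J, hp.pi_other)
    pi[:n_seed] = hp.pi_seed
    logit_pi = logit(pi)

    f, mu, lam, psi = _initialize(X, obs, n_seed)
    m, v = f, np.zeros(n)
    p = np.clip(pi.copy(), _PROB_EPS, 1 - _PROB_EPS)
    s_lam = np.full(J, hp.tau)

    trace = []
    elbo_prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, hp.max_iter + 1):
        # E-step: q(lambda | rho=1) Gaussian and exact q(rho) given q(f);
        # the inclusion odds are the Bernoulli-Gaussian marginal likelihood
        # ratio, whose log(s/tau) term is the Occam penalty that lets a
        # discordant peptide be excluded.
        R = np.where(obs, X - mu, 0.0)
        a = R.T @ m                      # sum_i obs * (x - mu) * E[f]
        b = obs.T @ (m**2 + v)           # sum_i obs * E[f^2]
        s_lam = 1.0 / (b / psi + 1.0 / hp.tau)
        lam = s_lam * a / psi            # posterior mean loading
        log_odds = logit_pi + 0.5 * (np.log(s_lam / hp.tau) + lam**2 / s_lam)
        p = np.clip(expit(log_odds), _PROB_EPS, 1 - _PROB_EPS)

        # E-step: q(f) given q(lambda, rho)
        e_lam2 = lam**2 + s_lam
        w = p * e_lam2 / psi
        v = 1.0 / (1.0 + obs @ w)
        m = v * (R @ (p * lam / psi))

        # M-step: mu and psi
        mu = (np.where(obs, X, 0.0).sum(axis=0) - p * lam * (obs.T @ m)) / n_j
        R = np.where(obs, X - mu, 0.0)
        T = np.where(obs, R - m[:, None] * lam[None, :], 0.0)
        e_f2 = obs.T @ (m**2 + v)
        e_incl = (T**2).sum(axis=0) + lam**2 * (obs.T @ v) + s_lam * e_f2
        e_excl = (R**2).sum(axis=0)
        psi = np.maximum((p * e_incl + (1 - p) * e_excl) / n_j, _PSI_FLOOR)

        # evidence lower bound
        ll = float(
            np.sum(-0.5 * n_j * np.log(2 * np.pi * psi))
            - np.sum((p * e_incl + (1 - p) * e_excl) / (2 * psi))
        )
        f_term = float(np.sum(-0.5 * (m**2 + v) + 0.5 * (1 + np.log(v))))
        rho_term = float(
            np.sum(
                p * np.log(pi)
                + (1 - p) * np.log1p(-pi)
                - p * np.log(p)
                - (1 - p) * np.log1p(-p)
            )
        )
        lam_term = float(
            np.sum(
                p
                * (
                    0.5 * (1.0 + np.log(s_lam / hp.tau))
                    - (lam**2 + s_lam) / (2.0 * hp.tau)
                )
            )
        )
        elbo = ll + f_term + rho_term + lam_term
        trace.append(elbo)
        if elbo - elbo_prev < hp.tol * (1.0 + abs(elbo)) and n_iter > 1:
            converged = True
            break
        elbo_prev = elbo

    if not converged:
        warnings.warn(
            f"{seed_protein}: factor EM did not converge in {hp.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    seed_probs = p[:n_seed]
    if (seed_probs < hp.membership_threshold).all():
        raise DegenerateFactorError(f"{seed_protein}: all seed peptides excluded")

    # sign convention: mean seed-member loading positive
    seed_members = seed_probs >= hp.membership_threshold
    if lam[:n_seed][seed_members].mean() < 0:
        lam, m = -lam, -m

    sd = m.std()
    if sd <= 0:
        raise DegenerateFactorError(f"{seed_protein}: degenerate (constant) factor score")
    score = (m - m.mean()) / sd

    member_mask = p >= hp.membership_threshold
    members = [
        (cols[j], float(lam[j]), float(p[j])) for j in np.nonzero(member_mask)[0]
    ]
    name = str(
        table.features.loc[usable_seed[0], "peptide_label"]
    )
    mp = Metaprotein(
        name=name,
        seed_protein=seed_protein,
        members=members,
        coverage_pct=np.nan,
        signature_pct=np.nan,
        inclusion_probs=pd.Series(p, index=cols),
        loadings=pd.Series(lam, index=cols),
    )
    mp.coverage_pct, mp.signature_pct = composition_metrics(mp, table)
    return _FactorFitState(
        metaprotein=mp,
        score=pd.Series(score, index=table.intensities.columns, name=name),
        residual_variances=pd.Series(psi, index=cols),
        objective_trace=np.asarray(trace),
        n_iterations=n_iter,
        converged=converged,
    )


def composition_metrics(mp: Metaprotein, table: IsotopeGroupTable) -> tuple[float, float]:
    """(% coverage, % signature) of a fitted metaprotein.

    Coverage: share of the seed protein's identified isotope groups that are
    factor members.  Signature: share of factor members that come from the
    seed protein.
    """
    seed_features = set(
        table.features.index[table.features["protein_id"] == mp.seed_protein]
    )
    members = set(mp.member_ids)
    coverage = 100.0 * len(members & seed_features) / len(seed_features)
    signature = 100.0 * len(members & seed_features) / len(members) if members else 0.0
    return coverage, signature


def peptide_correlations(mp: Metaprotein, table: IsotopeGroupTable) -> pd.DataFrame:
    """Pairwise Pearson correlations of member peptide intensities.

    Pairwise-complete samples; pairs with fewer than 3 overlapping samples
    get a missing entry and a warning.
    """
    member_ids = mp.member_ids
    if len(member_ids) < 2:
        raise DegenerateFactorError("need >= 2 members for a correlation matrix")
    frame = table.intensities.loc[member_ids].T
    corr = frame.corr(min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().any().any():
        warnings.warn(
            f"{mp.name}: some peptide pairs have < 3 overlapping samples",
            RuntimeWarning,
            stacklevel=2,
        )
    return corr


def fit_all(table: IsotopeGroupTable, hp: FactorHyperparams) -> MetaproteinFit:
    """Fit one metaprotein per seed protein, independently.

    The candidate set for each factor is every feature not assigned to the
    seed protein (identified elsewhere or unidentified), so a feature may end
    up in several metaproteins.  Per-factor failures are skipped and counted.
    """
    seeds = seed_factors(table)
    all_ids = list(table.features.index)

    factors: list[Metaprotein] = []
    score_columns: dict[str, pd.Series] = {}
    residual_variances: dict[str, pd.Series] = {}
    n_iterations: dict[str, int] = {}
    skipped: list[tuple[str, str]] = []
    all_converged = True

    for protein_id, seed_ids in seeds:
        seed_set = set(
            table.features.index[table.features["protein_id"] == protein_id]
        )
        candidates = [fid for fid in all_ids if fid not in seed_set]
        try:
            state = fit_metaprotein(table, protein_id, seed_ids, candidates, hp)
        except DegenerateFactorError as exc:
            logger.warning("skipping factor %s: %s", protein_id, exc)
            skipped.append((protein_id, str(exc)))
            continue
        name = state.metaprotein.name
        if name in score_columns:  # disambiguate duplicate short names
            name = f"{name}({protein_id})"
            state.metaprotein.name = name
            state.score.name = name
        factors.append(state.metaprotein)
        score_columns[name] = state.score
        residual_variances[name] = state.residual_variances
        n_iterations[name] = state.n_iterations
        all_converged = all_converged and state.converged
        logger.info(
            "factor %s: %d members, %d iterations, converged=%s",
            name,
            len(state.metaprotein.members),
            state.n_iterations,
            state.converged,
        )

    if not factors:
        raise DegenerateFactorError(
            f"all {len(seeds)} factors failed: " + "; ".join(msg for _, msg in skipped)
        )
    scores = pd.DataFrame(score_columns)
    return MetaproteinFit(
        factors=factors,
        scores=scores,
        residual_variances=residual_variances,
        n_iterations=n_iterations,
        converged=all_converged,
        seed=hp.seed,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_fit(fit: MetaproteinFit, directory, hp: FactorHyperparams, provenance: dict | None = None) -> None:
    """Serialize a fit as scores.tsv / membership.tsv / composition.tsv / fit_meta.yaml."""
    from pathlib import Path

    from .tables import provenance_lines

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = "".join(line + "\n" for line in provenance_lines(provenance))

    with open(directory / "scores.tsv", "w") as fh:
        fh.write(header)
        fit.scores.rename_axis("sample_id").reset_index().to_csv(fh, sep="\t", index=False)

    membership = pd.DataFrame(
        [
            (mp.name, fid, lam, prob)
            for mp in fit.factors
            for fid, lam, prob in mp.members
        ],
        columns=["factor", "feature_id", "loading", "inclusion_prob"],
    )
    with open(directory / "membership.tsv", "w") as fh:
        fh.write(header)
        membership.to_csv(fh, sep="\t", index=False)

    composition = pd.DataFrame(
        [(mp.name, mp.coverage_pct, mp.signature_pct) for mp in fit.factors],
        columns=["factor", "coverage_pct", "signature_pct"],
    )
    with open(directory / "composition.tsv", "w") as fh:
        fh.write(header)
        composition.to_csv(fh, sep="\t", index=False)

    meta = {
        "hyperparams": hp.to_dict(),
        "seed": fit.seed,
        "converged": bool(fit.converged),
        "n_factors": fit.k,
        "n_iterations": fit.n_iterations,
        "skipped": [list(item) for item in fit.skipped],
    }
    with open(directory / "fit_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_scores(directory) -> pd.DataFrame:
    """Read back a serialized score matrix (samples x metaproteins)."""
    from pathlib import Path

    frame = pd.read_csv(Path(directory) / "scores.tsv", sep="\t", comment="#")
    return frame.set_index("sample_id")
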