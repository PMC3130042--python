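"""End-to-end orchestration: factors -> scan -> peptide tests -> mediation.

The stages mirror how a serum pQTL analysis is actually run: seed and fit
one metaprotein per identified protein, scan every metaprotein score against
the SNP with sex/race adjustment and Bonferroni control, re-test the
component peptides of each Bonferroni-significant metaprotein individually,
and — when a treatment outcome is available — ask whether the top hit
mediates the genotype-outcome association via nested logistic models.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import ScanResult, qq_points, peptide_level_tests, scan
from .factor import FactorHyperparams, MetaproteinFit, fit_all, save_fit
from .mediation import MediationResult, mediation_analysis
from .tables import CohortTable, IsotopeGroupTable, provenance_lines

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "report_text", "write_outputs", "config_hash"]


@dataclass
class PipelineResult:
    fit: MetaproteinFit
    scans: dict[str, ScanResult]                  # keyed by genotype model
    peptide_tests: dict[str, ScanResult]          # keyed by factor name
    mediation: MediationResult | None
    mediation_factor: str | None
    primary_model: str

    @property
    def primary_scan(self) -> ScanResult:
        return self.scans[self.primary_model]


def config_hash(payload: dict) -> str:
    canonical = yaml.safe_dump(payload, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def run_pipeline(
    table: IsotopeGroupTable,
    cohort: CohortTable,
    hp: FactorHyperparams | None = None,
    model: str = "additive",
    family_alpha: float = 0.05,
    mediation_ci: str = "profile",
) -> PipelineResult:
    """Run every stage on in-memory tables.

    ``model`` is 'additive', 'recessive' or 'both' (both scans run; the
    additive one drives significance calls, matching the primary analysis).
    """
    if set(table.sample_ids) != set(cohort.sample_ids):
        raise_mismatch = set(table.sample_ids) ^ set(cohort.sample_ids)
        from .errors import DimensionError

        raise DimensionError(f"isotope and cohort tables disagree on samples: {sorted(raise_mismatch)}")
    cohort_data = cohort.data.loc[table.sample_ids]
    cohort = CohortTable(data=cohort_data)

    hp = hp or FactorHyperparams()
    fit = fit_all(table, hp)

    allele = cohort.allele_counts
    covariates = cohort.covariates.reset_index(drop=True)
    models = ["additive", "recessive"] if model == "both" else [model]
    scans = {m: scan(fit.scores, allele, covariates, model=m, family_alpha=family_alpha) for m in models}
    primary_model = models[0]

    peptide_tests: dict[str, ScanResult] = {}
    for result in scans[primary_model].significant:
        mp = next(f for f in fit.factors if f.name == result.target_id)
        peptide_tests[mp.name] = peptide_level_tests(
            table, mp.member_ids, allele, covariates, model=primary_model
        )

    mediation_result = None
    mediation_factor = None
    if cohort.has_outcome and scans[primary_model].significant:
        top = scans[primary_model].significant[0]
        mediation_factor = top.target_id
        mediation_result = mediation_analysis(
            cohort.outcome01,
            cohort.recessive_indicator,
            fit.scores[top.target_id].to_numpy(),
            covariates,
            ci_method=mediation_ci,
        )
    elif not cohort.has_outcome:
        logger.info("no outcome column: mediation stage skipped")
    else:
        logger.info("no Bonferroni-significant factor: mediation stage skipped")

    return PipelineResult(
        fit=fit,
        scans=scans,
        peptide_tests=peptide_tests,
        mediation=mediation_result,
        mediation_factor=mediation_factor,
        primary_model=primary_model,
    )


def _format_or(fit) -> str:
    return (
        f"OR={fit.odds_ratio:.3g} (95% CI {fit.ci95[0]:.3g}, {fit.ci95[1]:.3g}) "
        f"p={fit.p_value:.3g} [{fit.method}{'' if fit.converged else ', flagged'}]"
    )


def report_text(result: PipelineResult) -> str:
    """Human-readable run summary."""
    fit = result.fit
    scan_res = result.primary_scan
    lines = [
        f"metaproteins fitted: K={fit.k} (skipped: {len(fit.skipped)})",
        f"association model: {result.primary_model}; "
        f"Bonferroni alpha = {scan_res.bonferroni_alpha:.3g} over {scan_res.n_tests} tests",
        f"significant metaproteins: {len(scan_res.significant)}",
    ]
    for res in scan_res.significant:
        mp = next(f for f in fit.factors if f.name == res.target_id)
        lines.append(
            f"  {res.target_id}: beta={res.beta:.3f} p={res.p_value:.3g} "
            f"r2_genotype={res.r2_genotype:.3f} "
            f"coverage={mp.coverage_pct:.1f}% signature={mp.signature_pct:.1f}% "
            f"members={len(mp.members)}"
        )
        pep = result.peptide_tests.get(res.target_id)
        if pep is not None:
            n_sig = len(pep.significant)
            lines.append(
                f"    component peptides: {n_sig}/{pep.n_tests} significant at "
                f"Bonferroni alpha {pep.bonferroni_alpha:.3g}"
            )
    if result.mediation is not None:
        med = result.mediation
        lines += [
            f"mediation ({result.mediation_factor} as mediator):",
            f"  outcome ~ mediator + sex + race:          {_format_or(med.fit_m_only)}",
            f"  outcome ~ genotype + sex + race:          {_format_or(med.fit_g_only)}",
            f"  joint, genotype term:                     {_format_or(med.fit_joint_g)}",
            f"  joint, mediator term:                     {_format_or(med.fit_joint_m)}",
            f"  verdict: {med.attenuation_verdict}",
        ]
    else:
        lines.append("mediation: skipped")
    return "\n".join(lines) + "\n"


def _scan_frame(scans: dict[str, ScanResult]) -> pd.DataFrame:
    rows = []
    for model, scan_res in scans.items():
        for res in scan_res.results:
            rows.append(
                {
                    "target": res.target_id,
                    "model": res.model,
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p_value,
                    "r2_genotype": res.r2_genotype,
                    "r2_partial": res.r2_partial,
                    "n_used": res.n_used,
                    "significant": res.p_value <= scan_res.bonferroni_alpha,
                }
            )
    return pd.DataFrame(rows)


def _mediation_frame(result: PipelineResult) -> pd.DataFrame:
    med = result.mediation
    rows = []
    specs = [
        ("outcome~mediator+sex+race", med.fit_m_only),
        ("outcome~genotype+sex+race", med.fit_g_only),
        ("outcome~genotype+mediator+sex+race[genotype]", med.fit_joint_g),
        ("outcome~genotype+mediator+sex+race[mediator]", med.fit_joint_m),
    ]
    for spec_name, fit in specs:
        for item in [fit] + ([fit.fallback] if fit.fallback is not None else []):
            rows.append(
                {
                    "model": spec_name,
                    "predictor": item.predictor,
                    "odds_ratio": item.odds_ratio,
                    "ci_low": item.ci95[0],
                    "ci_high": item.ci95[1],
                    "ci_low_wald": item.ci95_wald[0],
                    "ci_high_wald": item.ci95_wald[1],
                    "p": item.p_value,
                    "method": item.method,
                    "n_used": item.n_used,
                    "converged": item.converged,
                }
            )
    rows.append(
        {
            "model": "verdict",
            "predictor": med.attenuation_verdict,
            "odds_ratio": float("nan"),
            "ci_low": float("nan"),
            "ci_high": float("nan"),
            "ci_low_wald": float("nan"),
            "ci_high_wald": float("nan"),
            "p": float("nan"),
            "method": "",
            "n_used": med.fit_m_only.n_used,
            "converged": True,
        }
    )
    return pd.DataFrame(rows)


def write_outputs(
    result: PipelineResult,
    outdir,
    hp: FactorHyperparams,
    provenance: dict | None = None,
) -> None:
    """Write fit directory, scan.tsv, qq.tsv, mediation.tsv and report.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "".join(line + "\n" for line in provenance_lines(provenance))

    save_fit(result.fit, outdir / "fit", hp, provenance=provenance)

    with open(outdir / "scan.tsv", "w") as fh:
        fh.write(header)
        _scan_frame(result.scans).to_csv(fh, sep="\t", index=False)

    points = qq_points([r.p_value for r in result.primary_scan.results])
    with open(outdir / "qq.tsv", "w") as fh:
        fh.write(header)
        pd.DataFrame(points, columns=["expected", "observed"]).to_csv(fh, sep="\t", index=False)

    if result.mediation is not None:
        with open(outdir / "mediation.tsv", "w") as fh:
            fh.write(header)
            _mediation_frame(result).to_csv(fh, sep="\t", index=False)

    with open(outdir / "report.txt", "w") as fh:
        fh.write(header)
        fh.write(report_text(result))


def standard_provenance(seed: int, config: dict) -> dict:
    return {
        "tool": f"metapqtl {__version__}",
        "seed": seed,
        "config_hash": config_hash(config),
    }
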