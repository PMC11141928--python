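"""End-to-end pipeline: score -> segregate -> biallelic model -> enrichment.

The pipeline consumes a trio cohort (in memory, or VCF + PED from disk),
applies QC and qualifying-variant filters, detects biallelic genotypes per
family, summarises qualifying probands per gene for the case and control
sub-cohorts, evaluates the closed-form biallelic inheritance probability
per population for the candidate gene, and runs the enrichment statistics.
A single JSON report collects every stage's numbers along with provenance
(config hash, seed, package version); identical config + seed give an
identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from trioburden import __version__ as _version
from trioburden import vcfio
from trioburden.annotation import (
    AnnotatedVariant,
    PREDICTOR_NAMES,
    ScoringConfig,
    score_variant,
    qualifying_variant,
)
from trioburden.biallelic import (
    biallelic_probability,
    expected_vs_observed,
    monte_carlo_mating,
)
from trioburden.enrichment import TwoByTwo, bonferroni, fisher_exact
from trioburden.segregation import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    cohort_summary,
    detect_biallelic,
    detect_de_novo,
)
from trioburden.simulate import TrioCohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "annotated_variants",
    "apply_qc",
    "score_cohort",
    "detect_cohort",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    vcf: Optional[str] = None
    ped: Optional[str] = None
    freq_table: Optional[str] = None
    outdir: str = "trioburden_out"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    target_gene: Optional[str] = None  # default: top-ranked gene in cases
    seed: int = 0
    mc_sims: int = 200_000
    run_monte_carlo: bool = True
    call_de_novo: bool = True


def annotated_variants(cohort: TrioCohort, pops=None) -> list:
    """Build AnnotatedVariant objects from the cohort's variant table."""
    frame = cohort.variants
    if pops is None:
        pops = [c[4:] for c in frame.columns if c.startswith("maf_")]
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        predictor_calls = {n: d[f"pred_{n}"] for n in PREDICTOR_NAMES}
        predictor_calls["CADD"] = float(d["cadd"])
        out.append(
            AnnotatedVariant(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                gene=d["gene"],
                consequence=d["consequence"],
                in_domain=bool(d["domain_flag"]),
                predictor_calls=predictor_calls,
                conservation_scores={
                    "GERP": float(d["gerp"]),
                    "phyloP": float(d["phylop"]),
                    "SiPhy": float(d["siphy"]),
                    "phastCons": float(d["phastcons"]),
                },
                maf_by_population={p: float(d[f"maf_{p}"]) for p in pops},
            )
        )
    return out


def apply_qc(cohort: TrioCohort, config: ScoringConfig) -> dict:
    """In-place QC: drop failing sites, set failing calls to missing.

    Vectorised equivalent of per-call ``qc_filter``: sites failing the
    FILTER or indel-size rule are masked entirely; calls with depth <= 10x,
    or carrying the alt allele at a fraction <= 4:10, become missing.
    Returns an audit dict of drop counts per rule.
    """
    variants = cohort.variants
    indel_len = (
        variants["ref"].str.len() - variants["alt"].str.len()
    ).abs().to_numpy()
    site_fail = indel_len > config.max_indel_len
    audit = {"sites_indel_size": int(site_fail.sum())}
    cohort.gt[site_fail, :] = MISSING

    depth_fail = cohort.dp <= config.min_depth
    carrier = (cohort.gt == HET) | (cohort.gt == HOM_ALT)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(cohort.dp > 0, cohort.ad_alt / np.maximum(cohort.dp, 1), 0.0)
    ratio_fail = carrier & (frac <= config.min_allelic_ratio)
    call_fail = (depth_fail | ratio_fail) & ~site_fail[:, None]
    audit["calls_depth"] = int((depth_fail & ~site_fail[:, None]).sum())
    audit["calls_allelic_ratio"] = int(
        (ratio_fail & ~depth_fail & ~site_fail[:, None]).sum()
    )
    cohort.gt[call_fail] = MISSING
    for rule, count in audit.items():
        if count:
            logger.info("QC dropped %d (%s)", count, rule)
    return audit


def score_cohort(cohort: TrioCohort, config: ScoringConfig) -> pd.DataFrame:
    """Score every variant; returns a frame with scores + qualifying flag."""
    rows = []
    for av in annotated_variants(cohort):
        scores = score_variant(av, config)
        rows.append(
            {
                "variant_id": av.variant_id,
                "gene": av.gene,
                "consequence": av.consequence,
                "in_domain": av.in_domain,
                "max_maf": max(av.maf_by_population.values()),
                "damage_proportion": scores.damage_proportion,
                "conservation_proportion": scores.conservation_proportion,
                "n_predictors_available": scores.n_predictors_available,
                "n_conservation_available": scores.n_conservation_available,
                "qualifying": qualifying_variant(av, scores, config),
            }
        )
    return pd.DataFrame(rows)


def detect_cohort(
    cohort: TrioCohort, qualifying_by_gene: dict, call_de_novo: bool = True
) -> list:
    """Run biallelic (and optional de novo) detection across all families.

    Families are pre-screened vectorially (a compound het needs >= 2
    proband-het qualifying variants in one gene; an AR homozygote needs a
    proband hom-alt; a de novo call needs a proband carrier with both
    parents hom-ref) and only candidates go through the per-trio logic.
    """
    events = []
    if not qualifying_by_gene:
        return events
    vid_index = pd.Index(cohort.variants["variant_id"])
    qual_rows = {
        gene: vid_index.get_indexer(vids) for gene, vids in qualifying_by_gene.items()
    }
    all_rows = np.concatenate(list(qual_rows.values()))
    all_vids = [v for vids in qualifying_by_gene.values() for v in vids]
    vid_to_gene = {
        v: gene for gene, vids in qualifying_by_gene.items() for v in vids
    }
    pb = cohort.gt[:, 2::3]
    fa = cohort.gt[:, 0::3]
    mo = cohort.gt[:, 1::3]
    candidates = np.zeros(cohort.n_families, dtype=bool)
    for gene, rows in qual_rows.items():
        het_count = (pb[rows] == HET).sum(axis=0)
        hom_any = (pb[rows] == HOM_ALT).any(axis=0)
        candidates |= (het_count >= 2) | hom_any
    if call_de_novo:
        dn = (
            ((pb[all_rows] == HET) | (pb[all_rows] == HOM_ALT))
            & (fa[all_rows] == HOM_REF)
            & (mo[all_rows] == HOM_REF)
        ).any(axis=0)
        candidates |= dn
    for i in np.flatnonzero(candidates):
        trio = cohort.trio_genotypes(int(i), all_vids)
        events.extend(detect_biallelic(trio, qualifying_by_gene))
        if call_de_novo:
            events.extend(detect_de_novo(trio, vid_to_gene))
    return events


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    fields = dataclasses.asdict(config)
    for path_field in ("vcf", "ped", "freq_table", "outdir"):
        fields.pop(path_field, None)  # analysis parameters only, not paths
    blob = json.dumps(fields, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, cohort: Optional[TrioCohort] = None
) -> dict:
    """Execute score -> segregate -> biallelic-prob -> enrich; write outputs.

    ``cohort`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``config.vcf`` / ``config.ped``.  Returns the
    report dict (also written to ``<outdir>/report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        if not (config.vcf and config.ped):
            raise ValueError("either a cohort object or vcf+ped paths are required")
        cohort = vcfio.read_cohort(config.vcf, config.ped)

    try:
        audit = apply_qc(cohort, config.scoring)
        scored = score_cohort(cohort, config.scoring)
        scored.to_csv(outdir / "variants_scored.tsv", sep="\t", index=False)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pipeline stage 'score' failed: {exc}") from exc

    qualifying = scored[scored["qualifying"]]
    qualifying_by_gene = {
        gene: list(grp["variant_id"]) for gene, grp in qualifying.groupby("gene")
    }

    try:
        events = detect_cohort(cohort, qualifying_by_gene, config.call_de_novo)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pipeline stage 'segregate' failed: {exc}") from exc
    events_frame = pd.DataFrame(
        [
            {
                "family_id": e.family_id,
                "gene": e.gene,
                "variant_a": e.variant_a,
                "variant_b": e.variant_b,
                "phase": e.phase or "",
                "model": e.model,
            }
            for e in events
        ],
        columns=["family_id", "gene", "variant_a", "variant_b", "phase", "model"],
    )
    events_frame.to_csv(outdir / "events.tsv", sep="\t", index=False)

    case_mask = cohort.families["is_case"].to_numpy(dtype=bool)
    case_ids = set(cohort.families.loc[case_mask, "family_id"])
    case_fams = cohort.families.loc[case_mask]
    ctrl_fams = cohort.families.loc[~case_mask]
    case_events = [e for e in events if e.family_id in case_ids]
    ctrl_events = [e for e in events if e.family_id not in case_ids]

    summaries = {}
    for label, evs, fams in (
        ("cases", case_events, case_fams),
        ("controls", ctrl_events, ctrl_fams),
    ):
        if len(fams):
            summary = cohort_summary(evs, list(fams["family_id"]))
        else:
            summary = pd.DataFrame(columns=["gene", "k", "n", "pct"])
        summary.to_csv(outdir / f"gene_summary_{label}.tsv", sep="\t", index=False)
        summaries[label] = summary

    report: dict = {
        "provenance": {
            "package_version": _version,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "qc_audit": audit,
            "n_variants": int(cohort.n_variants),
            "n_qualifying_variants": int(len(qualifying)),
            "n_case_families": int(case_mask.sum()),
            "n_control_families": int((~case_mask).sum()),
        },
        "events": {
            "total": len(events),
            "compound_het": sum(e.model == "compound_het" for e in events),
            "homozygous": sum(e.model == "homozygous" for e in events),
            "de_novo": sum(e.model == "de_novo" for e in events),
        },
        "gene_summaries": {
            label: s.to_dict(orient="records") for label, s in summaries.items()
        },
        "biallelic_model": {},
        "enrichment": [],
    }

    if not events:
        report["note"] = "no qualifying biallelic events; no tests run"
        _write_report(report, outdir)
        return report

    # --- enrichment: case vs control carriers per gene --------------------
    case_summary = summaries["cases"]
    fisher_rows = []
    for rec in case_summary.itertuples(index=False):
        ctrl = summaries["controls"]
        krow = ctrl[ctrl["gene"] == rec.gene]
        k2 = int(krow["k"].iloc[0]) if len(krow) else 0
        n2 = len(ctrl_fams)
        if n2 == 0:
            continue
        res = fisher_exact(TwoByTwo(rec.k, rec.n, k2, n2))
        fisher_rows.append(
            {
                "test": res.test,
                "gene": rec.gene,
                **res.inputs,
                "odds_ratio": res.statistic,
                "p_value": res.p_value,
            }
        )
    if fisher_rows:
        padj = bonferroni([r["p_value"] for r in fisher_rows])
        for r, p in zip(fisher_rows, padj):
            r["p_adjusted"] = float(p)
    report["enrichment"] = fisher_rows

    # --- biallelic inheritance model for the target gene -------------------
    target = config.target_gene
    if target is None and len(case_summary):
        target = case_summary["gene"].iloc[0]
    if target is not None:
        pops = [c[4:] for c in cohort.variants.columns if c.startswith("maf_")]
        gene_qual = qualifying[qualifying["gene"] == target]["variant_id"]
        sub = cohort.variants.set_index("variant_id").loc[list(gene_qual)]
        k_cases = int(case_summary.loc[case_summary["gene"] == target, "k"].sum())
        n_cases = len(case_fams)
        model_rows = []
        rng_seed = np.random.default_rng([config.seed, 3])
        for pop in pops:
            freqs = sub[f"maf_{pop}"].to_numpy(dtype=float)
            res = biallelic_probability(freqs)
            row = {
                "gene": target,
                "population": pop,
                "n_variants": res.n_variants,
                "A": res.A,
                "B": res.B,
                "P": res.P,
            }
            if config.run_monte_carlo and config.mc_sims > 0:
                mc = monte_carlo_mating(
                    freqs, config.mc_sims, rng_seed.integers(2**31)
                )
                row.update(
                    {
                        "mc_estimate": mc.estimate,
                        "mc_ci_low": mc.ci_low,
                        "mc_ci_high": mc.ci_high,
                        "mc_formula_ratio": (mc.estimate / res.P) if res.P > 0 else None,
                    }
                )
            if n_cases > 0:
                cmp = expected_vs_observed(k_cases, n_cases, res.P)
                row.update(
                    {"k": cmp.k, "n": cmp.n, "binomial_p": cmp.p_value,
                     "binomial_alternative": cmp.alternative}
                )
            model_rows.append(row)
        if model_rows and n_cases > 0:
            padj = bonferroni([r["binomial_p"] for r in model_rows])
            for r, p in zip(model_rows, padj):
                r["binomial_p_adjusted"] = float(p)
        pd.DataFrame(model_rows).to_csv(
            outdir / "biallelic_model.tsv", sep="\t", index=False
        )
        report["biallelic_model"] = {"target_gene": target, "per_population": model_rows}

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )
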