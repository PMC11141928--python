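"""Synthetic trio cohorts with planted in-trans compound-het variant pairs.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without protected cohort data:

* per-population rare-variant allele-frequency spectra (truncated
  exponential on the rare tail, all MAFs < 0.01), with per-population
  multipliers to emulate ancestry-enriched frequencies;
* parental genotypes drawn under Hardy-Weinberg from the family's
  population MAF, proband genotypes by Mendelian transmission;
* a configured fraction of case families receiving a planted in-trans
  compound-het pair in a target gene (father het at v1, mother het at v2,
  proband het at both with opposite parental origins), and optionally a
  per-family rate of such pairs among control families;
* predictor/conservation annotations written so planted variants pass the
  damaging/conserved thresholds with a configured probability and
  background variants at a (lower) background rate, with scores straddling
  the thresholds.

Identical seed + config produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from trioburden.annotation import PREDICTOR_NAMES
from trioburden.segregation import Family, Member, TrioGenotypes

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "TrioCohort",
    "generate_frequency_table",
    "generate_trio_cohort",
]


class ConfigurationError(ValueError):
    pass


#: damaging labels actually emitted per predictor (VCF-safe spellings)
_DAMAGING_LABELS = (
    "damaging",
    "deleterious",
    "disease_causing",
    "possibly_damaging",
    "probably_damaging",
    "medium",
)
_BENIGN_LABELS = ("tolerated", "benign", "neutral", "polymorphism", "low")


@dataclass
class SimulationConfig:
    """Study conditions of a simulated trio cohort.

    Defaults mirror the discovery design: 16 case trios of which a 0.1875
    fraction (3 families) carry a planted in-trans pair in the candidate
    gene, and a comparator cohort of 1,700 trios in which such pairs occur
    at a ~1.2% per-family rate.
    """

    n_case_families: int = 16
    n_control_families: int = 1700
    n_genes: int = 5
    variants_per_gene: int = 30
    maf_scale: float = 5e-4  # exponential scale of the rare-tail spectrum
    maf_min: float = 1e-5
    maf_max: float = 0.01
    maf_jitter_sigma: float = 0.3  # per-population lognormal jitter (clipped 2 sigma)
    planted_gene: str = "GENE1"
    planted_fraction: float = 0.1875
    control_planted_fraction: float = 0.012
    population_labels: tuple = ("AFR", "NFE", "EAS")
    per_population_maf_multipliers: tuple = (1.0, 1.0, 1.0)
    predictor_damaging_rate: float = 1.0
    background_damaging_rate: float = 0.0
    plant_de_novo: bool = False
    de_novo_fraction: float = 0.0
    qc_fail_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case_families", "n_genes", "variants_per_gene"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_control_families < 0:
            raise ConfigurationError("n_control_families must be >= 0")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ConfigurationError("planted_fraction must lie in [0, 1]")
        if not 0.0 <= self.control_planted_fraction <= 1.0:
            raise ConfigurationError("control_planted_fraction must lie in [0, 1]")
        if len(self.population_labels) != len(self.per_population_maf_multipliers):
            raise ConfigurationError(
                "per_population_maf_multipliers must match population_labels"
            )
        if not self.population_labels:
            raise ConfigurationError("at least one population label required")
        if not 0 < self.maf_min < self.maf_max <= 0.01:
            raise ConfigurationError("require 0 < maf_min < maf_max <= 0.01")
        for rate in (
            self.predictor_damaging_rate,
            self.background_damaging_rate,
            self.qc_fail_rate,
            self.de_novo_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")

    @property
    def gene_names(self) -> list:
        return [f"GENE{i + 1}" for i in range(self.n_genes)]


def _truncated_exponential(rng, n, scale, lo, hi) -> np.ndarray:
    """Inverse-CDF sampling of Exp(scale) truncated to (lo, hi)."""
    a, b = math.exp(-lo / scale), math.exp(-hi / scale)
    u = rng.random(n)
    return -scale * np.log(a - u * (a - b))


def generate_frequency_table(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Variant x population MAF table with the configured rare spectrum.

    Each variant has a base frequency from a truncated exponential on the
    rare tail; each population's MAF is the base scaled by that population's
    multiplier times an i.i.d. lognormal jitter (clipped at two sigma so the
    expected ratio of population means equals the multiplier ratio and every
    MAF stays strictly below ``maf_max``).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    n_var = config.n_genes * config.variants_per_gene
    max_mult = max(config.per_population_maf_multipliers)
    headroom = max_mult * math.exp(2 * config.maf_jitter_sigma)
    hi = config.maf_max / headroom * (1 - 1e-9)
    if hi <= config.maf_min:
        raise ConfigurationError(
            "maf_max too small for the configured multipliers/jitter"
        )
    base = _truncated_exponential(rng, n_var, config.maf_scale, config.maf_min, hi)

    bases = np.array(list("ACGT"))
    rows = []
    idx = 0
    for g, gene in enumerate(config.gene_names):
        chrom = str((g % 22) + 1)
        start = 1_000_000 * (1 + g // 22)
        planted = gene == config.planted_gene
        for j in range(config.variants_per_gene):
            ref = bases[rng.integers(4)]
            alt = bases[(np.flatnonzero(bases != ref))[rng.integers(3)]]
            pos = start + 150 * j
            domain = bool(rng.random() < (0.8 if planted else 0.5))
            rows.append(
                {
                    "variant_id": f"{chrom}:{pos}:{ref}:{alt}",
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "domain_flag": int(domain),
                    "_base_maf": base[idx],
                }
            )
            idx += 1
    frame = pd.DataFrame(rows)
    sigma = config.maf_jitter_sigma
    for pop, mult in zip(
        config.population_labels, config.per_population_maf_multipliers
    ):
        z = np.clip(rng.normal(0.0, sigma, n_var), -2 * sigma, 2 * sigma) if sigma > 0 else 0.0
        frame[f"maf_{pop}"] = frame["_base_maf"].to_numpy() * mult * np.exp(z)
    frame = frame.drop(columns="_base_maf")
    frame = frame.sort_values(["chrom", "pos"], key=_chrom_sort_key).reset_index(drop=True)
    return frame


def _chrom_sort_key(col):
    if col.name == "chrom":
        return col.astype(int)
    return col


@dataclass
class TrioCohort:
    """An in-memory simulated (or re-read) trio cohort.

    ``gt`` has one row per variant (same order as ``variants``) and three
    columns per family, ordered father, mother, proband; codes 0/1/2/-1.
    """

    variants: pd.DataFrame  # annotations incl. predictor/conservation/MAF columns
    families: pd.DataFrame  # family_id, is_case, population, sex columns
    gt: np.ndarray
    dp: np.ndarray
    ad_alt: np.ndarray
    truth: pd.DataFrame
    config: Optional[SimulationConfig] = None

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def sample_ids(self) -> list:
        out = []
        for fid in self.families["family_id"]:
            out.extend([f"{fid}_FA", f"{fid}_MO", f"{fid}_PB"])
        return out

    def family_columns(self, i: int) -> tuple:
        """(father, mother, proband) column indices of family i."""
        return 3 * i, 3 * i + 1, 3 * i + 2

    def to_families(self) -> list:
        fams = []
        for _, row in self.families.iterrows():
            fid = row["family_id"]
            fams.append(
                Family(
                    fid,
                    [
                        Member(f"{fid}_FA", "father", False),
                        Member(f"{fid}_MO", "mother", False),
                        Member(f"{fid}_PB", "proband", bool(row["is_case"])),
                    ],
                )
            )
        return fams

    def trio_genotypes(self, i: int, variant_ids: Sequence[str]) -> TrioGenotypes:
        """Extract a TrioGenotypes restricted to the given variant ids."""
        fa, mo, pb = self.family_columns(i)
        vid_index = pd.Index(self.variants["variant_id"])
        rows = vid_index.get_indexer(list(variant_ids))
        if (rows < 0).any():
            missing = [v for v, r in zip(variant_ids, rows) if r < 0]
            raise KeyError(f"unknown variant ids: {missing}")
        return TrioGenotypes(
            family_id=self.families["family_id"].iloc[i],
            proband={v: int(self.gt[r, pb]) for v, r in zip(variant_ids, rows)},
            mother={v: int(self.gt[r, mo]) for v, r in zip(variant_ids, rows)},
            father={v: int(self.gt[r, fa]) for v, r in zip(variant_ids, rows)},
        )

    def write(self, outdir, prefix: str = "cohort") -> dict:
        """Write VCF + PED + truth TSV; returns the paths."""
        from trioburden import vcfio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / f"{prefix}.vcf",
            "ped": outdir / f"{prefix}.ped",
            "truth": outdir / f"{prefix}_truth.tsv",
        }
        vcfio.write_vcf(self, paths["vcf"])
        vcfio.write_ped(self, paths["ped"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


_TRUTH_COLUMNS = ["family_id", "gene", "variant_a", "variant_b", "model", "cohort"]


def _draw_trio_genotypes(rng, p):
    """HWE parents + Mendelian transmission; p is (n_var, n_fam) MAFs."""
    father = rng.binomial(2, p).astype(np.int8)
    mother = rng.binomial(2, p).astype(np.int8)
    t_fa = (father == 2) | ((father == 1) & (rng.random(p.shape) < 0.5))
    t_mo = (mother == 2) | ((mother == 1) & (rng.random(p.shape) < 0.5))
    proband = (t_fa.astype(np.int8) + t_mo.astype(np.int8))
    return father, mother, proband


def generate_trio_cohort(
    config: SimulationConfig, freq_table: pd.DataFrame
) -> TrioCohort:
    """Simulate the full cohort (genotypes, annotations, QC fields, truth).

    Parental genotypes are drawn per variant from the family's population
    MAF under Hardy-Weinberg; probands follow Mendelian transmission.  For
    each planted family the father carries v1 (het), the mother v2 (het),
    and the proband is het at both with v1 paternal and v2 maternal.  The
    number of planted case families is floor(planted_fraction x
    n_case_families); control families are planted independently at
    ``control_planted_fraction`` per family.
    """
    config.validate()
    for pop in config.population_labels:
        if f"maf_{pop}" not in freq_table.columns:
            raise ConfigurationError(f"frequency table lacks maf_{pop}")
    rng = np.random.default_rng([config.seed, 2])

    variants = freq_table.copy().reset_index(drop=True)
    n_var = len(variants)
    gene_arr = variants["gene"].to_numpy()
    planted_gene_rows = np.flatnonzero(gene_arr == config.planted_gene)
    if config.planted_fraction > 0 or config.control_planted_fraction > 0:
        if planted_gene_rows.size == 0:
            raise ConfigurationError(
                f"no variants in planted gene {config.planted_gene!r}"
            )

    # --- families --------------------------------------------------------
    n_case, n_ctrl = config.n_case_families, config.n_control_families
    n_fam = n_case + n_ctrl
    fids = [f"FAM{i + 1:04d}" for i in range(n_case)] + [
        f"CTL{i + 1:04d}" for i in range(n_ctrl)
    ]
    pop_idx = rng.integers(len(config.population_labels), size=n_fam)
    families = pd.DataFrame(
        {
            "family_id": fids,
            "is_case": [True] * n_case + [False] * n_ctrl,
            "population": [config.population_labels[i] for i in pop_idx],
            "proband_sex": rng.integers(1, 3, size=n_fam),
        }
    )

    # --- genotypes -------------------------------------------------------
    maf_matrix = np.column_stack(
        [variants[f"maf_{p}"].to_numpy() for p in config.population_labels]
    )
    p = maf_matrix[:, pop_idx]  # (n_var, n_fam)
    father, mother, proband = _draw_trio_genotypes(rng, p)

    # --- consequence / domain eligibility --------------------------------
    consequence = np.where(
        gene_arr == config.planted_gene,
        "missense",
        rng.choice(["missense", "synonymous", "lof", "other"], size=n_var,
                   p=[0.65, 0.25, 0.05, 0.05]),
    )
    eligible = planted_gene_rows[
        (consequence[planted_gene_rows] == "missense")
        & (variants["domain_flag"].to_numpy()[planted_gene_rows] == 1)
    ]

    # --- planting --------------------------------------------------------
    n_planted_exact = config.planted_fraction * n_case
    n_planted = math.floor(n_planted_exact)
    truth_rows = []
    planted_variant_rows: set = set()

    def plant_pair(fam_idx: int) -> tuple:
        v1, v2 = rng.choice(eligible, size=2, replace=False)
        father[v1, fam_idx], father[v2, fam_idx] = 1, 0
        mother[v1, fam_idx], mother[v2, fam_idx] = 0, 1
        proband[v1, fam_idx], proband[v2, fam_idx] = 1, 1
        planted_variant_rows.update((int(v1), int(v2)))
        return int(v1), int(v2)

    if n_planted > 0 or config.control_planted_fraction > 0:
        if eligible.size < 2:
            raise ConfigurationError(
                f"planted gene {config.planted_gene!r} has fewer than 2 "
                "in-domain missense variants"
            )
    planted_case = sorted(rng.choice(n_case, size=n_planted, replace=False)) if n_planted else []
    for i in planted_case:
        v1, v2 = plant_pair(i)
        truth_rows.append(
            {
                "family_id": fids[i],
                "gene": config.planted_gene,
                "variant_a": variants["variant_id"].iloc[v1],
                "variant_b": variants["variant_id"].iloc[v2],
                "model": "compound_het",
                "cohort": "case",
            }
        )
    if n_ctrl and config.control_planted_fraction > 0:
        ctrl_mask = rng.random(n_ctrl) < config.control_planted_fraction
        for i in np.flatnonzero(ctrl_mask):
            fam_idx = n_case + int(i)
            v1, v2 = plant_pair(fam_idx)
            truth_rows.append(
                {
                    "family_id": fids[fam_idx],
                    "gene": config.planted_gene,
                    "variant_a": variants["variant_id"].iloc[v1],
                    "variant_b": variants["variant_id"].iloc[v2],
                    "model": "compound_het",
                    "cohort": "control",
                }
            )
    if config.plant_de_novo and config.de_novo_fraction > 0:
        n_dn = math.floor(config.de_novo_fraction * n_case)
        candidates = [i for i in range(n_case) if i not in set(planted_case)]
        for i in sorted(rng.choice(candidates, size=min(n_dn, len(candidates)), replace=False)):
            v = int(rng.choice(eligible))
            father[v, i], mother[v, i], proband[v, i] = 0, 0, 1
            planted_variant_rows.add(v)
            truth_rows.append(
                {
                    "family_id": fids[i],
                    "gene": config.planted_gene,
                    "variant_a": variants["variant_id"].iloc[v],
                    "variant_b": "",
                    "model": "de_novo",
                    "cohort": "case",
                }
            )
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)

    # --- predictor / conservation annotations ----------------------------
    is_planted = np.zeros(n_var, dtype=bool)
    if planted_variant_rows:
        is_planted[sorted(planted_variant_rows)] = True
    damaging_rate = np.where(
        is_planted, config.predictor_damaging_rate, config.background_damaging_rate
    )
    damaging = rng.random(n_var) < damaging_rate
    ann = _annotate(rng, n_var, damaging)
    variants["consequence"] = consequence
    for k, v in ann.items():
        variants[k] = v

    # --- per-call QC fields ----------------------------------------------
    gt = np.empty((n_var, 3 * n_fam), dtype=np.int8)
    gt[:, 0::3], gt[:, 1::3], gt[:, 2::3] = father, mother, proband
    dp = rng.integers(25, 81, size=gt.shape).astype(np.int16)
    if config.qc_fail_rate > 0:
        fail = rng.random(gt.shape) < config.qc_fail_rate
        dp[fail] = rng.integers(1, 11, size=int(fail.sum()))
    ad_alt = np.zeros_like(dp)
    het = gt == 1
    hom = gt == 2
    # het alt reads: binomial around 0.5, clamped strictly above the 4:10 ratio
    raw = rng.binomial(dp, 0.5)
    floor_ok = (np.floor(0.4 * dp) + 1).astype(np.int16)
    ad_alt[het] = np.maximum(raw, floor_ok)[het]
    ad_alt[hom] = np.maximum(rng.binomial(dp, 0.98), floor_ok)[hom]

    return TrioCohort(
        variants=variants,
        families=families,
        gt=gt,
        dp=dp,
        ad_alt=ad_alt,
        truth=truth,
        config=config,
    )


def _annotate(rng, n_var: int, damaging: np.ndarray) -> dict:
    """Predictor labels + CADD + conservation scores straddling thresholds.

    Damaging variants get 4-8 qualifying predictor calls (of 8, CADD
    included) and 2-4 strong conservation scores; background variants get
    at most 1 of each, so they land below the 0.25/0.5 score cut-offs.
    """
    out: dict = {}
    n_dmg_calls = np.where(damaging, rng.integers(4, 9, n_var), rng.integers(0, 2, n_var))
    n_cons_calls = np.where(damaging, rng.integers(2, 5, n_var), rng.integers(0, 2, n_var))

    # which of the 8 predictor slots (7 labels + CADD) qualify
    order = np.argsort(rng.random((n_var, 8)), axis=1)
    qualifies = order < n_dmg_calls[:, None]  # (n_var, 8); col 7 = CADD
    for j, name in enumerate(PREDICTOR_NAMES):
        dmg_lab = rng.choice(_DAMAGING_LABELS, size=n_var)
        ben_lab = rng.choice(_BENIGN_LABELS, size=n_var)
        out[f"pred_{name}"] = np.where(qualifies[:, j], dmg_lab, ben_lab)
    out["cadd"] = np.where(
        qualifies[:, 7], rng.uniform(12.5, 35.0, n_var), rng.uniform(0.0, 11.8, n_var)
    )

    cons_order = np.argsort(rng.random((n_var, 4)), axis=1)
    cons_q = cons_order < n_cons_calls[:, None]
    bands = {  # (below_lo, below_hi, above_lo, above_hi)
        "gerp": (0.0, 4.3, 4.5, 6.2),
        "phylop": (-2.0, 1.5, 1.7, 3.0),
        "siphy": (0.0, 11.8, 12.2, 20.0),
        "phastcons": (0.0, 0.49, 0.51, 1.0),
    }
    for j, (name, (blo, bhi, alo, ahi)) in enumerate(bands.items()):
        out[name] = np.where(
            cons_q[:, j], rng.uniform(alo, ahi, n_var), rng.uniform(blo, bhi, n_var)
        )
    return out
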