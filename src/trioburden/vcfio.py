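"""VCFv4.2 / PED / TSV reading and writing for trio cohorts.

Annotations travel as custom INFO keys: ``GENE``, ``CSQ_CLASS``, ``DOMAIN``
(0/1), ``PRED_<NAME>`` (categorical label), ``CADD``/``GERP``/``PHYLOP``/
``SIPHY``/``PHASTCONS`` (float), and ``MAF_<POP>`` (float per population).
Per-sample FORMAT is ``GT:DP:AD``.  Reading goes through cyvcf2; writing
emits plain text so the files stay diffable and deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from trioburden.annotation import PREDICTOR_NAMES
from trioburden.simulate import TrioCohort

__all__ = [
    "write_vcf",
    "write_ped",
    "read_cohort",
    "write_frequency_table",
    "read_frequency_table",
]

_FLOAT_FMT = "%.9g"
_SCORE_KEYS = ("CADD", "GERP", "PHYLOP", "SIPHY", "PHASTCONS")
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _maf_columns(variants: pd.DataFrame) -> list:
    return [c for c in variants.columns if c.startswith("maf_")]


def write_vcf(cohort: TrioCohort, path) -> None:
    variants = cohort.variants
    maf_cols = _maf_columns(variants)
    pops = [c[4:] for c in maf_cols]
    chroms = list(dict.fromkeys(variants["chrom"]))
    lines = ["##fileformat=VCFv4.2", "##source=trioburden-simulate"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    info_defs = [
        ("GENE", "1", "String", "Gene symbol"),
        ("CSQ_CLASS", "1", "String", "Consequence class"),
        ("DOMAIN", "1", "Integer", "1 if inside the configured protein domain"),
    ]
    info_defs += [
        (f"PRED_{n.upper()}", "1", "String", f"{n} prediction label")
        for n in PREDICTOR_NAMES
    ]
    info_defs += [(k, "1", "Float", f"{k} score") for k in _SCORE_KEYS]
    info_defs += [(f"MAF_{p}", "1", "Float", f"MAF in population {p}") for p in pops]
    for iid, num, typ, desc in info_defs:
        lines.append(
            f'##INFO=<ID={iid},Number={num},Type={typ},Description="{desc}">'
        )
    lines += [
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += cohort.sample_ids
    lines.append("\t".join(header))

    score_cols = {k: variants[k.lower()].to_numpy() for k in _SCORE_KEYS}
    pred_cols = {n: variants[f"pred_{n}"].to_numpy() for n in PREDICTOR_NAMES}
    maf_arrays = {c: variants[c].to_numpy() for c in maf_cols}
    for r in range(len(variants)):
        row = variants.iloc[r]
        info = [
            f"GENE={row['gene']}",
            f"CSQ_CLASS={row['consequence']}",
            f"DOMAIN={int(row['domain_flag'])}",
        ]
        info += [f"PRED_{n.upper()}={pred_cols[n][r]}" for n in PREDICTOR_NAMES]
        info += [f"{k}={_FLOAT_FMT % score_cols[k][r]}" for k in _SCORE_KEYS]
        info += [f"MAF_{c[4:]}={_FLOAT_FMT % maf_arrays[c][r]}" for c in maf_cols]
        fields = [
            str(row["chrom"]),
            str(row["pos"]),
            row["variant_id"],
            row["ref"],
            row["alt"],
            ".",
            "PASS",
            ";".join(info),
            "GT:DP:AD",
        ]
        gt, dp, ad = cohort.gt[r], cohort.dp[r], cohort.ad_alt[r]
        for s in range(gt.shape[0]):
            fields.append(f"{_GT_STR[int(gt[s])]}:{dp[s]}:{dp[s] - ad[s]},{ad[s]}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def write_ped(cohort: TrioCohort, path) -> None:
    """6-column PED: FID IID FATHER MOTHER SEX PHENO (2=affected)."""
    rows = []
    for _, fam in cohort.families.iterrows():
        fid = fam["family_id"]
        pheno = "2" if fam["is_case"] else "1"
        rows.append(f"{fid}\t{fid}_FA\t0\t0\t1\t1")
        rows.append(f"{fid}\t{fid}_MO\t0\t0\t2\t1")
        rows.append(
            f"{fid}\t{fid}_PB\t{fid}_FA\t{fid}_MO\t{fam['proband_sex']}\t{pheno}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_cohort(vcf_path, ped_path) -> TrioCohort:
    """Re-read a written cohort; inverse of write_vcf/write_ped.

    Population labels per family are simulation metadata not representable
    in PED and come back as None.
    """
    ped = pd.read_csv(
        ped_path,
        sep="\t",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    fam_rows = []
    for fid, grp in ped.groupby("fid", sort=False):
        probands = grp[(grp["father"] != "0") & (grp["mother"] != "0")]
        if len(probands) != 1:
            raise ValueError(f"family {fid}: expected exactly one proband in PED")
        pb = probands.iloc[0]
        fam_rows.append(
            {
                "family_id": fid,
                "is_case": pb["pheno"] == "2",
                "population": None,
                "proband_sex": int(pb["sex"]),
            }
        )
    families = pd.DataFrame(fam_rows)

    vcf = VCF(str(vcf_path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    order = []  # VCF sample column -> cohort column order (FA, MO, PB per family)
    for fid in families["family_id"]:
        for suffix in ("_FA", "_MO", "_PB"):
            order.append(sample_index[fid + suffix])
    order = np.asarray(order)

    var_rows, gts, dps, ads = [], [], [], []
    gt_map = {0: 0, 1: 1, 3: 2, 2: -1}
    for v in vcf:
        info = dict(v.INFO)
        row = {
            "variant_id": v.ID,
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0],
            "gene": info["GENE"],
            "domain_flag": int(info["DOMAIN"]),
            "consequence": info["CSQ_CLASS"],
        }
        for n in PREDICTOR_NAMES:
            row[f"pred_{n}"] = info[f"PRED_{n.upper()}"]
        for k in _SCORE_KEYS:
            row[k.lower()] = float(info[k])
        for key, value in info.items():
            if key.startswith("MAF_"):
                row[f"maf_{key[4:]}"] = float(value)
        var_rows.append(row)
        gts.append([gt_map[t] for t in v.gt_types])
        dps.append(v.format("DP")[:, 0])
        ads.append(v.format("AD")[:, 1])
    variants = pd.DataFrame(var_rows)
    gt = np.asarray(gts, dtype=np.int8)[:, order]
    dp = np.asarray(dps, dtype=np.int16)[:, order]
    ad = np.asarray(ads, dtype=np.int16)[:, order]
    return TrioCohort(
        variants=variants,
        families=families,
        gt=gt,
        dp=dp,
        ad_alt=ad,
        truth=pd.DataFrame(),
        config=None,
    )


def write_frequency_table(freq_table: pd.DataFrame, path) -> None:
    freq_table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_frequency_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
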