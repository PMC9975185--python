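"""Reading, harmonizing and QC-filtering GWAS summary statistics, and the
join with LD reference information.

Input tables are headered, whitespace- or tab-delimited text (gzip
transparent); column names are mapped onto a canonical schema via a name
map with sensible defaults for the common GWAS dialects.  Effects are
standardized to the per-SD-genotype / per-SD-phenotype scale
``tau = z / sqrt(n)`` with sampling variance ``1/n``, alleles harmonized
across the two tables (sign flips for swapped effect alleles,
strand-ambiguous SNPs dropped), QC filters applied, and the survivors
joined with the LD reference into a :class:`~mrci.data.SummaryDataset`.
"""

from __future__ import annotations

import logging
import pathlib

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import LdReference, SummaryDataset

__all__ = [
    "read_gwas_table",
    "standardize_effects",
    "harmonize_alleles",
    "qc_filter",
    "QcConfig",
    "build_dataset",
    "read_ld_reference",
    "write_gwas_table",
    "write_ld_reference",
    "load_pipeline",
]

logger = logging.getLogger("mrci.io")

#: default header aliases, lowercased
_ALIASES = {
    "snp_id": ("snp", "snpid", "rsid", "rs_id", "markername", "id"),
    "effect_allele": ("a1", "effect_allele", "ea", "allele1", "alt"),
    "other_allele": ("a2", "other_allele", "oa", "allele2", "ref", "nea"),
    "effect": ("beta", "b", "effect", "log_odds"),
    "se": ("se", "stderr", "standard_error"),
    "z": ("z", "zscore", "z_score", "zstat"),
    "n": ("n", "nobs", "sample_size", "neff"),
    "maf": ("maf", "frq", "freq", "eaf", "af"),
    "info": ("info", "imputation_quality", "rsq"),
    "chrom": ("chr", "chrom", "chromosome"),
    "pos": ("bp", "pos", "position", "base_pair"),
}

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def read_gwas_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a GWAS summary table into the canonical schema.

    ``column_map`` maps canonical names (``snp_id``, ``effect``, ``se``,
    ``z``, ``n``, ``maf``, ``info``, ``chrom``, ``pos``, alleles) to the
    file's column names, overriding the built-in aliases.
    """
    df = pd.read_csv(path, sep=r"\s+", compression="infer")
    lower = {c.lower(): c for c in df.columns}
    out = {}
    for canon, aliases in _ALIASES.items():
        if column_map and canon in column_map:
            src = column_map[canon]
            if src in df.columns:
                out[canon] = df[src]
            continue
        for a in aliases:
            if a in lower:
                out[canon] = df[lower[a]]
                break
    if "snp_id" not in out:
        raise ValueError(f"{path}: no SNP id column found")
    res = pd.DataFrame(out)
    res["snp_id"] = res["snp_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        if col in res:
            res[col] = res[col].astype(str).str.upper()
    if res["snp_id"].duplicated().any():
        dup = res["snp_id"].duplicated(keep="first")
        logger.warning("%s: dropping %d duplicated SNP ids", path, int(dup.sum()))
        res = res[~dup]
    return res.reset_index(drop=True)


def standardize_effects(table: pd.DataFrame):
    """Standardize to ``tau = z / sqrt(n)``; ``se`` becomes ``1/sqrt(n)``.

    Rows without a usable (effect, se, n) or (z, n) combination are
    rejected; returns ``(table, rejects)`` where ``rejects`` maps a reason
    code to the number of rows removed.
    """
    t = table.copy()
    rejects = {"missing_n": 0, "bad_se": 0, "missing_effect": 0}

    n = pd.to_numeric(t.get("n"), errors="coerce") if "n" in t else None
    if n is None:
        raise ValueError("sample-size column required for standardization")
    ok_n = n.notna() & (n > 0)
    rejects["missing_n"] = int((~ok_n).sum())

    if "z" in t and t["z"].notna().any():
        z = pd.to_numeric(t["z"], errors="coerce")
        ok = ok_n & z.notna()
        rejects["missing_effect"] = int((ok_n & ~z.notna()).sum())
    else:
        eff = pd.to_numeric(t.get("effect"), errors="coerce")
        se = pd.to_numeric(t.get("se"), errors="coerce")
        if eff is None or se is None:
            raise ValueError("need either a z column or effect + se columns")
        bad_se = se.notna() & (se <= 0)
        rejects["bad_se"] = int((ok_n & bad_se).sum())
        ok = ok_n & eff.notna() & se.notna() & (se > 0)
        rejects["missing_effect"] = int((ok_n & (eff.isna() | se.isna())).sum())
        z = eff / se
    t = t[ok].copy()
    n = n[ok]
    t["tau"] = (z[ok] / np.sqrt(n)).astype(float)
    t["se"] = 1.0 / np.sqrt(n.astype(float))
    t["n"] = n.astype(float)
    return t.reset_index(drop=True), rejects


def harmonize_alleles(t1: pd.DataFrame, t2: pd.DataFrame, ref: LdReference):
    """Align two standardized tables to the LD reference order.

    Keeps the intersection of the three SNP id sets, sign-flips ``t2``'s
    standardized effects where its effect allele is the other table's other
    allele (directly or on the complementary strand), and removes
    strand-ambiguous (A/T, C/G) and allele-mismatched SNPs.
    """
    common = [
        s for s in ref.snp_ids
        if s in set(t1.snp_id) and s in set(t2.snp_id)
    ]
    if not common:
        raise ValueError("no common SNPs between the two tables and the reference")
    a = t1.set_index("snp_id").loc[common].copy()
    b = t2.set_index("snp_id").loc[common].copy()

    keep = np.ones(len(common), dtype=bool)
    flip = np.zeros(len(common), dtype=bool)
    has_alleles = {"effect_allele", "other_allele"} <= set(a.columns) and {
        "effect_allele",
        "other_allele",
    } <= set(b.columns)
    if has_alleles:
        for i, s in enumerate(common):
            ea1, oa1 = a.effect_allele.iloc[i], a.other_allele.iloc[i]
            ea2, oa2 = b.effect_allele.iloc[i], b.other_allele.iloc[i]
            if (ea1, oa1) in _AMBIGUOUS or (ea2, oa2) in _AMBIGUOUS:
                keep[i] = False
                continue
            c_ea2 = _COMPLEMENT.get(ea2, "?")
            c_oa2 = _COMPLEMENT.get(oa2, "?")
            if (ea2, oa2) == (ea1, oa1) or (c_ea2, c_oa2) == (ea1, oa1):
                continue
            if (ea2, oa2) == (oa1, ea1) or (c_ea2, c_oa2) == (oa1, ea1):
                flip[i] = True
            else:
                keep[i] = False  # allele mismatch
    a = a[keep]
    b = b[keep]
    flip = flip[keep]
    if "tau" in b:
        b.loc[flip, "tau"] = -b.loc[flip, "tau"]
    if "effect" in b:
        b.loc[flip, "effect"] = -b.loc[flip, "effect"]
    if has_alleles:
        b.loc[flip, ["effect_allele", "other_allele"]] = b.loc[
            flip, ["other_allele", "effect_allele"]
        ].values
    return a.reset_index(), b.reset_index()


class QcConfig:
    """Thresholds for summary-statistic QC."""

    def __init__(
        self,
        maf_min: float = 0.05,
        info_min: float = 0.9,
        n_fraction: float = 0.67,
        mhc_chrom: str = "6",
        mhc_start: int = 25_000_000,
        mhc_end: int = 34_000_000,
        max_abs_tau: float = 0.1,
    ):
        self.maf_min = maf_min
        self.info_min = info_min
        self.n_fraction = n_fraction
        self.mhc_chrom = str(mhc_chrom)
        self.mhc_start = mhc_start
        self.mhc_end = mhc_end
        self.max_abs_tau = max_abs_tau


def qc_filter(table: pd.DataFrame, config: QcConfig | None = None):
    """Apply the summary-statistic exclusion rules.

    Removes SNPs with MAF < 5%, INFO < 0.9, per-SNP sample size below 0.67
    of the 90th percentile, position inside the MHC region, or
    |standardized effect| > 0.1.  Returns ``(table, report)`` with per-rule
    exclusion counts; applying the filter twice equals applying it once.
    """
    cfg = config or QcConfig()
    t = table
    report = {}
    if len(t) == 0:
        return t.copy(), report

    drop = pd.Series(False, index=t.index)

    def apply_rule(name, mask):
        new = mask & ~drop
        report[name] = int(new.sum())
        return drop | new

    if "maf" in t and t["maf"].notna().any():
        maf = pd.to_numeric(t["maf"], errors="coerce")
        maf = np.minimum(maf, 1.0 - maf)  # fold allele frequency
        drop = apply_rule("MAF", maf.notna() & (maf < cfg.maf_min))
    if "info" in t and t["info"].notna().any():
        info = pd.to_numeric(t["info"], errors="coerce")
        drop = apply_rule("INFO", info.notna() & (info < cfg.info_min))
    if "n" in t and t["n"].notna().any():
        n = pd.to_numeric(t["n"], errors="coerce")
        cutoff = cfg.n_fraction * np.nanpercentile(n, 90)
        drop = apply_rule("N", n.notna() & (n < cutoff))
    if {"chrom", "pos"} <= set(t.columns):
        chrom = t["chrom"].astype(str).str.replace("chr", "", regex=False)
        pos = pd.to_numeric(t["pos"], errors="coerce")
        in_mhc = (
            (chrom == cfg.mhc_chrom)
            & (pos >= cfg.mhc_start)
            & (pos <= cfg.mhc_end)
        )
        drop = apply_rule("MHC", in_mhc.fillna(False))
    if "tau" in t:
        drop = apply_rule("EFFECT", t["tau"].abs() > cfg.max_abs_tau)
    return t[~drop].reset_index(drop=True), report


def build_dataset(t1: pd.DataFrame, t2: pd.DataFrame, ref: LdReference) -> SummaryDataset:
    """Join two harmonized, QC'd tables with the LD reference.

    SNPs missing from the reference are dropped with a warning; LD scores
    and tag counts keep their reference values (they describe population
    LD, not the analysis set), while the tagging adjacency is restricted to
    retained SNPs for the downstream score sums.  Sample sizes are the
    per-table medians.
    """
    ids1 = set(t1.snp_id)
    ids2 = set(t2.snp_id)
    keep_idx = [
        i for i, s in enumerate(ref.snp_ids) if s in ids1 and s in ids2
    ]
    missing = (ids1 & ids2) - set(ref.snp_ids)
    if missing:
        logger.warning("%d SNPs absent from LD reference; dropped", len(missing))
    if not keep_idx:
        raise ValueError("no SNPs remain after joining with the LD reference")
    keep_idx = np.array(keep_idx)
    ids = ref.snp_ids[keep_idx]
    a = t1.set_index("snp_id").loc[ids]
    b = t2.set_index("snp_id").loc[ids]
    adj = ref.adjacency[keep_idx][:, keep_idx]
    return SummaryDataset(
        ids,
        a["tau"].to_numpy(float),
        b["tau"].to_numpy(float),
        ref.ld_score[keep_idx],
        adj,
        float(np.median(a["n"])),
        float(np.median(b["n"])),
    )


def read_ld_reference(scores_path, pairs_path=None) -> LdReference:
    """Read an LD reference: a score table plus an optional tag-pair list.

    The score table needs SNP-id and LD-score columns (the LDSC
    ``.l2.ldscore`` dialect with columns CHR/SNP/BP/L2 is accepted).  The
    pair file lists one tagged pair of SNP ids per line (two columns);
    without it, tagging is self-only.
    """
    df = pd.read_csv(scores_path, sep=r"\s+", compression="infer")
    lower = {c.lower(): c for c in df.columns}
    snp_col = next((lower[a] for a in ("snp", "snp_id", "rsid", "id") if a in lower), None)
    l2_col = next((lower[a] for a in ("l2", "ld_score", "ldscore") if a in lower), None)
    if snp_col is None or l2_col is None:
        raise ValueError(f"{scores_path}: need SNP and L2 columns")
    ids = df[snp_col].astype(str).to_numpy(object)
    l2 = df[l2_col].to_numpy(float)
    if pairs_path is None:
        return LdReference.self_only(ids) if np.allclose(l2, 1.0) else LdReference(
            ids, l2, sp.identity(len(ids), dtype=np.int8, format="csr")
        )
    pairs_df = pd.read_csv(pairs_path, sep=r"\s+", compression="infer")
    pairs = list(
        zip(pairs_df.iloc[:, 0].astype(str), pairs_df.iloc[:, 1].astype(str))
    )
    return LdReference.from_pairs(ids, l2, pairs)


def write_gwas_table(data: SummaryDataset, trait: int, path) -> None:
    """Write one trait's summary statistics (SNP A1 A2 Z N) as TSV."""
    tau = data.tau1 if trait == 1 else data.tau2
    n = data.n1 if trait == 1 else data.n2
    df = pd.DataFrame(
        {
            "SNP": data.snp_ids,
            "A1": "A",
            "A2": "G",
            "Z": tau * np.sqrt(n),
            "N": int(n),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_ld_reference(data: SummaryDataset, scores_path, pairs_path) -> None:
    """Write the LD reference of a dataset (scores + tag pairs) as TSV."""
    pd.DataFrame({"SNP": data.snp_ids, "L2": data.ld_score}).to_csv(
        scores_path, sep="\t", index=False
    )
    coo = sp.triu(data.adjacency, k=1).tocoo()
    pd.DataFrame(
        {"SNP_A": data.snp_ids[coo.row], "SNP_B": data.snp_ids[coo.col]}
    ).to_csv(pairs_path, sep="\t", index=False)


def load_pipeline(gwas1, gwas2, ld_scores, ld_pairs=None, qc=True,
                  column_map=None, qc_config=None):
    """Full preprocessing: read, standardize, harmonize, QC, join.

    Returns ``(SummaryDataset, report)`` where the report collects the
    standardization rejects and per-rule QC exclusions for both tables.
    """
    ref = read_ld_reference(ld_scores, ld_pairs)
    t1 = read_gwas_table(gwas1, column_map)
    t2 = read_gwas_table(gwas2, column_map)
    t1, rej1 = standardize_effects(t1)
    t2, rej2 = standardize_effects(t2)
    t1, t2 = harmonize_alleles(t1, t2, ref)
    report = {"standardize_1": rej1, "standardize_2": rej2}
    if qc:
        t1, qc1 = qc_filter(t1, qc_config)
        t2, qc2 = qc_filter(t2, qc_config)
        report["qc_1"] = qc1
        report["qc_2"] = qc2
        common = set(t1.snp_id) & set(t2.snp_id)
        t1 = t1[t1.snp_id.isin(common)]
        t2 = t2[t2.snp_id.isin(common)]
    data = build_dataset(t1, t2, ref)
    return data, report
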