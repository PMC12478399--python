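"""Cohort burden summaries and genic / regulatory SV annotation.

Burden summaries report per-cancer-type SV counts (median, min, max) with
stratification by chromothripsis status and TP53 status (two-sided Wilcoxon
rank-sum, restricted to cancer types with at least three TP53-altered
samples) and a per-type Pearson correlation of SV count against age at
diagnosis.

Genic annotation marks genes containing either breakpoint and flags common
fragile site (CFS) genes.  Regulatory annotation evaluates a configurable
set of locus rules describing non-coding SVs that cis-activate oncogenes
(enhancer hijacking, regulatory-region duplication, or regulatory
deletion); each rule is a pure predicate over one SV record.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats


# ---------------------------------------------------------------- burden

def burden_summary(
    svs: pd.DataFrame,
    metadata: pd.DataFrame,
    min_tp53_altered: int = 3,
) -> dict[str, pd.DataFrame]:
    """Summarize SV burden per cancer type with stratified comparisons.

    Returns a dict of tables: ``per_type``, ``per_category``,
    ``tp53`` (stratified medians plus rank-sum p where testable), and
    ``age_correlation``.  Samples with zero SVs stay in every median.
    """
    counts = metadata[["sample_id", "cancer_type", "category",
                       "tp53_status", "chromothripsis",
                       "age_at_diagnosis"]].copy()
    per_sample = svs.groupby("sample_id").size()
    counts["n_svs"] = counts["sample_id"].map(per_sample).fillna(0).astype(int)

    per_type_rows = []
    for ctype, grp in counts.groupby("cancer_type", sort=True):
        if len(grp) == 0:
            continue
        med = float(grp["n_svs"].median())
        ct_pos = grp[grp["chromothripsis"] == "positive"]["n_svs"]
        ct_neg = grp[grp["chromothripsis"] == "negative"]["n_svs"]
        per_type_rows.append({
            "cancer_type": ctype, "n_samples": len(grp),
            "median_svs": med,
            "min_svs": int(grp["n_svs"].min()),
            "max_svs": int(grp["n_svs"].max()),
            "median_svs_chromothripsis_pos":
                float(ct_pos.median()) if len(ct_pos) else np.nan,
            "median_svs_chromothripsis_neg":
                float(ct_neg.median()) if len(ct_neg) else np.nan,
        })
    per_type = pd.DataFrame(per_type_rows)
    if len(per_type):
        nonzero = per_type.loc[per_type["median_svs"] > 0, "median_svs"]
        per_type["fold_range_vs_min_type"] = (
            per_type["median_svs"] / nonzero.min() if len(nonzero) else np.nan
        )

    per_cat = (
        counts.groupby("category")["n_svs"]
        .median().rename("median_svs").reset_index()
    )

    tp53_rows = []
    for ctype, grp in counts.groupby("cancer_type", sort=True):
        alt = grp[grp["tp53_status"] == "altered"]["n_svs"]
        wt = grp[grp["tp53_status"] == "wildtype"]["n_svs"]
        row = {
            "cancer_type": ctype,
            "n_altered": len(alt), "n_wildtype": len(wt),
            "median_altered": float(alt.median()) if len(alt) else np.nan,
            "median_wildtype": float(wt.median()) if len(wt) else np.nan,
            "p_value": np.nan,
        }
        if len(alt) >= min_tp53_altered and len(wt) >= 1:
            row["p_value"] = float(
                stats.ranksums(alt, wt, alternative="two-sided").pvalue
            )
        tp53_rows.append(row)

    age_rows = []
    for ctype, grp in counts.groupby("cancer_type", sort=True):
        g = grp.dropna(subset=["age_at_diagnosis"])
        if len(g) >= 3 and g["n_svs"].nunique() > 1 and g["age_at_diagnosis"].nunique() > 1:
            r, p = stats.pearsonr(g["age_at_diagnosis"], g["n_svs"])
        else:
            r, p = np.nan, np.nan
        age_rows.append({"cancer_type": ctype, "n": len(g), "R": r, "p_value": p})

    return {
        "per_type": per_type,
        "per_category": per_cat,
        "tp53": pd.DataFrame(tp53_rows),
        "age_correlation": pd.DataFrame(age_rows),
        "per_sample": counts,
    }


# ------------------------------------------------------- genic annotation

def annotate_genic(
    svs: pd.DataFrame,
    gene_model: pd.DataFrame,
    fragile_site_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Genes containing either breakpoint of each SV, with a CFS flag.

    Returns one row per (sv, gene) hit with columns ``sv_id, sample_id,
    gene, fragile_site``.
    """
    fragile = fragile_site_genes or set()
    by_chrom = {c: g.sort_values("start") for c, g in gene_model.groupby("chrom")}
    rows = []
    for sv in svs.itertuples(index=False):
        hits: list[str] = []
        for chrom, pos in ((sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)):
            genes = by_chrom.get(chrom)
            if genes is None:
                continue
            inside = genes[(genes["start"] <= pos) & (genes["end"] >= pos)]
            hits.extend(inside["name"])
        for gene in dict.fromkeys(hits):
            rows.append({
                "sv_id": getattr(sv, "sv_id", None),
                "sample_id": sv.sample_id,
                "gene": gene,
                "fragile_site": gene in fragile,
            })
    return pd.DataFrame(rows, columns=["sv_id", "sample_id", "gene", "fragile_site"])


# --------------------------------------------------- regulatory rule engine

def load_regulatory_rules(path: str | Path | None = None) -> list[dict]:
    """Load regulatory locus rules from YAML (packaged asset by default)."""
    if path is None:
        ref = resources.files("svscape.assets") / "regulatory_rules.hg19.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    rules = cfg["rules"]
    for rule in rules:
        for region in _iter_regions(rule):
            if region["start"] > region["end"]:
                raise ValueError(
                    f"rule {rule['name']}: malformed interval "
                    f"{region['chrom']}:{region['start']}-{region['end']}"
                )
    return rules


def _iter_regions(node) -> list[dict]:
    found = []
    if isinstance(node, dict):
        if {"chrom", "start", "end"} <= set(node):
            found.append(node)
        else:
            for v in node.values():
                found.extend(_iter_regions(v))
    elif isinstance(node, list):
        for v in node:
            found.extend(_iter_regions(v))
    return found


def _pos_in(chrom: str, pos: int, region: dict) -> bool:
    return chrom == region["chrom"] and region["start"] <= pos <= region["end"]


def _interval_overlaps(sv, region: dict) -> bool:
    if sv.chrom1 != sv.chrom2 or sv.chrom1 != region["chrom"]:
        return False
    return sv.pos1 <= region["end"] and sv.pos2 >= region["start"]


def _interval_contains(sv, region: dict) -> bool:
    if sv.chrom1 != sv.chrom2 or sv.chrom1 != region["chrom"]:
        return False
    return sv.pos1 <= region["start"] and sv.pos2 >= region["end"]


def _predicate_matches(sv, pred: dict) -> bool:
    """Evaluate one predicate block (all clauses AND-ed) against one SV."""
    if "any_of" in pred:
        return any(_predicate_matches(sv, sub) for sub in pred["any_of"])
    if "sv_types" in pred and sv.sv_type not in pred["sv_types"]:
        return False
    intra = sv.chrom1 == sv.chrom2
    if pred.get("intra_only") and not intra:
        return False
    span = abs(sv.pos2 - sv.pos1) if intra else None
    if "max_span" in pred and (span is None or span >= pred["max_span"]):
        return False
    if "min_span" in pred and (span is None or span < pred["min_span"]):
        return False
    if "breakpoint_in" in pred:
        regions = pred["breakpoint_in"]
        bp_hits = [
            any(_pos_in(c, p, r) for r in regions)
            for c, p in ((sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2))
        ]
        if not any(bp_hits):
            return False
        if "partner_in" in pred:
            partner_regions = pred["partner_in"]
            ends = [(sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)]
            ok = False
            for k in (0, 1):
                if bp_hits[k] and any(
                    _pos_in(*ends[1 - k], r) for r in partner_regions
                ):
                    ok = True
            if not ok:
                return False
    if "overlaps" in pred and not _interval_overlaps(sv, pred["overlaps"]):
        return False
    if "not_contains" in pred:
        nc = pred["not_contains"]
        sv_types = nc.get("sv_types")
        if (sv_types is None or sv.sv_type in sv_types) and _interval_contains(
            sv, nc["region"] if "region" in nc else nc
        ):
            return False
    if "exclude_breakpoint_in" in pred:
        for r in pred["exclude_breakpoint_in"]:
            if _pos_in(sv.chrom1, sv.pos1, r) or _pos_in(sv.chrom2, sv.pos2, r):
                return False
    if "exclude_overlap" in pred:
        ex = pred["exclude_overlap"]
        sv_types = ex.get("sv_types")
        if (sv_types is None or sv.sv_type in sv_types) and _interval_overlaps(
            sv, ex["region"] if "region" in ex else ex
        ):
            return False
    return True


def classify_regulatory(sv, rules: list[dict]) -> list[str]:
    """Names of every regulatory rule the SV satisfies (pure per-SV check)."""
    return [rule["name"] for rule in rules if _predicate_matches(sv, rule)]


def classify_regulatory_cohort(svs: pd.DataFrame, rules: list[dict]) -> pd.DataFrame:
    """Rule matches for a cohort: one row per (sv, rule) hit."""
    rows = []
    for sv in svs.itertuples(index=False):
        for name in classify_regulatory(sv, rules):
            rows.append({
                "sv_id": getattr(sv, "sv_id", None),
                "sample_id": sv.sample_id,
                "rule": name,
            })
    return pd.DataFrame(rows, columns=["sv_id", "sample_id", "rule"])


# ------------------------------------------------------------ prevalence

def disruption_prevalence(
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    feature_col: str = "gene",
) -> pd.DataFrame:
    """Per-cancer-type percentage of samples with each feature impacted.

    A sample counts once per feature regardless of how many SVs hit it, so
    the measure is idempotent under SV duplication.
    """
    type_of = metadata.set_index("sample_id")["cancer_type"]
    denom = metadata.groupby("cancer_type")["sample_id"].nunique()
    hits = annotations[["sample_id", feature_col]].drop_duplicates()
    hits = hits.assign(cancer_type=hits["sample_id"].map(type_of))
    rows = []
    for (feature, ctype), grp in hits.groupby([feature_col, "cancer_type"], sort=True):
        rows.append({
            feature_col: feature, "cancer_type": ctype,
            "n_samples_impacted": grp["sample_id"].nunique(),
            "percent": 100.0 * grp["sample_id"].nunique() / denom[ctype],
        })
    return pd.DataFrame(rows, columns=[
        feature_col, "cancer_type", "n_samples_impacted", "percent",
    ])
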