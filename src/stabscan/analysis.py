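"""Variant-level statistics on top of saturation scans.

Joins population/clinical variant tables to predicted ΔΔG values (with
wild-type consistency enforcement), bins variants by allele frequency,
summarizes groups (median and central 95% range), and estimates the
difference in medians between two variant classes with a bootstrap
confidence interval (10⁴ resamples of each group independently, 2.5/97.5
percentiles of the resampled difference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import ScanTable

logger = logging.getLogger("stabscan.analysis")

VARIANT_COLUMNS = ["protein_id", "residue_index", "wt_aa", "mut_aa"]

#: Allele-frequency bin edges: common AF > 1e-2 >= intermediate > 1e-4 >= rare.
AF_THRESHOLDS = (1e-2, 1e-4)


@dataclass
class JoinStats:
    matched: int
    wt_mismatch: int
    missing: int


@dataclass
class GroupSummary:
    """n, median ΔΔG and the central 95% range (2.5–97.5 percentiles,
    linear interpolation)."""

    n: int
    median_ddg: float
    central95: tuple[float, float]


@dataclass
class BootstrapResult:
    """median(a) − median(b) with a percentile-bootstrap 95% CI."""

    diff: float
    ci95: tuple[float, float]
    n_resamples: int


def annotate_variants(scan: ScanTable | pd.DataFrame,
                      variants: pd.DataFrame
                      ) -> tuple[pd.DataFrame, JoinStats]:
    """Inner-join a variant table onto scan predictions.

    Keys are (protein_id, residue_index, mut_aa); rows whose stated
    wild-type disagrees with the structure's are rejected and counted, as
    are variants with no scan coverage (e.g. unresolved positions) — both
    reported in :class:`JoinStats` and logged.  An empty join is legal.
    """
    scan_df = scan.df if isinstance(scan, ScanTable) else scan
    pred = scan_df.rename(columns={"source_id": "protein_id",
                                   "wt_aa": "wt_aa_structure",
                                   "ddg_kcal_per_mol": "ddg"})
    pred = pred[["protein_id", "residue_index", "mut_aa", "wt_aa_structure",
                 "ddg"]]
    merged = variants.merge(pred, on=["protein_id", "residue_index", "mut_aa"],
                            how="left")
    missing = merged["ddg"].isna()
    mismatch = (~missing) & (merged["wt_aa"] != merged["wt_aa_structure"])
    keep = (~missing) & (~mismatch)
    stats = JoinStats(matched=int(keep.sum()), wt_mismatch=int(mismatch.sum()),
                      missing=int(missing.sum()))
    if stats.wt_mismatch or stats.missing:
        logger.info("annotate_variants: %d matched, %d wild-type mismatches "
                    "rejected, %d without scan coverage dropped",
                    stats.matched, stats.wt_mismatch, stats.missing)
    out = merged.loc[keep].drop(columns=["wt_aa_structure"]).reset_index(drop=True)
    return out, stats


def bin_by_allele_frequency(annotations: pd.DataFrame,
                            thresholds: tuple[float, float] = AF_THRESHOLDS
                            ) -> dict[str, pd.DataFrame]:
    """Partition AF-bearing rows into common / intermediate / rare.

    With the default thresholds: common AF > 1e-2; intermediate
    1e-4 < AF ≤ 1e-2; rare AF ≤ 1e-4.  A value exactly at a threshold goes
    to the lower bin.  Rows without an allele frequency are excluded;
    negative frequencies are an error.
    """
    hi, lo = thresholds
    if not hi > lo > 0:
        raise ValueError("thresholds must satisfy hi > lo > 0")
    af = annotations["allele_frequency"]
    if (af.dropna() < 0).any():
        raise ValueError("negative allele frequency")
    with_af = annotations[af.notna()]
    af = with_af["allele_frequency"]
    return {"common": with_af[af > hi],
            "intermediate": with_af[(af > lo) & (af <= hi)],
            "rare": with_af[af <= lo]}


def summarize(values) -> GroupSummary:
    """Median and central-95% range of a ΔΔG sample (n ≥ 1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty group")
    lo, hi = np.percentile(values, [2.5, 97.5], method="linear")
    return GroupSummary(n=int(values.size),
                        median_ddg=float(np.median(values)),
                        central95=(float(lo), float(hi)))


def bootstrap_median_difference(a, b, n_resamples: int = 10_000,
                                seed: int | None = None) -> BootstrapResult:
    """Difference in medians, median(a) − median(b), with a 95% bootstrap CI.

    Each group is resampled with replacement at its own size
    ``n_resamples`` times; the CI is the 2.5/97.5 percentile of the
    resampled differences.  Deterministic given the seed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = np.random.default_rng(seed)
    diff = float(np.median(a) - np.median(b))
    med_a = np.median(a[rng.integers(0, a.size, size=(n_resamples, a.size))],
                      axis=1)
    med_b = np.median(b[rng.integers(0, b.size, size=(n_resamples, b.size))],
                      axis=1)
    lo, hi = np.percentile(med_a - med_b, [2.5, 97.5], method="linear")
    return BootstrapResult(diff=diff, ci95=(float(lo), float(hi)),
                           n_resamples=n_resamples)


def summarize_classes(annotations: pd.DataFrame, n_resamples: int = 10_000,
                      seed: int | None = None) -> dict:
    """Convenience report: per-class summaries plus the pathogenic−benign
    bootstrap median difference (when both classes are present)."""
    out: dict = {"groups": {}}
    for klass, grp in annotations.groupby("class"):
        out["groups"][klass] = summarize(grp["ddg"])
    if {"pathogenic", "benign"} <= set(out["groups"]):
        path = annotations.loc[annotations["class"] == "pathogenic", "ddg"]
        ben = annotations.loc[annotations["class"] == "benign", "ddg"]
        out["pathogenic_minus_benign"] = bootstrap_median_difference(
            path, ben, n_resamples=n_resamples, seed=seed)
    return out
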