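"""Dice machinery, segmentation-variant harness, age-offset analysis,
one-way ANOVA, volumetric aging analyses and demographics summaries."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .segment import SegConfig, classify_hard, label_mask, segment_em
from .template import (
    PriorLibrary,
    group_for_age,
    scheme_groups,
    warp_priors_to_subject,
)
from .volume import GeometryError, PVEMap, Volume

logger = logging.getLogger(__name__)

TISSUES = ("gm", "wm")

#: The closed set of segmentation-variant labels (the 1 + 1 + 3x3 grid:
#: no-priors, reference priors a priori, and {image-avg a priori,
#: image-avg a posteriori, reference-avg a posteriori} x {young-adult,
#: five-year, ten-year}).
VARIANT_LABELS: tuple[str, ...] = (
    "image",
    "reference-apriori",
    "image-avg-apriori-young",
    "image-avg-apriori-5yr",
    "image-avg-apriori-10yr",
    "image-avg-aposteriori-young",
    "image-avg-aposteriori-5yr",
    "image-avg-aposteriori-10yr",
    "reference-avg-aposteriori-young",
    "reference-avg-aposteriori-5yr",
    "reference-avg-aposteriori-10yr",
)

_AGE_CHOICES = {"young": None, "5yr": "five_year", "10yr": "ten_year"}


@dataclass
class DiceRecord:
    subject_id: str
    tissue: str
    config_label: str
    dice: float

    def __post_init__(self) -> None:
        if self.config_label not in VARIANT_LABELS:
            raise ValueError(f"unknown variant label {self.config_label!r}")
        if not (0.0 <= self.dice <= 1.0):
            raise ValueError("dice outside [0, 1]")


@dataclass
class OffsetRecord:
    subject_id: str
    tissue: str
    template_offset: int      # signed five-year group steps; 0 = self
    dice: float


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); both-empty defined as 1.0 (logged)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        logger.warning("dice of two empty masks: returning 1.0 by convention")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_soft(pve_a: PVEMap, pve_b: PVEMap, tissue: str) -> float:
    """Soft Dice on PVE values (provided for inspection, not for acceptance)."""
    a, b = pve_a.maps[tissue], pve_b.maps[tissue]
    denom = float(a.sum() + b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.minimum(a, b).sum() / denom)


# ---------------------------------------------------------------------------
# variant harness

def _segment_with_entry(case_vol, case_mask, entry, base, usage, seg_kwargs,
                        xf=None):
    priors = warp_priors_to_subject(entry.priors[base], entry.template,
                                    case_vol, case_mask, xf=xf)
    cfg = SegConfig(prior_usage=usage, **seg_kwargs)
    return segment_em(case_vol, case_mask, priors=priors, config=cfg)


@dataclass
class HarnessCase:
    subject_id: str
    volume: Volume
    mask: np.ndarray
    reference_labels: np.ndarray    # gold/proxy standard hard labels
    age: float


def run_variant_harness(
    test_cases: list[HarnessCase],
    prior_library: PriorLibrary,
    seg_kwargs: dict | None = None,
) -> list[DiceRecord]:
    """Run the closed variant set on every case; Dice vs the reference labels.

    Raises ``KeyError`` naming any missing library entry (young-adult,
    five-year and ten-year entries are required for both base references).
    """
    seg_kwargs = seg_kwargs or {}
    records: list[DiceRecord] = []
    for case in test_cases:
        entries = {
            "young": prior_library.young_adult,
            "5yr": prior_library.entry_for_age(case.age, "five_year"),
            "10yr": prior_library.entry_for_age(case.age, "ten_year"),
        }
        # one rigid registration per case: all library templates share the
        # young-adult reference frame, so the transform is reused
        from .register import register_rigid

        case_xf = register_rigid(case.volume, entries["5yr"].template)
        warped_cache: dict[tuple[int, str], dict] = {}

        def priors_for(age_key: str, base: str) -> dict:
            entry = entries[age_key]
            key = (id(entry), base)
            if key not in warped_cache:
                warped_cache[key] = warp_priors_to_subject(
                    entry.priors[base], entry.template, case.volume, case.mask,
                    xf=case_xf,
                )
            return warped_cache[key]

        def seg(priors, usage):
            cfg = SegConfig(prior_usage=usage, **seg_kwargs)
            return segment_em(case.volume, case.mask, priors=priors, config=cfg)

        outputs = {}
        outputs["image"] = seg(None, "a_posteriori")
        outputs["reference-apriori"] = seg(priors_for("young", "image"), "a_priori")
        for age_key in ("young", "5yr", "10yr"):
            outputs[f"image-avg-apriori-{age_key}"] = seg(
                priors_for(age_key, "image"), "a_priori")
            outputs[f"image-avg-aposteriori-{age_key}"] = seg(
                priors_for(age_key, "image"), "a_posteriori")
            outputs[f"reference-avg-aposteriori-{age_key}"] = seg(
                priors_for(age_key, "reference"), "a_posteriori")

        for label in VARIANT_LABELS:
            hard = classify_hard(outputs[label].pve)
            for tissue in TISSUES:
                records.append(DiceRecord(
                    subject_id=case.subject_id,
                    tissue=tissue,
                    config_label=label,
                    dice=dice(label_mask(hard, tissue),
                              label_mask(case.reference_labels, tissue)),
                ))
    return records


# ---------------------------------------------------------------------------
# age-offset analysis

def five_year_offset_grid() -> list[int]:
    """Distinct nonzero signed group offsets over the 14 five-year groups."""
    n = len(scheme_groups("five_year"))
    offsets = {
        j - i
        for i, j in itertools.product(range(n), repeat=2)
        if i != j
    }
    return sorted(offsets)


def age_offset_analysis(
    cases: list[HarnessCase],
    prior_library: PriorLibrary,
    seg_kwargs: dict | None = None,
    include_zero: bool = True,
) -> list[OffsetRecord]:
    """Segment each case with every five-year group's image-avg priors
    (a posteriori) and Dice each offset segmentation against the
    age-appropriate (offset 0) segmentation, per tissue."""
    seg_kwargs = seg_kwargs or {}
    groups = scheme_groups("five_year")
    labels_by_index = [g.label for g in groups]
    records: list[OffsetRecord] = []
    for case in cases:
        own = group_for_age(case.age, "five_year")
        own_idx = labels_by_index.index(own.label)
        from .register import register_rigid

        case_xf = register_rigid(
            case.volume, prior_library.get("five_year", own.label).template
        )
        hard_by_offset: dict[int, np.ndarray] = {}
        for idx, label in enumerate(labels_by_index):
            entry = prior_library.get("five_year", label)
            res = _segment_with_entry(case.volume, case.mask, entry, "image",
                                      "a_posteriori", seg_kwargs, xf=case_xf)
            hard_by_offset[idx - own_idx] = classify_hard(res.pve)
        ref = hard_by_offset[0]
        for offset in sorted(hard_by_offset):
            if offset == 0 and not include_zero:
                continue
            for tissue in TISSUES:
                records.append(OffsetRecord(
                    subject_id=case.subject_id,
                    tissue=tissue,
                    template_offset=offset,
                    dice=dice(label_mask(hard_by_offset[offset], tissue),
                              label_mask(ref, tissue)),
                ))
    return records


def offset_trend(records: list[OffsetRecord], tissue: str = "gm"):
    """Spearman correlation between |offset| and dice (nonzero offsets)."""
    pts = [(abs(r.template_offset), r.dice) for r in records
           if r.tissue == tissue and r.template_offset != 0]
    x, y = zip(*pts)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# statistics

def anova_oneway(values, groups) -> tuple[float, int, int, float]:
    """One-way ANOVA: (F, df_between, df_within, p)."""
    values = np.asarray(values, dtype=np.float64)
    labels = list(groups)
    if len(values) != len(labels):
        raise ValueError("values and groups differ in length")
    uniq = sorted(set(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[[g == u for g in labels]] for u in uniq]
    for u, arr in zip(uniq, by_group):
        if arr.size == 0:
            raise ValueError(f"group {u!r} has zero observations")
    n = values.size
    k = len(uniq)
    df_between, df_within = k - 1, n - k
    if df_within < 1:
        raise ValueError("not enough residual degrees of freedom")
    grand = values.mean()
    ssb = sum(arr.size * (arr.mean() - grand) ** 2 for arr in by_group)
    ssw = sum(((arr - arr.mean()) ** 2).sum() for arr in by_group)
    if ssw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within)) if np.isfinite(f) else 0.0
    return float(f), df_between, df_within, p


# ---------------------------------------------------------------------------
# volumetrics

def tissue_volumes(pve: PVEMap, voxel_volume: float | None = None) -> dict[str, float]:
    """Per-class volume in mm^3: (sum of PVE) x voxel volume; plus GM+WM."""
    if voxel_volume is None:
        voxel_volume = float(abs(np.linalg.det(np.asarray(pve.affine)[:3, :3])))
    out = {k: float(pve.maps[k].sum()) * voxel_volume for k in pve.maps}
    out["gm_wm"] = out["gm"] + out["wm"]
    return out


@dataclass
class TrendReport:
    table: pd.DataFrame                 # per five-year group means and SEs
    gm_slope: float                     # mm^3 / year, linear fit
    gm_slope_ci: tuple[float, float]    # 95% CI
    wm_coeffs: tuple[float, float, float]  # quadratic a, b, c
    wm_vertex_age: float


def volumetric_trend_report(
    volumes: list[dict[str, float]],
    ages: list[float],
    inner_skull: list[float] | None = None,
) -> TrendReport:
    """Five-year-group summary table plus GM linear and WM quadratic fits."""
    df = pd.DataFrame(volumes)
    df["age"] = list(ages)
    df["inner_skull"] = list(inner_skull) if inner_skull is not None else np.nan
    df["group"] = [group_for_age(a, "five_year").label for a in df["age"]]
    order = [g.label for g in scheme_groups("five_year") if g.label in set(df["group"])]
    cols = ["gm", "wm", "om", "gm_wm", "inner_skull"]
    agg = df.groupby("group")[cols].agg(["mean", "sem"])
    agg = agg.reindex(order)

    age_arr = df["age"].to_numpy()
    gm_arr = df["gm"].to_numpy()
    lin = stats.linregress(age_arr, gm_arr)
    tcrit = stats.t.ppf(0.975, len(df) - 2)
    ci = (lin.slope - tcrit * lin.stderr, lin.slope + tcrit * lin.stderr)

    a, b, c = np.polyfit(age_arr, df["wm"].to_numpy(), 2)
    vertex = float(-b / (2 * a)) if a != 0 else np.nan
    return TrendReport(
        table=agg,
        gm_slope=float(lin.slope),
        gm_slope_ci=(float(ci[0]), float(ci[1])),
        wm_coeffs=(float(a), float(b), float(c)),
        wm_vertex_age=vertex,
    )


# ---------------------------------------------------------------------------
# demographics

#: Published per-five-year-group counts of the validation cohorts
#: (total, female, then per-source scan counts), used to exercise the
#: demographics summary on real numbers.
SOURCE_COHORT_COUNTS: list[dict] = [
    {"group": "20-24", "total": 244, "female": 139, "ixi": 42, "mcbi": 88, "nihpd": 26, "oasis_cs": 88, "oasis_long": 0},
    {"group": "25-29", "total": 101, "female": 62, "ixi": 58, "mcbi": 15, "nihpd": 0, "oasis_cs": 28, "oasis_long": 0},
    {"group": "30-34", "total": 79, "female": 29, "ixi": 52, "mcbi": 16, "nihpd": 0, "oasis_cs": 11, "oasis_long": 0},
    {"group": "35-39", "total": 50, "female": 22, "ixi": 44, "mcbi": 1, "nihpd": 0, "oasis_cs": 5, "oasis_long": 0},
    {"group": "40-44", "total": 61, "female": 37, "ixi": 47, "mcbi": 4, "nihpd": 0, "oasis_cs": 10, "oasis_long": 0},
    {"group": "45-49", "total": 65, "female": 33, "ixi": 41, "mcbi": 3, "nihpd": 0, "oasis_cs": 21, "oasis_long": 0},
    {"group": "50-54", "total": 57, "female": 38, "ixi": 38, "mcbi": 2, "nihpd": 0, "oasis_cs": 17, "oasis_long": 0},
    {"group": "55-59", "total": 73, "female": 45, "ixi": 55, "mcbi": 2, "nihpd": 0, "oasis_cs": 16, "oasis_long": 0},
    {"group": "60-64", "total": 83, "female": 58, "ixi": 61, "mcbi": 0, "nihpd": 0, "oasis_cs": 11, "oasis_long": 11},
    {"group": "65-69", "total": 89, "female": 54, "ixi": 51, "mcbi": 1, "nihpd": 0, "oasis_cs": 14, "oasis_long": 23},
    {"group": "70-74", "total": 101, "female": 70, "ixi": 37, "mcbi": 0, "nihpd": 0, "oasis_cs": 24, "oasis_long": 40},
    {"group": "75-79", "total": 61, "female": 41, "ixi": 12, "mcbi": 0, "nihpd": 0, "oasis_cs": 9, "oasis_long": 40},
    {"group": "80-84", "total": 62, "female": 43, "ixi": 6, "mcbi": 0, "nihpd": 0, "oasis_cs": 17, "oasis_long": 39},
    {"group": "85-89", "total": 36, "female": 22, "ixi": 2, "mcbi": 0, "nihpd": 0, "oasis_cs": 12, "oasis_long": 22},
]

SOURCES = ("ixi", "mcbi", "nihpd", "oasis_cs", "oasis_long")


def expand_cohort_counts(counts: list[dict] | None = None) -> list[tuple[float, str, str]]:
    """Expand per-group marginal counts into (age, sex, source) records.

    The joint sex x source distribution is not specified by the marginals;
    records are synthesized in order, which preserves every marginal the
    summary reports.
    """
    counts = counts if counts is not None else SOURCE_COHORT_COUNTS
    records: list[tuple[float, str, str]] = []
    for row in counts:
        lo = float(row["group"].split("-")[0])
        sources: list[str] = []
        for src in SOURCES:
            sources.extend([src] * int(row[src]))
        if len(sources) != int(row["total"]):
            raise ValueError(f"source counts do not sum to total for {row['group']}")
        for i, src in enumerate(sources):
            sex = "F" if i < int(row["female"]) else "M"
            records.append((lo, sex, src))
    return records


def summarize_cohort(records: list[tuple[float, str, str]]) -> pd.DataFrame:
    """Demographics table by five-year group with a grand-total row.

    ``records`` are (age, sex, source) tuples; sex is "F"/"M"; percent
    female is rounded to the nearest integer.
    """
    groups = [g.label for g in scheme_groups("five_year")]
    rows = {g: {"total": 0, "female": 0, **{s: 0 for s in SOURCES}} for g in groups}
    for age, sex, source in records:
        if not (20 <= age <= 89):
            raise ValueError(f"record age {age} outside [20, 89]")
        g = group_for_age(age, "five_year").label
        rows[g]["total"] += 1
        if str(sex).upper().startswith("F"):
            rows[g]["female"] += 1
        if source in SOURCES:
            rows[g][source] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    total = df.sum(axis=0)
    df.loc["total"] = total
    pct = np.where(df["total"] > 0,
                   np.round(100.0 * df["female"] / np.maximum(df["total"], 1)), 0)
    df.insert(2, "pct_female", pct.astype(int))
    df.index.name = "group"
    return df


# ---------------------------------------------------------------------------
# TSV writers

def dice_records_frame(records: list[DiceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.subject_id, r.tissue, r.config_label, r.dice) for r in records],
        columns=["subject", "tissue", "config", "dice"],
    )


def offset_records_frame(records: list[OffsetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.subject_id, r.tissue, r.template_offset, r.dice) for r in records],
        columns=["subject", "tissue", "offset", "dice"],
    )


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
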