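"""Cohort statistics for morphometric tables.

Works on per-record tables in the supplementary-table schema (subject,
vowel, mode, ELA, ELV, HPA, HPV, LH) with a full subject x vowel x mode
within-subject design:

* two-way repeated-measures ANOVA (phonation mode x vowel) with
  Greenhouse-Geisser-corrected p-values reported alongside uncorrected ones,
* ordinary least-squares regressions reporting the signed correlation
  coefficient r and r^2 separately (a "negative r^2" can only be a signed
  r, so both are always given),
* summary tables of the relative singing-vs-speech measures: percentage
  changes (mean of per-record pc values), larynx lowering, area and volume
  ratios per mode, and Hammarberg-index aggregates.

No multiple-testing correction is applied; p-values are reported to full
precision and rounding is left to the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .containers import MODES, S1_COLUMNS, VOWELS

__all__ = [
    "rm_anova",
    "AnovaResult",
    "EffectResult",
    "linreg",
    "RegressionResult",
    "mode_contrasts",
    "summarize_cohort",
    "correlate_groups",
    "hpv_height_regression",
    "load_s1_table",
    "HPV_HEIGHT_MM",
]

#: Height of the hypopharyngeal volume window: 30 slices at 0.3255 mm.
HPV_HEIGHT_MM = 9.765

MEASURES = ("ELA", "ELV", "HPA", "HPV", "LH")


def _check_design(table: pd.DataFrame, measure: str) -> None:
    missing = [c for c in ("subject", "vowel", "mode", measure) if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    counts = table.groupby(["subject", "vowel", "mode"], observed=True).size()
    subjects = table["subject"].unique()
    vowels = table["vowel"].unique()
    modes = table["mode"].unique()
    full = pd.MultiIndex.from_product([subjects, vowels, modes],
                                      names=["subject", "vowel", "mode"])
    absent = full.difference(counts.index)
    if len(absent):
        raise ValueError(f"unbalanced design; missing cells: {list(absent[:10])}"
                         + (" ..." if len(absent) > 10 else ""))
    if (counts != 1).any():
        dup = counts[counts != 1].index.tolist()
        raise ValueError(f"duplicated cells in design: {dup[:10]}")


@dataclass
class EffectResult:
    F: float
    df1: float
    df2: float
    p: float
    p_gg: float
    eps: float


@dataclass
class AnovaResult:
    """Two-way within-subject ANOVA: mode, vowel and their interaction."""

    measure: str
    effects: dict[str, EffectResult] = field(default_factory=dict)

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]


def rm_anova(table: pd.DataFrame, measure: str) -> AnovaResult:
    """Two-way repeated-measures ANOVA with phonation mode and vowel within.

    Requires a balanced, complete subject x vowel x mode design (missing
    cells raise, listing them; they are never imputed).  Greenhouse-Geisser
    corrected p-values are reported for every effect; for the two-level
    mode factor the correction is the identity.  A measure with zero
    variance has no defined F and raises.
    """
    _check_design(table, measure)
    if np.isclose(table[measure].var(ddof=1), 0.0):
        raise ValueError(f"{measure} is constant; F undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=table, dv=measure, within=["mode", "vowel"],
                          subject="subject", detailed=True)
    name_map = {"mode": "mode", "vowel": "vowel", "mode * vowel": "mode:vowel"}
    res = AnovaResult(measure=measure)
    for _, row in aov.iterrows():
        key = name_map.get(row["Source"])
        if key is None:
            continue
        p_gg = row.get("p_GG_corr", np.nan)
        res.effects[key] = EffectResult(
            F=float(row["F"]), df1=float(row["ddof1"]), df2=float(row["ddof2"]),
            p=float(row["p_unc"]),
            p_gg=float(p_gg) if np.isfinite(p_gg) else float(row["p_unc"]),
            eps=float(row.get("eps", 1.0)),
        )
    return res


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float        # signed correlation coefficient
    r2: float       # coefficient of determination, r*r
    p: float
    n: int


def linreg(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with signed r and r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.isclose(x.var(), 0.0):
        raise ValueError("zero variance in x; slope undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), r2=float(fit.rvalue**2),
                            p=float(fit.pvalue), n=len(x))


def mode_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x vowel singing-vs-speech contrasts.

    Returns one row per subject and vowel with ``pc_<measure>`` (singing /
    speech-like x 100) and ``delta_pc_<measure>`` for the areas and volumes,
    plus ``delta_LH`` (speech-like minus singing; positive = lower larynx in
    singing) and the per-mode area and volume ratios.
    """
    wide = table.pivot_table(index=["subject", "vowel"], columns="mode",
                             values=list(MEASURES))
    out = pd.DataFrame(index=wide.index)
    for m in ("ELA", "ELV", "HPA", "HPV"):
        pc = wide[(m, "singing")] / wide[(m, "speech_like")] * 100.0
        out[f"pc_{m}"] = pc
        out[f"delta_pc_{m}"] = pc - 100.0
    out["delta_LH"] = wide[("LH", "speech_like")] - wide[("LH", "singing")]
    for mode in MODES:
        out[f"area_ratio_{mode}"] = wide[("ELA", mode)] / wide[("HPA", mode)]
        out[f"volume_ratio_{mode}"] = wide[("ELV", mode)] / wide[("HPV", mode)]
    return out.reset_index()


def summarize_cohort(table: pd.DataFrame,
                     delta_hi: pd.DataFrame | None = None) -> dict[str, pd.DataFrame | dict]:
    """Aggregate a cohort table into the standard summary blocks.

    Returns a dict with

    ``"delta_pc"``
        per-vowel and grand mean +/- SD of the percentage changes of ELA,
        ELV, HPA and HPV (mean of per-record pc values),
    ``"delta_lh"``
        per-vowel and grand mean +/- SD of the larynx lowering (mm),
    ``"ratios"``
        per-mode mean +/- SD of ELA/HPA and ELV/HPV,
    ``"delta_hi"``
        mean, SD, subject count and number of subjects with negative values
        (present when a per-subject delta-HI table is supplied).

    The summary is invariant to the row order of the input table.
    """
    con = mode_contrasts(table)
    pc_cols = [f"delta_pc_{m}" for m in ("ELA", "ELV", "HPA", "HPV")]
    per_vowel = con.groupby("vowel", observed=True)[pc_cols].agg(["mean", "std"])
    grand = con[pc_cols].agg(["mean", "std"]).T.stack()
    grand.index = pd.MultiIndex.from_tuples([(c, s) for c, s in grand.index])
    delta_pc = per_vowel.copy()
    delta_pc.loc["all"] = grand

    lh_vowel = con.groupby("vowel", observed=True)["delta_LH"].agg(["mean", "std"])
    lh_vowel.loc["all"] = con["delta_LH"].agg(["mean", "std"])

    ratio_rows = {}
    for mode in MODES:
        ratio_rows[mode] = {
            "area_ratio_mean": con[f"area_ratio_{mode}"].mean(),
            "area_ratio_std": con[f"area_ratio_{mode}"].std(),
            "volume_ratio_mean": con[f"volume_ratio_{mode}"].mean(),
            "volume_ratio_std": con[f"volume_ratio_{mode}"].std(),
        }
    ratios = pd.DataFrame(ratio_rows).T

    out: dict[str, pd.DataFrame | dict] = {
        "delta_pc": delta_pc,
        "delta_lh": lh_vowel,
        "ratios": ratios,
    }
    if delta_hi is not None:
        vals = np.asarray(delta_hi["delta_hi"], dtype=float)
        out["delta_hi"] = {
            "mean": float(vals.mean()),
            "std": float(vals.std(ddof=1)),
            "n": int(len(vals)),
            "n_negative": int((vals < 0).sum()),
        }
    return out


def correlate_groups(table: pd.DataFrame, x: str, y: str,
                     by: str | None = "vowel") -> dict[str, RegressionResult]:
    """Per-group regression of ``y`` on ``x`` with signed r.

    ``by=None`` pools all rows into a single group ``"all"``.  Groups with
    fewer than 3 records are skipped with a warning.
    """
    groups = [("all", table)] if by is None else list(table.groupby(by, observed=True))
    out: dict[str, RegressionResult] = {}
    for name, g in groups:
        if len(g) < 3:
            warnings.warn(f"group {name!r} has {len(g)} < 3 records; skipped",
                          stacklevel=2)
            continue
        out[str(name)] = linreg(g[x].to_numpy(), g[y].to_numpy())
    return out


def hpv_height_regression(table: pd.DataFrame) -> RegressionResult:
    """Regress HPV on HPA x 9.765 mm across all records.

    On a hypopharynx whose cross-section varies little over the volume
    window, the slope approaches 1 with r^2 near 1; the regression
    quantifies the fidelity of the area-times-height approximation.
    """
    con = table.pivot_table(index=["subject", "vowel", "mode"],
                            values=["HPA", "HPV"]).reset_index()
    return linreg(con["HPA"].to_numpy() * HPV_HEIGHT_MM, con["HPV"].to_numpy())


def load_s1_table(path) -> pd.DataFrame:
    """Read a per-record morphometric CSV in the supplementary-table schema.

    Expected columns: subject, vowel, mode, ELA (mm^2), ELV (mm^3), HPA
    (mm^2), HPV (mm^3), LH (mm).
    """
    df = pd.read_csv(path)
    missing = [c for c in S1_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"S1-schema table lacks columns {missing}")
    bad_vowel = set(df["vowel"]) - set(VOWELS)
    bad_mode = set(df["mode"]) - set(MODES)
    if bad_vowel or bad_mode:
        raise ValueError(f"unknown vowels {bad_vowel} or modes {bad_mode}")
    return df[S1_COLUMNS].copy()
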