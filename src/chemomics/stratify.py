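"""Response labels, the genomic-instability classifier, and association sweeps.

Chemotherapy response is pathological noninvasive downstaging (<= pTa or
CIS, node-negative) after neoadjuvant chemotherapy (NAC), or complete /
partial response (RECIST 1.1) after first-line treatment; a radiologic CR
with an intact bladder and available post-treatment pathology must show
pT0/pTa to remain a response.  Patients evaluated in both contexts use the
first-line evaluation.

The genomic-instability classifier labels a tumor high-instability (HGI)
when any of its SBS5 mutation count, indel count, or percent genome in
allelic imbalance is strictly above the cohort median, or when BRCA2 is
mutated; otherwise low (LGI).  Feature-response associations are reported
as 2x2 odds ratios with Fisher exact p-values, continuous features being
median-dichotomized.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

RESPONSIVE_STAGES = ("pT0", "pTa", "CIS")
CR_DEFINITIVE_STAGES = ("pT0", "pTa")

_STAGE_RE = re.compile(r"^(CIS|pT(?:[0-9]+[ab]?|a|is))?(N([0-9+]+))?$")


def _parse_stage(stage: str):
    """Split e.g. 'pT0N0' / 'pTa' / 'CISN0' into (T-part, N-part or None)."""
    m = _STAGE_RE.match(str(stage).strip())
    if not m or (m.group(1) is None and m.group(2) is None):
        raise ValueError(f"unparseable pathological stage {stage!r}")
    return m.group(1), m.group(3)


def response_label(record) -> bool | None:
    """Responder flag for one clinical record (mapping/Series), or None if unevaluable.

    NAC: responder iff the post-chemotherapy pathological stage is pT0, pTa
    or CIS and node-negative (N0; a missing N component is unevaluable).
    First-line: responder iff RECIST is CR or PR; a radiologic CR with an
    intact bladder and available post-treatment pathology is downgraded to
    non-response unless that pathology shows pT0/pTa (the definitive-CR
    rule).  A patient with both evaluations uses the first-line one.
    """
    recist = record.get("recist")
    has_first_line = recist is not None and not (isinstance(recist, float) and np.isnan(recist)) and recist != "NA"
    context = record.get("treatment_context")
    if context == "first_line" or (context == "both") or (context is None and has_first_line):
        has_first_line = True
    if context == "first_line" and not has_first_line:
        return None

    if has_first_line and context != "NAC":
        if recist not in ("CR", "PR", "SD", "PD"):
            return None
        if recist == "CR":
            post = record.get("post_cr_path_stage")
            if record.get("bladder_intact") and post not in (None, "", "NA") and not (
                isinstance(post, float) and np.isnan(post)
            ):
                t_part, _ = _parse_stage(post)
                return t_part in CR_DEFINITIVE_STAGES
            return True
        return recist == "PR"

    # NAC evaluation
    stage = record.get("post_cx_stage")
    if stage is None or stage == "" or (isinstance(stage, float) and np.isnan(stage)):
        return None
    t_part, n_part = _parse_stage(stage)
    if n_part is None:
        return None
    return (t_part in RESPONSIVE_STAGES) and n_part == "0"


def genomic_instability_group(
    features: pd.DataFrame, medians: pd.Series | None = None
) -> pd.Series:
    """HGI/LGI labels from instability features.

    ``features`` has columns ``sbs5_count``, ``indel_count``, ``percent_ai``
    and boolean ``brca2_mutated``.  A sample is HGI when any count feature
    is strictly above the cohort median (complete cases) or BRCA2 is
    mutated.  Samples with a missing feature (and no deciding BRCA2
    mutation or above-median feature) get NaN.
    """
    cont = ["sbs5_count", "indel_count", "percent_ai"]
    missing = [c for c in cont + ["brca2_mutated"] if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if medians is None:
        medians = features[cont].dropna().median()
    above = features[cont].gt(medians[cont], axis=1)  # NaN compares False
    hgi = above.any(axis=1) | features["brca2_mutated"].fillna(False).astype(bool)
    labels = pd.Series(np.where(hgi, "HGI", "LGI"), index=features.index, name="instability")
    undecided = features[cont].isna().any(axis=1) & ~hgi
    labels[undecided] = np.nan
    return labels


def _fisher_or(a: int, b: int, c: int, d: int):
    """OR (cross-product, 0.5 continuity correction on zero cells), 95% CI, Fisher p.

    Table rows are feature-positive (a responders, b non-) and
    feature-negative (c responders, d non-).
    """
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    zero = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if zero else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return or_, lo, hi, p, zero


def stratify_response(
    instability: pd.Series, basq: pd.Series, responses: pd.Series
) -> dict:
    """Response rates across the instability x expression-subtype strata.

    ``instability`` holds HGI/LGI labels, ``basq`` flags the Ba/Sq subtype,
    ``responses`` boolean.  Returns per-stratum rates and counts, the
    overall chi-square p across the four strata, and the extreme-group
    contrast (HGI & non-Ba/Sq vs LGI & Ba/Sq, Fisher exact).
    """
    df = pd.DataFrame(
        {"inst": instability, "basq": basq.astype(bool), "resp": responses}
    ).dropna()
    if df.empty:
        raise ValueError("no samples with complete stratification data")
    df["resp"] = df["resp"].astype(bool)
    strata = {}
    table = []
    for inst in ("HGI", "LGI"):
        for is_basq in (False, True):
            sub = df[(df["inst"] == inst) & (df["basq"] == is_basq)]
            name = f"{inst}/{'Ba-Sq' if is_basq else 'non-Ba-Sq'}"
            n, r = len(sub), int(sub["resp"].sum())
            strata[name] = {"n": n, "responders": r, "rate": r / n if n else float("nan")}
            if n:
                table.append([r, n - r])
    chi_p = stats.chi2_contingency(np.array(table))[1] if len(table) > 1 else float("nan")

    hi = df[(df["inst"] == "HGI") & ~df["basq"]]
    lo = df[(df["inst"] == "LGI") & df["basq"]]
    if len(hi) and len(lo):
        contrast_p = stats.fisher_exact(
            [
                [int(hi["resp"].sum()), len(hi) - int(hi["resp"].sum())],
                [int(lo["resp"].sum()), len(lo) - int(lo["resp"].sum())],
            ]
        )[1]
        contrast = {
            "hgi_non_basq_rate": hi["resp"].mean(),
            "lgi_basq_rate": lo["resp"].mean(),
            "fisher_p": contrast_p,
        }
    else:
        contrast = None
    return {"strata": strata, "chi2_p": chi_p, "extreme_contrast": contrast}


def association_table(
    features: pd.DataFrame,
    responses: pd.Series,
    subgroups: pd.Series | None = None,
) -> pd.DataFrame:
    """Feature-by-feature response association sweep (forest-plot table).

    Boolean features are used as-is; continuous features are dichotomized
    at the subgroup median (strictly above -> high) and additionally get a
    logistic-regression p-value on the continuous scale.  Each feature is
    evaluated in the full cohort and within each treatment subgroup.
    Returns one row per feature x subgroup with the 2x2 counts, odds ratio
    (0.5 continuity correction on zero cells, flagged), normal-approximation
    95% CI on the log OR, and two-sided Fisher exact p.
    """
    responses = responses.astype("boolean")
    groups = {"all": responses.index}
    if subgroups is not None:
        for g in subgroups.dropna().unique():
            groups[str(g)] = subgroups.index[subgroups == g]
    rows = []
    for gname, idx in groups.items():
        resp = responses.loc[idx].dropna().astype(bool)
        for feat in features.columns:
            vals = features.loc[resp.index, feat].dropna()
            r = resp.loc[vals.index]
            if vals.nunique() < 2:
                raise ValueError(f"feature {feat!r} is constant in subgroup {gname!r}")
            if vals.dtype == bool or set(vals.unique()) <= {0, 1, True, False}:
                high = vals.astype(bool)
                logit_p = np.nan
            else:
                high = vals > vals.median()
                logit_p = _logistic_p(vals, r)
            a = int((high & r).sum())
            b = int((high & ~r).sum())
            c = int((~high & r).sum())
            d = int((~high & ~r).sum())
            or_, lo, hi, p, zero = _fisher_or(a, b, c, d)
            rows.append(
                {
                    "feature": feat,
                    "subgroup": gname,
                    "n": len(vals),
                    "high_resp": a,
                    "high_nonresp": b,
                    "low_resp": c,
                    "low_nonresp": d,
                    "odds_ratio": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "fisher_p": p,
                    "zero_cell": zero,
                    "logistic_p": logit_p,
                }
            )
    return pd.DataFrame(rows)


def _logistic_p(values: pd.Series, responses: pd.Series) -> float:
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(values, dtype=float))
    try:
        fit = sm.Logit(responses.astype(float).values, X).fit(disp=0)
        return float(fit.pvalues[1])
    except Exception:
        return float("nan")


def logistic_effects(covariates: pd.DataFrame, responses: pd.Series) -> pd.DataFrame:
    """Joint (multivariable) logistic fit of response on the covariates.

    Returns per-covariate log-odds estimates with Wald 95% CIs and p-values;
    the companion to the marginal 2x2 sweep for recovering planted
    conditional effects.
    """
    import statsmodels.api as sm

    df = covariates.astype(float)
    y = responses.loc[df.index].astype(float)
    X = sm.add_constant(df.values)
    fit = sm.Logit(y.values, X).fit(disp=0)
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "log_odds": fit.params[1:],
            "ci_low": ci[1:, 0],
            "ci_high": ci[1:, 1],
            "p": fit.pvalues[1:],
        },
        index=df.columns,
    )
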