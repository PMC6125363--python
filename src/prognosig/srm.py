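"""Targeted SRM quantification of saliva peptides.

Each monitored peptide is measured as three fragment-ion transitions for
the endogenous (light) form and the spiked stable-isotope-labelled (heavy)
standard, in technical replicates. Quantification divides the summed light
transition areas by the summed heavy areas (L/H ratio); rdotp — the
normalized dot product of the light and heavy transition-intensity
vectors — checks that the fragmentation patterns match. Replicate ratios
are averaged per patient, and group differences (N+ vs N0 lymph-node
status) are tested with the Mann-Whitney U test on the untransformed
ratios, Benjamini-Hochberg adjusted within the monitored peptide (or
protein) family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, QCUndefinedError, UndefinedRatioError
from .simulate import peptide_protein


def peptide_ratio(light_areas, heavy_areas) -> float:
    """Light/heavy ratio for one peptide in one replicate.

    ``sum(light transition areas) / sum(heavy transition areas)``; the
    heavy standard is spiked at fixed amount, so the ratio is the relative
    endogenous abundance. Scale-invariant by construction.
    """
    light = np.asarray(light_areas, dtype=float)
    heavy = np.asarray(heavy_areas, dtype=float)
    if light.size == 0 or heavy.size == 0:
        raise ParameterError("need at least one light and one heavy transition")
    if (light < 0).any() or (heavy < 0).any():
        raise ParameterError("transition areas must be non-negative")
    heavy_sum = heavy.sum()
    if heavy_sum == 0:
        raise UndefinedRatioError("heavy transition areas sum to zero")
    return float(light.sum() / heavy_sum)


def rdotp(light_areas, heavy_areas) -> float:
    """Normalized dot product of light and heavy transition intensities.

    1.0 iff the two vectors are proportional (identical relative
    fragmentation), the QC expectation for a genuine endogenous signal.
    """
    light = np.asarray(light_areas, dtype=float)
    heavy = np.asarray(heavy_areas, dtype=float)
    if light.shape != heavy.shape or light.size < 2:
        raise ParameterError("light and heavy vectors must have equal length >= 2")
    nl, nh = np.linalg.norm(light), np.linalg.norm(heavy)
    if nl == 0 or nh == 0:
        raise QCUndefinedError("rdotp undefined for an all-zero transition vector")
    return float(np.dot(light, heavy) / (nl * nh))


def aggregate_replicates(ratios) -> dict:
    """Mean L/H ratio over technical replicates with a CV quality flag.

    Returns ``lh_ratio`` (arithmetic mean), ``replicate_cv`` (sd/mean,
    ``NaN`` for a single replicate) and ``n_replicates``.
    """
    r = np.asarray(ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ParameterError("need at least one replicate ratio")
    mean = float(r.mean())
    cv = float(r.std(ddof=1) / mean) if r.size > 1 and mean != 0 else float("nan")
    return {"lh_ratio": mean, "replicate_cv": cv, "n_replicates": int(r.size)}


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Exact null distribution when both groups have n <= 8 and no ties
    occur; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_ratio_table(
    records: pd.DataFrame, min_rdotp: float | None = None, cv_flag: float = 0.2
) -> pd.DataFrame:
    """Patient x peptide L/H ratio table from a long transition table.

    For every (patient, peptide, replicate) the light and heavy transition
    areas are summed and divided; replicate ratios are then averaged. Rows
    carry ``replicate_cv`` and, when ``min_rdotp`` is given, replicates
    whose light/heavy fragmentation correlation falls below it are dropped
    before averaging. ``cv_flag`` marks (does not drop) high-variance rows.
    """
    required = {"patient", "group", "peptide", "transition", "isotope", "replicate", "area"}
    missing = required - set(records.columns)
    if missing:
        raise ParameterError(f"transition table lacks columns: {sorted(missing)}")

    keys = ["patient", "group", "peptide", "replicate"]
    sums = (
        records.groupby(keys + ["isotope"], sort=True)["area"].sum().unstack("isotope")
    )
    if "light" not in sums.columns or "heavy" not in sums.columns:
        raise ParameterError("transition table must contain both light and heavy areas")
    usable = sums["light"].notna() & sums["heavy"].notna() & (sums["heavy"] > 0)

    if min_rdotp is not None:
        # per-replicate fragmentation-pattern QC needs the transition vectors
        vec = records.pivot_table(
            index=keys, columns=["isotope", "transition"], values="area", aggfunc="sum"
        )
        light_v = vec["light"].to_numpy(dtype=float)
        heavy_v = vec["heavy"].to_numpy(dtype=float)
        num = np.nansum(light_v * heavy_v, axis=1)
        denom = np.sqrt(np.nansum(light_v**2, axis=1) * np.nansum(heavy_v**2, axis=1))
        rdotp_vals = pd.Series(
            np.divide(num, denom, out=np.zeros_like(num), where=denom > 0), index=vec.index
        )
        usable &= rdotp_vals.reindex(sums.index) >= min_rdotp

    rep_ratio = (sums["light"] / sums["heavy"])[usable]
    dropped = sums.index[~usable].to_frame(index=False)[["patient", "peptide"]]
    for pat, pep in dropped.drop_duplicates().itertuples(index=False):
        if (pat, pep) not in {i[:3:2] for i in rep_ratio.index}:
            warnings.warn(f"no usable replicates for {pat}/{pep}; row skipped")

    grouped = rep_ratio.groupby(["patient", "group", "peptide"])
    out = grouped.agg(lh_ratio="mean", n_replicates="size").reset_index()
    sd = grouped.std(ddof=1).reset_index(drop=True)
    out["replicate_cv"] = np.where(
        (out["n_replicates"] > 1) & (out["lh_ratio"] != 0),
        sd / out["lh_ratio"],
        np.nan,
    )
    out["protein"] = out["peptide"].map(peptide_protein)
    out["cv_flagged"] = out["replicate_cv"].gt(cv_flag).fillna(False)
    cols = ["patient", "group", "peptide", "protein", "lh_ratio", "replicate_cv", "n_replicates", "cv_flagged"]
    return out[cols]


def rt_agreement(records: pd.DataFrame, predicted_rt: dict) -> pd.DataFrame:
    """Retention-time QC: Pearson r between measured and predicted RT per run.

    ``predicted_rt`` maps peptide name to its expected retention time
    (minutes), e.g. from an iRT calibration. One row per
    (patient, replicate) run; r close to 1 indicates stable
    chromatography, a drop flags gradient or scheduling problems.
    """
    if "rt" not in records.columns:
        raise ParameterError("transition table lacks an 'rt' column")
    sub = records[records["peptide"].isin(predicted_rt)]
    rows = []
    for (pat, rep), run in sub.groupby(["patient", "replicate"]):
        measured = run.groupby("peptide")["rt"].mean()
        if len(measured) < 3:
            continue
        predicted = measured.index.map(predicted_rt)
        r = stats.pearsonr(measured.to_numpy(), np.asarray(predicted))[0]
        rows.append(
            {"patient": pat, "replicate": rep, "n_peptides": len(measured), "rt_r": float(r)}
        )
    return pd.DataFrame(rows)


def _differential(wide: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    rows = []
    n0_mask = (groups == "N0").to_numpy()
    np_mask = (groups == "N+").to_numpy()
    for feat in wide.columns:
        vals = wide[feat].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        x = vals[np_mask & ok]  # N+ first: U and ratio reported as N+ vs N0
        y = vals[n0_mask & ok]
        if x.size == 0 or y.size == 0:
            warnings.warn(f"feature {feat!r} absent in one group; skipped")
            continue
        u, p = mann_whitney(x, y)
        med0, medp = np.median(y), np.median(x)
        rows.append(
            {
                "feature": feat,
                "u_stat": u,
                "p_value": p,
                "log2_ratio_Nplus_N0": float(np.log2(medp / med0))
                if med0 > 0 and medp > 0
                else float("nan"),
                "n_Nplus": int(x.size),
                "n_N0": int(y.size),
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["adj_p_value"] = bh_adjust(res["p_value"].to_numpy())
    return res.set_index("feature")


def summarize_protein_ratios(ratio_table: pd.DataFrame, mode: str = "mean") -> pd.DataFrame:
    """Patient x protein table: roll up peptide ratios per parent protein.

    ``mode='mean'`` (default) averages a protein's peptide ratios within
    each patient; ``mode='best'`` keeps, per protein, the single peptide
    with the lowest median replicate CV across patients.
    """
    if mode == "mean":
        return ratio_table.pivot_table(
            index="patient", columns="protein", values="lh_ratio", aggfunc="mean"
        )
    if mode == "best":
        cv_by_pep = ratio_table.groupby(["protein", "peptide"])["replicate_cv"].median()
        best = cv_by_pep.groupby("protein").idxmin().map(lambda t: t[1])
        sub = ratio_table[ratio_table["peptide"].isin(set(best))]
        return sub.pivot_table(index="patient", columns="protein", values="lh_ratio")
    raise ParameterError(f"unknown protein roll-up mode {mode!r}")


def group_differential(
    ratio_table: pd.DataFrame, protein_mode: str = "mean"
) -> dict[str, pd.DataFrame]:
    """Mann-Whitney + BH differential results at peptide and protein level.

    Tests run on the untransformed L/H ratios. The BH family is all
    monitored peptides for the peptide table and all proteins for the
    protein table (two separate families). ``log2_ratio_Nplus_N0`` is the
    log2 of the ratio of group medians.
    """
    groups = ratio_table.drop_duplicates("patient").set_index("patient")["group"]
    pep_wide = ratio_table.pivot_table(index="patient", columns="peptide", values="lh_ratio")
    prot_wide = summarize_protein_ratios(ratio_table, mode=protein_mode)
    g = groups.reindex(pep_wide.index)
    return {
        "peptide": _differential(pep_wide, g),
        "protein": _differential(prot_wide.reindex(pep_wide.index), g),
    }
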