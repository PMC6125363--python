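"""Discovery-phase differential analysis of laser-microdissected tumor regions.

Label-free quantification (LFQ) protein intensities from the invasive tumor
front (ITF) and the inner tumor are compared per protein after valid-value
filtering and downshifted-Gaussian imputation of missing values, the
Perseus-style workflow: proteins are kept when observed in enough samples of
at least one region, remaining gaps are filled with draws from a normal
distribution shifted toward the detection limit, and region differences are
assessed with Student's t tests. Candidate proteins are then prioritized by
their linear association with clinicopathological covariates.

All matrices are log2 LFQ intensity, proteins in rows, samples in columns;
missing values are ``NaN``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage

from .errors import (
    DegenerateCovariateError,
    ImputationError,
    OverlapError,
    PairingError,
    ParameterError,
    SchemaError,
    ZScoreError,
)

REGIONS = ("ITF", "inner")
COMPARTMENTS = ("island", "stroma")


@dataclass
class QuantMatrix:
    """Proteins x samples matrix of log2 LFQ intensities with annotations.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = protein ids (unique),
        columns = sample ids. ``NaN`` marks a missing value.
    samples
        One row per sample (index matches ``values.columns``) with columns
        ``patient``, ``region`` (``ITF`` or ``inner``) and optionally
        ``compartment`` (``island`` or ``stroma``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise SchemaError("protein row names must be unique")
        if list(self.values.columns) != list(self.samples.index):
            raise SchemaError("sample annotation index must match matrix columns")
        missing = {"patient", "region"} - set(self.samples.columns)
        if missing:
            raise SchemaError(f"sample annotation lacks columns: {sorted(missing)}")
        bad_region = set(self.samples["region"]) - set(REGIONS)
        if bad_region:
            raise SchemaError(f"unknown region labels: {sorted(bad_region)}")
        dup = self.samples.groupby(["patient", "region"]).size()
        if (dup > 1).any():
            raise SchemaError("each patient may contribute at most one sample per region")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise SchemaError("matrix values must be finite where present")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def region_columns(self, region: str) -> list:
        return list(self.samples.index[self.samples["region"] == region])

    def subset(self, proteins) -> "QuantMatrix":
        return dataclasses.replace(self, values=self.values.loc[list(proteins)])


def combine_regions(itf: QuantMatrix, inner: QuantMatrix) -> QuantMatrix:
    """Concatenate two single-region matrices on shared protein rows.

    Sample ids are suffixed with the region when the two matrices use the
    same column names (e.g. patient ids), so that the combined matrix keeps
    unique columns while annotations preserve the patient pairing.
    """
    if not itf.values.index.equals(inner.values.index):
        raise SchemaError("region matrices must share an identical protein index")

    def _tag(m: QuantMatrix, region: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        cols = [f"{c}:{region}" for c in m.values.columns]
        v = m.values.copy()
        v.columns = cols
        s = m.samples.copy()
        s.index = cols
        return v, s

    v1, s1 = _tag(itf, "ITF")
    v2, s2 = _tag(inner, "inner")
    return QuantMatrix(values=pd.concat([v1, v2], axis=1), samples=pd.concat([s1, s2]))


def filter_min_valid(m: QuantMatrix, min_valid: int) -> QuantMatrix:
    """Keep proteins with >= ``min_valid`` observed values in at least one region.

    This mirrors the "minimum valid values in at least one group" filter:
    a protein quantified consistently in only one region survives (such
    region-exclusive proteins feed the presence partition).
    """
    counts = {}
    for region in REGIONS:
        cols = m.region_columns(region)
        if cols and min_valid > len(cols):
            raise ParameterError(
                f"min_valid={min_valid} exceeds the {region} group size {len(cols)}"
            )
        counts[region] = (
            m.values[cols].notna().sum(axis=1) if cols else pd.Series(0, index=m.proteins)
        )
    keep = (counts["ITF"] >= min_valid) | (counts["inner"] >= min_valid)
    return dataclasses.replace(m, values=m.values.loc[keep])


def impute_downshift(
    m: QuantMatrix,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | None = None,
) -> QuantMatrix:
    """Impute missing values from a downshifted normal, per sample column.

    For each column the observed mean ``mu`` and standard deviation ``sd``
    are computed; missing entries are replaced by draws from
    ``Normal(mu - shift*sd, (width*sd)^2)``. The defaults (width 0.3,
    shift 1.8) emulate low-abundance signal near the detection limit.
    Observed entries are never altered.
    """
    rng = np.random.default_rng(seed)
    out = m.values.copy()
    for col in out.columns:
        column = out[col]
        observed = column.dropna()
        n_missing = column.isna().sum()
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ImputationError(
                f"column {col!r} has {len(observed)} observed values; need >= 2"
            )
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - shift * sd, width * sd, size=n_missing)
        out.loc[column.isna(), col] = draws
    return dataclasses.replace(m, values=out)


def two_group_ttest(m: QuantMatrix, paired: bool = False) -> pd.DataFrame:
    """Student's t test of ITF vs inner per protein on a complete matrix.

    Unpaired mode uses the classic pooled-variance statistic; paired mode
    aligns samples by patient and tests the within-patient differences.
    Returns a DataFrame indexed by protein with columns ``log2_ratio``
    (mean ITF minus mean inner), ``t_stat``, ``p_value``, ``n_ITF``,
    ``n_inner``. Proteins with zero difference and zero variance are
    reported as t=0, p=1 (no evidence either way).
    """
    itf_cols = m.region_columns("ITF")
    inner_cols = m.region_columns("inner")
    if not itf_cols or not inner_cols:
        raise ParameterError("matrix must contain samples from both regions")
    if m.values[itf_cols + inner_cols].isna().any().any():
        raise ParameterError("matrix contains missing values; impute before testing")

    x = m.values[itf_cols].to_numpy(dtype=float)
    y_cols = inner_cols
    if paired:
        itf_pat = m.samples.loc[itf_cols, "patient"]
        inner_by_pat = {p: c for c, p in m.samples.loc[inner_cols, "patient"].items()}
        try:
            y_cols = [inner_by_pat[p] for p in itf_pat]
        except KeyError as exc:
            raise PairingError(f"patient {exc.args[0]!r} has no inner-region sample") from exc
        if len(itf_cols) != len(inner_cols):
            raise PairingError("paired test requires one inner sample per ITF sample")
    y = m.values[y_cols].to_numpy(dtype=float)

    ratio = x.mean(axis=1) - y.mean(axis=1)
    if paired:
        t, p = stats.ttest_rel(x, y, axis=1)
    else:
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    # zero-variance, zero-difference rows are uninformative, not undefined
    degenerate = ~np.isfinite(t) & np.isclose(ratio, 0.0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "log2_ratio": ratio,
            "t_stat": t,
            "p_value": p,
            "n_ITF": x.shape[1],
            "n_inner": y.shape[1],
        },
        index=m.proteins,
    )


@dataclass
class ClusterResult:
    """Agglomerative clustering output: scipy-format merge tree + leaf order."""

    labels: list
    merges: np.ndarray  # (n-1) x 4 scipy linkage matrix
    leaf_order: list = field(init=False)

    def __post_init__(self) -> None:
        from scipy.cluster.hierarchy import leaves_list

        self.leaf_order = [self.labels[i] for i in leaves_list(self.merges)]


def zscore_cluster(m: QuantMatrix, method: str = "complete", axis: str = "samples") -> ClusterResult:
    """Hierarchically cluster samples (or proteins) of row-z-scored data.

    Each protein row is standardized to mean 0, sd 1 across samples, then
    agglomerative clustering with Euclidean distance and ``complete`` or
    ``average`` linkage is run over ``axis`` (``"samples"`` for columns,
    ``"proteins"`` for rows). Ties merge lowest-index-first.
    """
    if method not in ("complete", "average"):
        raise ParameterError(f"linkage must be 'complete' or 'average', got {method!r}")
    if m.values.isna().any().any():
        raise ParameterError("matrix contains missing values; impute before clustering")
    vals = m.values.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ZScoreError(f"constant row cannot be z-scored: {m.proteins[flat[0]]!r}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    if axis == "samples":
        data, labels = z.T, list(m.values.columns)
    elif axis == "proteins":
        data, labels = z, list(m.proteins)
    else:
        raise ParameterError("axis must be 'samples' or 'proteins'")
    merges = _scipy_linkage(data, method=method, metric="euclidean")
    return ClusterResult(labels=labels, merges=merges)


def sample_correlation(m: QuantMatrix, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between samples.

    Entries use only proteins observed in both samples of a pair; pairs
    sharing fewer than ``min_overlap`` proteins are an error rather than a
    silent ``NaN``.
    """
    present = m.values.notna().astype(int)
    overlap = present.T @ present
    offdiag = overlap.where(~np.eye(len(overlap), dtype=bool))
    if (offdiag < min_overlap).any().any():
        bad = offdiag.stack().idxmin()
        raise OverlapError(
            f"samples {bad[0]!r} and {bad[1]!r} share {int(offdiag.loc[bad])} "
            f"observed proteins; need >= {min_overlap}"
        )
    corr = m.values.corr(method="pearson", min_periods=min_overlap)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def presence_partition(
    itf: QuantMatrix, inner: QuantMatrix, min_valid: int
) -> dict[str, set]:
    """Venn partition of proteins retained in each region.

    Both matrices are filtered with the same minimum-valid-value rule; the
    result splits the union into ``itf_only``, ``inner_only`` and
    ``common`` (disjoint by construction).
    """
    kept_itf = set(filter_min_valid(itf, min_valid).proteins)
    kept_inner = set(filter_min_valid(inner, min_valid).proteins)
    return {
        "itf_only": kept_itf - kept_inner,
        "inner_only": kept_inner - kept_itf,
        "common": kept_itf & kept_inner,
    }


def clin_association(abundance, covariate, protein: str = "", covariate_name: str = "") -> dict:
    """Simple linear regression of protein abundance on one clinical covariate.

    Returns the OLS slope with its two-sided p-value plus the Pearson
    product-moment correlation r and r^2. Categorical covariates must be
    numerically encoded by the caller (binary as 0/1, ordered categories as
    integer ranks).
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(abundance, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ParameterError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateCovariateError(f"covariate {covariate_name!r} is constant")
    fit = stats.linregress(x, y)
    return {
        "protein": protein,
        "covariate": covariate_name,
        "slope": fit.slope,
        "p_value": fit.pvalue,
        "r": fit.rvalue,
        "r_squared": fit.rvalue**2,
        "n": int(x.size),
    }


def associate_clinical(
    m: QuantMatrix, clinical: pd.DataFrame, proteins=None
) -> pd.DataFrame:
    """Run :func:`clin_association` for every protein x covariate pair.

    ``clinical`` is indexed by patient with numeric-encoded covariates in
    columns; per-patient abundance is averaged over that patient's samples.
    """
    prots = list(proteins) if proteins is not None else list(m.proteins)
    by_patient = m.values.T.groupby(m.samples["patient"]).mean().T
    shared = [p for p in by_patient.columns if p in clinical.index]
    rows = []
    for prot in prots:
        for cov in clinical.columns:
            rows.append(
                clin_association(
                    by_patient.loc[prot, shared],
                    clinical.loc[shared, cov],
                    protein=prot,
                    covariate_name=cov,
                )
            )
    return pd.DataFrame(rows)


def prioritize(
    assoc: pd.DataFrame,
    diff: pd.DataFrame,
    diff_alpha: float = 0.05,
    assoc_alpha: float = 0.05,
    r_threshold: float = 0.7,
    r2_threshold: float = 0.4,
    allow_list=None,
) -> list:
    """Select candidate proteins passing the differential and clinical gates.

    A protein is kept when its region t test has p < ``diff_alpha`` AND at
    least one covariate association has p < ``assoc_alpha`` with
    |r| strictly greater than ``r_threshold`` and r^2 > ``r2_threshold``.
    ``allow_list``, when given, encodes external criteria (staining
    evidence, literature novelty) as a final intersection. The returned
    list is sorted and therefore independent of input row order.
    """
    diff_pass = set(diff.index[diff["p_value"] < diff_alpha])
    gates = (
        (assoc["p_value"] < assoc_alpha)
        & (assoc["r"].abs() > r_threshold)
        & (assoc["r_squared"] > r2_threshold)
    )
    assoc_pass = set(assoc.loc[gates, "protein"])
    selected = diff_pass & assoc_pass
    if allow_list is not None:
        selected &= set(allow_list)
    return sorted(selected)
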