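"""Covariate-adjusted group inference on AUC summaries, multiple-testing
control, brain-cognition correlation, and the descriptive cohort table.

The group comparison is a one-way ANCOVA: a linear model
``AUC ~ group + age + sex + education + SDS`` whose omnibus p-value is
the partial F-test of the group factor, with Bonferroni-corrected
covariate-adjusted pairwise contrasts as post hoc tests.  Nodal families
are corrected with Benjamini-Hochberg FDR.  Brain-cognition association
uses rank-based (Spearman) partial correlation with the same covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import GROUPS

__all__ = [
    "AncovaResult",
    "PartialSpearmanResult",
    "ancova_auc",
    "bonferroni_posthoc",
    "bh_fdr",
    "partial_spearman",
    "cohort_table",
    "nodal_ancova_table",
    "correlation_table",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "sds_score")

#: pairwise contrast order used throughout: p1, p2, p3 of the report tables
PAIRS = (("MHD_noCI", "HC"), ("MHD_CI", "HC"), ("MHD_CI", "MHD_noCI"))


@dataclass
class AncovaResult:
    metric: str
    f_stat: float
    p_omnibus: float
    adjusted_means: dict[str, float]
    posthoc_p: dict[str, float]  # keys "noCI_vs_HC", "CI_vs_HC", "CI_vs_noCI"
    n_used: int
    node: int | None = None


@dataclass
class PartialSpearmanResult:
    parameter: str
    score: str
    r: float
    p: float
    n: int
    q: float = np.nan


def _design(meta: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix [1 | group dummies (ref=HC) | covariates] and keep-mask."""
    cols = []
    names = []
    g = meta["group"].to_numpy()
    for grp in GROUPS[1:]:
        cols.append((g == grp).astype(float))
        names.append(f"group[{grp}]")
    cov_block = []
    for c in covariates:
        v = meta[c]
        if v.dtype == object or str(v.dtype) == "category":
            # sex coded as an indicator, reference = female
            v = (v == "male").astype(float)
        cov_block.append(np.asarray(v, dtype=float))
        names.append(c)
    x = np.column_stack([np.ones(len(meta))] + cols + cov_block)
    mask = np.isfinite(x).all(axis=1)
    return x, mask, names


def _drop_collinear(x: np.ndarray, protected: int) -> tuple[np.ndarray, list[int]]:
    """Greedily drop collinear columns beyond the first `protected` ones."""
    keep = list(range(protected))
    for c in range(protected, x.shape[1]):
        cand = x[:, keep + [c]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(c)
    if len(keep) < x.shape[1]:
        warnings.warn(f"dropped {x.shape[1] - len(keep)} collinear covariate column(s)")
    return x[:, keep], keep


def _ancova_engine(y: np.ndarray, x: np.ndarray):
    """Partial F-test of the 2 group columns (cols 1-2) plus contrasts."""
    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sse_full = float(resid @ resid)
    df_resid = n - p
    x_red = np.delete(x, [1, 2], axis=1)
    beta_r, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    resid_r = y - x_red @ beta_r
    sse_red = float(resid_r @ resid_r)
    f = ((sse_red - sse_full) / 2.0) / (sse_full / df_resid)
    p_omni = float(stats.f.sf(f, 2, df_resid))
    sigma2 = sse_full / df_resid
    xtx_inv = np.linalg.pinv(x.T @ x)
    # contrasts on (b1, b2): noCI-HC = b1, CI-HC = b2, CI-noCI = b2-b1
    contrasts = {
        "noCI_vs_HC": np.array([0.0, 1.0, 0.0]),
        "CI_vs_HC": np.array([0.0, 0.0, 1.0]),
        "CI_vs_noCI": np.array([0.0, -1.0, 1.0]),
    }
    raw = {}
    for name, l3 in contrasts.items():
        l_vec = np.zeros(p)
        l_vec[:3] = l3
        est = float(l_vec @ beta)
        se = float(np.sqrt(sigma2 * l_vec @ xtx_inv @ l_vec))
        t = est / se if se > 0 else np.nan
        raw[name] = float(2.0 * stats.t.sf(abs(t), df_resid))
    return beta, f, p_omni, raw, xtx_inv


def ancova_auc(
    auc: np.ndarray | pd.Series,
    meta: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    metric: str = "metric",
    node: int | None = None,
) -> AncovaResult:
    """One-way ANCOVA of a per-subject AUC across the three groups.

    Rows with missing covariates or outcome are dropped with a warning
    (listwise deletion); a group left with < 2 subjects is an error.
    """
    y = np.asarray(auc, dtype=float)
    if len(y) != len(meta):
        raise ValueError("auc and meta must align row-wise")
    x, mask, _ = _design(meta, covariates)
    mask &= np.isfinite(y)
    if not mask.all():
        warnings.warn(f"dropping {(~mask).sum()} row(s) with missing values")
    y, x = y[mask], x[mask]
    g = meta.loc[mask, "group"].to_numpy()
    counts = {grp: int((g == grp).sum()) for grp in GROUPS}
    if any(c < 2 for c in counts.values()):
        raise ValueError(f"every group needs >= 2 subjects, got {counts}")
    x, _ = _drop_collinear(x, protected=3)
    beta, f, p_omni, raw, _ = _ancova_engine(y, x)
    posthoc = bonferroni_posthoc(raw)
    cov_means = x[:, 3:].mean(axis=0)
    base = float(beta[0] + beta[3:] @ cov_means)
    adjusted = {
        "HC": base,
        "MHD_noCI": base + float(beta[1]),
        "MHD_CI": base + float(beta[2]),
    }
    return AncovaResult(
        metric=metric, f_stat=float(f), p_omnibus=p_omni,
        adjusted_means=adjusted, posthoc_p=posthoc, n_used=int(mask.sum()),
        node=node,
    )


def bonferroni_posthoc(pairwise_p) -> dict[str, float] | np.ndarray:
    """Bonferroni correction for the three pairwise tests: p * 3, capped at 1."""
    if isinstance(pairwise_p, dict):
        items = pairwise_p.items()
        out = {}
        for k, p in items:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} outside [0, 1]")
            out[k] = min(3.0 * p, 1.0)
        return out
    p = np.asarray(pairwise_p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(3.0 * p, 1.0)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_spearman(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None,
    parameter: str = "x", score: str = "y",
) -> PartialSpearmanResult:
    """Spearman correlation of `x` and `y` partialling out `covariates`.

    All variables are rank-transformed; the partial correlation is the
    Pearson correlation of the rank residuals after regressing on the
    ranked covariates, with p from the t approximation on n - k - 2
    degrees of freedom.  With no covariates this reduces to the ordinary
    Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        z = np.empty((len(x), 0))
    else:
        if isinstance(covariates, pd.DataFrame):
            cov = covariates.copy()
            for c in cov.columns:
                if cov[c].dtype == object:
                    cov[c] = (cov[c] == "male").astype(float)
            z = cov.to_numpy(dtype=float)
        else:
            z = np.asarray(covariates, dtype=float)
            if z.ndim == 1:
                z = z[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z).all(axis=1)
    x, y, z = x[mask], y[mask], z[mask]
    n, k = len(x), z.shape[1]
    if n < k + 3:
        raise ValueError(f"need n >= {k + 3} complete observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n)] + [stats.rankdata(z[:, c]) for c in range(k)])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex, ey = rx - design @ bx, ry - design @ by
    r = float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialSpearmanResult(parameter=parameter, score=score, r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_THREE_GROUP_VARS = (
    "age", "education", "bmi", "moca", "tmt_a_seconds",
    "dst_f", "dst_b", "dst_t", "sds_score", "sas_score",
)
_PATIENT_VARS = ("dialysis_months",)


def _median_iqr(v: pd.Series) -> str:
    q1, q2, q3 = np.nanpercentile(v.astype(float), [25, 50, 75])
    return f"{q2:.2f} ({q1:.2f}, {q3:.2f})"


def cohort_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Descriptive comparison of the three groups.

    Continuous variables: median (IQR), three-group Kruskal-Wallis with
    pairwise Mann-Whitney x Bonferroni post hoc when significant; sex by
    chi-square; patient-only variables by Mann-Whitney between the two
    patient groups.
    """
    rows = []
    by = {grp: meta[meta["group"] == grp] for grp in GROUPS}

    sex_tab = pd.crosstab(meta["sex"], meta["group"])
    chi2, p_sex = stats.chi2_contingency(sex_tab, correction=False)[:2]
    rows.append({
        "variable": "sex (male/female)",
        **{
            grp: f"{(by[grp]['sex'] == 'male').sum()}/{(by[grp]['sex'] == 'female').sum()}"
            for grp in GROUPS
        },
        "test": "chi-square", "p": p_sex, "p1": np.nan, "p2": np.nan, "p3": np.nan,
    })

    for var in _THREE_GROUP_VARS:
        if var not in meta.columns:
            warnings.warn(f"variable {var!r} absent from metadata: skipped")
            continue
        samples = [by[grp][var].dropna().astype(float) for grp in GROUPS]
        stat, p = stats.kruskal(*samples)
        row = {
            "variable": var,
            **{grp: _median_iqr(by[grp][var]) for grp in GROUPS},
            "test": "kruskal-wallis", "p": p,
            "p1": np.nan, "p2": np.nan, "p3": np.nan,
        }
        if p < 0.05:
            for label, (ga, gb) in zip(("p1", "p2", "p3"), PAIRS):
                u, pu = stats.mannwhitneyu(
                    by[ga][var].dropna(), by[gb][var].dropna(), alternative="two-sided"
                )
                row[label] = min(3.0 * pu, 1.0)
        rows.append(row)

    for var in _PATIENT_VARS:
        if var not in meta.columns:
            continue
        a = by["MHD_noCI"][var].dropna().astype(float)
        b = by["MHD_CI"][var].dropna().astype(float)
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({
            "variable": var, "HC": "-",
            "MHD_noCI": _median_iqr(a), "MHD_CI": _median_iqr(b),
            "test": "mann-whitney", "p": p, "p1": np.nan, "p2": np.nan, "p3": np.nan,
        })
    return pd.DataFrame(rows)


def nodal_ancova_table(
    auc_by_node: pd.DataFrame,
    meta: pd.DataFrame,
    metric: str,
    covariates=DEFAULT_COVARIATES,
    q_threshold: float = 0.05,
    node_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-node ANCOVA with a BH-FDR family across all nodes of one metric.

    `auc_by_node`: subjects x nodes AUC values aligned with `meta` rows.
    Returns every node's omnibus p and q plus post hoc p-values, with a
    `significant` flag at q < `q_threshold`.
    """
    results = []
    for col in auc_by_node.columns:
        res = ancova_auc(auc_by_node[col].to_numpy(), meta, covariates,
                         metric=metric, node=int(col))
        results.append(res)
    pvals = np.array([r.p_omnibus for r in results])
    qvals = bh_fdr(pvals)
    rows = []
    for res, q in zip(results, qvals):
        label = node_labels[res.node] if node_labels else f"node{res.node:03d}"
        rows.append({
            "metric": metric, "node": res.node, "label": label,
            "mean_HC": res.adjusted_means["HC"],
            "mean_MHD_noCI": res.adjusted_means["MHD_noCI"],
            "mean_MHD_CI": res.adjusted_means["MHD_CI"],
            "F": res.f_stat, "p": res.p_omnibus, "q": q,
            "significant": bool(q < q_threshold),
            "p1": res.posthoc_p["noCI_vs_HC"],
            "p2": res.posthoc_p["CI_vs_HC"],
            "p3": res.posthoc_p["CI_vs_noCI"],
        })
    return pd.DataFrame(rows)


def correlation_table(
    parameters: pd.DataFrame,
    cognition: pd.DataFrame,
    covariates: pd.DataFrame,
    blocks: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Partial-Spearman r/p/q grid of network parameters x cognition scores.

    `parameters`, `cognition`, `covariates`: row-aligned DataFrames (one
    row per patient).  FDR is applied per cognition score within each
    parameter block (``blocks`` maps block name -> parameter columns;
    default one block with every parameter).
    """
    if blocks is None:
        blocks = {"all": list(parameters.columns)}
    rows = []
    for block, params in blocks.items():
        for score in cognition.columns:
            block_results = []
            for par in params:
                res = partial_spearman(
                    parameters[par], cognition[score], covariates,
                    parameter=par, score=score,
                )
                block_results.append(res)
            qvals = bh_fdr([r.p for r in block_results])
            for res, q in zip(block_results, qvals):
                rows.append({
                    "block": block, "parameter": res.parameter, "score": res.score,
                    "r": res.r, "p": res.p, "q": q, "n": res.n,
                })
    return pd.DataFrame(rows)
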