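"""ROI statistics battery: zone comparisons, ROC ranking, marker correlations.

The only statistics input is the ROI table — one mean value per case × ROI
× parameter.  Three analyses mirror the invasion-border workflow:

* two-sided Mann-Whitney comparisons between adjacent ROI pairs
  (1 vs 2, 2 vs 3, 3 vs 4) at a strict alpha (default 0.001);
* empirical ROC per parameter with a Youden-J cutoff and percentile
  bootstrap CIs (cases resampled within group), parameters ranked by AUC;
* Spearman correlations between imaging parameters and immunohistochemical
  markers, with bootstrap 95% CIs, at alpha 0.05.

AUC is computed from the rank (Mann-Whitney) statistic, i.e. the
normalised count of concordant pairs with ties scored 1/2, and is oriented
so AUC ≥ 0.5 with the comparison direction recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PARAMS

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = ((1, 2), (2, 3), (3, 4))
ALPHA_COMPARISONS = 0.001
ALPHA_CORRELATIONS = 0.05
N_BOOT_DEFAULT = 2000


# result records -------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    roi_pair: tuple[int, int]
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class ROCResult:
    parameter: str
    roi_pair: tuple[int, int]
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    direction: str  # "greater": ROI-a values above cutoff; "less": below
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    roi: int
    marker: str
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    significant: bool
    degenerate: bool = False


# helpers --------------------------------------------------------------------

def _pair_values(table: pd.DataFrame, param: str, roi_a: int, roi_b: int):
    """Per-group finite values (pairwise deletion per parameter)."""
    a = table.loc[table["roi"] == roi_a, param].to_numpy(dtype=float)
    b = table.loc[table["roi"] == roi_b, param].to_numpy(dtype=float)
    return a[np.isfinite(a)], b[np.isfinite(b)]


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney; exact enumeration for tie-free n ≤ 8 per
    group, normal approximation with tie correction otherwise.

    Returns (U of the first sample, two-sided p, degenerate flag).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return len(a) * len(b) / 2.0, 1.0, True
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and len(a) <= 8 and len(b) <= 8) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), False


def auc_concordance(a: np.ndarray, b: np.ndarray) -> float:
    """P(a > b) + ½·P(a = b) via midranks — the concordant-pair AUC."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0
    return float(u / (len(a) * len(b)))


def _youden_cutoff(pos: np.ndarray, neg: np.ndarray):
    """Best threshold on 'positive if value ≥ t': maximise J = sens+spec−1,
    ties broken toward higher specificity."""
    vals = np.unique(np.concatenate([pos, neg]))
    if vals.size == 1:
        return float(vals[0]), float(np.mean(pos >= vals[0])), \
            float(np.mean(neg < vals[0]))
    mids = (vals[:-1] + vals[1:]) / 2.0
    cands = np.concatenate([[vals[0] - 1.0], mids, [vals[-1] + 1.0]])
    sens = (pos[None, :] >= cands[:, None]).mean(axis=1)
    spec = (neg[None, :] < cands[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    best = best[np.argmax(spec[best])]   # prefer higher specificity
    return float(cands[best]), float(sens[best]), float(spec[best])


# operations -----------------------------------------------------------------

def compare_rois(table: pd.DataFrame, roi_a: int, roi_b: int,
                 alpha: float = ALPHA_COMPARISONS,
                 params: list[str] | None = None,
                 correction: str = "none") -> list[ComparisonResult]:
    """Two-sided Mann-Whitney per parameter between two ROIs.

    correction : ``"none"`` (default — fixed per-test alpha, matching the
        study design) or ``"holm"`` (step-down familywise correction over
        the parameters of this ROI pair).
    """
    if correction not in ("none", "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    out = []
    for p in (params or [c for c in PARAMS if c in table.columns]):
        a, b = _pair_values(table, p, roi_a, roi_b)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(
                f"need >=3 cases per group for {p} ({len(a)} vs {len(b)})")
        u, pval, degen = mann_whitney(a, b)
        out.append(ComparisonResult(
            parameter=p, roi_pair=(roi_a, roi_b), u_statistic=u,
            p_value=pval, n_a=len(a), n_b=len(b),
            significant=bool(pval < alpha), degenerate=degen))
    if correction == "holm":
        from dataclasses import replace
        order = np.argsort([r.p_value for r in out], kind="stable")
        m = len(out)
        reject_so_far = True
        flags = [False] * m
        for rank, idx in enumerate(order):
            reject_so_far = reject_so_far and \
                out[idx].p_value < alpha / (m - rank)
            flags[idx] = reject_so_far
        out = [replace(r, significant=f) for r, f in zip(out, flags)]
    return out


def roc_analysis(table: pd.DataFrame, roi_a: int, roi_b: int,
                 n_boot: int = N_BOOT_DEFAULT, seed: int = 0,
                 params: list[str] | None = None) -> list[ROCResult]:
    """Empirical ROC per parameter, ranked by AUC (descending).

    ROI-a is the positive class; orientation is flipped (and recorded)
    when its values run lower, so the reported AUC is always ≥ 0.5.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    rng = np.random.default_rng(seed)
    out = []
    for p in (params or [c for c in PARAMS if c in table.columns]):
        a, b = _pair_values(table, p, roi_a, roi_b)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group for {p}")
        degenerate = np.unique(np.concatenate([a, b])).size == 1
        auc = auc_concordance(a, b)
        direction = "greater"
        pos, neg = a, b
        if auc < 0.5:
            direction, auc, pos, neg = "less", 1.0 - auc, -a, -b
        cut, sens, spec = _youden_cutoff(pos, neg)
        cutoff = cut if direction == "greater" else -cut

        boots = np.empty(n_boot)
        for k in range(n_boot):
            ra = pos[rng.integers(0, len(pos), len(pos))]
            rb = neg[rng.integers(0, len(neg), len(neg))]
            boots[k] = auc_concordance(ra, rb)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out.append(ROCResult(
            parameter=p, roi_pair=(roi_a, roi_b),
            auc=0.5 if degenerate else auc, cutoff=cutoff,
            sensitivity=sens, specificity=spec,
            ci_low=float(min(lo, hi)), ci_high=float(max(lo, hi)),
            n_boot=n_boot, seed=seed, direction=direction,
            degenerate=degenerate))
    # rank by AUC; deterministic name tiebreak
    out.sort(key=lambda r: (-r.auc, r.parameter))
    return out


def spearman_ci(x: np.ndarray, y: np.ndarray, n_boot: int, seed: int):
    """Percentile bootstrap 95% CI of Spearman rho (cases resampled)."""
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, (n_boot, n))
    xr = stats.rankdata(x[idx], axis=1)
    yr = stats.rankdata(y[idx], axis=1)
    xc = xr - xr.mean(axis=1, keepdims=True)
    yc = yr - yr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rhos = (xc * yc).sum(axis=1) / denom
    rhos = rhos[np.isfinite(rhos)]
    if rhos.size == 0:
        return np.nan, np.nan
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return float(lo), float(hi)


def marker_correlations(table: pd.DataFrame, roi: int,
                        markers: list[str] | None = None,
                        alpha: float = ALPHA_CORRELATIONS,
                        n_boot: int = N_BOOT_DEFAULT, seed: int = 0,
                        params: list[str] | None = None
                        ) -> list[CorrelationResult]:
    """Spearman rho (tie-corrected p) between imaging parameters and
    marker columns within one ROI, with bootstrap 95% CIs."""
    sub = table[table["roi"] == roi]
    if markers is None:
        markers = [c for c in ("Ki67_LI", "Bcl2_EA", "CD133_EA")
                   if c in table.columns]
    out = []
    for marker in markers:
        for p in (params or [c for c in PARAMS if c in table.columns]):
            x = sub[p].to_numpy(dtype=float)
            y = sub[marker].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            x, y = x[keep], y[keep]
            if len(x) < 5:
                raise ValueError(
                    f"need >=5 paired observations for {p} vs {marker}")
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                out.append(CorrelationResult(
                    parameter=p, roi=roi, marker=marker, rho=np.nan,
                    p_value=np.nan, ci_low=np.nan, ci_high=np.nan,
                    n=len(x), significant=False, degenerate=True))
                continue
            rho, pval = stats.spearmanr(x, y)
            lo, hi = spearman_ci(x, y, n_boot, seed)
            out.append(CorrelationResult(
                parameter=p, roi=roi, marker=marker, rho=float(rho),
                p_value=float(pval), ci_low=lo, ci_high=hi, n=len(x),
                significant=bool(pval < alpha)))
    return out


# reporting ------------------------------------------------------------------

def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair": f"{r.roi_pair[0]}-{r.roi_pair[1]}", "parameter": r.parameter,
        "U": r.u_statistic, "p": r.p_value, "n_a": r.n_a, "n_b": r.n_b,
        "significant": r.significant, "degenerate": r.degenerate,
    } for r in results])


def roc_frame(results: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair": f"{r.roi_pair[0]}-{r.roi_pair[1]}", "parameter": r.parameter,
        "AUC": r.auc, "cutoff": r.cutoff, "specificity": r.specificity,
        "sensitivity": r.sensitivity, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "direction": r.direction,
        "degenerate": r.degenerate,
    } for r in results])


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "roi": r.roi, "marker": r.marker, "parameter": r.parameter,
        "rho": r.rho, "p": r.p_value, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "n": r.n, "significant": r.significant,
    } for r in results])


def report(comparisons: list[ComparisonResult], rocs: list[ROCResult],
           correlations: list[CorrelationResult] | None = None
           ) -> tuple[dict[str, pd.DataFrame], str]:
    """Deterministic CSV-able frames + a human-readable Markdown summary.

    ROC rows are ordered by AUC within each ROI pair, mirroring a ranked
    biomarker table; identical inputs produce byte-identical output.
    """
    if not comparisons or not rocs:
        raise ValueError("comparisons and ROC results must be non-empty")
    frames = {
        "comparisons": comparisons_frame(comparisons).sort_values(
            ["pair", "parameter"], kind="stable").reset_index(drop=True),
        "roc": roc_frame(rocs).sort_values(
            ["pair", "AUC", "parameter"], ascending=[True, False, True],
            kind="stable").reset_index(drop=True),
    }
    if correlations:
        frames["correlations"] = correlations_frame(correlations).sort_values(
            ["roi", "marker", "parameter"], kind="stable").reset_index(drop=True)

    lines = ["# ROI statistics report", ""]
    lines.append("## ROC ranking (per ROI pair)")
    for pair, grp in frames["roc"].groupby("pair", sort=True):
        lines.append(f"\n### ROI pair {pair}\n")
        lines.append("| rank | parameter | AUC | cutoff | spec. | sens. | 95% CI |")
        lines.append("|---|---|---|---|---|---|---|")
        for rank, (_, row) in enumerate(grp.iterrows(), start=1):
            lines.append(
                f"| {rank} | {row.parameter} | {row.AUC:.3f} | "
                f"{row.cutoff:.3g} | {row.specificity:.2f} | "
                f"{row.sensitivity:.2f} | "
                f"[{row.ci_low:.3f}, {row.ci_high:.3f}] |")
    lines.append("\n## Group comparisons (Mann-Whitney)\n")
    sig = frames["comparisons"][frames["comparisons"]["significant"]]
    for pair, grp in sig.groupby("pair", sort=True):
        names = ", ".join(sorted(grp["parameter"]))
        lines.append(f"- pair {pair}: significant — {names}")
    if "correlations" in frames:
        lines.append("\n## Marker correlations (Spearman)\n")
        csig = frames["correlations"][frames["correlations"]["significant"]]
        for _, row in csig.iterrows():
            lines.append(
                f"- ROI{row.roi}: {row.marker} vs {row.parameter} "
                f"rho = {row.rho:.3f} (p = {row.p:.2g}, "
                f"CI [{row.ci_low:.3f}, {row.ci_high:.3f}])")
    return frames, "\n".join(lines) + "\n"


def roi_means(scalar_maps, wmti_maps, cbf: np.ndarray, rois: np.ndarray,
              case_id: str) -> pd.DataFrame:
    """One table row per ROI label: mean over valid voxels per parameter.

    A parameter whose valid voxels are all QC-deleted inside a ROI yields a
    missing value; a label absent from the mask yields a warning and no row.
    """
    rois = np.asarray(rois)
    rows = []
    for lab in (1, 2, 3, 4):
        sel = rois == lab
        if not sel.any():
            warnings.warn(f"missing ROI {lab} for {case_id}", stacklevel=2)
            continue
        row: dict = {"case_id": case_id, "roi": lab}
        maps = dict(scalar_maps.as_dict())
        maps.update(wmti_maps.as_dict())
        for name, arr in maps.items():
            mask = (scalar_maps.mask_for(name) if name in scalar_maps.as_dict()
                    else wmti_maps.mask_for(name))
            ok = sel & mask
            if ok.any():
                row[name] = float(arr[ok].mean())
            else:
                row[name] = np.nan
                logger.info("roi_means: ROI %d has no valid voxels for %s "
                            "(%s)", lab, name, case_id)
        row["CBF"] = float(cbf[sel].mean()) if cbf is not None else np.nan
        n_vox = int(sel.sum())
        logger.debug("roi_means: %s ROI %d n=%d voxels", case_id, lab, n_vox)
        rows.append(row)
    return pd.DataFrame(rows)
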