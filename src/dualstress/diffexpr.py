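"""Two-stage mixed linear model for per-probe differential expression.

Stage 1 removes array-level variability: the fitted array effect is
subtracted from every log-ratio, so per-array residual means are zero.
Stage 2 models each unique probe's residuals with fixed treatment, time
(categorical) and interaction effects plus a random intercept grouped by
biological replicate pair (run x replicate; configurable to run level).
The fit is parameterised directly in the 2x3 = 6 treatment-by-time cell
means, so the "expected expression" vectors fall straight out of the
coefficients; treatment/time/interaction F-tests are Wald contrasts.

Multiplicity handling is two-layered, both explicit: within each probe the
six cell t-tests (and optionally the pairwise cell contrasts) are adjusted
with the Tukey-Kramer studentized-range method; across probes the
interaction F-test p-values are screened with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .errors import ValidationError
from .tukey import studentized_range_sf

__all__ = [
    "Stage1Fit",
    "ProbeFit",
    "DESummary",
    "fit_stage1",
    "fit_stage2",
    "fit_stage2_probe",
    "adjust_pvalues",
    "fdr_select",
    "count_de",
    "stage2_table",
]


@dataclass
class Stage1Fit:
    """Array-effect removal: effects, residual table, variance components."""

    array_effects: pd.Series
    residuals: pd.DataFrame       # probe_id, array_id, residual
    var_array: float
    var_resid: float


@dataclass
class ProbeFit:
    """Stage-2 result for one unique probe.

    ``cells`` orders the (treatment, time) design cells; ``cell_means`` et
    al. follow that order with NaN for unpopulated cells.  ``f_tests`` maps
    ``trt``/``time``/``trt_time`` to ``(F, df1, df2, p)`` (NaN entries when
    untestable).
    """

    probe_id: str
    n_obs: int
    cells: tuple
    cell_means: np.ndarray
    cell_se: np.ndarray
    cell_t: np.ndarray
    cell_p: np.ndarray
    cov_cells: np.ndarray
    f_tests: dict
    sigma2: float
    tau2: float
    ddf: float
    used_ols: bool
    incomplete: bool
    coefficients: dict = field(default_factory=dict)
    cell_p_adj: np.ndarray | None = None
    pairwise: pd.DataFrame | None = None


@dataclass
class DESummary:
    """Per treatment-by-time significance counts and cross-treatment overlaps."""

    threshold: float
    counts: pd.DataFrame          # treatment, time_h, n_sig, n_up, n_down
    overlaps: pd.DataFrame        # time_h, n_overlap
    sig_sets: dict                # (treatment, time_h) -> frozenset of probe ids


def fit_stage1(lr: pd.DataFrame, design: pd.DataFrame) -> Stage1Fit:
    """Remove the per-array effect from the log-ratio table."""
    if len(lr) == 0:
        raise ValidationError("empty log-ratio table")
    known = set(design["array_id"])
    missing = set(lr["array_id"]) - known
    if missing:
        raise ValidationError(f"arrays absent from design: {sorted(missing)[:5]}")
    eff = lr.groupby("array_id")["log_ratio"].mean()
    resid = lr["log_ratio"] - lr["array_id"].map(eff)
    residuals = pd.DataFrame(
        {"probe_id": lr["probe_id"].to_numpy(),
         "array_id": lr["array_id"].to_numpy(),
         "residual": resid.to_numpy()}
    )
    var_array = float(eff.var(ddof=1)) if len(eff) > 1 else 0.0
    var_resid = float(residuals["residual"].var(ddof=1)) if len(residuals) > 1 else 0.0
    return Stage1Fit(eff.rename("array_effect"), residuals, var_array, var_resid)


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------

def _design_frame(design: pd.DataFrame, grouping: str):
    treatments = list(dict.fromkeys(design["treatment"]))
    times = sorted(pd.unique(design["time_h"]))
    n_times = len(times)
    cell_of = {
        (t, h): i * n_times + j
        for i, t in enumerate(treatments) for j, h in enumerate(times)
    }
    cells = tuple((t, h) for t in treatments for h in times)
    d = design.reset_index(drop=True)
    cell_idx = np.array([cell_of[(t, h)] for t, h in zip(d["treatment"], d["time_h"])])
    if grouping == "run_rep":
        keys = list(zip(d["run"], d["replicate"]))
    elif grouping == "run":
        keys = list(d["run"])
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    codes = pd.factorize(pd.Series(keys).astype(str))[0]
    return treatments, times, cells, cell_idx, codes


def _contrasts(n_trt: int, n_times: int):
    p = n_trt * n_times
    L_trt = np.zeros((n_trt - 1, p))
    for i in range(1, n_trt):
        L_trt[i - 1, i * n_times:(i + 1) * n_times] = 1.0 / n_times
        L_trt[i - 1, 0:n_times] = -1.0 / n_times
    L_time = np.zeros((n_times - 1, p))
    for j in range(1, n_times):
        for i in range(n_trt):
            L_time[j - 1, i * n_times + j] += 1.0 / n_trt
            L_time[j - 1, i * n_times + 0] -= 1.0 / n_trt
    L_int = np.zeros(((n_trt - 1) * (n_times - 1), p))
    r = 0
    for i in range(1, n_trt):
        for j in range(1, n_times):
            L_int[r, i * n_times + j] += 1.0
            L_int[r, i * n_times + 0] -= 1.0
            L_int[r, 0 * n_times + j] -= 1.0
            L_int[r, 0 * n_times + 0] += 1.0
            r += 1
    return {"trt": L_trt, "time": L_time, "trt_time": L_int}


def _reference_coefficients(cells, means):
    """Reference-coded effects derived from the cell means."""
    (t0, h0) = cells[0]
    out = {"intercept": means[0]}
    times = sorted({h for _, h in cells})
    trts = list(dict.fromkeys(t for t, _ in cells))
    idx = {c: i for i, c in enumerate(cells)}
    for t in trts[1:]:
        out[f"trt[{t}]"] = means[idx[(t, h0)]] - means[0]
    for h in times[1:]:
        out[f"time[{h:g}]"] = means[idx[(t0, h)]] - means[0]
    for t in trts[1:]:
        for h in times[1:]:
            out[f"trt_time[{t},{h:g}]"] = (
                means[idx[(t, h)]] - means[idx[(t, h0)]]
                - means[idx[(t0, h)]] + means[0]
            )
    return out


_NAN_F = (np.nan, np.nan, np.nan, np.nan)


def fit_stage2(
    residuals: pd.DataFrame,
    design: pd.DataFrame,
    grouping: str = "run_rep",
) -> list[ProbeFit]:
    """Fit the stage-2 model for every probe in the residual table.

    Probes with complete, balanced data share one design and are fitted
    through the vectorised exact-REML path; the rest fall back to the
    generic numeric REML fit (and to OLS when the random-intercept variance
    estimate hits zero — recorded per probe in ``used_ols``).
    """
    treatments, times, cells, cell_idx, codes = _design_frame(design, grouping)
    n_times, n_trt = len(times), len(treatments)
    p = n_trt * n_times
    arrays = list(design["array_id"])
    X = np.zeros((len(arrays), p))
    X[np.arange(len(arrays)), cell_idx] = 1.0
    Ls = _contrasts(n_trt, n_times)

    mat = (residuals.pivot_table(index="probe_id", columns="array_id",
                                 values="residual", aggfunc="mean")
           .reindex(columns=arrays))
    complete = ~mat.isna().any(axis=1).to_numpy()
    fits: dict[str, ProbeFit] = {}

    balanced = lmm.is_cell_balanced(X, codes) and n_trt * n_times == p
    if balanced and complete.any():
        sub = mat.loc[complete]
        Y = sub.to_numpy()
        bm = lmm.fit_balanced_many(Y, X, codes)
        ww = np.outer(bm.w, bm.w)
        diag0 = np.diag(bm.xtx_inv)
        w2 = bm.w**2
        var_cells = bm.sigma2[:, None] * (diag0[None, :] + bm.gamma[:, None] * w2[None, :])
        se = np.sqrt(var_cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = bm.beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), bm.ddf[:, None])
        fstats = {}
        for name, L in Ls.items():
            Q0 = L @ bm.xtx_inv @ L.T  # L @ s == 0, so lambda drops out
            Lw = L @ bm.w
            # guard in case a contrast is not orthogonal to the group sums
            corr = bm.gamma[:, None, None] * np.outer(Lw, Lw)[None, :, :]
            Qi = np.linalg.inv(Q0[None, :, :] + corr)
            bc = bm.beta @ L.T
            q = L.shape[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.einsum("ki,kij,kj->k", bc, Qi, bc) / (q * bm.sigma2)
            pf = stats.f.sf(F, q, bm.ddf)
            fstats[name] = (F, q, pf)
        for r, pid in enumerate(sub.index):
            cov = bm.sigma2[r] * (bm.xtx_inv + bm.gamma[r] * ww)
            fits[pid] = ProbeFit(
                probe_id=pid, n_obs=bm.n_obs, cells=cells,
                cell_means=bm.beta[r].copy(), cell_se=se[r], cell_t=tvals[r],
                cell_p=pvals[r], cov_cells=cov,
                f_tests={
                    name: (float(fstats[name][0][r]), fstats[name][1],
                           float(bm.ddf[r]), float(fstats[name][2][r]))
                    for name in Ls
                },
                sigma2=float(bm.sigma2[r]), tau2=float(bm.tau2[r]),
                ddf=float(bm.ddf[r]), used_ols=bool(bm.used_ols[r]),
                incomplete=False,
                coefficients=_reference_coefficients(cells, bm.beta[r]),
            )
        rest = mat.index[~complete]
    else:
        rest = mat.index

    for pid in rest:
        row = mat.loc[pid].to_numpy()
        have = ~np.isnan(row)
        fits[pid] = fit_stage2_probe(
            pid, row[have], cell_idx[have], codes[have], cells, Ls
        )
    return [fits[pid] for pid in mat.index]


def _degenerate_fit(probe_id, y, cell_idx, cells) -> ProbeFit:
    """Too little data to model: raw cell averages, everything untestable."""
    p = len(cells)
    means = np.full(p, np.nan)
    for c in np.unique(cell_idx):
        means[c] = float(np.mean(y[cell_idx == c]))
    nan = np.full(p, np.nan)
    return ProbeFit(
        probe_id=probe_id, n_obs=len(y), cells=cells, cell_means=means,
        cell_se=nan.copy(), cell_t=nan.copy(), cell_p=nan.copy(),
        cov_cells=np.full((p, p), np.nan),
        f_tests={name: _NAN_F for name in ("trt", "time", "trt_time")},
        sigma2=np.nan, tau2=np.nan, ddf=np.nan, used_ols=True, incomplete=True,
    )


def fit_stage2_probe(probe_id, y, cell_idx, codes, cells, Ls=None) -> ProbeFit:
    """Generic (possibly unbalanced) stage-2 fit for one probe."""
    p = len(cells)
    if Ls is None:
        times = sorted({h for _, h in cells})
        trts = list(dict.fromkeys(t for t, _ in cells))
        Ls = _contrasts(len(trts), len(times))
    present = np.unique(cell_idx)
    if len(present) < 2 or len(y) <= len(present):
        return _degenerate_fit(probe_id, y, cell_idx, cells)
    col_of = {c: k for k, c in enumerate(present)}
    Xs = np.zeros((len(y), len(present)))
    Xs[np.arange(len(y)), [col_of[c] for c in cell_idx]] = 1.0
    codes = pd.factorize(codes)[0]
    fit = lmm.fit_random_intercept(y, Xs, codes)
    t, se, pv = lmm.coef_t(fit)

    means = np.full(p, np.nan)
    ses = np.full(p, np.nan)
    ts = np.full(p, np.nan)
    ps = np.full(p, np.nan)
    cov = np.full((p, p), np.nan)
    means[present] = fit.beta
    ses[present] = se
    ts[present] = t
    ps[present] = pv
    cov[np.ix_(present, present)] = fit.cov_beta

    incomplete = len(present) < p
    trts_present = {cells[c][0] for c in present}
    f_tests = {}
    for name, L in Ls.items():
        if incomplete or (name != "time" and len(trts_present) < 2):
            f_tests[name] = _NAN_F
        else:
            F, q, df2, pf = lmm.contrast_f(fit, L[:, present])
            f_tests[name] = (F, q, df2, pf)
    coeffs = _reference_coefficients(cells, means) if not incomplete else {}
    return ProbeFit(
        probe_id=probe_id, n_obs=len(y), cells=cells,
        cell_means=means, cell_se=ses, cell_t=ts, cell_p=ps, cov_cells=cov,
        f_tests=f_tests, sigma2=fit.sigma2, tau2=fit.tau2, ddf=float(fit.ddf),
        used_ols=fit.used_ols, incomplete=incomplete, coefficients=coeffs,
    )


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def tukey_p(t_abs, k, df):
    """Tukey-Kramer adjusted p for |t| with k means: studentized-range tail."""
    scalar = np.ndim(t_abs) == 0
    t_abs = np.atleast_1d(np.asarray(t_abs, dtype=float))
    if k < 2:
        out = 2.0 * stats.t.sf(t_abs, df)
    else:
        out = studentized_range_sf(t_abs * np.sqrt(2.0), k, df)
    return float(out[0]) if scalar else out


def adjust_pvalues(fits: list[ProbeFit], pairwise: bool = False) -> list[ProbeFit]:
    """Tukey-Kramer adjust the within-probe cell tests (in place).

    With ``pairwise=True`` the 15 pairwise cell contrasts are also tested
    and adjusted; results land in ``fit.pairwise``.
    """
    for fit in fits:
        have = np.where(np.isfinite(fit.cell_means))[0]
        k = len(have)
        adj = np.full_like(fit.cell_p, np.nan)
        if k >= 1:
            raw = fit.cell_p[have]
            if k == 1:
                adj[have] = raw
            else:
                a = tukey_p(np.abs(fit.cell_t[have]), k, fit.ddf)
                adj[have] = np.maximum(a, raw)  # adjusted >= raw by construction
        fit.cell_p_adj = adj
        if pairwise and k >= 2:
            rows = []
            for ai in range(len(have)):
                for bi in range(ai + 1, len(have)):
                    i, j = have[ai], have[bi]
                    d = fit.cell_means[i] - fit.cell_means[j]
                    v = (fit.cov_cells[i, i] + fit.cov_cells[j, j]
                         - 2.0 * fit.cov_cells[i, j])
                    t = d / np.sqrt(v) if v > 0 else np.nan
                    p_raw = 2.0 * stats.t.sf(abs(t), fit.ddf)
                    p_adj = float(max(tukey_p(abs(t), k, fit.ddf), p_raw))
                    ca, cb = fit.cells[i], fit.cells[j]
                    rows.append((f"{ca[0]}:{ca[1]:g}h", f"{cb[0]}:{cb[1]:g}h",
                                 d, t, p_raw, p_adj))
            fit.pairwise = pd.DataFrame(
                rows, columns=["cell_a", "cell_b", "diff", "t", "p_raw", "p_adj"]
            )
    return fits


def fdr_select(pvals: pd.Series, alpha: float = 0.05):
    """Benjamini-Hochberg step-up; returns (selected ids, BH threshold)."""
    pv = pvals.dropna()
    if len(pv) == 0:
        return [], 0.0
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    order = np.argsort(pv.to_numpy(), kind="mergesort")
    sorted_p = pv.to_numpy()[order]
    m = len(sorted_p)
    crit = alpha * np.arange(1, m + 1) / m
    ok = np.where(sorted_p <= crit)[0]
    if len(ok) == 0:
        return [], 0.0
    kmax = ok.max()
    threshold = float(sorted_p[kmax])
    selected = pv.index[pv.to_numpy() <= threshold]
    return list(selected), threshold


def count_de(fits: list[ProbeFit], threshold: float = 0.001) -> DESummary:
    """Figure-1 style counts: per-cell significance at a raw-p threshold."""
    if not fits:
        raise ValidationError("no fitted probes")
    cells = fits[0].cells
    sig_sets = {c: set() for c in cells}
    up = {c: 0 for c in cells}
    down = {c: 0 for c in cells}
    for fit in fits:
        for k, c in enumerate(cells):
            pv = fit.cell_p[k]
            if np.isfinite(pv) and pv < threshold:
                sig_sets[c].add(fit.probe_id)
                if fit.cell_means[k] > 0:
                    up[c] += 1
                else:
                    down[c] += 1
    counts = pd.DataFrame(
        [(t, h, len(sig_sets[(t, h)]), up[(t, h)], down[(t, h)]) for (t, h) in cells],
        columns=["treatment", "time_h", "n_sig", "n_up", "n_down"],
    )
    treatments = list(dict.fromkeys(t for t, _ in cells))
    times = sorted({h for _, h in cells})
    rows = []
    for h in times:
        sets = [sig_sets[(t, h)] for t in treatments]
        rows.append((h, len(set.intersection(*sets)) if sets else 0))
    overlaps = pd.DataFrame(rows, columns=["time_h", "n_overlap"])
    return DESummary(threshold, counts, overlaps,
                     {c: frozenset(s) for c, s in sig_sets.items()})


def stage2_table(fits: list[ProbeFit]) -> pd.DataFrame:
    """Flatten probe fits into one results row per probe."""
    if not fits:
        return pd.DataFrame()
    cells = fits[0].cells
    rows = []
    for fit in fits:
        row = {"probe_id": fit.probe_id, "n_obs": fit.n_obs,
               "sigma2": fit.sigma2, "tau2": fit.tau2, "ddf": fit.ddf,
               "used_ols": fit.used_ols, "incomplete": fit.incomplete}
        for k, (t, h) in enumerate(cells):
            tag = f"{t}_{h:g}h"
            row[f"mean_{tag}"] = fit.cell_means[k]
            row[f"p_{tag}"] = fit.cell_p[k]
            if fit.cell_p_adj is not None:
                row[f"padj_{tag}"] = fit.cell_p_adj[k]
        for name in ("trt", "time", "trt_time"):
            F, _, _, pv = fit.f_tests.get(name, _NAN_F)
            row[f"F_{name}"] = F
            row[f"p_{name}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)
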