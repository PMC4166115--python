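"""LC-MS peak-area normalisation and the metabolite mixed model.

Raw peak areas are adjusted for sample mass and to the nearest-eluting
internal standard (retention-time ties break toward the earlier standard),
then each fraction is scaled so its maximum across samples equals 100.
Fractions detected in fewer than a configurable share of samples (default
90%) are treated as present/absent (dichotomous) and summarised by
presence counts only; the rest are log2-transformed and fitted with a
mixed model carrying fixed experiment-run, treatment, treated/control and
interaction effects plus a random intercept per biological replicate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm
from .diffexpr import tukey_p
from .errors import ValidationError

__all__ = [
    "MetaboliteFit",
    "normalize_peak_areas",
    "partition_metabolites",
    "presence_table",
    "fit_metabolite_model",
    "metabolite_table",
]


@dataclass
class MetaboliteFit:
    """Per-fraction model result (continuous class only carries estimates)."""

    fraction: str
    metab_class: str              # "continuous" | "dichotomous"
    n_obs: int = 0
    n_excluded_zero: int = 0
    beta: dict = field(default_factory=dict)
    cell_means: np.ndarray | None = None
    cells: tuple = ()
    f_tests: dict = field(default_factory=dict)
    cell_p: np.ndarray | None = None
    cell_p_adj: np.ndarray | None = None
    pairwise: pd.DataFrame | None = None
    sigma2: float = np.nan
    tau2: float = np.nan
    ddf: float = np.nan
    used_ols: bool = False
    testable: bool = True
    note: str = ""


def nearest_standard(fraction_rt: float, standards: pd.DataFrame) -> pd.Series:
    """Row of the internal standard nearest in retention time.

    Exact ties break toward the earlier-eluting standard.
    """
    s = standards.sort_values(["rt", "standard"], kind="mergesort").reset_index(drop=True)
    gaps = (s["rt"] - fraction_rt).abs().to_numpy()
    return s.iloc[int(np.argmin(gaps))]  # argmin takes the first (earlier) on ties


def normalize_peak_areas(
    areas: pd.DataFrame,
    samples: pd.DataFrame,
    fraction_rt: pd.Series,
    standards: pd.DataFrame,
    scaling: str = "fraction_max",
) -> pd.DataFrame:
    """Mass- and internal-standard-adjust raw areas, then scale to 100.

    ``areas`` is samples x fractions (indexed by sample_id).  ``scaling``
    is ``fraction_max`` (each fraction's max across samples becomes 100,
    the default reading) or ``sample_total`` (each sample's areas sum to
    100).  Multiplying one fraction's raw areas by any c > 0 leaves the
    fraction_max-normalised values unchanged.
    """
    if scaling not in ("fraction_max", "sample_total"):
        raise ValidationError(f"unknown scaling {scaling!r}")
    meta = samples.set_index("sample_id")
    missing = [s for s in areas.index if s not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")
    if (meta.loc[areas.index, "sample_mass"] <= 0).any():
        raise ValidationError("sample masses must be positive")

    zero_std = standards[standards["area"] <= 0]
    if len(zero_std):
        raise ValidationError(
            "internal standard area <= 0 for sample(s): "
            f"{sorted(set(zero_std['sample_id']))[:5]}"
        )
    # per-sample area of the standard nearest each fraction
    is_by_sample = standards.pivot(index="sample_id", columns="standard", values="area")
    rts = (standards.drop_duplicates("standard")
           .set_index("standard")["rt"].sort_values(kind="mergesort"))
    std_order = list(rts.index)
    nearest = {}
    for frac in areas.columns:
        gaps = np.abs(rts.to_numpy() - float(fraction_rt[frac]))
        nearest[frac] = std_order[int(np.argmin(gaps))]

    mass = meta.loc[areas.index, "sample_mass"].to_numpy()
    adj = areas.copy().astype(float)
    for frac in areas.columns:
        std_area = is_by_sample.loc[areas.index, nearest[frac]].to_numpy()
        adj[frac] = areas[frac].to_numpy() / mass / std_area
    if scaling == "fraction_max":
        peak = adj.max(axis=0).replace(0.0, np.nan)
        adj = adj.div(peak, axis=1).fillna(0.0) * 100.0
    else:
        tot = adj.sum(axis=1).replace(0.0, np.nan)
        adj = adj.div(tot, axis=0).fillna(0.0) * 100.0
    return adj


def partition_metabolites(
    norm: pd.DataFrame, presence_threshold: float = 0.90, floor: float = 0.0
) -> pd.Series:
    """Label each fraction ``continuous`` or ``dichotomous``.

    A fraction is continuous iff it is detected (area > ``floor``) in at
    least ``presence_threshold`` of the samples.
    """
    if not 0.0 < presence_threshold <= 1.0:
        raise ValidationError("presence_threshold must be in (0, 1]")
    frac_present = (norm > floor).mean(axis=0)
    labels = np.where(frac_present >= presence_threshold, "continuous", "dichotomous")
    return pd.Series(labels, index=norm.columns, name="metab_class")


def presence_table(norm: pd.DataFrame, samples: pd.DataFrame,
                   fractions, floor: float = 0.0) -> pd.DataFrame:
    """Presence counts per (treatment, tc) condition for selected fractions."""
    meta = samples.set_index("sample_id").loc[norm.index]
    key = meta["treatment"].astype(str) + ":" + meta["tc"].astype(str)
    rows = []
    for frac in fractions:
        present = norm[frac] > floor
        for cond, sub in present.groupby(key.to_numpy()):
            rows.append((frac, cond, int(sub.sum()), int(len(sub))))
    return pd.DataFrame(rows, columns=["fraction", "condition", "n_present", "n_total"])


def _metab_design(samples: pd.DataFrame):
    meta = samples.reset_index(drop=True)
    treatments = list(dict.fromkeys(meta["treatment"]))
    cells = tuple((t, c) for t in treatments for c in ("C", "T"))
    cell_of = {c: i for i, c in enumerate(cells)}
    cell_idx = np.array([cell_of[(t, c)] for t, c in zip(meta["treatment"], meta["tc"])])
    runs = sorted(pd.unique(meta["run"]))
    exp_col = np.where(meta["run"].to_numpy() == runs[0], -0.5, 0.5)
    codes = pd.factorize(meta["run"].astype(str) + "_" + meta["replicate"].astype(str))[0]
    return treatments, cells, cell_idx, exp_col, codes


def _metab_contrasts(n_trt: int):
    p = 2 * n_trt + 1  # cell means + centred run column
    L_trt = np.zeros((n_trt - 1, p))
    for i in range(1, n_trt):
        L_trt[i - 1, 2 * i:2 * i + 2] = 0.5
        L_trt[i - 1, 0:2] = -0.5
    L_tc = np.zeros((1, p))
    for i in range(n_trt):
        L_tc[0, 2 * i + 1] += 1.0 / n_trt   # T
        L_tc[0, 2 * i] -= 1.0 / n_trt       # C
    L_int = np.zeros((n_trt - 1, p))
    for i in range(1, n_trt):
        L_int[i - 1, 2 * i + 1] += 1.0
        L_int[i - 1, 2 * i] -= 1.0
        L_int[i - 1, 1] -= 1.0
        L_int[i - 1, 0] += 1.0
    return {"trt": L_trt, "tc": L_tc, "trt_tc": L_int}


def fit_metabolite_model(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    classes: pd.Series,
    floor: float = 0.0,
    pairwise: bool = True,
) -> list[MetaboliteFit]:
    """Fit the mixed model to every continuous fraction.

    Dichotomous fractions never enter the model; they come back as
    presence-only records.  Zero areas inside a continuous fraction are
    excluded from its fit (logged in ``n_excluded_zero``).
    """
    meta = samples.reset_index(drop=True)
    if list(norm.index) != list(meta["sample_id"]):
        norm = norm.loc[meta["sample_id"]]
    treatments, cells, cell_idx, exp_col, codes = _metab_design(meta)
    Ls = _metab_contrasts(len(treatments))
    p_cells = len(cells)

    fits = []
    for frac in norm.columns:
        cls = classes[frac]
        if cls != "continuous":
            fits.append(MetaboliteFit(frac, "dichotomous", testable=False,
                                      note="present/absent only; not modelled"))
            continue
        vals = norm[frac].to_numpy(dtype=float)
        ok = vals > floor
        n_zero = int((~ok).sum())
        y = np.log2(vals[ok])
        ci = cell_idx[ok]
        tc_counts = pd.Series([cells[c][1] for c in ci]).value_counts()
        if tc_counts.reindex(["C", "T"]).fillna(0).min() < 2:
            fits.append(MetaboliteFit(frac, "continuous", n_obs=int(ok.sum()),
                                      n_excluded_zero=n_zero, testable=False,
                                      note="fewer than 2 samples in a T/C level"))
            continue
        Xc = np.zeros((ok.sum(), p_cells))
        Xc[np.arange(ok.sum()), ci] = 1.0
        X = np.column_stack([Xc, exp_col[ok]])
        fit = lmm.fit_random_intercept(y, X, pd.factorize(codes[ok])[0])
        t, se, pv = lmm.coef_t(fit)
        means = fit.beta[:p_cells]
        f_tests = {name: lmm.contrast_f(fit, L) for name, L in Ls.items()}
        beta = {
            "intercept": means[0],
            "exp": fit.beta[-1],
            "trt": means[2] - means[0] if len(treatments) > 1 else np.nan,
            "tc": means[1] - means[0],
            "trt_tc": (means[3] - means[2] - means[1] + means[0])
            if len(treatments) > 1 else np.nan,
        }
        cell_p = pv[:p_cells]
        adj = np.maximum(tukey_p(np.abs(t[:p_cells]), p_cells, fit.ddf), cell_p)
        pw = None
        if pairwise:
            rows = []
            for i in range(p_cells):
                for j in range(i + 1, p_cells):
                    d = means[i] - means[j]
                    v = (fit.cov_beta[i, i] + fit.cov_beta[j, j]
                         - 2.0 * fit.cov_beta[i, j])
                    tt = d / np.sqrt(v) if v > 0 else np.nan
                    p_raw = 2.0 * stats.t.sf(abs(tt), fit.ddf)
                    rows.append((f"{cells[i][0]}:{cells[i][1]}",
                                 f"{cells[j][0]}:{cells[j][1]}", d, tt, p_raw,
                                 float(max(tukey_p(abs(tt), p_cells, fit.ddf), p_raw))))
            pw = pd.DataFrame(rows, columns=["cell_a", "cell_b", "diff", "t",
                                             "p_raw", "p_adj"])
        fits.append(MetaboliteFit(
            frac, "continuous", n_obs=int(ok.sum()), n_excluded_zero=n_zero,
            beta=beta, cell_means=means, cells=cells,
            f_tests={k: v for k, v in f_tests.items()},
            cell_p=cell_p, cell_p_adj=adj, pairwise=pw,
            sigma2=fit.sigma2, tau2=fit.tau2, ddf=float(fit.ddf),
            used_ols=fit.used_ols,
        ))
    return fits


def metabolite_table(fits: list[MetaboliteFit]) -> pd.DataFrame:
    """One results row per fraction."""
    rows = []
    for f in fits:
        row = {"fraction": f.fraction, "class": f.metab_class, "n_obs": f.n_obs,
               "n_excluded_zero": f.n_excluded_zero, "testable": f.testable,
               "used_ols": f.used_ols, "sigma2": f.sigma2, "tau2": f.tau2,
               "note": f.note}
        for name in ("exp", "trt", "tc", "trt_tc"):
            row[f"beta_{name}"] = f.beta.get(name, np.nan)
        for name in ("trt", "tc", "trt_tc"):
            F, _, _, pv = f.f_tests.get(name, (np.nan,) * 4)
            row[f"F_{name}"] = F
            row[f"p_{name}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)
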