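"""Synthetic two-colour microarray experiments and metabolite peak tables.

Everything downstream of the wet lab is testable against these generators:
they emit spot tables, sample sheets and metabolite peak tables together
with the ground truth that was planted (which probes are differential and
their six treatment-by-time cell means; which peak-table fractions carry
planted factor effects).

Generation model for the arrays, on the log2 scale::

    treated channel  = probe + array + dye + cell_mean + replicate + noise
    control channel  = probe + array + noise

so the per-spot log-ratio is ``dye + cell_mean + replicate + noise`` and a
per-array mean-centering (global normalisation) removes the dye offset.
Log2 signals are exponentiated and an additive background is drawn per spot
and channel.  Control-class spots (spikes, poly(dA), blanks, buffer,
negatives) are generated signal-free except spikes, so the preprocessing
exclusions can be exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "ArrayDesignSpec",
    "EffectSpec",
    "MetabDesignSpec",
    "ArrayExperiment",
    "MetaboliteExperiment",
    "generate_array_experiment",
    "generate_metabolite_experiment",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20140917

# archetype 6-vectors in (treatment-major, time-minor) order; the planted
# profile of a differential probe is a scaled, sign-flipped archetype
_ARCHETYPES = np.array(
    [
        [2.0, 1.0, 0.0, 0.0, 1.0, 2.0],   # early under trt A, late under trt B
        [0.0, 1.0, 2.0, 2.0, 1.0, 0.0],
        [1.5, 1.5, 0.0, 0.0, 0.0, 0.0],   # trt-A only, early
        [0.0, 0.0, 0.0, 0.0, 1.5, 1.5],   # trt-B only, late
        [2.0, 0.0, 1.0, 0.0, 1.5, 0.0],
    ]
)

_CONTROL_CLASSES_DEFAULT = (
    ("spike", 10),
    ("polyA", 4),
    ("blank", 8),
    ("buffer", 8),
    ("negative", 6),
)


@dataclass(frozen=True)
class ArrayDesignSpec:
    """Factorial layout of a two-colour microarray experiment."""

    n_runs: int = 2
    treatments: tuple[str, ...] = ("Psyr", "Spod")
    times_h: tuple[float, ...] = (1, 6, 24)
    n_reps: int = 5
    n_probes: int = 1287
    n_duplicated: int = 26
    control_classes: tuple[tuple[str, int], ...] = _CONTROL_CLASSES_DEFAULT
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        for name in ("n_runs", "n_reps", "n_probes"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not self.treatments or not self.times_h:
            raise ParameterError("need at least one treatment and one time point")
        if not 0 <= self.n_duplicated <= self.n_probes // 2:
            raise ParameterError(
                "n_duplicated must be in [0, n_probes/2] so every duplicate "
                "has a distinct parent probe"
            )
        if any(n < 0 for _, n in self.control_classes):
            raise ParameterError("control spot counts must be >= 0")

    @property
    def n_arrays(self) -> int:
        return self.n_runs * len(self.treatments) * len(self.times_h) * self.n_reps

    @property
    def n_unique_probes(self) -> int:
        return self.n_probes - self.n_duplicated


@dataclass(frozen=True)
class EffectSpec:
    """Magnitudes of the planted effects, all on the log2 scale.

    The paper reports no effect sizes; these defaults are arbitrary
    plumbing chosen so that signal, replicate and residual variation are
    all visible.  ``dye_bias`` is the SD of the per-array additive channel
    offset.  ``sign_balanced`` pairs every planted profile with its
    negation so the per-array mean of true effects is zero and global
    normalisation is exactly unbiased (use an even number of differential
    probes for exact balance).
    """

    frac_differential: float = 0.10
    effect_scale: float = 1.0
    sd_probe: float = 1.0
    sd_array: float = 0.5
    sd_replicate: float = 0.25
    sd_noise: float = 0.30
    dye_bias: float = 0.30
    missing_rate: float = 0.02
    background_mean: float = 100.0
    background_sd: float = 30.0
    probe_base: float = 10.0
    sign_balanced: bool = True

    def __post_init__(self):
        for name in ("sd_probe", "sd_array", "sd_replicate", "sd_noise",
                     "dye_bias", "background_sd", "effect_scale"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ParameterError("frac_differential must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0, 1)")


@dataclass
class ArrayExperiment:
    """Bundle returned by :func:`generate_array_experiment`.

    ``spots`` is a single long table with an ``array_id`` column (one
    GPR-like file per array is produced by :func:`dualstress.io.write_spot_tables`).
    """

    spots: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    design: ArrayDesignSpec
    effects: EffectSpec
    seed: int

    def cell_columns(self) -> list[str]:
        return [c for c in self.truth.columns if c.startswith("y_")]


def _cell_label(trt: str, time_h) -> str:
    return f"y_{trt}_{time_h:g}h"


def generate_array_experiment(
    design: ArrayDesignSpec | None = None,
    effects: EffectSpec | None = None,
    seed: int | None = None,
) -> ArrayExperiment:
    """Generate a full two-colour experiment with known ground truth.

    Identical ``(design, effects, seed)`` give bit-identical output.
    """
    design = design or ArrayDesignSpec()
    effects = effects or EffectSpec()
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    nu = design.n_unique_probes
    width = max(5, len(str(nu)))
    probe_ids = np.array([f"P{i:0{width}d}" for i in range(1, nu + 1)])
    # the first n_duplicated probes are printed twice
    spot_probe_idx = np.concatenate(
        [np.arange(nu), np.arange(design.n_duplicated)]
    )
    n_exp_spots = spot_probe_idx.size  # == design.n_probes

    treatments = list(design.treatments)
    times = list(design.times_h)
    n_cells = len(treatments) * len(times)

    # --- sample sheet -----------------------------------------------------
    rows = []
    for run in range(1, design.n_runs + 1):
        for ti, trt in enumerate(treatments):
            for hi, time_h in enumerate(times):
                for rep in range(1, design.n_reps + 1):
                    array_id = f"r{run}_{trt}_{time_h:g}h_rep{rep}"
                    rows.append((array_id, run, trt, time_h, rep,
                                 ti * len(times) + hi,
                                 (run - 1) * design.n_reps + (rep - 1)))
    sheet = pd.DataFrame(
        rows, columns=["array_id", "run", "treatment", "time_h", "replicate",
                       "_cell", "_pair"]
    )
    n_arrays = len(sheet)
    assert n_arrays == design.n_arrays

    # --- planted truth ----------------------------------------------------
    n_diff = int(round(effects.frac_differential * nu))
    diff_idx = np.sort(rng.choice(nu, size=n_diff, replace=False))
    T = np.zeros((nu, n_cells))
    if n_diff:
        n_base = (n_diff + 1) // 2 if effects.sign_balanced else n_diff
        picks = rng.integers(0, len(_ARCHETYPES), size=n_base)
        signs = rng.choice([-1.0, 1.0], size=n_base)
        profs = effects.effect_scale * signs[:, None] * _ARCHETYPES[picks][:, :n_cells]
        if effects.sign_balanced:
            paired = np.concatenate([profs, -profs], axis=0)[:n_diff]
        else:
            paired = profs
        T[diff_idx] = paired
    cell_cols = [_cell_label(t, h) for t in treatments for h in times]
    truth = pd.DataFrame(T, columns=cell_cols)
    truth.insert(0, "probe_id", probe_ids)
    truth.insert(1, "is_differential", np.isin(np.arange(nu), diff_idx))

    # --- random effects ---------------------------------------------------
    probe_eff = rng.normal(effects.probe_base, effects.sd_probe, nu)
    array_eff = rng.normal(0.0, effects.sd_array, n_arrays)
    dye_eff = rng.normal(0.0, effects.dye_bias, n_arrays)
    n_pairs = design.n_runs * design.n_reps
    rep_eff = rng.normal(0.0, effects.sd_replicate, (nu, n_pairs))

    n_ctrl = sum(n for _, n in design.control_classes)
    n_spots = n_exp_spots + n_ctrl
    noise_sd = effects.sd_noise / math.sqrt(2.0)  # per channel; ratio gets sd_noise
    noise = rng.normal(0.0, noise_sd, (n_arrays, n_spots, 2))
    bg = rng.normal(effects.background_mean, effects.background_sd,
                    (n_arrays, n_spots, 2)).clip(min=0.0)
    flagged = rng.random((n_arrays, n_spots)) < effects.missing_rate
    n_spikes = dict(design.control_classes).get("spike", 0)
    spike_sig = rng.normal(12.0, 0.2, (n_arrays, n_spikes, 2)) if n_spikes else None

    cells = sheet["_cell"].to_numpy()
    pairs = sheet["_pair"].to_numpy()

    # --- compose log2 signals (arrays x spots) ----------------------------
    pe = probe_eff[spot_probe_idx]                             # (n_exp,)
    cell_sig = T[spot_probe_idx]                               # (n_exp, n_cells)
    lt = (pe[None, :] + array_eff[:, None] + dye_eff[:, None]
          + cell_sig[:, cells].T
          + rep_eff[spot_probe_idx][:, pairs].T
          + noise[:, :n_exp_spots, 0])
    lc = pe[None, :] + array_eff[:, None] + noise[:, :n_exp_spots, 1]

    f_treat = np.zeros((n_arrays, n_spots))
    f_ctrl = np.zeros((n_arrays, n_spots))
    f_treat[:, :n_exp_spots] = np.exp2(lt) + bg[:, :n_exp_spots, 0]
    f_ctrl[:, :n_exp_spots] = np.exp2(lc) + bg[:, :n_exp_spots, 1]

    ctrl_ids = []
    ctrl_classes = []
    offset = n_exp_spots
    for cls, count in design.control_classes:
        for j in range(count):
            ctrl_ids.append(f"{cls}_{j + 1:02d}")
            ctrl_classes.append(cls)
        sl = slice(offset, offset + count)
        if cls == "spike" and count:
            f_treat[:, sl] = np.exp2(spike_sig[..., 0] + noise[:, sl, 0]) + bg[:, sl, 0]
            f_ctrl[:, sl] = np.exp2(spike_sig[..., 1] + noise[:, sl, 1]) + bg[:, sl, 1]
        else:
            # signal-free: foreground fluctuates around background
            f_treat[:, sl] = (bg[:, sl, 0] + noise[:, sl, 0] * 10.0).clip(min=0.0)
            f_ctrl[:, sl] = (bg[:, sl, 1] + noise[:, sl, 1] * 10.0).clip(min=0.0)
        offset += count

    spot_ids = np.concatenate([probe_ids[spot_probe_idx], np.array(ctrl_ids, dtype=object)]) \
        if ctrl_ids else probe_ids[spot_probe_idx]
    spot_cls = np.concatenate(
        [np.full(n_exp_spots, "experimental", dtype=object),
         np.array(ctrl_classes, dtype=object)]
    ) if ctrl_classes else np.full(n_exp_spots, "experimental", dtype=object)

    spots = pd.DataFrame(
        {
            "array_id": np.repeat(sheet["array_id"].to_numpy(), n_spots),
            "probe_id": np.tile(spot_ids, n_arrays),
            "spot_class": np.tile(spot_cls, n_arrays),
            "f_treat": f_treat.ravel(),
            "b_treat": bg[:, :, 0].ravel(),
            "f_ctrl": f_ctrl.ravel(),
            "b_ctrl": bg[:, :, 1].ravel(),
            "flag": np.where(flagged.ravel(), "bad", "good"),
        }
    )

    sheet = sheet.drop(columns=["_cell", "_pair"])
    return ArrayExperiment(spots, sheet, truth, design, effects, seed)


# ---------------------------------------------------------------------------
# metabolite experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetabDesignSpec:
    """Design and planted effects for the LC-MS peak-area generator."""

    n_runs: int = 2
    treatments: tuple[str, ...] = ("Psyr", "Spod")
    tc_levels: tuple[str, ...] = ("C", "T")
    n_reps: int = 8
    n_fractions: int = 33
    frac_dichotomous: float = 0.15
    frac_affected: float = 0.30
    effect_exp: float = 0.5
    effect_trt: float = 1.0
    effect_tc: float = 1.5
    effect_trt_tc: float = 1.0
    sd_fraction: float = 1.5
    sd_replicate: float = 0.20
    sd_noise: float = 0.10
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_runs <= 0 or self.n_reps <= 0 or self.n_fractions <= 0:
            raise ParameterError("counts must be positive")
        if len(self.treatments) < 1 or len(self.tc_levels) != 2:
            raise ParameterError("need >=1 treatment and exactly 2 T/C levels")
        for name in ("sd_fraction", "sd_replicate", "sd_noise"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("frac_dichotomous", "frac_affected"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")

    @property
    def n_analyses(self) -> int:
        return self.n_runs * len(self.treatments) * len(self.tc_levels) * self.n_reps


@dataclass
class MetaboliteExperiment:
    """Peak-area bundle: sample metadata, raw areas, standards and truth."""

    samples: pd.DataFrame          # sample_id, run, treatment, tc, replicate, sample_mass
    areas: pd.DataFrame            # sample_id x fraction raw peak areas
    fraction_rt: pd.Series         # fraction -> retention time (min)
    standards: pd.DataFrame        # sample_id, standard, rt, area
    truth: pd.DataFrame            # per-fraction planted effects / presence
    spec: MetabDesignSpec
    seed: int


_IS_RTS = {"IS_C2": 6.0, "IS_C4": 18.0, "IS_C8": 30.0}  # alkyl hydroxybenzoate series


def generate_metabolite_experiment(
    spec: MetabDesignSpec | None = None, seed: int | None = None
) -> MetaboliteExperiment:
    """Generate the 2-run x 2-treatment x T/C x replicate peak table."""
    spec = spec or MetabDesignSpec()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    fractions = [f"F{i:02d}" for i in range(1, spec.n_fractions + 1)]
    frac_rt = pd.Series(
        np.linspace(2.0, 36.0, spec.n_fractions) + rng.uniform(-0.4, 0.4, spec.n_fractions),
        index=fractions, name="rt",
    )

    rows = []
    for run in range(1, spec.n_runs + 1):
        for trt in spec.treatments:
            for tc in spec.tc_levels:
                for rep in range(1, spec.n_reps + 1):
                    rows.append((f"e{run}_{trt}_{tc}_rep{rep}", run, trt, tc, rep))
    samples = pd.DataFrame(rows, columns=["sample_id", "run", "treatment", "tc", "replicate"])
    samples["sample_mass"] = rng.normal(15.0, 1.5, len(samples)).clip(min=5.0)

    nf = spec.n_fractions
    n_dich = int(round(spec.frac_dichotomous * nf))
    dich_idx = np.sort(rng.choice(nf, size=n_dich, replace=False))
    affected = rng.random(nf) < spec.frac_affected
    signs = rng.choice([-1.0, 1.0], size=(nf, 3))
    beta_exp = rng.normal(0.0, spec.effect_exp, nf)
    beta_trt = np.where(affected, signs[:, 0] * spec.effect_trt, 0.0)
    beta_tc = np.where(affected, signs[:, 1] * spec.effect_tc, 0.0)
    beta_int = np.where(affected, signs[:, 2] * spec.effect_trt_tc, 0.0)

    base = rng.normal(8.0, spec.sd_fraction, nf)
    is_run2 = (samples["run"] > 1).to_numpy(dtype=float)
    is_trt1 = (samples["treatment"] == spec.treatments[-1]).to_numpy(dtype=float)
    is_t = (samples["tc"] == "T").to_numpy(dtype=float)
    pair = ((samples["run"] - 1) * spec.n_reps + (samples["replicate"] - 1)).to_numpy()
    n_pairs = spec.n_runs * spec.n_reps
    rep_eff = rng.normal(0.0, spec.sd_replicate, (nf, n_pairs))
    noise = rng.normal(0.0, spec.sd_noise, (len(samples), nf))

    log2adj = (base[None, :]
               + np.outer(is_run2, beta_exp)
               + np.outer(is_trt1, beta_trt)
               + np.outer(is_t, beta_tc)
               + np.outer(is_trt1 * is_t, beta_int)
               + rep_eff[:, pair].T
               + noise)
    adjusted = np.exp2(log2adj)

    # dichotomous fractions: present only in a proper subset of trt x tc cells
    cell_of_sample = (is_trt1 * 2 + is_t).astype(int)
    present_cells = {}
    for j in dich_idx:
        k = rng.integers(1, 4)  # 1..3 of the 4 cells
        cells = np.sort(rng.choice(4, size=k, replace=False))
        present_cells[j] = set(int(c) for c in cells)
        mask = np.isin(cell_of_sample, cells)
        adjusted[~mask, j] = 0.0

    # internal standards: ~constant amount, instrument response varies/sample
    std_rows = []
    is_area = rng.normal(1e5, 8e3, (len(samples), len(_IS_RTS))).clip(min=1e4)
    for i, sid in enumerate(samples["sample_id"]):
        for k, (name, rt) in enumerate(_IS_RTS.items()):
            std_rows.append((sid, name, rt, is_area[i, k]))
    standards = pd.DataFrame(std_rows, columns=["sample_id", "standard", "rt", "area"])

    # reconstruct "raw" areas so that raw / mass / nearest-IS == adjusted
    is_rt = np.array(list(_IS_RTS.values()))
    nearest = np.array([int(np.argmin(np.abs(is_rt - rt))) for rt in frac_rt])
    raw = adjusted * samples["sample_mass"].to_numpy()[:, None] * is_area[:, nearest]
    areas = pd.DataFrame(raw, columns=fractions)
    areas.insert(0, "sample_id", samples["sample_id"])
    areas = areas.set_index("sample_id")

    cell_names = [f"{t}:{c}" for t in ([spec.treatments[0], spec.treatments[-1]]
                                       if len(spec.treatments) > 1 else list(spec.treatments))
                  for c in ("C", "T")]
    truth = pd.DataFrame(
        {
            "fraction": fractions,
            "is_dichotomous": np.isin(np.arange(nf), dich_idx),
            "present_cells": [
                ";".join(cell_names[c] for c in sorted(present_cells[j]))
                if j in present_cells else "all"
                for j in range(nf)
            ],
            "beta_exp": beta_exp,
            "beta_trt": beta_trt,
            "beta_tc": beta_tc,
            "beta_trt_tc": beta_int,
        }
    )
    return MetaboliteExperiment(samples, areas, frac_rt, standards, truth, spec, seed)
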