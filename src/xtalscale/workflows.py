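"""Scaling workflows: the core multi-round algorithm, reference and
incremental scaling, deltaCC1/2 scale-and-filter cycles, and free-set
cross-validation.

The default single/multi-sweep algorithm runs, in order: initial per-sweep
outlier rejection (multi-sweep only), reflection-subset selection,
quasi-Newton model-optimization blocks interleaved with outlier rounds,
profile/summation combination optimization, error-model refinement with a
weight update, further optimization and outlier rounds, a final full-matrix
(Levenberg-Marquardt) cycle with uncertainty propagation, a final
error-model refinement and outlier marking, and a merging report.  Each
optional step can be disabled independently; with everything disabled the
run is a pure pass-through (g = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reflection_data as rd
from .error_model import ErrorModel, apply_error_model, refine_error_model
from .merging import binned_report, delta_cc_half, merge, r_metrics, \
    cc_half_sigma_tau, resolution_bins_of_groups
from .models import ModelConfig, ScalingModel, build_model
from .outliers import CombinationChoice, apply_combination, flag_outliers, \
    optimize_combination
from .selection import SelectionThresholds, select_quasi_random, \
    select_random, split_free_set
from .target import MinimizerResult, ScalingTarget, anchor_mean_scale, \
    minimize, propagate_uncertainties

log = logging.getLogger("xtalscale")

#: sweeps narrower than this default to the KB model when model="auto"
KB_WIDTH_LIMIT = 5.0


@dataclass
class ScalingRunConfig:
    model: str = "auto"                  # physical | kb | array | auto
    model_config: ModelConfig = field(default_factory=ModelConfig)
    selection: str = "auto"              # random | quasi_random | all | auto
    thresholds: SelectionThresholds = field(
        default_factory=SelectionThresholds)
    outlier_rejection: bool = True
    outlier_z: float = 6.0
    error_model: bool = True
    combine: bool = True
    full_matrix: bool = True
    n_blocks_before: int = 2             # quasi-Newton blocks before the
    n_blocks_after: int = 1              # error model, and after
    max_iter: int = 100
    tol: float = 1e-6
    anomalous: bool = False
    d_min: float | None = None
    # deltaCC1/2 filtering
    filter_k_sd: float = 4.0
    filter_image_group: int = 10         # images per deltaCC group
    filter_partition: str = "image_group"  # or "sweep"
    filter_max_cycles: int = 10
    filter_min_completeness: float = 90.0
    filter_max_percent_removed: float = 10.0
    # free set
    free_fraction: float = 0.1
    seed: int = 0


@dataclass
class RunState:
    table: pd.DataFrame
    models: dict
    sweeps: dict
    space_group: str
    error_model: ErrorModel | None = None
    combination: CombinationChoice | None = None
    minimizer: MinimizerResult | None = None
    report: dict = field(default_factory=dict)
    cycle_log: list = field(default_factory=list)
    config: ScalingRunConfig | None = None

    def merged(self) -> pd.DataFrame:
        t = self.table
        ok = rd.usable(t)
        sub = t[ok]
        return merge(sub["group_id"].to_numpy(),
                     sub["I_work"].to_numpy(dtype=float),
                     sub["var_prime"].to_numpy(dtype=float),
                     sub["g"].to_numpy(dtype=float),
                     asu_hkl=sub[["asu_h", "asu_k", "asu_l"]].to_numpy(),
                     n_groups=int(t["group_id"].max()) + 1)


def _model_type_for(config: ScalingRunConfig, meta: rd.SweepMetadata) -> str:
    if config.model != "auto":
        return config.model
    return "physical" if meta.width >= KB_WIDTH_LIMIT else "kb"


def _prepare_table(table: pd.DataFrame, sweeps: dict, space_group: str,
                   config: ScalingRunConfig, models: dict | None):
    """ASU mapping, per-sweep models + normalized coordinates, work columns."""
    table = rd.map_to_asu(table, space_group, config.anomalous)
    if config.d_min is not None:
        low = table["d"].to_numpy(dtype=float) < config.d_min
        table.loc[low, "flags"] |= rd.EXCLUDED
    out_models: dict[str, ScalingModel] = {}
    parts = []
    for sid, meta in sweeps.items():
        sub = table[table["sweep_id"] == sid]
        if len(sub) == 0:
            continue
        if models and sid in models:
            model = models[sid]
        else:
            mtype = _model_type_for(config, meta)
            cfg = replace(config.model_config, model_type=mtype)
            model = build_model(mtype, meta, cfg)
        out_models[sid] = model
        parts.append(model.normalize(sub, meta))
    table = pd.concat(parts).sort_index() if parts else table
    if "I_work" not in table.columns:
        table["I_work"] = table["I_prof"]
        table["var_work"] = table["var_prof"]
    table["var_prime"] = table["var_work"]
    return table, out_models


def _update_scales(table, models, sweeps) -> pd.DataFrame:
    for sid, model in models.items():
        mask = (table["sweep_id"] == sid).to_numpy()
        sub = table[mask]
        g = model.inverse_scales(model.prepare(sub))
        table.loc[mask, "g"] = g
    return table


def _outlier_round(table, config: ScalingRunConfig, per_sweep=False):
    if not config.outlier_rejection:
        return table
    flags = table["flags"].to_numpy().copy()
    flags &= ~np.int64(rd.OUTLIER)   # re-test previously flagged rows
    table["flags"] = flags
    testable = (flags & (rd.EXCLUDED | rd.BAD_FOR_SCALING)) == 0
    sub = table[testable]
    if len(sub) == 0:
        return table
    if per_sweep:
        gid = sub["group_id"].to_numpy()
        scode = pd.factorize(sub["sweep_id"].to_numpy())[0]
        key = np.unique(scode * (gid.max() + 1) + gid, return_inverse=True)[1]
    else:
        key = sub["group_id"].to_numpy()
    mask = flag_outliers(key, sub["I_work"].to_numpy(dtype=float),
                         sub["var_prime"].to_numpy(dtype=float),
                         sub["g"].to_numpy(dtype=float), config.outlier_z)
    idx = sub.index[mask]
    table.loc[idx, "flags"] |= rd.OUTLIER
    return table


def _select_groups(table, config: ScalingRunConfig, n_sweeps: int):
    ok = rd.usable(table, exclude_free=True)
    sub = table[ok]
    gid = sub["group_id"].to_numpy()
    mode = config.selection
    if mode == "auto":
        mode = "quasi_random" if n_sweeps >= 2 else "random"
    if mode == "all":
        return np.unique(gid)
    if mode == "quasi_random" and n_sweeps >= 2:
        return select_quasi_random(gid, sub["sweep_id"].to_numpy(),
                                   sub["d"].to_numpy(dtype=float),
                                   config.thresholds, config.seed)
    return select_random(gid, config.thresholds, config.seed)


def _build_target(table, models, selected_groups, reference=None):
    ok = rd.usable(table, exclude_free=True)
    in_sel = np.isin(table["group_id"].to_numpy(), selected_groups)
    rows = ok & in_sel
    n_groups = int(table["group_id"].max()) + 1
    blocks = []
    for sid, model in models.items():
        sub = table[rows & (table["sweep_id"] == sid).to_numpy()]
        if len(sub):
            blocks.append((model, sub))
    return ScalingTarget(blocks, n_groups, reference=reference)


def _reference_array(reference: pd.DataFrame, table: pd.DataFrame,
                     space_group: str, anomalous: bool) -> np.ndarray:
    """Map a merged reference (h k l I) onto the table's group-id space."""
    ref = rd.map_to_asu(reference, space_group, anomalous)
    lookup = {}
    for h, k, l, I in zip(ref["asu_h"], ref["asu_k"], ref["asu_l"], ref["I"]):
        lookup[(int(h), int(k), int(l))] = float(I)
    n_groups = int(table["group_id"].max()) + 1
    out = np.full(n_groups, np.nan)
    firsts = table.drop_duplicates("group_id")
    for h, k, l, gid in zip(firsts["asu_h"], firsts["asu_k"],
                            firsts["asu_l"], firsts["group_id"]):
        out[int(gid)] = lookup.get((int(h), int(k), int(l)), np.nan)
    cover = np.isfinite(out[table["group_id"].to_numpy()]).mean() \
        if len(table) else 0.0
    if cover == 0.0:
        raise ValueError("reference shares no reflections with the data")
    if cover < 0.5:
        warnings.warn(f"reference covers only {100 * cover:.1f}% of the "
                      "observations")
    return out


def _refine_em(table, config) -> ErrorModel | None:
    ok = rd.usable(table, exclude_free=True)
    sub = table[ok]
    em = refine_error_model(sub["group_id"].to_numpy(),
                            sub["I_work"].to_numpy(dtype=float),
                            sub["var_work"].to_numpy(dtype=float),
                            sub["g"].to_numpy(dtype=float))
    # the b*I term acts on the scaled intensity; in raw units this is
    # a^2 (sigma^2 + (b I_raw)^2) since I_raw = g * I_scaled
    table["var_prime"] = apply_error_model(
        em.a, em.b, table["I_work"].to_numpy(dtype=float),
        table["var_work"].to_numpy(dtype=float))
    return em


def scale(table: pd.DataFrame, sweeps: dict, space_group: str,
          config: ScalingRunConfig | None = None,
          reference: pd.DataFrame | None = None,
          initial_models: dict | None = None) -> RunState:
    """Run the scaling algorithm on one or more sweeps.

    ``reference`` (a merged table with columns ``h k l I``) switches to
    reference mode: <I_h> is fixed to the reference values and only the
    input data are updated.
    """
    config = config or ScalingRunConfig()
    table = table.copy()
    table, models = _prepare_table(table, sweeps, space_group, config,
                                   initial_models)
    state = RunState(table, models, sweeps, space_group, config=config)
    n_sweeps = len(models)
    if n_sweeps == 0:
        warnings.warn("no observations: nothing to scale")
        return state
    ref_array = None
    if reference is not None:
        ref_array = _reference_array(reference, table, space_group,
                                     config.anomalous)
    # initial per-sweep outlier rejection for multi-sweep data
    if n_sweeps > 1:
        table = _outlier_round(table, config, per_sweep=True)
    selected = _select_groups(table, config, n_sweeps)
    log.info("selected %d symmetry groups for model optimization",
             len(selected))

    def block(stage: str) -> MinimizerResult | None:
        target = _build_target(table, models, selected, ref_array)
        if target.n_params == 0 or len(target.I) == 0:
            return None
        result = minimize(target, stage=stage, max_iter=config.max_iter,
                          tol=config.tol)
        if ref_array is None:
            anchor_mean_scale(list(models.values()))
        _update_scales(table, models, sweeps)
        state.cycle_log.append({"stage": stage, "phi": result.phi,
                                "iterations": result.n_iter,
                                "status": result.status})
        log.info("%s block: phi=%.6g after %d iterations (%s)", stage,
                 result.phi, result.n_iter, result.status)
        return result

    any_opt = any(m.n_params for m in models.values())
    if any_opt:
        for _ in range(config.n_blocks_before):
            block("quasi_newton")
            table = _outlier_round(table, config)
    # profile/summation combination
    if config.combine:
        choice = optimize_combination(table)
        state.combination = choice
        table = apply_combination(table, choice)
        table["var_prime"] = table["var_work"]
        table = _outlier_round(table, config)
        log.info("intensity choice: %s", choice.summary())
    # error model, then weights updated for subsequent rounds
    if config.error_model:
        state.error_model = _refine_em(table, config)
        table = _outlier_round(table, config)
    if any_opt:
        for _ in range(config.n_blocks_after):
            block("quasi_newton")
            table = _outlier_round(table, config)
        if config.full_matrix:
            result = block("full_matrix")
            state.minimizer = result
            if result is not None and result.covariance is not None:
                full_target = _build_target(
                    table, models, np.unique(table["group_id"]), ref_array)
                g, var_g, var_scaled = propagate_uncertainties(result,
                                                               full_target)
                order = np.concatenate(
                    [t.index.to_numpy() for _, t in full_target.blocks])
                table.loc[order, "var_g"] = var_g
                table.loc[order, "var_scaled"] = var_scaled
    # penultimate step: final error model, variances of all data updated
    if config.error_model:
        state.error_model = _refine_em(table, config)
    table = _outlier_round(table, config)
    state.table = table
    state.report = _make_report(state)
    return state


def _make_report(state: RunState) -> dict:
    table = state.table
    rep: dict = {}
    try:
        mrep = binned_report(table, space_group=state.space_group)
        rep["merging"] = mrep.to_dict()
    except Exception as exc:  # degenerate inputs still produce a report
        rep["merging"] = {"error": str(exc)}
    if state.error_model is not None:
        rep["error_model"] = state.error_model.summary()
    if state.combination is not None:
        rep["combination"] = state.combination.summary()
    rep["models"] = {sid: m.parameter_report()
                     for sid, m in state.models.items()}
    rep["n_outliers"] = int(((table["flags"] & rd.OUTLIER) > 0).sum())
    rep["cycles"] = state.cycle_log
    return rep


def scale_against_reference(table, sweeps, space_group, reference,
                            config: ScalingRunConfig | None = None) -> RunState:
    """Scale the input data against fixed reference <I_h> values."""
    return scale(table, sweeps, space_group, config=config,
                 reference=reference)


def scale_incremental(state: RunState, new_table: pd.DataFrame,
                      new_sweeps: dict,
                      config: ScalingRunConfig | None = None) -> RunState:
    """Add sweeps to an already scaled data set.

    The new sweeps are first scaled quickly against reference <I_h> values
    from the existing data, then all sweeps are jointly re-optimized with
    the previously refined models restored.
    """
    config = config or state.config or ScalingRunConfig()
    if len(new_table) == 0:
        warnings.warn("empty table added: state unchanged")
        return state
    reference = state.merged()
    pre = scale(new_table, new_sweeps, state.space_group, config=config,
                reference=reference[["h", "k", "l", "I"]])
    combined = pd.concat([state.table, pre.table], ignore_index=True)
    keep_cols = [c for c in combined.columns
                 if c in rd.REQUIRED_COLUMNS + rd.OUTPUT_COLUMNS
                 or c in ("g_true", "I_true", "injected_outlier")]
    combined = combined[keep_cols].copy()
    sweeps = dict(state.sweeps)
    sweeps.update(new_sweeps)
    models = dict(state.models)
    models.update(pre.models)
    return scale(combined, sweeps, state.space_group, config=config,
                 initial_models=models)


def _partition_labels(table, sweeps, config: ScalingRunConfig) -> np.ndarray:
    if config.filter_partition == "sweep":
        return table["sweep_id"].to_numpy()
    labels = np.empty(len(table), dtype=object)
    for sid, meta in sweeps.items():
        mask = (table["sweep_id"] == sid).to_numpy()
        width = config.filter_image_group * meta.image_width
        grp = np.floor((table["phi"].to_numpy(dtype=float)[mask]
                        - meta.phi_start) / width).astype(int)
        labels[mask] = [f"{sid}:{g}" for g in grp]
    return labels


def scale_and_filter(table, sweeps, space_group,
                     config: ScalingRunConfig | None = None) -> RunState:
    """Successive cycles of scaling and deltaCC1/2-based exclusion.

    Each cycle scales without the full-matrix stage, computes deltaCC1/2
    per partition subset (whole sweeps or image groups) and excludes
    subsets more than ``filter_k_sd`` standard deviations below the mean,
    subject to the completeness and total-removal guards.  A final
    full-matrix scaling pass follows.  The exclusion history is stored in
    ``state.report["filter_history"]``.
    """
    config = config or ScalingRunConfig()
    work = table.copy()
    n_total = len(work)
    history = []
    removed = 0
    cheap = replace(config, full_matrix=False)
    state = None
    for cycle in range(1, config.filter_max_cycles + 1):
        state = scale(work, sweeps, space_group, config=cheap)
        t = state.table
        ok = rd.usable(t)
        if ok.sum() == 0:
            raise RuntimeError("all observations excluded during filtering")
        sub = t[ok]
        labels = _partition_labels(sub, sweeps, config)
        if len(pd.unique(labels)) < 2:
            break
        res = delta_cc_half(sub["group_id"].to_numpy(),
                            sub["I_work"].to_numpy(dtype=float),
                            sub["var_prime"].to_numpy(dtype=float),
                            sub["g"].to_numpy(dtype=float),
                            labels, d=sub["d"].to_numpy(dtype=float),
                            k_sd=config.filter_k_sd)
        entry = {"cycle": cycle, "cc_half": res.cc_overall,
                 "mean": res.mean, "sd": res.sd,
                 "excluded": [str(s) for s in res.excluded]}
        allowed = []
        budget = config.filter_max_percent_removed / 100.0 * n_total
        all_labels = _partition_labels(t, sweeps, config)
        for sid in res.excluded:
            size = int((all_labels == sid).sum())
            if removed + size > budget:
                continue
            allowed.append(sid)
            removed += size
        entry["applied"] = [str(s) for s in allowed]
        history.append(entry)
        if not allowed:
            break
        excl_mask = np.isin(all_labels, allowed)
        t = t.copy()
        t.loc[t.index[excl_mask], "flags"] |= rd.EXCLUDED
        work = t
        # completeness guard
        comp = state.report.get("merging", {}).get("overall", {}) \
            .get("completeness")
        if comp is not None and comp < config.filter_min_completeness:
            break
    state = scale(work, sweeps, space_group, config=config)
    state.report["filter_history"] = history
    state.report["observations_removed"] = removed
    return state


def cross_validate(table, sweeps, space_group,
                   config: ScalingRunConfig | None = None,
                   n_folds: int | None = None) -> dict:
    """n-fold free-set validation of the scaling model.

    For each fold, whole symmetry groups forming ``free_fraction`` of the
    data are withheld from model optimization; models are applied to all
    observations and outlier rejection runs on both sets.  Work and free
    Rmeas and CC1/2 are reported per fold and averaged.
    """
    config = config or ScalingRunConfig()
    prepped = rd.map_to_asu(table.copy(), space_group, config.anomalous)
    split = split_free_set(prepped["group_id"].to_numpy(),
                           fraction=config.free_fraction, n_folds=n_folds,
                           seed=config.seed)
    folds = []
    for fold in range(split.n_folds):
        t = prepped.copy()
        free = split.free_mask(t["group_id"].to_numpy(), fold)
        t.loc[t.index[free], "flags"] |= rd.FREE_SET
        state = scale(t, sweeps, space_group, config=config)
        st = state.table
        ok = rd.usable(st)
        isfree = (st["flags"].to_numpy() & rd.FREE_SET) > 0
        metrics = {}
        for name, m in (("work", ok & ~isfree), ("free", ok & isfree)):
            sub = st[m]
            gid = sub["group_id"].to_numpy()
            _, rmeas, _ = r_metrics(gid, sub["I_work"].to_numpy(dtype=float),
                                    sub["g"].to_numpy(dtype=float))
            nb = resolution_bins_of_groups(
                np.unique(gid, return_inverse=True)[1],
                sub["d"].to_numpy(dtype=float), 10)
            cc, _ = cc_half_sigma_tau(
                np.unique(gid, return_inverse=True)[1],
                sub["I_work"].to_numpy(dtype=float),
                sub["var_prime"].to_numpy(dtype=float),
                sub["g"].to_numpy(dtype=float), nb)
            metrics[f"{name}_r_meas"] = rmeas
            metrics[f"{name}_cc_half"] = cc
        folds.append(metrics)
    mean = {key: float(np.mean([f[key] for f in folds
                                if f[key] is not None]))
            for key in folds[0]}
    return {"folds": folds, "mean": mean}
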