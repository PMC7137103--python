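"""Merging, data-quality statistics and the delta-CC1/2 filter statistic.

Implements the standard agreement metrics among symmetry equivalents
(Rmerge, Rmeas, Rpim, with the multiplicity corrections sqrt(n/(n-1)) and
sqrt(1/(n-1)) respectively; the group mean is the unweighted mean of the
corrected intensities), the sigma-tau estimator of the half-data-set
correlation CC1/2,

    CC1/2 = (sigma_y^2 - sigma_e^2/2) / (sigma_y^2 + sigma_e^2/2)

where per resolution bin sigma_y^2 is the variance of the merged
intensities across unique reflections and sigma_e^2 the average per-group
error variance of a half-data-set mean (unbiased within-group variance
divided by n/2), and the per-subset statistic

    deltaCC1/2^i = CC1/2 - CC1/2(-i)

whose strongly negative values mark subsets that systematically disagree
with the rest of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reflection_data as rd


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge(group_id, I, var, g, asu_hkl=None, n_groups=None) -> pd.DataFrame:
    """Inverse-variance weighted mean of corrected intensities per group.

    Returns a table with columns ``I sigI n_obs`` (plus ``h k l`` if
    ``asu_hkl`` is given), one row per observed group.
    """
    group_id = np.asarray(group_id)
    if n_groups is None:
        n_groups = int(group_id.max()) + 1 if len(group_id) else 0
    g = np.asarray(g, dtype=float)
    I_sc = np.asarray(I, dtype=float) / g
    w = g ** 2 / np.asarray(var, dtype=float)
    n = np.bincount(group_id, minlength=n_groups)
    sw = np.bincount(group_id, weights=w, minlength=n_groups)
    swi = np.bincount(group_id, weights=w * I_sc, minlength=n_groups)
    seen = n > 0
    out = pd.DataFrame({
        "group_id": np.flatnonzero(seen),
        "I": swi[seen] / sw[seen],
        "sigI": 1.0 / np.sqrt(sw[seen]),
        "n_obs": n[seen]})
    if asu_hkl is not None:
        hkl = np.asarray(asu_hkl)
        first = np.full(n_groups, -1, dtype=np.int64)
        first[group_id[::-1]] = np.arange(len(group_id))[::-1]
        out[["h", "k", "l"]] = hkl[first[seen]]
    return out


# ---------------------------------------------------------------------------
# R metrics
# ---------------------------------------------------------------------------

def r_metrics(group_id, I, g):
    """(Rmerge, Rmeas, Rpim) over groups with multiplicity >= 2.

    The group mean is the unweighted mean of corrected intensities.  Returns
    (None, None, None) if no group has n >= 2.
    """
    group_id = np.asarray(group_id)
    n_groups = int(group_id.max()) + 1 if len(group_id) else 0
    I_sc = np.asarray(I, dtype=float) / np.asarray(g, dtype=float)
    n = np.bincount(group_id, minlength=n_groups)
    tot = np.bincount(group_id, weights=I_sc, minlength=n_groups)
    contributes = (n >= 2)[group_id]
    if not contributes.any():
        return None, None, None
    mean = np.where(n > 0, tot / np.maximum(n, 1), 0.0)
    dev = np.abs(I_sc - mean[group_id])[contributes]
    nn = n[group_id][contributes].astype(float)
    denom = I_sc[contributes].sum()
    rmerge = dev.sum() / denom
    rmeas = (dev * np.sqrt(nn / (nn - 1.0))).sum() / denom
    rpim = (dev * np.sqrt(1.0 / (nn - 1.0))).sum() / denom
    return float(rmerge), float(rmeas), float(rpim)


# ---------------------------------------------------------------------------
# sigma-tau CC1/2
# ---------------------------------------------------------------------------

def _sigma_tau_bin(group_id, I_sc, w, groups_in_bin, n_groups):
    """(sigma_y^2, sigma_e^2, n_groups) for one resolution bin."""
    n = np.bincount(group_id, minlength=n_groups)
    sw = np.bincount(group_id, weights=w, minlength=n_groups)
    swi = np.bincount(group_id, weights=w * I_sc, minlength=n_groups)
    si = np.bincount(group_id, weights=I_sc, minlength=n_groups)
    si2 = np.bincount(group_id, weights=I_sc ** 2, minlength=n_groups)
    sel = np.zeros(len(n), dtype=bool)
    sel[groups_in_bin] = True
    sel &= n >= 2
    if sel.sum() < 2:
        return None
    merged = swi[sel] / sw[sel]
    sigma_y2 = float(np.var(merged, ddof=1))
    nn = n[sel].astype(float)
    within = (si2[sel] - si[sel] ** 2 / nn) / (nn - 1.0)
    sigma_e2 = float(np.mean(within / (nn / 2.0)))
    return sigma_y2, sigma_e2, int(sel.sum())


def cc_half_sigma_tau(group_id, I, var, g, bin_of_group=None):
    """sigma-tau CC1/2 per resolution bin and overall.

    ``bin_of_group`` assigns each group to a resolution bin (a single bin if
    omitted).  Returns (overall, per-bin list); the overall value is the
    group-count weighted average over non-degenerate bins.
    """
    group_id = np.asarray(group_id)
    if len(group_id) == 0:
        return None, []
    n_groups = int(group_id.max()) + 1
    g = np.asarray(g, dtype=float)
    I_sc = np.asarray(I, dtype=float) / g
    w = g ** 2 / np.asarray(var, dtype=float)
    if bin_of_group is None:
        bin_of_group = np.zeros(n_groups, dtype=int)
    bin_of_group = np.asarray(bin_of_group)
    n_groups = max(n_groups, len(bin_of_group))
    per_bin = []
    weights = []
    for b in range(int(bin_of_group.max()) + 1):
        groups = np.flatnonzero(bin_of_group == b)
        res = _sigma_tau_bin(group_id, I_sc, w, groups, n_groups)
        if res is None:
            per_bin.append(None)
            continue
        sy2, se2, ng = res
        denom = sy2 + 0.5 * se2
        cc = (sy2 - 0.5 * se2) / denom if denom > 0 else 0.0
        per_bin.append(float(cc))
        weights.append((cc, ng))
    if not weights:
        return None, per_bin
    overall = sum(c * n for c, n in weights) / sum(n for _, n in weights)
    return float(overall), per_bin


def equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign values to equal-count bins (0 = lowest value)."""
    n = len(values)
    n_bins = max(1, min(n_bins, n))
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def resolution_bins_of_groups(group_id, d, n_bins: int):
    """Equal-count resolution bins on unique groups (by mean 1/d^2).

    Bin 0 is the lowest resolution (largest d).  Returns the per-group bin
    index.
    """
    group_id = np.asarray(group_id)
    n_groups = int(group_id.max()) + 1 if len(group_id) else 0
    s = 1.0 / np.asarray(d, dtype=float) ** 2
    n = np.bincount(group_id, minlength=n_groups)
    mean_s = np.bincount(group_id, weights=s, minlength=n_groups) \
        / np.maximum(n, 1)
    seen = np.flatnonzero(n > 0)
    bins = np.zeros(n_groups, dtype=int)
    bins[seen] = equal_count_bins(mean_s[seen], n_bins)
    return bins


# ---------------------------------------------------------------------------
# delta CC1/2
# ---------------------------------------------------------------------------

@dataclass
class DeltaCCResult:
    subset_ids: list
    delta_cc: np.ndarray
    cc_overall: float
    mean: float
    sd: float
    excluded: list

    def summary(self) -> dict:
        return {"cc_half": self.cc_overall,
                "delta_cc_half": {str(s): float(v) for s, v in
                                  zip(self.subset_ids, self.delta_cc)},
                "mean": self.mean, "sd": self.sd,
                "excluded": [str(s) for s in self.excluded]}


def delta_cc_half(group_id, I, var, g, subset, d=None, n_bins: int = 10,
                  k_sd: float = 4.0) -> DeltaCCResult:
    """Per-subset deltaCC1/2 with the mean - k*sd exclusion rule.

    ``subset`` labels each observation with its partition element (a sweep
    id or an image-group id).  For each subset i the sigma-tau CC1/2 is
    recomputed without subset i's observations (bins held fixed);
    deltaCC1/2^i = CC1/2 - CC1/2(-i).  Subsets with
    deltaCC1/2^i < mean - k_sd * sd are listed for exclusion.
    """
    group_id = np.asarray(group_id)
    subset = np.asarray(subset)
    n_groups = int(group_id.max()) + 1 if len(group_id) else 0
    if d is not None and n_bins > 1:
        bins = resolution_bins_of_groups(group_id, d, n_bins)
    else:
        bins = np.zeros(n_groups, dtype=int)
    cc_all, _ = cc_half_sigma_tau(group_id, I, var, g, bins)
    ids = list(pd.unique(subset))
    deltas = np.empty(len(ids))
    for j, sid in enumerate(ids):
        keep = subset != sid
        cc_i, _ = cc_half_sigma_tau(group_id[keep], np.asarray(I)[keep],
                                    np.asarray(var)[keep],
                                    np.asarray(g)[keep], bins)
        deltas[j] = cc_all - cc_i if cc_i is not None else 0.0
    mean, sd = float(np.mean(deltas)), float(np.std(deltas))
    # the cut for subset i is evaluated against the distribution of the
    # *other* subsets: a strongly discordant subset would otherwise inflate
    # the spread enough to hide itself when the partition is small
    excluded = []
    for j, sid in enumerate(ids):
        others = np.delete(deltas, j)
        sd_o = float(np.std(others))
        if sd_o > 0 and deltas[j] < float(np.mean(others)) - k_sd * sd_o:
            excluded.append(sid)
    return DeltaCCResult(ids, deltas, float(cc_all), mean, sd, excluded)


# ---------------------------------------------------------------------------
# binned report
# ---------------------------------------------------------------------------

@dataclass
class MergingReport:
    overall: dict
    bins: list = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"overall": self.overall, "bins": self.bins,
                "notes": self.notes}


def binned_report(table, n_bins: int = 20, cell=None,
                  space_group: str | None = None, d_min: float | None = None,
                  anomalous: bool = False) -> MergingReport:
    """Resolution-binned and overall merging statistics.

    Statistics use non-outlier, non-excluded observations and the current
    inverse scales.  Completeness (observed unique / theoretically possible
    unique ASU reflections to d_min) requires ``cell`` and ``space_group``;
    it is omitted otherwise.  The merged mean is inverse-variance weighted;
    R metrics use the unweighted group mean.
    """
    ok = rd.usable(table)
    sub = table[ok]
    gid_raw = sub["group_id"].to_numpy()
    _, gid = np.unique(gid_raw, return_inverse=True)
    I = sub["I_work"].to_numpy(dtype=float) if "I_work" in sub else \
        sub["I_prof"].to_numpy(dtype=float)
    var = sub["var_prime"].to_numpy(dtype=float) if "var_prime" in sub else \
        sub["var_prof"].to_numpy(dtype=float)
    g = sub["g"].to_numpy(dtype=float)
    d = sub["d"].to_numpy(dtype=float)
    if d_min is None:
        d_min = float(d.min()) if len(d) else 0.0
    n_groups = int(gid.max()) + 1 if len(gid) else 0
    eff_bins = max(1, min(n_bins, n_groups // 2 or 1))
    gbins = resolution_bins_of_groups(gid, d, eff_bins)
    # theoretical unique counts per bin
    theo_d = None
    if cell is not None and space_group is not None and n_groups:
        theo = rd.unique_reflections(cell, space_group, d_min, anomalous)
        theo_d = theo["d"].to_numpy()
    # per-group mean d for bin edges
    nper = np.bincount(gid, minlength=n_groups)
    mean_d = np.bincount(gid, weights=d, minlength=n_groups) / \
        np.maximum(nper, 1)
    cc_overall, cc_bins = cc_half_sigma_tau(gid, I, var, g, gbins)
    rows = []
    for b in range(eff_bins):
        gsel = gbins == b
        osel = gsel[gid]
        if not osel.any():
            continue
        d_lo, d_hi = float(d[osel].min()), float(d[osel].max())
        rmerge, rmeas, rpim = r_metrics(gid[osel], I[osel], g[osel])
        m = merge(gid[osel], I[osel], var[osel], g[osel])
        ios = float(np.mean(m["I"] / m["sigI"]))
        row = {"d_max": d_hi, "d_min": d_lo,
               "n_obs": int(osel.sum()), "n_unique": int(gsel.sum()),
               "multiplicity": float(osel.sum() / gsel.sum()),
               "r_merge": rmerge, "r_meas": rmeas, "r_pim": rpim,
               "cc_half": cc_bins[b], "i_over_sigma": ios}
        if theo_d is not None:
            hi_edge = d_hi if b > 0 else np.inf
            lo_edge = d_lo if b < eff_bins - 1 else d_min
            n_theo = int(np.sum((theo_d <= hi_edge) & (theo_d >= lo_edge)))
            row["completeness"] = 100.0 * min(gsel.sum() / n_theo, 1.0) \
                if n_theo else None
        rows.append(row)
    rmerge, rmeas, rpim = r_metrics(gid, I, g)
    m = merge(gid, I, var, g)
    overall = {"n_obs": int(len(gid)), "n_unique": n_groups,
               "multiplicity": float(len(gid) / n_groups) if n_groups else 0.0,
               "d_max": float(d.max()) if len(d) else None,
               "d_min": float(d.min()) if len(d) else None,
               "r_merge": rmerge, "r_meas": rmeas, "r_pim": rpim,
               "cc_half": cc_overall,
               "i_over_sigma": float(np.mean(m["I"] / m["sigI"]))
               if len(m) else None}
    if theo_d is not None:
        n_theo = int(np.sum(theo_d >= d_min))
        overall["completeness"] = 100.0 * min(n_groups / n_theo, 1.0) \
            if n_theo else None
    notes = {"r_metric_mean": "unweighted", "merged_mean": "inverse-variance "
             "weighted", "cc_half": "sigma-tau, group-count weighted over "
             "resolution bins"}
    return MergingReport(overall, rows, notes)
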