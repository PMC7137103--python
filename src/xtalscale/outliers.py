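"""Outlier rejection on symmetry groups and profile/summation combination.

Outliers are detected by the normalized deviation of each observation from
the inverse-variance weighted mean of its group of symmetry equivalents,
excluding the test reflection; observations beyond ``z_max`` (default 6
sigma) are rejected worst-first within each group until no member exceeds
the threshold.  Size-2 groups use a mutual-difference test that flags both
members (the deviant one cannot be attributed); singletons are never
flagged.

Profile and summation intensity estimates can be blended with a smooth
crossover in the raw summation intensity:

    w = 1 / (1 + (I_sum_raw / I_mid)^3),  I_comb = w I_prof + (1 - w) I_sum

so ``I_mid = inf`` reduces to pure profile and ``I_mid -> 0`` to pure
summation.  ``optimize_combination`` tests the pure modes plus a
logarithmic grid of crossover values and keeps the choice with the lowest
Rmeas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .merging import r_metrics


def _loo_stats(I_sc, w):
    """Leave-one-out weighted mean and its variance within one group."""
    sw = w.sum()
    swi = (w * I_sc).sum()
    denom = sw - w
    mean = (swi - w * I_sc) / denom
    var_mean = 1.0 / denom
    return mean, var_mean


def flag_outliers(group_id: np.ndarray, I: np.ndarray, var: np.ndarray,
                  g: np.ndarray, z_max: float = 6.0,
                  test_size2: bool = True) -> np.ndarray:
    """Boolean outlier mask over all observations.

    ``I``/``var`` are unscaled working intensities/variances; the test is
    performed on corrected intensities I/g with sigma/g uncertainties.
    """
    group_id = np.asarray(group_id)
    I_sc = np.asarray(I, dtype=float) / g
    var_sc = np.asarray(var, dtype=float) / np.asarray(g, dtype=float) ** 2
    w = 1.0 / var_sc
    n = len(group_id)
    mask = np.zeros(n, dtype=bool)
    order = np.argsort(group_id, kind="stable")
    bounds = np.searchsorted(group_id[order],
                             np.arange(group_id.max() + 2 if n else 1))
    for gi in range(len(bounds) - 1):
        idx = order[bounds[gi]:bounds[gi + 1]]
        if len(idx) < 2:
            continue
        if len(idx) == 2:
            if test_size2:
                i, j = idx
                z = abs(I_sc[i] - I_sc[j]) / np.sqrt(var_sc[i] + var_sc[j])
                if z > z_max:
                    mask[i] = mask[j] = True
            continue
        live = list(idx)
        while len(live) >= 3:
            sub = np.array(live)
            mean, var_mean = _loo_stats(I_sc[sub], w[sub])
            z = np.abs(I_sc[sub] - mean) / np.sqrt(var_sc[sub] + var_mean)
            worst = int(np.argmax(z))
            if z[worst] > z_max:
                mask[sub[worst]] = True
                live.pop(worst)
            else:
                break
    return mask


@dataclass
class CombinationChoice:
    mode: str                 # "profile" | "summation" | "combined"
    I_mid: float | None       # crossover value for "combined"
    rmeas: float | None
    tested: dict | None = None

    def summary(self) -> dict:
        return {"mode": self.mode,
                "I_mid": None if self.I_mid is None else float(self.I_mid),
                "rmeas": None if self.rmeas is None else float(self.rmeas)}


def combine_intensities(I_prof, var_prof, I_sum, var_sum, I_mid: float):
    """Blend profile and summation estimates at crossover ``I_mid``.

    The crossover argument is the raw (unscaled) summation intensity.
    Variances combine with the same weights assuming independent errors:
    var = w^2 var_prof + (1-w)^2 var_sum.
    """
    I_prof = np.asarray(I_prof, dtype=float)
    I_sum = np.asarray(I_sum, dtype=float)
    if np.isinf(I_mid):
        return I_prof.copy(), np.asarray(var_prof, dtype=float).copy()
    if I_mid <= 0:
        return I_sum.copy(), np.asarray(var_sum, dtype=float).copy()
    raw = np.maximum(I_sum, 0.0)
    w = 1.0 / (1.0 + (raw / I_mid) ** 3)
    I_comb = w * I_prof + (1.0 - w) * I_sum
    var_comb = w ** 2 * np.asarray(var_prof, dtype=float) \
        + (1.0 - w) ** 2 * np.asarray(var_sum, dtype=float)
    return I_comb, var_comb


def optimize_combination(table, n_grid: int = 8) -> CombinationChoice:
    """Pick the intensity choice (profile/summation/blend) minimizing Rmeas.

    Evaluates Rmeas on the currently scaled data for pure profile, pure
    summation and ``n_grid`` logarithmically spaced I_mid values spanning
    [Imin + 1, Imax] of the raw summation intensities.  Ties break toward
    profile.  Requires multiplicity >= 2 somewhere; otherwise profile is
    returned with a warning.
    """
    gid = table["group_id"].to_numpy()
    g = table["g"].to_numpy(dtype=float)
    from .reflection_data import usable
    ok = usable(table)
    sizes = np.bincount(gid[ok]) if ok.any() else np.zeros(1)
    if not np.any(sizes >= 2):
        warnings.warn("no multiplicity >= 2: keeping profile intensities")
        return CombinationChoice("profile", None, None)
    I_prof = table["I_prof"].to_numpy(dtype=float)
    var_prof = table["var_prof"].to_numpy(dtype=float)
    I_sum = table["I_sum"].to_numpy(dtype=float)
    var_sum = table["var_sum"].to_numpy(dtype=float)
    raw = I_sum[ok]
    lo = max(float(raw.min()), 0.0) + 1.0
    hi = max(float(raw.max()), lo * 10.0)
    grid = np.geomspace(lo, hi, n_grid)
    candidates: list[tuple[str, float | None]] = [("profile", None),
                                                 ("summation", None)]
    candidates += [("combined", float(m)) for m in grid]
    tested = {}
    best = None
    for mode, imid in candidates:
        if mode == "profile":
            I, _ = I_prof, var_prof
        elif mode == "summation":
            I = I_sum
        else:
            I, _ = combine_intensities(I_prof, var_prof, I_sum, var_sum, imid)
        rmerge, rmeas, rpim = r_metrics(gid[ok], I[ok], g[ok])
        key = mode if imid is None else f"I_mid={imid:.4g}"
        tested[key] = rmeas
        if rmeas is not None and (best is None or rmeas < best[2] - 1e-12):
            best = (mode, imid, rmeas)
    if best is None:
        return CombinationChoice("profile", None, None, tested)
    return CombinationChoice(best[0], best[1], best[2], tested)


def apply_combination(table, choice: CombinationChoice):
    """Set the working intensity columns per the combination choice."""
    table = table.copy()
    if choice.mode == "profile":
        table["I_work"] = table["I_prof"]
        table["var_work"] = table["var_prof"]
    elif choice.mode == "summation":
        table["I_work"] = table["I_sum"]
        table["var_work"] = table["var_sum"]
    else:
        I, v = combine_intensities(
            table["I_prof"], table["var_prof"], table["I_sum"],
            table["var_sum"], choice.I_mid)
        table["I_work"] = I
        table["var_work"] = v
    return table
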