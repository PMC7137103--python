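"""Reflection-subset selection for model optimization and free-set splits.

Model optimization is heavily overdetermined, so a subset of the symmetry
groups is used.  Two selection rules are provided:

* random — uniform sampling of groups without replacement until at least
  ``min_groups`` groups *and* ``min_reflections`` observations are selected
  (defaults 2000 and 50 000, which keep the observation-to-parameter ratio
  high while bounding runtime on large data sets);
* quasi-random — for multi-sweep data, a greedy inter-sweep connectivity
  pass run per resolution bin (pick the group spanning the most sweeps
  among those covering the currently least-populated sweep), followed by
  random augmentation per sweep and across sweeps up to the thresholds.

Free-set splitting deals whole symmetry groups into ``round(1/fraction)``
folds so all symmetry equivalents of a reflection share a fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .merging import resolution_bins_of_groups


@dataclass
class SelectionThresholds:
    min_groups: int = 2000
    min_reflections: int = 50000
    n_resolution_bins: int = 10

    def __post_init__(self):
        if self.min_groups <= 0 or self.min_reflections <= 0:
            raise ValueError("selection thresholds must be positive")


def select_random(group_id: np.ndarray, thresholds: SelectionThresholds,
                  seed: int, candidates: np.ndarray | None = None
                  ) -> np.ndarray:
    """Randomly chosen group ids meeting both thresholds (or all groups)."""
    group_id = np.asarray(group_id)
    n_groups = int(group_id.max()) + 1 if len(group_id) else 0
    sizes = np.bincount(group_id, minlength=n_groups)
    pool = np.flatnonzero(sizes > 0) if candidates is None \
        else np.asarray(candidates)
    rng = np.random.default_rng(seed)
    order = rng.permutation(pool)
    csum = np.cumsum(sizes[order])
    count = np.arange(1, len(order) + 1)
    enough = (count >= thresholds.min_groups) & \
        (csum >= thresholds.min_reflections)
    if not enough.any():
        return np.sort(order)
    stop = int(np.argmax(enough)) + 1
    return np.sort(order[:stop])


def _sweep_codes(sweep_ids) -> tuple[np.ndarray, list]:
    uniq = list(dict.fromkeys(sweep_ids))
    code = {s: i for i, s in enumerate(uniq)}
    return np.array([code[s] for s in sweep_ids]), uniq


def select_quasi_random(group_id: np.ndarray, sweep_id, d: np.ndarray,
                        thresholds: SelectionThresholds, seed: int
                        ) -> np.ndarray:
    """Quasi-random inter-sweep connected selection of group ids.

    Run per resolution bin: repeatedly pick, among groups with an
    observation in the currently least-populated sweep, the group spanning
    the most sweeps (ties: larger group, then lower group id), until every
    sweep reaches its per-bin share of the per-sweep target
    (min_reflections / n_sweeps) or runs out.  Afterwards random groups are
    added per sweep and across sweeps up to the global thresholds.
    """
    group_id = np.asarray(group_id)
    sweep, sweep_names = _sweep_codes(np.asarray(sweep_id))
    n_sweeps = len(sweep_names)
    if n_sweeps < 2:
        raise ValueError("quasi-random selection needs >= 2 sweeps")
    n_groups = int(group_id.max()) + 1
    bins = resolution_bins_of_groups(group_id, d,
                                     thresholds.n_resolution_bins)
    per_sweep_target = int(np.ceil(thresholds.min_reflections / n_sweeps))
    per_bin_target = int(np.ceil(per_sweep_target
                                 / max(bins.max() + 1, 1)))
    counts = np.zeros((n_groups, n_sweeps), dtype=np.int64)
    np.add.at(counts, (group_id, sweep), 1)
    selected: list[int] = []
    selected_mask = np.zeros(n_groups, dtype=bool)
    sweep_tally = np.zeros(n_sweeps, dtype=np.int64)
    for b in range(bins.max() + 1):
        gids = np.flatnonzero((bins == b) & (counts.sum(axis=1) > 0))
        if len(gids) == 0:
            continue
        sub = counts[gids]                     # (n_gids, n_sweeps)
        span = (sub > 0).sum(axis=1)
        size = sub.sum(axis=1)
        avail = np.ones(len(gids), dtype=bool)
        bin_tally = np.zeros(n_sweeps, dtype=np.int64)
        sweep_has = sub.sum(axis=0) > 0
        while True:
            open_sweeps = sweep_has & (bin_tally < per_bin_target)
            if not open_sweeps.any() or not avail.any():
                break
            # least-populated open sweep that still has available groups
            cand_any = (sub[avail][:, open_sweeps] > 0).any(axis=0)
            if not cand_any.any():
                break
            open_idx = np.flatnonzero(open_sweeps)[cand_any]
            least = open_idx[np.argmin(bin_tally[open_idx])]
            cand = np.flatnonzero(avail & (sub[:, least] > 0))
            # greedy pick: max sweep span, then larger group, then lowest id
            key = (span[cand] * 10 ** 9 + size[cand]) * 10 ** 9 \
                - gids[cand]
            pick = cand[np.argmax(key)]
            avail[pick] = False
            bin_tally += sub[pick]
            gid = int(gids[pick])
            selected.append(gid)
            selected_mask[gid] = True
        sweep_tally += bin_tally
    # augmentation: random per-sweep selections, then across sweeps
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    sizes = counts.sum(axis=1)
    for s in range(n_sweeps):
        deficit = per_sweep_target - int(sweep_tally[s])
        if deficit <= 0:
            continue
        pool = np.flatnonzero((counts[:, s] > 0) & ~selected_mask)
        order = rng.permutation(pool)
        got = 0
        for gid in order:
            if got >= deficit:
                break
            selected.append(int(gid))
            selected_mask[gid] = True
            sweep_tally += counts[gid]
            got += counts[gid, s]
    total_refl = int(sizes[selected_mask].sum())
    if len(selected) < thresholds.min_groups \
            or total_refl < thresholds.min_reflections:
        pool = np.flatnonzero((sizes > 0) & ~selected_mask)
        order = rng.permutation(pool)
        for gid in order:
            if len(selected) >= thresholds.min_groups \
                    and total_refl >= thresholds.min_reflections:
                break
            selected.append(int(gid))
            selected_mask[gid] = True
            total_refl += int(sizes[gid])
    return np.sort(np.array(selected, dtype=np.int64))


@dataclass
class FreeSetSplit:
    fold_of_group: np.ndarray   # fold index per group id (-1: unobserved)
    n_folds: int

    def free_groups(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_group == fold)

    def free_mask(self, group_id: np.ndarray, fold: int) -> np.ndarray:
        return self.fold_of_group[np.asarray(group_id)] == fold


def split_free_set(group_id: np.ndarray, fraction: float = 0.1,
                   n_folds: int | None = None, seed: int = 0) -> FreeSetSplit:
    """Deal whole symmetry groups into folds for free-set validation.

    ``n_folds`` defaults to round(1/fraction); fold sizes differ by at most
    one group.  Fold k is the free set of repeat k.
    """
    group_id = np.asarray(group_id)
    n_groups = int(group_id.max()) + 1 if len(group_id) else 0
    sizes = np.bincount(group_id, minlength=n_groups)
    observed = np.flatnonzero(sizes > 0)
    if n_folds is None:
        n_folds = max(int(round(1.0 / fraction)), 1)
    if len(observed) * max(fraction, 1.0 / n_folds) < 1:
        raise ValueError("free fraction selects less than one group")
    rng = np.random.default_rng(seed)
    order = rng.permutation(observed)
    fold = np.full(n_groups, -1, dtype=int)
    fold[order] = np.arange(len(order)) % n_folds
    return FreeSetSplit(fold, n_folds)
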