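"""Data model and I/O for unmerged reflection observations.

The central container is a plain :class:`pandas.DataFrame` with one row per
integrated observation.  Required columns are::

    h k l sweep_id I_prof var_prof I_sum var_sum phi d x_det y_det
    s0cx s0cy s0cz s1cx s1cy s1cz

where ``phi`` is the rotation angle (degrees) of the reflection centroid,
``d`` the resolution in Angstrom, ``x_det``/``y_det`` the detector position
normalized to [0, 1], and ``s0c``/``s1c`` the reverse incident beam and the
scattered beam as unit vectors in the crystal frame.  Scaling adds derived
columns: the canonical symmetry-unique index (``asu_h asu_k asu_l``), an
integer ``group_id`` shared by symmetry equivalents, the inverse scale ``g``
and its variance ``var_g``, working intensity columns, and a ``flags``
bitmask.

The native on-disk format is a TSV file with ``#``-prefixed metadata lines
carrying the space group and the per-sweep rotation ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

# flag bits
OUTLIER = 1
EXCLUDED = 2
FREE_SET = 4
BAD_FOR_SCALING = 8

GEOMETRY_COLUMNS = ["s0cx", "s0cy", "s0cz", "s1cx", "s1cy", "s1cz"]
REQUIRED_COLUMNS = (
    ["h", "k", "l", "sweep_id", "I_prof", "var_prof", "I_sum", "var_sum",
     "phi", "d", "x_det", "y_det"] + GEOMETRY_COLUMNS
)
#: columns preserved by the unmerged writer in addition to the required ones
OUTPUT_COLUMNS = ["g", "var_g", "flags"]


class FormatError(ValueError):
    """Raised when an input file does not conform to the documented dialect."""


@dataclass
class SweepMetadata:
    """Rotation-range bookkeeping for one sweep.

    ``n_images * image_width`` must equal ``phi_end - phi_start``; ``t`` (the
    time proxy used by the decay component) assumes constant rotation per
    image within the sweep.
    """

    sweep_id: str
    phi_start: float
    phi_end: float
    image_width: float = 1.0

    def __post_init__(self) -> None:
        if not self.phi_end > self.phi_start:
            raise ValueError("phi_end must exceed phi_start")
        if self.image_width <= 0:
            raise ValueError("image_width must be positive")

    @property
    def width(self) -> float:
        return self.phi_end - self.phi_start

    @property
    def n_images(self) -> int:
        n = self.width / self.image_width
        if abs(n - round(n)) > 1e-6:
            raise ValueError("sweep width is not an integer number of images")
        return int(round(n))


def new_table(n: int = 0) -> pd.DataFrame:
    """Empty reflection table with all required columns."""
    data: dict[str, np.ndarray] = {}
    for c in ["h", "k", "l"]:
        data[c] = np.zeros(n, dtype=np.int32)
    data["sweep_id"] = np.array([""] * n, dtype=object)
    for c in REQUIRED_COLUMNS[4:]:
        data[c] = np.zeros(n, dtype=float)
    df = pd.DataFrame(data)
    return _init_derived(df)


def _init_derived(df: pd.DataFrame) -> pd.DataFrame:
    df["g"] = np.ones(len(df))
    df["var_g"] = np.zeros(len(df))
    if "flags" not in df.columns:
        df["flags"] = np.zeros(len(df), dtype=np.int64)
    df["flags"] = df["flags"].astype(np.int64)
    return df


def usable(df: pd.DataFrame, exclude_free: bool = False) -> np.ndarray:
    """Boolean mask of rows usable for scaling-model optimization."""
    bad = OUTLIER | EXCLUDED | BAD_FOR_SCALING
    if exclude_free:
        bad |= FREE_SET
    return (df["flags"].to_numpy() & bad) == 0


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_reflection_table(path, metadata: dict[str, SweepMetadata] | None = None):
    """Read the native unmerged TSV format.

    Returns ``(table, space_group, sweeps)``.  ``#``-metadata lines take the
    form ``# space_group: <symbol>`` and
    ``# sweep: <id> phi_start=<f> phi_end=<f> image_width=<f>``.  Rows with
    non-finite or non-positive variances are kept but flagged
    ``BAD_FOR_SCALING``.
    """
    space_group = None
    sweeps: dict[str, SweepMetadata] = dict(metadata or {})
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("space_group:"):
                    space_group = body.split(":", 1)[1].strip()
                elif body.startswith("sweep:"):
                    parts = body.split(":", 1)[1].split()
                    sid = parts[0]
                    kv = dict(p.split("=", 1) for p in parts[1:])
                    sweeps[sid] = SweepMetadata(
                        sid, float(kv["phi_start"]), float(kv["phi_end"]),
                        float(kv.get("image_width", 1.0)))
                continue
            if header is None:
                header = line.split("\t")
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise FormatError(
                        f"malformed header: missing column(s) {missing}")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise FormatError("file contains no header line")
    df = pd.DataFrame(rows, columns=header) if rows else pd.DataFrame(
        {c: [] for c in header})
    for c in header:
        if c in ("sweep_id",):
            df[c] = df[c].astype(str) if len(df) else df[c].astype(object)
        elif c in ("h", "k", "l", "flags"):
            df[c] = df[c].astype(np.int64) if len(df) else \
                np.zeros(0, dtype=np.int64)
        else:
            # astype goes through exact float() parsing (pd.to_numeric's
            # fast path is lossy in the last bit); malformed fields become
            # NaN and are flagged below
            try:
                parsed = df[c].astype(np.float64)
            except ValueError:
                parsed = pd.to_numeric(df[c], errors="coerce")
            df[c] = parsed if len(df) else np.zeros(0)
    had_g = "g" in header and len(df)
    g_vals = df["g"].to_numpy(dtype=float) if had_g else None
    df = _init_derived(df)
    if had_g:
        df["g"] = g_vals
    # flag unusable rows rather than dropping them: row count is preserved
    num = df[["I_prof", "var_prof", "I_sum", "var_sum"]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(num), axis=1)
    bad |= (df["var_prof"].to_numpy(dtype=float) <= 0)
    bad |= (df["var_sum"].to_numpy(dtype=float) <= 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} row(s) with non-finite or "
                      "non-positive intensity/variance flagged bad_for_scaling")
        df.loc[bad, "flags"] |= BAD_FOR_SCALING
    return df, space_group, sweeps


def write_reflection_table(path, table: pd.DataFrame, space_group: str | None,
                           sweeps: dict[str, SweepMetadata] | None = None) -> None:
    """Write the unmerged TSV format (adds g, var_g, flags columns)."""
    cols = REQUIRED_COLUMNS + [c for c in OUTPUT_COLUMNS if c in table.columns]
    with open(path, "w") as fh:
        if space_group:
            fh.write(f"# space_group: {space_group}\n")
        for sw in (sweeps or {}).values():
            fh.write(f"# sweep: {sw.sweep_id} phi_start={sw.phi_start!r} "
                     f"phi_end={sw.phi_end!r} image_width={sw.image_width!r}\n")
        fh.write("\t".join(cols) + "\n")
        out = table[cols]
        for row in out.itertuples(index=False):
            fields = []
            for c, v in zip(cols, row):
                if c in ("h", "k", "l", "flags"):
                    fields.append(str(int(v)))
                elif c == "sweep_id":
                    fields.append(str(v))
                else:
                    fields.append(repr(float(v)))
            fh.write("\t".join(fields) + "\n")


def write_merged_tsv(path, merged: pd.DataFrame) -> None:
    """Write a merged table (``h k l I sigI n_obs``)."""
    with open(path, "w") as fh:
        fh.write("h\tk\tl\tI\tsigI\tn_obs\n")
        for row in merged.itertuples(index=False):
            fh.write(f"{int(row.h)}\t{int(row.k)}\t{int(row.l)}\t"
                     f"{row.I!r}\t{row.sigI!r}\t{int(row.n_obs)}\n")


def write_merged_mtz(path, merged: pd.DataFrame, cell, space_group: str) -> None:
    """Write merged intensities as a standard MTZ file (via gemmi)."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup(space_group)
    mtz.set_cell_for_all(gemmi.UnitCell(*cell))
    mtz.add_dataset("merged")
    mtz.add_column("IMEAN", "J")
    mtz.add_column("SIGIMEAN", "Q")
    arr = np.column_stack([
        merged["h"], merged["k"], merged["l"], merged["I"], merged["sigI"]])
    mtz.set_data(arr.astype(float))
    mtz.write_to_file(str(path))


# ---------------------------------------------------------------------------
# Symmetry: ASU mapping and grouping
# ---------------------------------------------------------------------------

def _space_group(symbol: str) -> gemmi.SpaceGroup:
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise ValueError(
            f"unknown space-group symbol {symbol!r}; accepted notations are "
            "Hermann-Mauguin (e.g. 'P 21 21 21', 'P212121'), short symbols "
            "(e.g. 'P61 2 2') or space-group numbers via gemmi")
    return sg


def rotation_ops(space_group: str, anomalous: bool = False) -> np.ndarray:
    """Integer hkl-transform matrices of the point group, as an (n, 3, 3) array.

    Friedel inversion is included unless ``anomalous``.
    """
    sg = _space_group(space_group)
    mats = []
    for op in sg.operations().sym_ops:
        r = np.array(op.rot, dtype=np.int64) // op.DEN
        mats.append(r)
    mats = np.unique(np.array(mats), axis=0)
    if not anomalous:
        mats = np.unique(np.concatenate([mats, -mats]), axis=0)
    return mats


def map_to_asu(table: pd.DataFrame, space_group: str,
               anomalous: bool = False) -> pd.DataFrame:
    """Annotate each observation with its canonical symmetry-unique index.

    The canonical representative of an orbit is its lexicographically greatest
    member (over the point-group operations, plus Friedel inversion unless
    ``anomalous``).  Adds ``asu_h asu_k asu_l`` and an integer ``group_id``
    shared by all symmetry equivalents.  Idempotent.
    """
    hkl = table[["h", "k", "l"]].to_numpy(dtype=np.int64)
    ops = rotation_ops(space_group, anomalous)
    # reciprocal-space transform: h' = h . R  (row vector convention)
    orbit = np.einsum("ij,ojk->oik", hkl, ops)  # (n_ops, n, 3)
    # lexicographic max over the orbit
    keys = (orbit[:, :, 0] * (1 << 42) + orbit[:, :, 1] * (1 << 21)
            + orbit[:, :, 2])
    best = np.argmax(keys, axis=0)
    asu = orbit[best, np.arange(hkl.shape[0])]
    table = table.copy()
    table["asu_h"], table["asu_k"], table["asu_l"] = asu.T
    if len(table):
        _, codes = np.unique(asu, axis=0, return_inverse=True)
    else:
        codes = np.zeros(0, dtype=np.int64)
    table["group_id"] = codes.astype(np.int64)
    return table


class SymmetryGroups:
    """Observations grouped by symmetry-unique (ASU) index.

    Thin wrapper over the integer ``group_id`` codes providing the group
    reductions used throughout scaling (sizes, weighted means).
    """

    def __init__(self, group_id: np.ndarray, n_groups: int | None = None):
        self.group_id = np.asarray(group_id, dtype=np.int64)
        self.n_groups = int(n_groups if n_groups is not None
                            else (self.group_id.max() + 1 if len(self.group_id)
                                  else 0))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SymmetryGroups":
        return cls(table["group_id"].to_numpy())

    def __len__(self) -> int:
        return self.n_groups

    def sizes(self, mask: np.ndarray | None = None) -> np.ndarray:
        gid = self.group_id if mask is None else self.group_id[mask]
        return np.bincount(gid, minlength=self.n_groups)

    def sum(self, values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        gid = self.group_id
        if mask is not None:
            gid, values = gid[mask], values[mask]
        return np.bincount(gid, weights=values, minlength=self.n_groups)


# ---------------------------------------------------------------------------
# Normalized coordinates
# ---------------------------------------------------------------------------

def normalize_coordinates(table: pd.DataFrame, metadata: SweepMetadata,
                          spacing_scale: float, spacing_decay: float) -> pd.DataFrame:
    """Add the adjusted/normalized coordinates used by the scaling models.

    ``r = (phi - phi_start)/spacing_scale`` and
    ``t = (phi - phi_start)/spacing_decay`` are the adjusted rotation angles
    (``t`` acting as a proxy for time); ``phi_norm`` is rotation normalized to
    [0, 1]; ``dprime`` is 1/d^2 rescaled to [0, 1] over the sweep's usable
    resolution range (degenerate range maps to 0); ``xp``/``yp`` are detector
    coordinates clipped to [0, 1].
    """
    if spacing_scale <= 0 or spacing_decay <= 0:
        raise ValueError("spacings must be positive")
    table = table.copy()
    phi = table["phi"].to_numpy(dtype=float)
    width = metadata.width
    if width <= 0:
        warnings.warn("zero-width sweep: r = t = 0 for all rows")
        rel = np.zeros_like(phi)
        width = 1.0
    else:
        rel = phi - metadata.phi_start
    table["r"] = rel / spacing_scale
    table["t"] = rel / spacing_decay
    table["phi_norm"] = rel / width
    s = 1.0 / table["d"].to_numpy(dtype=float) ** 2
    ok = usable(table)
    ref = s[ok] if ok.any() else s
    lo, hi = (ref.min(), ref.max()) if len(ref) else (0.0, 0.0)
    if hi - lo < 1e-12:
        table["dprime"] = np.zeros_like(s)
    else:
        table["dprime"] = np.clip((s - lo) / (hi - lo), 0.0, 1.0)
    table["xp"] = np.clip(table["x_det"].to_numpy(dtype=float), 0.0, 1.0)
    table["yp"] = np.clip(table["y_det"].to_numpy(dtype=float), 0.0, 1.0)
    return table


# ---------------------------------------------------------------------------
# Cell / completeness helpers
# ---------------------------------------------------------------------------

def d_spacings(cell, hkl: np.ndarray) -> np.ndarray:
    """Resolution of each hkl for the given unit cell (a,b,c,al,be,ga)."""
    uc = gemmi.UnitCell(*cell)
    # reciprocal metric tensor from the direct metric
    a, b, c = uc.a, uc.b, uc.c
    al, be, ga = np.radians([uc.alpha, uc.beta, uc.gamma])
    G = np.array([
        [a * a, a * b * np.cos(ga), a * c * np.cos(be)],
        [a * b * np.cos(ga), b * b, b * c * np.cos(al)],
        [a * c * np.cos(be), b * c * np.cos(al), c * c]])
    Gstar = np.linalg.inv(G)
    hkl = np.asarray(hkl, dtype=float)
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, Gstar, hkl)
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(inv_d2)


def unique_reflections(cell, space_group: str, d_min: float,
                       anomalous: bool = False) -> pd.DataFrame:
    """Enumerate the theoretically possible unique reflections to ``d_min``.

    Brute-force lattice enumeration within the resolution sphere, mapped to
    the same canonical ASU convention as :func:`map_to_asu`, with
    systematically absent reflections removed.  Returns a table with columns
    ``h k l d`` (one row per unique reflection).
    """
    uc = gemmi.UnitCell(*cell)
    hmax = int(np.floor(uc.a / d_min)) + 1
    kmax = int(np.floor(uc.b / d_min)) + 1
    lmax = int(np.floor(uc.c / d_min)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = d_spacings(cell, hkl)
    sel = d >= d_min
    hkl, d = hkl[sel], d[sel]
    sg = _space_group(space_group)
    gops = sg.operations()
    absent = np.array([gops.is_systematically_absent(list(map(int, x)))
                       for x in hkl])
    hkl, d = hkl[~absent], d[~absent]
    tab = pd.DataFrame({"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2]})
    tab = map_to_asu(tab, space_group, anomalous)
    uniq = tab.drop_duplicates("group_id")
    out = pd.DataFrame({
        "h": uniq["asu_h"].to_numpy(), "k": uniq["asu_k"].to_numpy(),
        "l": uniq["asu_l"].to_numpy()})
    out["d"] = d_spacings(cell, out[["h", "k", "l"]].to_numpy())
    return out.reset_index(drop=True)
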