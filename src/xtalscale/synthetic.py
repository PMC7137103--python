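"""Synthetic multi-sweep reflection tables with known ground truth.

The generator emulates the data model that scaling operates on — unmerged
observations of symmetry-unique reflections with smooth per-sweep scale
variation, resolution-dependent decay, a mild absorption surface, counting
noise and optional variance inflation — without attempting a physically
rigorous diffraction simulation.  Everything needed to assert recovery is
retrievable from the returned :class:`GroundTruth` (per-row true inverse
scales, true mean intensities, injected-outlier mask), and regeneration
from the same seed is bit-identical.

True unmerged intensities are drawn per unique reflection from an
exponential (Wilson-like) distribution whose mean decays as
``exp(-wilson_B/(2 d^2))``.  Observed intensity: ``I = g_true * (I_h + e)``
with noise variance ``a^2 (sigma0^2/g^2 + (b I_h)^2)`` in scaled space
(``sigma0^2 = I_obs + background`` is the *reported* variance, so nonzero
(a, b) inflate the real errors relative to the reported ones exactly as the
two-parameter error model assumes).  Geometry: the reverse incident beam is
rotated with phi about the lab x axis into the crystal frame and the
scattered beam lies on the cone of scattering angle 2*theta(d) at a random
azimuth, which gives the absorption surface an identifiable signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .components import n_sph_coeffs, real_sph_harm_basis
from .reflection_data import SweepMetadata, unique_reflections, _init_derived

WAVELENGTH = 1.0  # Angstrom; only sets the scattering-cone opening


@dataclass
class GroundTruth:
    """Generating conditions and, after generation, the realized truth."""

    space_group: str = "P 2 2 2"
    cell: tuple = (50.0, 60.0, 70.0, 90.0, 90.0, 90.0)
    d_min: float = 2.0
    n_sweeps: int = 1
    sweep_width: float = 90.0
    image_width: float = 0.1
    multiplicity: float = 5.0       # mean observations per unique per sweep
    mean_I: float = 2000.0          # Wilson-plateau mean intensity (counts)
    wilson_B: float = 10.0          # A^2 falloff of the true intensities
    background: float = 50.0        # additive variance (background counts)
    scale_amplitude: float = 0.2    # fractional smooth scale variation
    scale_period: float = 180.0     # degrees
    decay_B_final: float = 0.0      # relative B at sweep end (A^2)
    absorption_lmax: int = 2
    absorption_amplitude: float = 0.0
    error_a: float = 1.0
    error_b: float = 0.0
    outlier_fraction: float = 0.0
    sum_noise_factor: float = 1.5   # extra variance factor of summation data
    # filled in by generate_sweeps
    scale_phase: dict = field(default_factory=dict)
    absorption_coeffs: np.ndarray | None = None

    def scale_at(self, sweep_id: str, phi_rel: np.ndarray) -> np.ndarray:
        phase = self.scale_phase.get(sweep_id, 0.0)
        return 1.0 + self.scale_amplitude * np.sin(
            2.0 * np.pi * phi_rel / self.scale_period + phase)

    def b_at(self, phi_rel: np.ndarray) -> np.ndarray:
        # relative B, linear in time and mean-zero over the sweep (a constant
        # B offset is not identifiable: it is absorbed by the group means, and
        # the fitted relative B is restrained towards zero mean)
        return self.decay_B_final * (phi_rel / self.sweep_width - 0.5)

    def g_at(self, sweep_id: str, phi_rel, d, s0c, s1c) -> np.ndarray:
        g = self.scale_at(sweep_id, phi_rel)
        g = g * np.exp(self.b_at(phi_rel) / (2.0 * np.asarray(d) ** 2))
        if self.absorption_coeffs is not None and \
                len(self.absorption_coeffs):
            basis = 0.5 * (real_sph_harm_basis(self.absorption_lmax, s0c)
                           + real_sph_harm_basis(self.absorption_lmax, s1c))
            g = g * (1.0 + basis @ self.absorption_coeffs)
        return g


def _rot_x(phi_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices about x by -phi (lab -> crystal frame)."""
    c = np.cos(np.radians(-phi_deg))
    s = np.sin(np.radians(-phi_deg))
    R = np.zeros((len(phi_deg), 3, 3))
    R[:, 0, 0] = 1.0
    R[:, 1, 1] = c
    R[:, 1, 2] = -s
    R[:, 2, 1] = s
    R[:, 2, 2] = c
    return R


def generate_sweeps(truth: GroundTruth, seed: int,
                    n_obs: int | None = None):
    """Generate unmerged observations for ``truth.n_sweeps`` sweeps.

    Returns ``(table, sweeps, truth)`` — the combined reflection table (with
    extra ground-truth columns ``g_true``, ``I_true`` and
    ``injected_outlier``), per-sweep metadata, and the completed truth.
    If ``n_obs`` is given the per-sweep multiplicity is rescaled so the
    expected total observation count is about ``n_obs``.
    """
    rng = np.random.default_rng(seed)
    uniq = unique_reflections(truth.cell, truth.space_group, truth.d_min)
    n_uniq = len(uniq)
    mult = truth.multiplicity
    if n_obs is not None:
        mult = n_obs / (n_uniq * truth.n_sweeps)
    truth = replace(truth)
    truth.scale_phase = {}
    if truth.absorption_amplitude > 0 and truth.absorption_lmax >= 1:
        nco = n_sph_coeffs(truth.absorption_lmax)
        truth.absorption_coeffs = truth.absorption_amplitude * \
            rng.standard_normal(nco) / np.sqrt(nco)
    else:
        truth.absorption_coeffs = None
    d_u = uniq["d"].to_numpy()
    mean_int = truth.mean_I * np.exp(-truth.wilson_B / (2.0 * d_u ** 2))
    I_h = rng.exponential(mean_int)
    sweeps: dict[str, SweepMetadata] = {}
    frames = []
    for si in range(truth.n_sweeps):
        sid = f"sweep{si}"
        phi0 = 0.0
        sweeps[sid] = SweepMetadata(sid, phi0, phi0 + truth.sweep_width,
                                    truth.image_width)
        truth.scale_phase[sid] = float(rng.uniform(0, 2 * np.pi)) \
            if truth.n_sweeps > 1 else 0.0
        counts = rng.poisson(mult, size=n_uniq)
        ridx = np.repeat(np.arange(n_uniq), counts)
        n = len(ridx)
        if n == 0:
            continue
        phi_rel = rng.uniform(0.0, truth.sweep_width, size=n)
        d = d_u[ridx]
        # geometry: beam along +z in the lab, crystal rotated about x
        sin_t = WAVELENGTH / (2.0 * d)
        two_theta = 2.0 * np.arcsin(np.clip(sin_t, 0, 1))
        psi = rng.uniform(0, 2 * np.pi, size=n)
        s1_lab = np.column_stack([
            np.sin(two_theta) * np.cos(psi),
            np.sin(two_theta) * np.sin(psi),
            np.cos(two_theta)])
        R = _rot_x(phi_rel + phi0)
        s0c = np.einsum("nij,j->ni", R, np.array([0.0, 0.0, 1.0]))
        s1c = np.einsum("nij,nj->ni", R, s1_lab)
        g_true = truth.g_at(sid, phi_rel, d, s0c, s1c)
        I_true = I_h[ridx]
        sigma0_sq = np.maximum(g_true * I_true, 0.0) + truth.background
        noise_var_sc = truth.error_a ** 2 * (
            sigma0_sq / g_true ** 2 + (truth.error_b * I_true) ** 2)
        I_sc_prof = I_true + rng.normal(0.0, np.sqrt(noise_var_sc))
        I_sc_sum = I_true + rng.normal(
            0.0, np.sqrt(noise_var_sc * truth.sum_noise_factor))
        out_mask = rng.random(n) < truth.outlier_fraction
        if out_mask.any():
            factor = rng.uniform(3.0, 10.0, size=int(out_mask.sum()))
            I_sc_prof[out_mask] = np.abs(I_sc_prof[out_mask]) * factor + \
                10.0 * np.sqrt(noise_var_sc[out_mask])
        df = pd.DataFrame({
            "h": uniq["h"].to_numpy()[ridx],
            "k": uniq["k"].to_numpy()[ridx],
            "l": uniq["l"].to_numpy()[ridx],
            "sweep_id": sid,
            "I_prof": g_true * I_sc_prof,
            "var_prof": sigma0_sq,
            "I_sum": g_true * I_sc_sum,
            "var_sum": sigma0_sq * truth.sum_noise_factor,
            "phi": phi0 + phi_rel,
            "d": d,
            "x_det": 0.5 * (s1_lab[:, 0] + 1.0),
            "y_det": 0.5 * (s1_lab[:, 1] + 1.0),
            "s0cx": s0c[:, 0], "s0cy": s0c[:, 1], "s0cz": s0c[:, 2],
            "s1cx": s1c[:, 0], "s1cy": s1c[:, 1], "s1cz": s1c[:, 2],
            "g_true": g_true,
            "I_true": I_true,
            "injected_outlier": out_mask})
        frames.append(df)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table = _init_derived(table)
    return table, sweeps, truth


def generate_filter_fixture(n_subsets: int, bad_subsets, distortion: float,
                            seed: int, truth: GroundTruth | None = None,
                            mode: str = "resolution"):
    """Multi-sweep fixture where some sweeps carry a systematic distortion.

    ``mode="resolution"``: bad sweeps have their observed intensities
    multiplied by a smooth resolution-dependent factor interpolating from 1
    (low resolution) to ``distortion`` (at d_min), mimicking radiation
    damage.  Being a smooth per-sweep multiplicative effect it is largely
    absorbable by a per-sweep scaling model, so it shows up in a direct
    deltaCC1/2 analysis of unscaled data but not necessarily after
    rescaling.  ``mode="scramble"``: a fraction ``1 - 1/distortion`` of the
    bad sweeps' observations have their intensities permuted within the
    sweep — non-isomorphism that no smooth scaling model can absorb.
    Reported variances are left untouched in both modes.
    """
    base = truth or GroundTruth(n_sweeps=n_subsets, sweep_width=10.0,
                                multiplicity=1.5, scale_amplitude=0.05,
                                cell=(30.0, 35.0, 40.0, 90.0, 90.0, 90.0),
                                d_min=2.5)
    base = replace(base, n_sweeps=n_subsets)
    table, sweeps, out_truth = generate_sweeps(base, seed)
    bad = {f"sweep{b}" if isinstance(b, int) else b for b in bad_subsets}
    in_bad = table["sweep_id"].isin(bad).to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    if mode == "resolution":
        s = 1.0 / table["d"].to_numpy() ** 2
        frac = (s - s.min()) / max(s.max() - s.min(), 1e-12)
        factor = distortion ** frac
        for col in ("I_prof", "I_sum"):
            vals = table[col].to_numpy(dtype=float)
            vals[in_bad] *= factor[in_bad]
            table[col] = vals
    elif mode == "scramble":
        frac_bad = 1.0 - 1.0 / max(distortion, 1.0)
        idx = np.flatnonzero(in_bad)
        pick = idx[rng.random(len(idx)) < frac_bad]
        perm = rng.permutation(pick)
        for col in ("I_prof", "I_sum"):
            vals = table[col].to_numpy(dtype=float)
            vals[pick] = vals[perm]
            table[col] = vals
    else:
        raise ValueError(f"unknown distortion mode {mode!r}")
    return table, sweeps, out_truth
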