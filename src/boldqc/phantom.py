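"""Seeded synthetic 4D phantoms with known ground truth.

The generator emulates the data regimes seen in rodent resting-state scans:
planted network maps with band-limited (0.01-0.1 Hz) timecourses riding on
a baseline intensity, optional confound components with CSF, brain-edge and
global spatial signatures, per-voxel linear drift, Gaussian thermal noise,
and rigid motion traces whose planted step displacements exceed the 0.05 mm
framewise-displacement preset at exactly the spiked frames (with a matching
one-frame intensity artefact). Everything is a pure function of
(config, seed), and the noiseless mixing model reconstructs the data
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal

from .aroma import make_edge_mask
from .core import (
    ComponentSet,
    Grid,
    MotionParameters,
    Timeseries4D,
    VolumeMap,
    map_from_voxels,
    mask_indices,
)

DEFAULT_SHAPE = (16, 16, 8)
DEFAULT_SPACING_MM = 0.2
DEFAULT_TR_S = 1.2
DEFAULT_N_FRAMES = 200


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic scan.

    Amplitudes are in raw intensity units on a baseline of 100, so a network
    amplitude of 3 corresponds to ~3% BOLD fluctuations — the upper end of
    realistic rodent BOLD — and noise_sigma 1 gives ~1% thermal noise.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_mm: float = DEFAULT_SPACING_MM
    tr: float = DEFAULT_TR_S
    n_frames: int = DEFAULT_N_FRAMES
    baseline: float = 100.0
    n_networks: int = 2
    network_amplitude: float = 3.0
    network_band_hz: tuple[float, float] = (0.01, 0.1)
    include_confounds: bool = False
    confound_types: tuple = ("csf", "edge", "global")
    confound_amplitude: float = 3.0
    confound_prior_mismatch: float = 0.8
    noise_sigma: float = 1.0
    n_noise_fields: int = 4
    structured_noise_amplitude: float = 0.3
    noise_field_sigma_vox: float = 2.0
    drift_amplitude: float = 2.0  # intensity change over the scan duration
    n_motion_spikes: int = 3
    spike_displacement_mm: float = 0.08
    spike_artifact_amplitude: float = 6.0
    motion_noise_mm: float = 0.0008
    motion_noise_rad: float = 0.00015

    def __post_init__(self) -> None:
        if self.n_networks + 3 * self.include_confounds > self.n_frames:
            raise ValueError("more planted components than frames; infeasible config")


@dataclass
class GroundTruth:
    """Planted structure of a phantom, sufficient to rebuild the noiseless data."""

    network_maps: np.ndarray  # (network, voxel)
    network_timecourses: np.ndarray  # (network, frame)
    confound_maps: np.ndarray  # (confound, voxel); empty when no confounds
    confound_timecourses: np.ndarray
    confound_names: list[str]
    spike_frames: np.ndarray
    drift_slopes: np.ndarray  # per voxel, intensity per second
    baseline: np.ndarray  # per voxel
    spike_artifact: np.ndarray  # (voxel, frame) additive artefact

    def noiseless(self, tr: float, n_frames: int) -> np.ndarray:
        """The full mixing model without the Gaussian noise term."""
        t = np.arange(n_frames) * tr
        data = self.baseline[:, None] + np.outer(self.drift_slopes, t)
        if self.network_maps.size:
            data = data + self.network_maps.T @ self.network_timecourses
        if self.confound_maps.size:
            data = data + self.confound_maps.T @ self.confound_timecourses
        data = data + self.spike_artifact
        return data


@dataclass
class Phantom:
    ts: Timeseries4D
    brain_mask: VolumeMap
    csf_mask: VolumeMap
    wm_mask: VolumeMap
    edge_mask: VolumeMap
    parcellation: VolumeMap
    motion: MotionParameters
    truth: GroundTruth
    config: PhantomConfig

    def priors(self) -> ComponentSet:
        """Prior set for dual regression: the planted network maps plus the
        *idealised* confound signatures (CSF / edge / graded global).

        The confound priors are deliberately the atlas-style signatures, not
        the scan's true confound expression — mirroring practice, where
        group-level priors never match the confounds of an individual scan
        exactly."""
        maps = [self.truth.network_maps, self._confound_signatures()]
        labels = ["network"] * self.truth.network_maps.shape[0] + ["confound"] * 3
        return ComponentSet(
            maps=np.vstack(maps), mask=self.brain_mask, labels=labels
        )

    def _confound_signatures(self) -> np.ndarray:
        csf = self.csf_mask.in_mask(self.brain_mask).astype(float)
        edge = self.edge_mask.in_mask(self.brain_mask).astype(float)
        glob = _global_profile(self.brain_mask)
        return np.vstack([csf, edge, glob])

    def canonical_map(self, network: int = 0) -> VolumeMap:
        return map_from_voxels(
            self.truth.network_maps[network], self.brain_mask, kind="canonical"
        )


def _ellipsoid(shape: tuple[int, int, int], radii: np.ndarray, center: np.ndarray) -> np.ndarray:
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    d = ((coords - center) / radii) ** 2
    return d.sum(axis=-1) <= 1.0


def _band_limited(rng: np.random.Generator, n: int, tr: float,
                  band: tuple[float, float]) -> np.ndarray:
    """Unit-SD noise band-passed to the requested frequency band."""
    white = rng.standard_normal(n)
    nyq = 1.0 / (2.0 * tr)
    lo = max(band[0], 1e-4)
    hi = min(band[1], 0.95 * nyq)
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=1.0 / tr, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _global_profile(brain_mask: VolumeMap) -> np.ndarray:
    """Brain-wide confound signature: radially graded rather than uniform so
    it stays linearly separable from a regression intercept."""
    shape = brain_mask.grid.shape
    center = (np.asarray(shape) - 1) / 2.0
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    r2 = (((coords - center) / (np.asarray(shape) * 0.45)) ** 2).sum(axis=-1)
    profile = 1.0 - 0.5 * np.clip(r2, 0.0, 1.0)
    return profile.reshape(-1)[mask_indices(brain_mask)]


def _gaussian_blob(shape, center, sigma_vox) -> np.ndarray:
    coords = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    d2 = (((coords - np.asarray(center)) / sigma_vox) ** 2).sum(axis=-1)
    return np.exp(-0.5 * d2)


def _smooth_field(rng: np.random.Generator, shape, idx, sigma_vox: float = 2.0) -> np.ndarray:
    """Zero-mean, unit-SD smooth random field sampled at in-mask voxels."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    vox = field.reshape(-1)[idx]
    sd = vox.std()
    return (vox - vox.mean()) / sd if sd > 0 else vox


def make_phantom(config: Optional[PhantomConfig] = None, seed: int = 0) -> Phantom:
    """Generate one synthetic scan with full ground truth."""
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    grid = Grid.isotropic(cfg.shape, cfg.spacing_mm)
    shape = cfg.shape
    center = (np.asarray(shape) - 1) / 2.0

    brain = _ellipsoid(shape, radii=np.asarray(shape) * 0.45, center=center)
    brain_mask = VolumeMap(brain.astype(int), grid, kind="brain_mask")
    csf = _ellipsoid(shape, radii=np.array([1.6, 1.6, 1.1]), center=center) & brain
    csf_mask = VolumeMap(csf.astype(int), grid, kind="csf_mask")
    edge_mask = make_edge_mask(brain_mask, k=1)
    # white matter: a ring just inside the edge band, outside CSF
    inner = _ellipsoid(shape, radii=np.asarray(shape) * 0.45 - 2.0, center=center)
    wm = brain & ~np.asarray(edge_mask.values, dtype=bool) & ~inner & ~csf
    wm_mask = VolumeMap(wm.astype(int), grid, kind="wm_mask")

    # quadrant parcellation within the brain (labels 1..4)
    parc = np.zeros(shape, dtype=int)
    xs = np.arange(shape[0])[:, None, None] < center[0]
    ys = np.arange(shape[1])[None, :, None] < center[1]
    parc[brain] = (1 + 2 * (~xs) + 1 * (~ys) + np.zeros(shape, dtype=int))[brain]
    parcellation = VolumeMap(parc, grid, kind="parcellation")

    idx = mask_indices(brain_mask)
    n_vox = idx.size
    n = cfg.n_frames

    # planted networks: compact blobs in opposite quadrants
    centers = [
        center + np.array([-4.0, -4.0, 0.0]),
        center + np.array([4.0, 4.0, 0.0]),
        center + np.array([-4.0, 4.0, 0.0]),
        center + np.array([4.0, -4.0, 0.0]),
    ]
    net_maps = []
    net_tcs = []
    for i in range(cfg.n_networks):
        blob = _gaussian_blob(shape, centers[i % len(centers)], sigma_vox=1.5)
        blob[~brain] = 0.0
        vox = blob.reshape(-1)[idx]
        vox /= vox.max() if vox.max() > 0 else 1.0
        net_maps.append(vox)
        net_tcs.append(_band_limited(rng, n, cfg.tr, cfg.network_band_hz) * cfg.network_amplitude)
    network_maps = np.asarray(net_maps) if net_maps else np.zeros((0, n_vox))
    network_tcs = np.asarray(net_tcs) if net_tcs else np.zeros((0, n))

    # confound components: CSF-localised, edge-localised, global. The planted
    # spatial expression is a smooth-field modulation of the idealised
    # signature used as the dual-regression prior — real confounds never
    # match the atlas-derived prior exactly, and this mismatch is what lets
    # confound variance leak into the network timecourse of spurious scans.
    conf_maps: list[np.ndarray] = []
    conf_tcs: list[np.ndarray] = []
    conf_names: list[str] = []
    if cfg.include_confounds:
        csf_vox = csf_mask.in_mask(brain_mask).astype(float)
        edge_vox = edge_mask.in_mask(brain_mask).astype(float)
        # the planted "global" physiological confound is grey-matter weighted
        # (vascular/respiratory fluctuations express in tissue), whereas the
        # prior signature is a crude brain-wide profile — the mismatch is
        # what lets global confound variance bleed into network read-outs
        gm_vox = (
            ~wm_mask.in_mask(brain_mask).astype(bool)
            & ~csf_mask.in_mask(brain_mask).astype(bool)
            & ~edge_mask.in_mask(brain_mask).astype(bool)
        ).astype(float)
        profile = _global_profile(brain_mask)
        # two global-artifact archetypes: "global" is grey-matter-weighted
        # physiology; "global_uniform" is a brain-wide artefact (e.g. B0 or
        # coil drift) whose spatial expression wanders around the profile
        for name, vox, modulate in (
            ("csf", csf_vox, True),
            ("edge", edge_vox, True),
            ("global", gm_vox * profile, False),
            ("global_uniform", profile, True),
        ):
            if name not in cfg.confound_types:
                continue
            planted = vox
            if modulate:
                field = _smooth_field(rng, shape, idx, sigma_vox=2.0)
                planted = vox * (1.0 + cfg.confound_prior_mismatch * field)
            conf_maps.append(planted)
            conf_tcs.append(
                _band_limited(rng, n, cfg.tr, (0.01, 0.25)) * cfg.confound_amplitude
            )
            conf_names.append(name)
    confound_maps = np.asarray(conf_maps) if conf_maps else np.zeros((0, n_vox))
    confound_tcs = np.asarray(conf_tcs) if conf_tcs else np.zeros((0, n))

    drift_slopes = (
        rng.uniform(0.5, 1.0, n_vox)
        * rng.choice([-1.0, 1.0], n_vox)
        * cfg.drift_amplitude
        / (n * cfg.tr)
    )
    baseline = cfg.baseline + rng.normal(0.0, 1.0, n_vox)

    # motion: stationary white jitter around a fixed restrained pose, plus a
    # permanent step displacement (repositioning event) at each spike frame,
    # producing a single supra-threshold FD value there
    params = np.zeros((n, 6))
    params[:, :3] = rng.normal(0.0, cfg.motion_noise_mm, (n, 3))
    params[:, 3:] = rng.normal(0.0, cfg.motion_noise_rad, (n, 3))
    spike_frames = np.array([], dtype=int)
    if cfg.n_motion_spikes > 0:
        candidates = np.arange(5, n - 5)
        chosen: list[int] = []
        rng.shuffle(candidates)
        for c in candidates:
            if all(abs(c - k) >= 5 for k in chosen):
                chosen.append(int(c))
            if len(chosen) == cfg.n_motion_spikes:
                break
        spike_frames = np.sort(np.asarray(chosen, dtype=int))
        for f in spike_frames:
            params[f:, 0] += cfg.spike_displacement_mm * rng.choice([-1.0, 1.0])
    motion = MotionParameters(params)

    spike_artifact = np.zeros((n_vox, n))
    if spike_frames.size:
        pattern = rng.normal(0.0, 1.0, n_vox)
        for f in spike_frames:
            spike_artifact[:, f] = pattern * cfg.spike_artifact_amplitude

    truth = GroundTruth(
        network_maps=network_maps,
        network_timecourses=network_tcs,
        confound_maps=confound_maps,
        confound_timecourses=confound_tcs,
        confound_names=conf_names,
        spike_frames=spike_frames,
        drift_slopes=drift_slopes,
        baseline=baseline,
        spike_artifact=spike_artifact,
    )
    data = truth.noiseless(cfg.tr, n)
    if cfg.noise_sigma > 0:
        data = data + rng.normal(0.0, cfg.noise_sigma, (n_vox, n))
    # spatially structured noise: brain-wide smooth random fields with their
    # own timecourses, emulating physiological/scanner fluctuations that are
    # coherent over space but unrelated to the planted networks
    if cfg.n_noise_fields > 0 and cfg.structured_noise_amplitude > 0:
        for _ in range(cfg.n_noise_fields):
            fvox = _smooth_field(rng, shape, idx, cfg.noise_field_sigma_vox)
            tc = _band_limited(rng, n, cfg.tr, (0.01, 0.2))
            data = data + np.outer(fvox, tc * cfg.structured_noise_amplitude)
    ts = Timeseries4D(data, brain_mask, tr=cfg.tr, space_tag="phantom")
    return Phantom(
        ts=ts,
        brain_mask=brain_mask,
        csf_mask=csf_mask,
        wm_mask=wm_mask,
        edge_mask=edge_mask,
        parcellation=parcellation,
        motion=motion,
        truth=truth,
        config=cfg,
    )


CATEGORIES = ("specific", "absent", "mixed", "spurious")


def make_category_fixture(category: str, seed: int = 0,
                          config: Optional[PhantomConfig] = None) -> Phantom:
    """Phantom parameterised to reproduce one of the four scan-quality
    categories: specific (clean network), absent (no network, structured
    noise dominating), spurious (confounds only), mixed (network +
    confounds).

    The categories are distinct data-quality regimes, so beyond the
    presence/absence flags they also differ in noise structure: scans with
    undetectable networks are dominated by coherent physiological/scanner
    fluctuations (stronger structured noise), while confounded scans carry
    strong confound components over an otherwise quiet background.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; choose from {CATEGORIES}")
    if config is not None:
        cfg = config
        if category == "specific":
            cfg = replace(cfg, n_networks=max(cfg.n_networks, 1), include_confounds=False)
        elif category == "absent":
            cfg = replace(cfg, n_networks=0, include_confounds=False)
        elif category == "spurious":
            cfg = replace(cfg, n_networks=0, include_confounds=True)
        else:
            cfg = replace(cfg, n_networks=max(cfg.n_networks, 1), include_confounds=True)
    elif category == "specific":
        cfg = PhantomConfig(include_confounds=False)
    elif category == "absent":
        cfg = PhantomConfig(n_networks=0, include_confounds=False,
                            structured_noise_amplitude=1.0)
    elif category == "spurious":
        cfg = PhantomConfig(n_networks=0, include_confounds=True,
                            confound_amplitude=4.0, structured_noise_amplitude=0.2)
    else:  # mixed
        cfg = PhantomConfig(include_confounds=True, confound_amplitude=4.0)
    return make_category_fixture_phantom(cfg, seed, category)


def make_category_fixture_phantom(cfg: PhantomConfig, seed: int, category: str) -> Phantom:
    phantom = make_phantom(cfg, seed)
    if category in ("absent", "spurious") and phantom.truth.network_maps.shape[0] == 0:
        # keep the canonical network definition available for specificity
        # scoring even though the network signal itself is absent
        ref = make_phantom(replace(cfg, n_networks=2, include_confounds=False), seed)
        phantom.truth.network_maps = ref.truth.network_maps
        phantom.truth.network_timecourses = np.zeros_like(ref.truth.network_timecourses)
    return phantom


@dataclass
class GroupFixture:
    """Cross-scan fixture for the group statistical report."""

    scan_maps: list
    canonical: VolumeMap
    records: list
    brain_mask: VolumeMap


def make_fd_effect_group(
    n_scans: int = 15,
    effect_gain: float = 20.0,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> GroupFixture:
    """Scans whose connectivity scales linearly with mean framewise
    displacement: scan map = canonical * (1 + gain * (FD - mean FD)) + noise.
    ``effect_gain = 0`` yields the matching null-world fixture."""
    from .core import ScanQCRecord

    rng = np.random.default_rng(seed)
    base = make_phantom(PhantomConfig(), seed)
    canonical = base.canonical_map(0)
    mask = base.brain_mask
    canon_vox = canonical.in_mask(mask)
    fd_values = np.linspace(0.01, 0.04, n_scans)
    scan_maps = []
    records = []
    for i in range(n_scans):
        eff = 1.0 + effect_gain * (fd_values[i] - fd_values.mean())
        vox = canon_vox * eff + rng.normal(0.0, noise_sigma, canon_vox.size)
        scan_maps.append(map_from_voxels(vox, mask, kind="connectivity"))
        cr_vox = np.abs(rng.normal(1.0, 0.1, canon_vox.size))
        records.append(
            ScanQCRecord(
                scan_id=f"scan{i:02d}",
                dice_specificity=0.6,
                confound_correlation=0.1,
                amplitude_l2=float(np.linalg.norm(vox)),
                mean_fd=float(fd_values[i]),
                tdof=150 + i,
                retained_fraction=1.0,
                cr_sd_map=map_from_voxels(cr_vox, mask, kind="variability"),
                mean_cr_sd=float(cr_vox.mean()),
            )
        )
    return GroupFixture(scan_maps=scan_maps, canonical=canonical, records=records,
                        brain_mask=mask)
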