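"""Synthetic LC-DAD study generator.

Emulates the screening study design used for detecting regulated plants in
botanical supplements: per target plant, 55 spiked triturations (11 blank
matrices x 5 spike ratios 1/20, 1/15, 1/10, 1/5, 1/2, where a ratio is the
*mass fraction* of the reference plant, i.e. 5 %..50 %), 11 blanks and one
pure reference, giving 67 records; the multiclass pool combines 4 plants
(4 x 55 triturations + 11 blanks + 4 references = 235 records).

The physical model is deliberately simple but carries the statistical
structure the downstream analysis assumes:

* each constituent is a Gaussian chromatographic peak (retention center and
  width in minutes) carrying a UV spectrum that is a weighted sum of
  Gaussians in wavelength (a narrow primary band, a secondary band, and a
  broad tail so adjacent DAD channels correlate smoothly);
* absorbances mix additively in mass fraction (Beer-Lambert); two mild,
  monotone saturations bound the response the way real measurements are
  bounded -- a solubility-limited extraction yield per constituent
  (``extraction_cap_au``) and the detector's stray-light flattening of
  strong bands (``saturation_au``).  With both disabled the simulated
  record is exactly linear in the mass fractions;
* matrix profiles share a backbone of ubiquitous formulation compounds
  (with modest product-to-product abundance variation) that reference
  plant powders lack; spiking therefore dilutes it.  Matrices additionally
  carry 3 product-specific peaks, plants 6 (fingerprint windows are chosen
  where the plant is peak-rich);
* each injection carries one global retention-time jitter (instrument
  drift), a slow low-order polynomial baseline that decays toward long
  wavelengths (end absorbance), and i.i.d. Gaussian detector noise.

Profiles are laid out on retention-time and spectral lattices so that every
plant is provably distinguishable from every blank matrix: peak retention
centers of distinct profiles are separated by more than twice the largest
peak width, and signature spectral centers by at least ``176/n_profiles - 4``
nm; randomly drawn non-signature spectral centers keep >= 10 nm away from
every plant signature center.  The last matrix profile is a lactose
stand-in: a single near-flat peak with minimal UV absorbance and no
botanical backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import DataCube

__all__ = [
    "CompoundPeak",
    "PlantProfile",
    "SimConfig",
    "build_plant_library",
    "default_study_library",
    "simulate_dad_record",
    "simulate_study",
]

# retention-time band holding all generated peaks; inside the 1.5-6.6 min
# fingerprint window with margin so that COW's cumulative slack can reach
# the earliest and latest peaks
_RT_LO, _RT_HI = 1.8, 6.3
_SPEC_LO, _SPEC_SPAN = 212.0, 176.0  # signature spectral lattice, nm
_SPEC_EXCLUSION_NM = 10.0  # random spectral centers keep this far from signatures
_N_BACKBONE = 8  # ubiquitous compounds shared by every profile


@dataclass(frozen=True)
class CompoundPeak:
    """One chromatographic peak with its UV spectrum.

    retention_center/retention_width in minutes (width = Gaussian sigma),
    amplitude in AU; the spectrum is sum_g weights[g] *
    N(wavelength; spectrum_centers[g], spectrum_widths[g]) evaluated as an
    unnormalized Gaussian.
    """

    retention_center: float
    retention_width: float
    amplitude: float
    spectrum_centers: tuple[float, ...]
    spectrum_widths: tuple[float, ...]
    spectrum_weights: tuple[float, ...]

    def __post_init__(self):
        if self.retention_width <= 0:
            raise ValueError("retention_width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (
            len(self.spectrum_centers)
            == len(self.spectrum_widths)
            == len(self.spectrum_weights)
        ):
            raise ValueError("spectrum component lists must have equal length")
        if any(w <= 0 for w in self.spectrum_widths):
            raise ValueError("spectrum_widths must all be > 0")

    def spectral_factor(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(lam)
        for c, s, w in zip(
            self.spectrum_centers, self.spectrum_widths, self.spectrum_weights
        ):
            out += w * np.exp(-0.5 * ((lam - c) / s) ** 2)
        return out

    def temporal_profile(self, times: np.ndarray, jitter: float = 0.0) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        mu = self.retention_center + jitter
        return np.exp(-0.5 * ((t - mu) / self.retention_width) ** 2)


@dataclass(frozen=True)
class PlantProfile:
    """A named set of peaks; ``kind`` is 'plant' or 'matrix'."""

    name: str
    peaks: tuple[CompoundPeak, ...]
    kind: str = "plant"

    def __post_init__(self):
        if len(self.peaks) == 0:
            raise ValueError("a profile needs at least one peak")
        if self.kind not in ("plant", "matrix"):
            raise ValueError("kind must be 'plant' or 'matrix'")


def _default_wavelengths() -> np.ndarray:
    return np.arange(200.0, 401.0, 1.0)  # 201 channels


def _default_times() -> np.ndarray:
    # 0-8 min sampled every 0.05 s: 9601 points; the 1.5-6.6 min window
    # then holds 6121 of them
    return np.linspace(0.0, 8.0, 9601)


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings.

    Defaults mirror the screening study design: 11 matrices (the last a
    lactose stand-in), spike ratios {1/20, 1/15, 1/10, 1/5, 1/2} read as
    plant mass fractions, a 200-400 nm DAD grid and an 8 min run sampled
    every 0.05 s.  ``rt_jitter_sd`` (minutes), ``noise_sd`` (AU) and
    ``baseline_drift_amp`` (AU) control the nuisance structure that the
    alignment stage has to undo; ``saturation_au`` and
    ``extraction_cap_au`` set the detector and extraction nonlinearities
    (None = ideal linear detector / ideal extraction).  See
    docs/methods.md for the rationale behind each default.
    """

    n_matrices: int = 11
    spike_ratios: tuple[float, ...] = (1 / 20, 1 / 15, 1 / 10, 1 / 5, 1 / 2)
    wavelength_grid: np.ndarray = field(default_factory=_default_wavelengths)
    time_grid: np.ndarray = field(default_factory=_default_times)
    rt_jitter_sd: float = 0.005
    noise_sd: float = 0.0005
    baseline_drift_amp: float = 0.001
    saturation_au: float | None = 1.0
    extraction_cap_au: float | None = 0.2
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "wavelength_grid", np.asarray(self.wavelength_grid, dtype=float)
        )
        object.__setattr__(self, "time_grid", np.asarray(self.time_grid, dtype=float))
        if self.n_matrices < 1:
            raise ValueError("n_matrices must be >= 1")
        if not all(0 < r < 1 for r in self.spike_ratios):
            raise ValueError("spike_ratios must lie in (0, 1)")
        for name in ("wavelength_grid", "time_grid"):
            g = getattr(self, name)
            if g.size < 2 or not np.all(np.diff(g) > 0):
                raise ValueError(f"{name} must be strictly increasing with >= 2 points")
        if self.rt_jitter_sd < 0 or self.noise_sd < 0 or self.baseline_drift_amp < 0:
            raise ValueError("jitter/noise/baseline magnitudes must be >= 0")
        if self.saturation_au is not None and self.saturation_au <= 0:
            raise ValueError("saturation_au must be > 0 (or None for a linear detector)")
        if self.extraction_cap_au is not None and self.extraction_cap_au <= 0:
            raise ValueError("extraction_cap_au must be > 0 (or None for ideal extraction)")


def build_plant_library(
    n_plants: int, n_matrices: int, seed: int
) -> list[PlantProfile]:
    """Generate ``n_plants`` plant and ``n_matrices`` matrix profiles.

    Deterministic for a fixed seed.  Plants come first in the returned
    list; the last matrix is the lactose stand-in.  Plants carry 6
    specific peaks, non-lactose matrices 3 specific peaks plus the shared
    backbone; all peaks lie inside the fingerprint window and the first
    peak of each profile acts as its signature (lattice-assigned retention
    and spectral centers, see module docstring for the separation
    guarantees).
    """
    if n_plants < 1 or n_matrices < 1:
        raise ValueError("n_plants and n_matrices must be >= 1")
    total = n_plants + n_matrices
    rng = np.random.default_rng(seed)

    # retention lattice: profile-specific slots (plants are peak-rich --
    # the fingerprint window is chosen for "most number of peaks" of the
    # plant -- so plants get 6 specific peaks, matrices 3) plus slots for
    # a backbone of ubiquitous compounds shared by every profile
    # (co-extracted common phytochemicals); the backbone gives alignment
    # anchors and the shared chromatographic background real botanical
    # extracts have
    n_backbone = _N_BACKBONE
    n_plant_peaks, n_matrix_peaks = 6, 3
    n_specific = n_plant_peaks * n_plants + n_matrix_peaks * n_matrices
    n_slots = n_specific + n_backbone
    lattice = np.linspace(_RT_LO, _RT_HI, n_slots)
    spacing = lattice[1] - lattice[0]
    rt_jit = min(0.005, 0.1 * spacing)
    width_hi = min(0.038, (spacing - 2 * rt_jit) / 2.2)
    width_lo = 0.4 * width_hi
    backbone_idx = np.unique(np.round(np.linspace(0, n_slots - 1, n_backbone)).astype(int))
    slot_pool = lattice[np.setdiff1d(np.arange(n_slots), backbone_idx)]
    # deal the specific slots round-robin so each profile's peaks spread
    # over the whole window instead of clustering
    slot_of: dict[int, list[float]] = {i: [] for i in range(total)}
    counts = [n_plant_peaks if i < n_plants else n_matrix_peaks for i in range(total)]
    k = 0
    for rounds in range(max(counts)):
        for i in range(total):
            if rounds < counts[i]:
                slot_of[i].append(float(slot_pool[k]))
                k += 1
    sig_spec_centers = _SPEC_LO + (np.arange(total) + 0.5) * _SPEC_SPAN / total
    plant_sig_centers = sig_spec_centers[:n_plants]

    def random_primary_center() -> float:
        # keep random (non-signature) spectral centers away from every
        # plant signature band so blanks cannot mimic a plant spectrally
        for _ in range(200):
            c = rng.uniform(_SPEC_LO, _SPEC_LO + _SPEC_SPAN)
            if np.all(np.abs(plant_sig_centers - c) >= _SPEC_EXCLUSION_NM):
                return c
        return float(_SPEC_LO + _SPEC_SPAN)  # unreachable in practice

    def make_peak(center: float, width: float, amplitude: float, primary: float):
        secondary = rng.uniform(_SPEC_LO + 3, _SPEC_LO + _SPEC_SPAN - 3)
        # broad third component: compound UV bands have wide tails, so
        # every DAD channel carries correlated signal above the noise
        # floor and adjacent channels correlate smoothly
        broad = rng.uniform(240.0, 340.0)
        return CompoundPeak(
            retention_center=float(center),
            retention_width=float(width),
            amplitude=float(amplitude),
            spectrum_centers=(float(primary), float(secondary), float(broad)),
            spectrum_widths=(
                float(rng.uniform(9.0, 16.0)),
                float(rng.uniform(15.0, 30.0)),
                float(rng.uniform(60.0, 90.0)),
            ),
            spectrum_weights=(1.0, float(rng.uniform(0.2, 0.5)),
                              float(rng.uniform(0.04, 0.1))),
        )

    backbone = [
        make_peak(
            lattice[i] + rng.uniform(-rt_jit, rt_jit),
            rng.uniform(width_lo, width_hi),
            rng.uniform(0.5, 1.2),
            random_primary_center(),
        )
        for i in backbone_idx
    ]

    profiles: list[PlantProfile] = []
    for i in range(total):
        is_plant = i < n_plants
        kind = "plant" if is_plant else "matrix"
        number = i + 1 if is_plant else i - n_plants + 1
        if not is_plant and number == n_matrices:
            # lactose stand-in: one tiny, nearly UV-transparent peak
            center = float(slot_of[i][0] + rng.uniform(-rt_jit, rt_jit))
            profiles.append(
                PlantProfile(
                    name=f"matrix-{number:02d}-lactose",
                    kind="matrix",
                    peaks=(
                        CompoundPeak(
                            retention_center=center,
                            retention_width=0.03,
                            amplitude=0.002,
                            spectrum_centers=(202.0,),
                            spectrum_widths=(5.0,),
                            spectrum_weights=(1.0,),
                        ),
                    ),
                )
            )
            continue

        n_peaks = len(slot_of[i])
        centers = np.asarray(slot_of[i]) + rng.uniform(-rt_jit, rt_jit, n_peaks)
        widths = rng.uniform(width_lo, width_hi, n_peaks)
        if is_plant:
            amps = rng.uniform(0.3, 1.0, n_peaks)
            amps[0] = rng.uniform(0.5, 1.0)
        else:
            amps = rng.uniform(0.3, 1.2, n_peaks)
        peaks = []
        for p in range(n_peaks):
            # the first peak is the profile's signature: lattice spectral center
            primary = sig_spec_centers[i] if p == 0 else random_primary_center()
            peaks.append(make_peak(centers[p], widths[p], amps[p], primary))
        # matrices share the formulation backbone (with modest
        # product-to-product abundance variation); reference plant powders
        # do not contain it
        if not is_plant:
            for bp in backbone:
                peaks.append(
                    CompoundPeak(
                        retention_center=bp.retention_center,
                        retention_width=bp.retention_width,
                        amplitude=bp.amplitude * float(rng.uniform(0.85, 1.15)),
                        spectrum_centers=bp.spectrum_centers,
                        spectrum_widths=bp.spectrum_widths,
                        spectrum_weights=bp.spectrum_weights,
                    )
                )
        profiles.append(
            PlantProfile(name=f"{kind}-{number:02d}", kind=kind, peaks=tuple(peaks))
        )
    return profiles


def simulate_dad_record(
    profiles_with_weights,
    config: SimConfig,
    jitter: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate one injection's (wavelength x time) absorbance slice.

    ``profiles_with_weights`` is a list of (PlantProfile, mass fraction);
    fractions must be >= 0 and sum to <= 1 (the remainder is a diluent that
    contributes only baseline).  The same seed always reproduces the same
    baseline and noise realization, independent of the profile list, so
    zero-noise mixtures are exactly linear in the mass fractions.
    """
    fracs = [float(f) for _, f in profiles_with_weights]
    if any(f < 0 for f in fracs):
        raise ValueError("mass fractions must be >= 0")
    if sum(fracs) > 1 + 1e-9:
        raise ValueError("mass fractions must sum to <= 1")

    lam = config.wavelength_grid
    t = config.time_grid
    signal = np.zeros((lam.size, t.size))
    for profile, frac in profiles_with_weights:
        for peak in profile.peaks:
            # evaluate the peak only within +-6 sigma (tail < 2e-8 of the
            # amplitude, far below the noise floor)
            mu = peak.retention_center + jitter
            i0 = int(np.searchsorted(t, mu - 6 * peak.retention_width))
            i1 = int(np.searchsorted(t, mu + 6 * peak.retention_width))
            if i0 >= i1:
                continue
            g_t = peak.temporal_profile(t[i0:i1], jitter)
            s_l = peak.spectral_factor(lam)
            eff = frac * peak.amplitude
            if config.extraction_cap_au is not None:
                # solubility-limited extraction: the recovered amount of a
                # constituent grows sub-linearly once its load approaches
                # the solvent's capacity, so a 1/2 trituration does not
                # yield 10x the peak of a 1/20 one.  None restores ideal
                # (linear) extraction.
                c = config.extraction_cap_au
                eff = c * (1.0 - np.exp(-eff / c))
            signal[:, i0:i1] += eff * np.outer(s_l, g_t)

    rng = np.random.default_rng(seed)
    coeff = rng.uniform(0.2, 1.0, 3)
    tt = t / t[-1] if t[-1] > 0 else t
    drift = coeff[0] + coeff[1] * tt + coeff[2] * tt**2
    drift = drift / drift.max()
    lam_decay = np.exp(-(lam - lam[0]) / 80.0)  # UV end absorbance
    baseline = config.baseline_drift_amp * np.outer(lam_decay, drift)
    absorbance = signal + baseline
    if config.saturation_au is not None:
        # detector response nonlinearity: DAD readings flatten as strong
        # bands approach the stray-light limit; monotone and concave, so
        # peak locations are preserved.  Disable (None) for an ideal
        # linear detector, under which mixtures are exactly linear in the
        # mass fractions.
        s = config.saturation_au
        absorbance = s * (1.0 - np.exp(-absorbance / s))
    noise = rng.normal(0.0, config.noise_sd, signal.shape) if config.noise_sd > 0 else 0.0
    return absorbance + noise


def _match_wavelengths(grid: np.ndarray, wanted) -> np.ndarray:
    idx = []
    for w in np.atleast_1d(wanted):
        hits = np.nonzero(np.abs(grid - w) <= 1e-9)[0]
        if hits.size == 0:
            raise ValueError(f"wavelength {w} nm is not on the simulation grid")
        idx.append(int(hits[0]))
    return np.array(sorted(set(idx)), dtype=int)


def simulate_study(
    library,
    target_plant: str | None,
    design: str,
    config: SimConfig,
    keep_wavelengths=None,
):
    """Simulate a full screening study.

    design='binary': 55 triturations of ``target_plant`` (each matrix x
    each spike ratio), 11 blanks, 1 pure reference; labels are 1 for
    records containing the target (triturations + reference) and 2 for
    blanks.  design='multiclass': per plant 55 triturations plus one
    reference (labels 1..n_plants by library order) and the blanks
    (label n_plants+1): 235 records under the default design.

    Each record draws an independent retention jitter and noise
    realization.  ``keep_wavelengths`` optionally restricts the returned
    cube to a channel subset; records are still generated on the full grid
    and sliced afterwards, so the random stream (and hence every retained
    value) is identical with or without the restriction.

    Returns ``(DataCube, labels)``; the labels are also attached to the cube.
    """
    plants = [p for p in library if p.kind == "plant"]
    matrices = [p for p in library if p.kind == "matrix"]
    if design not in ("binary", "multiclass"):
        raise ValueError("design must be 'binary' or 'multiclass'")
    if len(matrices) < config.n_matrices:
        raise ValueError(
            f"library has {len(matrices)} matrices, config needs {config.n_matrices}"
        )
    matrices = matrices[: config.n_matrices]
    by_name = {p.name: p for p in plants}

    records: list[tuple[list, int, str]] = []  # (mixture, label, id-suffix)
    if design == "binary":
        if target_plant is None:
            raise ValueError("binary design needs a target_plant")
        if target_plant not in by_name:
            raise ValueError(f"unknown plant {target_plant!r}")
        plant = by_name[target_plant]
        for m in matrices:
            for j, r in enumerate(config.spike_ratios):
                records.append(
                    ([(plant, r), (m, 1.0 - r)], 1, f"{plant.name}-{m.name}-r{j}")
                )
        for m in matrices:
            records.append(([(m, 1.0)], 2, f"blank-{m.name}"))
        records.append(([(plant, 1.0)], 1, f"{plant.name}-ref"))
    else:
        if len(plants) < 2:
            raise ValueError("multiclass design needs >= 2 plants in the library")
        blank_label = len(plants) + 1
        for k, plant in enumerate(plants):
            for m in matrices:
                for j, r in enumerate(config.spike_ratios):
                    records.append(
                        (
                            [(plant, r), (m, 1.0 - r)],
                            k + 1,
                            f"{plant.name}-{m.name}-r{j}",
                        )
                    )
        for m in matrices:
            records.append(([(m, 1.0)], blank_label, f"blank-{m.name}"))
        for k, plant in enumerate(plants):
            records.append(([(plant, 1.0)], k + 1, f"{plant.name}-ref"))

    n = len(records)
    master = np.random.default_rng(config.seed)
    record_seeds = master.integers(0, 2**31 - 1, n)
    jitters = master.normal(0.0, config.rt_jitter_sd, n)

    if keep_wavelengths is None:
        keep_idx = np.arange(config.wavelength_grid.size)
    else:
        keep_idx = _match_wavelengths(config.wavelength_grid, keep_wavelengths)

    values = np.empty((n, keep_idx.size, config.time_grid.size))
    labels = np.empty(n, dtype=int)
    ids = []
    for i, (mixture, label, suffix) in enumerate(records):
        rec = simulate_dad_record(
            mixture, config, jitter=float(jitters[i]), seed=int(record_seeds[i])
        )
        values[i] = rec[keep_idx]
        labels[i] = label
        ids.append(f"s{i:04d}-{suffix}")

    cube = DataCube(
        values=values,
        sample_ids=ids,
        wavelengths=config.wavelength_grid[keep_idx].copy(),
        times=config.time_grid.copy(),
        labels=labels,
    )
    return cube, labels


def default_study_library() -> list[PlantProfile]:
    """The packaged study materials: 4 reference plants and 11 blank
    matrices (the last a lactose stand-in).

    The library is a fixed set of profiles, mirroring the fixed physical
    reference materials of a screening study; simulation seeds vary only
    the measurement realization (noise, baselines, retention jitter).
    """
    return build_plant_library(4, 11, seed=1)
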