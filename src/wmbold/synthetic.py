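"""Forward simulation of the study conditions.

Generates every input the analysis pipeline needs, at the statistical
structure the analysis assumes, with no external data:

* a 3D parcellation with cortical GM parcels, pseudo-GM parcels
  (cerebellar / spinal stand-ins), and an interior WM region;
* streamlines with endpoints in designated parcel pairs, giving
  ground-truth association and projection bundles;
* per-bundle hemodynamic/metabolic feature tables in which the coupling
  identities CBF = CBV/MTT and CMRO2 = α·OEF·CBF hold exactly, with
  class-specific myelin water fractions (association 0.09±0.01,
  projection 0.12±0.02);
* resting-state BOLD series from the susceptibility forward model
  S(t) = S̄·(1 − TE·δR2*(t)) + ε with δR2*(t) = β·OEF(t)·CBV(t), where
  OEF(t) and CBV(t) are independent stationary AR(1)
  (Ornstein–Uhlenbeck-like) processes around the bundle means, CBV(t)
  additionally carries a narrowband component centred at 0.055 Hz (the
  characteristic low-frequency spectral bump), and optional sparse
  Poisson events convolved with an HRF kernel bearing an initial dip;
* z-scale moderation tables drawn from
  fALFF_z = β0 + β1·X_z + β2·M_z + β3·X_z·M_z + e;
* block-design task runs with a boxcar (or HRF-convolved) response.

All outputs are bit-reproducible given the same config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bundles import Parcellation
from .evoked import Paradigm
from .spectral import BoldSeries

__all__ = [
    "ConfigError",
    "HrfKernel",
    "SyntheticConfig",
    "StreamlineSet",
    "make_parcellation",
    "make_streamlines",
    "simulate_hemo_features",
    "simulate_bold",
    "simulate_voxel_block",
    "simulate_moderation_table",
    "simulate_task_run",
]


class ConfigError(ValueError):
    """A generator configuration violates its preconditions."""


@dataclass
class HrfKernel:
    """Hemodynamic response kernel with a parameterized initial dip.

    ``values`` has unit peak, starts at exactly 0, and its minimum over
    [0, peak_time_s) equals −dip_depth.
    """

    time_grid_s: np.ndarray
    values: np.ndarray
    dip_depth: float
    peak_time_s: float
    dip_time_s: float

    def __post_init__(self) -> None:
        self.time_grid_s = np.asarray(self.time_grid_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_grid_s[0] != 0 or np.any(np.diff(self.time_grid_s) <= 0):
            raise ValueError("time grid must increase from 0")
        if self.values[0] != 0:
            raise ValueError("kernel must start at 0")
        if self.dip_depth < 0:
            raise ValueError("dip_depth must be non-negative")
        if not (0 < self.dip_time_s < self.peak_time_s):
            raise ValueError("need 0 < dip_time_s < peak_time_s")

    @classmethod
    def double_gamma(
        cls,
        dip_depth: float = 0.25,
        dip_time_s: float = 2.0,
        peak_time_s: float = 6.0,
        undershoot_time_s: float = 16.0,
        undershoot_ratio: float = 0.1,
        duration_s: float = 30.0,
        dt_s: float = 0.1,
    ) -> "HrfKernel":
        """Canonical double-gamma response with an explicit pre-peak
        negative lobe scaled so the minimum before the peak is exactly
        −dip_depth."""
        t = np.arange(0.0, duration_s + dt_s / 2, dt_s)

        def gamma_bump(mode: float, shape: float) -> np.ndarray:
            theta = mode / (shape - 1.0)
            g = stats.gamma.pdf(t, a=shape, scale=theta)
            return g / g.max()

        base = gamma_bump(peak_time_s, 6.0) - undershoot_ratio * gamma_bump(
            undershoot_time_s, 12.0
        )
        base /= base.max()
        dip_lobe = gamma_bump(dip_time_s, 5.0)

        def normalized(c: float) -> np.ndarray:
            v = base - c * dip_lobe
            return v / v.max()

        if dip_depth == 0:
            values = base.copy()
        else:
            def objective(c: float) -> float:
                v = normalized(c)
                pre = t < t[np.argmax(v)]
                return float(v[pre].min()) + dip_depth

            c = optimize.brentq(objective, 0.0, 2.0, xtol=1e-12)
            values = normalized(c)
        peak_idx = int(np.argmax(values))
        pre = t < t[peak_idx]
        dip_idx = int(np.argmin(values[pre]))
        dip_time = float(t[dip_idx]) if dip_depth > 0 else dip_time_s
        return cls(
            time_grid_s=t,
            values=values,
            dip_depth=dip_depth,
            peak_time_s=float(t[peak_idx]),
            dip_time_s=dip_time,
        )

    def sampled(self, tr_s: float) -> np.ndarray:
        """Kernel resampled on a TR grid (linear interpolation)."""
        t = np.arange(0.0, self.time_grid_s[-1] + tr_s / 2, tr_s)
        return np.interp(t, self.time_grid_s, self.values)


@dataclass
class SyntheticConfig:
    """All generator parameters.  Defaults are the study conditions:
    TR 0.72 s, TE 33.1 ms, 1200 time points, 120 association + 40
    projection bundles, MWF 0.09±0.01 vs 0.12±0.02, spectral bump at
    0.055 Hz."""

    seed: int = 0
    # geometry
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    n_gm_parcels: int = 16
    n_pseudo_gm_parcels: int = 3
    parcel_size_vox: int = 3
    streamlines_per_bundle: int = 8
    # bundle populations
    n_assoc_bundles: int = 120
    n_proj_bundles: int = 40
    # myelin water fraction, class-specific Gaussians
    mwf_assoc_mean: float = 0.09
    mwf_assoc_sd: float = 0.01
    mwf_proj_mean: float = 0.12
    mwf_proj_sd: float = 0.02
    # hemodynamic means / between-bundle SDs (CBV relative units, MTT s)
    cbv_mean: float = 2.0
    cbv_sd: float = 0.3
    mtt_mean: float = 4.0
    mtt_sd: float = 0.5
    oef_mean: float = 0.4
    oef_sd: float = 0.05
    # coupling and susceptibility coefficients
    alpha: float = 1.0
    beta_suscept: float = 1.0
    # acquisition
    te_s: float = 0.0331
    tr_s: float = 0.72
    n_timepoints: int = 1200
    baseline: float = 1000.0
    # within-bundle temporal fluctuations (AR(1) around the means)
    oef_fluct_sd: float = 0.01
    cbv_fluct_sd: float = 0.05
    fluct_tau_s: float = 10.0
    # narrowband spectral bump injected into CBV(t)
    bump_freq_hz: float = 0.055
    bump_width_hz: float = 0.005
    bump_amp: float = 0.05
    # thermal noise (fraction of baseline)
    noise_sd: float = 0.002
    # sparse spontaneous events convolved with the HRF kernel
    hrf: HrfKernel | None = None
    event_rate_hz: float = 0.05
    event_amp_pct: float = 0.0
    # moderation generator: (β0, β1, β2, β3) and residual SD
    moderation_truth: tuple[float, float, float, float] | None = None
    moderation_resid_sd: float = 0.5
    moderation_corr: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ConfigError("grid_shape must be 3 positive integers")
        for name in ("voxel_size_mm", "alpha", "beta_suscept", "te_s", "tr_s",
                     "bump_freq_hz", "bump_width_hz", "baseline",
                     "fluct_tau_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("mwf_assoc_sd", "mwf_proj_sd", "cbv_sd", "mtt_sd",
                     "oef_sd", "oef_fluct_sd", "cbv_fluct_sd", "noise_sd",
                     "bump_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("mwf_assoc_mean", "mwf_proj_mean"):
            if not (0 < getattr(self, name) < 1):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.n_assoc_bundles < 0 or self.n_proj_bundles < 0:
            raise ConfigError("bundle counts must be non-negative")
        if self.n_timepoints <= 0:
            raise ConfigError("n_timepoints must be positive")
        # linearization bound: TE * max plausible δR2* must stay small
        oef_hi = min(self.oef_mean + 4 * (self.oef_sd + self.oef_fluct_sd), 1.0)
        cbv_hi = self.cbv_mean + 4 * (self.cbv_sd + self.cbv_fluct_sd + self.bump_amp)
        worst = self.te_s * self.beta_suscept * oef_hi * cbv_hi
        if worst >= 0.1:
            raise ConfigError(
                f"linearization violated: TE*beta*OEF*CBV can reach {worst:.3f} >= 0.1"
            )

    def hrf_kernel(self) -> HrfKernel:
        return self.hrf if self.hrf is not None else HrfKernel.double_gamma()

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for a named sub-stream of this config's seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        if self.hrf is not None:
            d["hrf"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(self.hrf).items()
            }
        d["grid_shape"] = list(self.grid_shape)
        if self.moderation_truth is not None:
            d["moderation_truth"] = list(self.moderation_truth)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        if d.get("hrf") is not None:
            d["hrf"] = HrfKernel(
                time_grid_s=np.asarray(d["hrf"]["time_grid_s"]),
                values=np.asarray(d["hrf"]["values"]),
                dip_depth=d["hrf"]["dip_depth"],
                peak_time_s=d["hrf"]["peak_time_s"],
                dip_time_s=d["hrf"]["dip_time_s"],
            )
        d["grid_shape"] = tuple(d["grid_shape"])
        if d.get("moderation_truth") is not None:
            d["moderation_truth"] = tuple(d["moderation_truth"])
        return cls(**d)


@dataclass
class StreamlineSet:
    """Generated streamlines with their ground-truth bundle assignment."""

    streamlines: list[np.ndarray]
    bundle_of_streamline: np.ndarray  # bundle index per streamline
    pairs: list[frozenset[int]]  # parcel pair per bundle
    kinds: list[str]  # "association"/"projection" per bundle

    def __len__(self) -> int:
        return len(self.streamlines)


# ---------------------------------------------------------------------------
# parcellation and streamlines


def make_parcellation(config: SyntheticConfig) -> Parcellation:
    """Deterministic toy parcellation: cortical GM cubes on the left/right
    faces of the grid, pseudo-GM cubes on the inferior face, and an
    interior WM region labelled distinctly.

    Raises a sizing ``ConfigError`` when the grid cannot host the
    requested number of parcels.
    """
    nx, ny, nz = config.grid_shape
    s = config.parcel_size_vox
    gap = 1

    def anchors_1d(extent: int, start: int = 1) -> list[int]:
        return list(range(start, extent - s, s + gap))

    # GM sites on the two x faces, keeping the bottom slab free for pseudo-GM
    gm_sites: list[tuple[slice, slice, slice]] = []
    z0 = s + 2 * gap + 1  # above the pseudo-GM slab
    for x_face in (slice(1, 1 + s), slice(nx - 1 - s, nx - 1)):
        for y in anchors_1d(ny):
            for z in anchors_1d(nz, start=z0):
                gm_sites.append((x_face, slice(y, y + s), slice(z, z + s)))
    pseudo_sites = [
        (slice(x, x + s), slice(y, y + s), slice(1, 1 + s))
        for x in anchors_1d(nx, start=s + 2)
        for y in anchors_1d(ny)
    ]
    n_gm, n_pseudo = config.n_gm_parcels, config.n_pseudo_gm_parcels
    if len(gm_sites) < n_gm or len(pseudo_sites) < n_pseudo:
        raise ConfigError(
            f"grid {config.grid_shape} too small for {n_gm} GM + "
            f"{n_pseudo} pseudo-GM parcels of size {s}"
        )
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    # interleave the two faces so consecutive labels sit on opposite sides
    order = sorted(range(len(gm_sites)), key=lambda i: (i % 2, i))
    for lab, i in enumerate(order[:n_gm], start=1):
        labels[gm_sites[i]] = lab
    pseudo_labels = []
    for k, site in enumerate(pseudo_sites[:n_pseudo]):
        lab = n_gm + 1 + k
        labels[site] = lab
        pseudo_labels.append(lab)
    wm_label = n_gm + n_pseudo + 1
    interior = labels == 0
    interior[0, :, :] = interior[-1, :, :] = False
    interior[:, 0, :] = interior[:, -1, :] = False
    interior[:, :, 0] = interior[:, :, -1] = False
    labels[interior] = wm_label
    vs = config.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    return Parcellation(
        labels=labels,
        affine=affine,
        pseudo_gm_labels=frozenset(pseudo_labels),
        wm_label=wm_label,
    )


def _random_point_in_parcel(
    parc: Parcellation, label: int, rng: np.random.Generator
) -> np.ndarray:
    vox = np.argwhere(parc.labels == label)
    center = vox[rng.integers(len(vox))]
    return parc.voxel_to_world(center)[0]


def make_streamlines(
    config: SyntheticConfig, parc: Parcellation
) -> StreamlineSet:
    """Streamlines whose endpoints lie inside designated parcel pairs.

    Association bundles connect distinct cortical GM parcels; projection
    bundles connect a cortical parcel to a pseudo-GM parcel.  Each
    streamline is a jittered quadratic arc between random voxel centres
    of its two parcels, resampled so consecutive points are no farther
    apart than the voxel size.
    """
    rng = config.rng(stream=1)
    gm = sorted(parc.parcel_labels - parc.pseudo_gm_labels)
    pseudo = sorted(parc.pseudo_gm_labels)
    assoc_pairs = [
        frozenset((a, b)) for i, a in enumerate(gm) for b in gm[i + 1 :]
    ]
    proj_pairs = [frozenset((a, p)) for a in gm for p in pseudo]
    if config.n_assoc_bundles > len(assoc_pairs):
        raise ConfigError(
            f"only {len(assoc_pairs)} association pairs available, "
            f"{config.n_assoc_bundles} requested"
        )
    if config.n_proj_bundles > len(proj_pairs):
        raise ConfigError(
            f"only {len(proj_pairs)} projection pairs available, "
            f"{config.n_proj_bundles} requested"
        )
    pairs = assoc_pairs[: config.n_assoc_bundles]
    kinds = ["association"] * len(pairs)
    pairs += proj_pairs[: config.n_proj_bundles]
    kinds += ["projection"] * config.n_proj_bundles

    step = config.voxel_size_mm * 0.5
    streamlines: list[np.ndarray] = []
    owner: list[int] = []
    jitter_sd = config.voxel_size_mm * 1.5
    for b, pair in enumerate(pairs):
        la, lb = sorted(pair)
        for _ in range(config.streamlines_per_bundle):
            p0 = _random_point_in_parcel(parc, la, rng)
            p1 = _random_point_in_parcel(parc, lb, rng)
            mid = 0.5 * (p0 + p1) + rng.normal(0.0, jitter_sd, size=3)
            # quadratic Bezier, sampled finely then resampled to `step`
            t = np.linspace(0.0, 1.0, 64)[:, None]
            arc = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * mid + t**2 * p1
            seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
            arclen = np.concatenate([[0.0], np.cumsum(seg)])
            n_pts = max(int(np.ceil(arclen[-1] / step)) + 1, 2)
            grid = np.linspace(0.0, arclen[-1], n_pts)
            pts = np.column_stack(
                [np.interp(grid, arclen, arc[:, d]) for d in range(3)]
            )
            pts[0], pts[-1] = p0, p1  # endpoints exactly at parcel voxel centres
            streamlines.append(pts)
            owner.append(b)
    return StreamlineSet(
        streamlines=streamlines,
        bundle_of_streamline=np.array(owner, dtype=int),
        pairs=pairs,
        kinds=kinds,
    )


# ---------------------------------------------------------------------------
# feature tables


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    size: int,
    lo: float = 0.0,
    hi: float = np.inf,
) -> np.ndarray:
    """Gaussian draws with out-of-range values resampled (not clipped)."""
    if sd == 0:
        out = np.full(size, mean)
        if np.any((out <= lo) | (out >= hi)):
            raise ConfigError(f"degenerate mean {mean} outside ({lo}, {hi})")
        return out
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def simulate_hemo_features(config: SyntheticConfig) -> pd.DataFrame:
    """Per-bundle hemodynamic feature table.

    CBV, MTT and OEF are drawn from the configured (truncated) Gaussians;
    CBF and CMRO2 are *computed* from the identities CBF = CBV/MTT and
    CMRO2 = α·OEF·CBF so the couplings hold exactly.  MWF comes from the
    class-specific Gaussian (association vs projection).
    """
    rng = config.rng(stream=2)
    n_a, n_p = config.n_assoc_bundles, config.n_proj_bundles
    n = n_a + n_p
    kind = np.array(["association"] * n_a + ["projection"] * n_p)
    cbv = _truncated_normal(rng, config.cbv_mean, config.cbv_sd, n)
    mtt = _truncated_normal(rng, config.mtt_mean, config.mtt_sd, n)
    if config.oef_sd == 0 and config.oef_mean == 0:
        oef = np.zeros(n)  # degenerate-at-zero case: CMRO2 identically 0
    else:
        oef = _truncated_normal(rng, config.oef_mean, config.oef_sd, n, lo=0.0, hi=1.0)
    mwf = np.empty(n)
    mwf[:n_a] = _truncated_normal(rng, config.mwf_assoc_mean, config.mwf_assoc_sd,
                                  n_a, lo=0.0, hi=1.0)
    mwf[n_a:] = _truncated_normal(rng, config.mwf_proj_mean, config.mwf_proj_sd,
                                  n_p, lo=0.0, hi=1.0)
    cbf = cbv / mtt
    cmro2 = config.alpha * oef * cbf
    df = pd.DataFrame(
        dict(
            bundle_id=np.arange(n),
            kind=kind,
            mwf=mwf,
            cbv=cbv,
            mtt=mtt,
            oef=oef,
            cbf=cbf,
            cmro2=cmro2,
        )
    )
    df.attrs["alpha"] = config.alpha
    df.attrs["beta_suscept"] = config.beta_suscept
    return df


# ---------------------------------------------------------------------------
# BOLD forward model


def _ar1(
    rng: np.random.Generator, n: int, sd: float, tau_s: float, dt_s: float
) -> np.ndarray:
    """Stationary AR(1) (discretized Ornstein–Uhlenbeck) with exact
    marginal SD ``sd`` and correlation time ``tau_s``."""
    if sd == 0:
        return np.zeros(n)
    phi = np.exp(-dt_s / tau_s)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    w = rng.normal(0.0, innov_sd, n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + w[t - 1]
    return x


def _narrowband(
    rng: np.random.Generator,
    n: int,
    dt_s: float,
    f0_hz: float,
    width_hz: float,
    sd: float,
) -> np.ndarray:
    """Gaussian-envelope narrowband noise centred at ``f0_hz``,
    rescaled to marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt_s)
    h = np.exp(-0.5 * ((freqs - f0_hz) / width_hz) ** 2)
    x = np.fft.irfft(spec * h, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _poisson_train(
    rng: np.random.Generator, n: int, dt_s: float, rate_hz: float
) -> np.ndarray:
    """Homogeneous Poisson event train on the sampling grid (0/1 counts)."""
    return (rng.random(n) < rate_hz * dt_s).astype(float)


def simulate_bold(
    features: pd.Series | dict,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    return_components: bool = False,
):
    """Resting-state BOLD series for one bundle.

    OEF(t) and CBV(t) fluctuate as independent AR(1) processes around the
    bundle means; CBV(t) additionally carries the narrowband 0.055-Hz
    component.  δR2*(t) = β·OEF(t)·CBV(t) enters the signal through the
    linearized susceptibility model, sparse HRF-convolved events are
    added in fractional signal units when ``event_amp_pct > 0``, and
    i.i.d. Gaussian thermal noise is added last.  The returned series
    stores the true baseline S̄, so inverting with
    :func:`wmbold.biophys.delta_r2star_from_signal` recovers δR2* exactly
    in the noise-free case.

    Raises ``ConfigError`` when TE·max|δR2*| breaches the linearization
    bound, naming the offending product.
    """
    if rng is None:
        rng = config.rng(stream=3)
    row = features if isinstance(features, dict) else features.to_dict()
    n, dt = config.n_timepoints, config.tr_s
    oef_t = row["oef"] + _ar1(rng, n, config.oef_fluct_sd, config.fluct_tau_s, dt)
    cbv_t = (
        row["cbv"]
        + _ar1(rng, n, config.cbv_fluct_sd, config.fluct_tau_s, dt)
        + _narrowband(rng, n, dt, config.bump_freq_hz, config.bump_width_hz,
                      config.bump_amp)
    )
    dr2 = config.beta_suscept * oef_t * cbv_t
    worst = config.te_s * float(np.abs(dr2).max())
    if worst >= 0.1:
        raise ConfigError(
            f"linearization violated: TE*beta*OEF(t)*CBV(t) reaches {worst:.3f} >= 0.1"
        )
    event_signal = np.zeros(n)
    if config.event_amp_pct > 0:
        train = _poisson_train(rng, n, dt, config.event_rate_hz)
        kernel = config.hrf_kernel().sampled(dt)
        event_signal = np.convolve(train, kernel)[:n] * (config.event_amp_pct / 100.0)
    s_bar = config.baseline
    values = s_bar * (1.0 - config.te_s * dr2 + event_signal)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd * s_bar, n)
    series = BoldSeries(values=values, tr_s=dt, te_s=config.te_s, baseline=s_bar)
    if return_components:
        return series, dict(oef_t=oef_t, cbv_t=cbv_t, dr2_t=dr2,
                            event_signal=event_signal)
    return series


def simulate_voxel_block(
    features: pd.Series | dict,
    config: SyntheticConfig,
    n_voxels: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n_voxels, n_timepoints) block sharing one bundle signal plus
    i.i.d. voxel noise at the configured noise SD."""
    if rng is None:
        rng = config.rng(stream=4)
    clean_cfg = replace(config, noise_sd=0.0)
    series = simulate_bold(features, clean_cfg, rng=rng)
    noise = rng.normal(0.0, config.noise_sd * config.baseline,
                       (n_voxels, config.n_timepoints))
    return series.values[None, :] + noise


# ---------------------------------------------------------------------------
# moderation tables and task runs


def simulate_moderation_table(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Bundle table drawn from the interaction model on the z-scale:

        fALFF_z = β0 + β1·X_z + β2·M_z + β3·X_z·M_z + e

    X_z and M_z are standard normal (correlated by ``moderation_corr``
    when configured) and e ~ Normal(0, moderation_resid_sd).  Row count
    is n_assoc_bundles + n_proj_bundles.  Because the columns are
    generated directly on the z-scale, fit them with
    ``fit_moderation(..., z_score=False)`` to recover the coefficients.
    """
    if config.moderation_truth is None:
        raise ConfigError("moderation_truth must be set")
    if rng is None:
        rng = config.rng(stream=5)
    b0, b1, b2, b3 = config.moderation_truth
    n = config.n_assoc_bundles + config.n_proj_bundles
    x = rng.standard_normal(n)
    r = config.moderation_corr
    m = r * x + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n)
    e = rng.normal(0.0, config.moderation_resid_sd, n) if config.moderation_resid_sd > 0 else np.zeros(n)
    y = b0 + b1 * x + b2 * m + b3 * x * m + e
    return pd.DataFrame(dict(falff_z=y, predictor_z=x, mwf_z=m))


def simulate_task_run(
    config: SyntheticConfig,
    paradigm: Paradigm,
    amplitude_pct: float = 1.0,
    noise_sd: float | None = None,
    convolve_hrf: bool = False,
    rng: np.random.Generator | None = None,
) -> BoldSeries:
    """Block-design task run with a block-locked response.

    The response is a boxcar of ``amplitude_pct`` percent of baseline
    during the stimulus-on portion of each block (HRF-convolved when
    requested) and baseline during rests and blank tails.  Paradigm
    timing is validated by the :class:`~wmbold.evoked.Paradigm` itself.
    """
    if rng is None:
        rng = config.rng(stream=6)
    if noise_sd is None:
        noise_sd = config.noise_sd
    box = paradigm.stimulus_mask().astype(float)
    if convolve_hrf:
        kernel = config.hrf_kernel().sampled(paradigm.tr_s)
        resp = np.convolve(box, kernel)[: paradigm.n_timepoints]
        peak = np.abs(resp).max()
        if peak > 0:
            resp = resp / peak
    else:
        resp = box
    s_bar = config.baseline
    values = s_bar * (1.0 + (amplitude_pct / 100.0) * resp)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd * s_bar, paradigm.n_timepoints)
    return BoldSeries(values=values, tr_s=paradigm.tr_s, te_s=config.te_s,
                      baseline=s_bar)
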