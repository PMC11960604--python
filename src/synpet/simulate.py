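"""Synthetic dynamic-PET data: plasma input, tissue curves, cohorts, phantoms.

Everything the quantification pipeline consumes can be generated here,
with ground truth attached, so the package is testable end to end
without any acquired scans.

The forward model is deliberately simple and fully known:

* a tri-exponential-with-ramp plasma input (Feng model),
* one-tissue-compartment (1TC) tissue responses
  ``CT = K1 * [exp(-k2 t) conv Cp]``,
* frame values reported as interval averages, the way scanners bin
  counts (midpoint sampling available as an option),
* Gaussian frame noise with variance shrinking with frame duration.

Because both target and reference tissues are 1TC with a shared input,
SRTM holds exactly for the generating reference region, and the ground
truth DVR of a target is ``(K1/k2) / (K1'/k2')``.  Candidate reference
regions other than the generating one are mixtures of two 1TC
components, which breaks the single-compartment assumption and degrades
SRTM2 fit quality — emulating the real situation where only one
candidate's kinetics match the model.

Radioactive decay is not modeled: frame data are assumed decay-corrected,
as reconstructed PET conventionally is.

Every stochastic operation is a pure function of (inputs, seed); all
per-subject / per-region streams are spawned deterministically from the
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .frames import FrameSchedule, TimeActivityCurve, default_schedule, parse_frame_schedule
from .images import DynamicImage
from .regions import DK_CORTICAL_NAMES, cortical_roi_table

__all__ = [
    "InputFunctionParams",
    "CohortConfig",
    "SyntheticCohort",
    "feng_input",
    "simulate_tissue_tac",
    "add_tac_noise",
    "simulate_cohort",
    "generate_phantom",
    "pvc_acceptance_phantom",
]

FINE_DT = 0.05  # min

REFERENCE_REGIONS = ("cereb_gm", "cereb_whole", "wm_eroded")


@dataclass(frozen=True)
class InputFunctionParams:
    """Feng-style plasma model: zero before the delay ``tau``, then a
    linear ramp times a fast exponential plus two slow washout
    exponentials, continuous at ``tau``:

    Cp(t) = (A1*(t-tau) - A2 - A3) e^{-l1 (t-tau)}
            + A2 e^{-l2 (t-tau)} + A3 e^{-l3 (t-tau)}.

    Rates must be ordered ``l1 > l2 > l3 > 0``.  Amplitudes are in the
    same arbitrary activity units as the tissue curves.
    """

    tau: float = 0.7
    a1: float = 851.1
    a2: float = 21.9
    a3: float = 20.8
    l1: float = 4.134
    l2: float = 0.119
    l3: float = 0.0104
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 > 0):
            raise ValueError("rate constants must satisfy l1 > l2 > l3 > 0")
        if self.tau < 0:
            raise ValueError("delay tau must be nonnegative")
        t = np.linspace(0.0, 90.0, 1801)
        if np.any(feng_input(self, t, _validate=False) < -1e-9):
            raise ValueError("plasma curve must be nonnegative on [0, 90] min")


def feng_input(params: InputFunctionParams, times, _validate: bool = True) -> np.ndarray:
    """Evaluate the plasma input at ``times`` (minutes)."""
    t = np.asarray(times, float)
    if _validate and np.any(t < 0):
        raise ValueError("times must be nonnegative")
    s = t - params.tau
    pos = s > 0
    out = np.zeros_like(t)
    sp = s[pos]
    out[pos] = ((params.a1 * sp - params.a2 - params.a3) * np.exp(-params.l1 * sp)
                + params.a2 * np.exp(-params.l2 * sp)
                + params.a3 * np.exp(-params.l3 * sp))
    return params.scale * out


def _conv_exp(curve_fine: np.ndarray, k: float, dt: float) -> np.ndarray:
    """[curve conv exp(-k t)] on a uniform grid (trapezoid increments)."""
    a = float(np.exp(-k * dt))
    b = np.empty_like(curve_fine)
    b[0] = 0.0
    b[1:] = 0.5 * dt * (a * curve_fine[:-1] + curve_fine[1:])
    return signal.lfilter([1.0], [1.0, -a], b)


def _frame_average(t_fine: np.ndarray, c_fine: np.ndarray,
                   schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval."""
    dt = t_fine[1] - t_fine[0]
    running = np.concatenate([[0.0], np.cumsum(dt * (c_fine[:-1] + c_fine[1:]) / 2.0)])
    starts, ends = schedule.frame_edges_minutes()
    f0 = np.interp(starts, t_fine, running)
    f1 = np.interp(ends, t_fine, running)
    return (f1 - f0) / (ends - starts)


def simulate_tissue_tac(k1: float, k2: float, plasma,
                        schedule: FrameSchedule,
                        frame_mode: str = "average") -> TimeActivityCurve:
    """One-tissue-compartment tissue curve on a frame schedule.

    ``CT = K1 * [exp(-k2 t) conv Cp]`` evaluated on a 0.05-min grid,
    then either averaged over each frame interval (default, matching how
    scanners report frames) or sampled at frame midpoints.  ``plasma``
    is an :class:`InputFunctionParams` or any callable mapping minutes
    to activity.
    """
    if k1 < 0 or k2 <= 0:
        raise ValueError("require K1 >= 0 and k2 > 0")
    t_end = schedule.total_minutes
    t_fine = np.arange(0.0, t_end + FINE_DT / 2, FINE_DT)
    cp = plasma(t_fine) if callable(plasma) else feng_input(plasma, t_fine)
    ct_fine = k1 * _conv_exp(cp, k2, FINE_DT)
    if frame_mode == "average":
        vals = _frame_average(t_fine, ct_fine, schedule)
    elif frame_mode == "midpoint":
        vals = np.interp(schedule.mid_times(), t_fine, ct_fine)
    else:
        raise ValueError(f"unknown frame_mode {frame_mode!r}")
    return TimeActivityCurve.from_schedule(schedule, vals)


def _mixture_tac(components, plasma, schedule, frame_mode="average") -> np.ndarray:
    vals = np.zeros(len(schedule))
    for frac, k1, k2 in components:
        vals += frac * simulate_tissue_tac(k1, k2, plasma, schedule, frame_mode).values
    return vals


def add_tac_noise(tac: TimeActivityCurve, schedule: FrameSchedule, sigma0: float,
                  seed) -> TimeActivityCurve:
    """Add frame noise with SD = sigma0 * sqrt(max(value, eps) / duration_min).

    Variance grows with count rate and shrinks with frame duration — the
    usual first-order model for reconstructed PET frame noise.  The same
    seed always reproduces the same curve.
    """
    if sigma0 < 0:
        raise ValueError("sigma0 must be nonnegative")
    if sigma0 == 0:
        return TimeActivityCurve.from_schedule(schedule, tac.values.copy(), name=tac.name)
    rng = np.random.default_rng(seed)
    dur_min = schedule.durations / 60.0
    sd = sigma0 * np.sqrt(np.maximum(tac.values, 1e-3) / dur_min)
    noisy = tac.values + rng.normal(0.0, 1.0, size=len(tac)) * sd
    return TimeActivityCurve.from_schedule(schedule, noisy, name=tac.name)


@dataclass
class CohortConfig:
    """Study conditions for the simulated three-group cohort.

    Defaults mirror the study design the package targets: 7 young (Y),
    14 cognitively normal older (O) and 7 patients, scanned on the
    35-frame / 90-min schedule; group-graded cortical binding with the
    highest uptake in Y and the lowest in patients.
    """

    n_young: int = 7
    n_old: int = 14
    n_patient: int = 7
    schedule_spec: str = "4x15,8x30,9x60,2x180,10x300,2x600"
    sigma0: float = 0.15
    seed: int = 0
    # generating reference kinetics (per min)
    ref_k1: float = 0.3
    ref_k2: float = 0.055
    # cortical apparent efflux range (per min) and baseline DVR range
    k2_range: tuple[float, float] = (0.02, 0.08)
    dvr_range: tuple[float, float] = (1.5, 2.3)
    dvr_multipliers: dict = field(default_factory=lambda: {"Y": 1.0, "O": 0.9, "patient": 0.75})
    # between-subject kinetic variability (lognormal SDs)
    subject_k1_sd: float = 0.10
    subject_k2p_sd: float = 0.05
    # plasma scaling so late reference activity lands near typical SUV units
    plasma_scale: float = 0.072
    # gray-matter tissue fraction per group (partial-volume dilution of
    # observed regional values)
    gm_fraction: dict = field(default_factory=lambda: {"Y": 0.95, "O": 0.88, "patient": 0.80})
    gm_fraction_sd: float = 0.02
    # demographics / outcome models
    age_mean_sd: dict = field(default_factory=lambda: {
        "Y": (26.1, 3.8), "O": (80.2, 4.4), "patient": (66.4, 7.5)})
    vol_mean_sd: dict = field(default_factory=lambda: {
        "Y": (0.021, 0.001), "O": (0.019, 0.001), "patient": (0.016, 0.0015)})
    # MMSE = b0 + bv*z(vol) + bu*z(uptake) + bint*z(vol)*z(uptake) + ba*z(age) + noise
    mmse_coefs: tuple[float, float, float, float, float] = (27.5, 1.5, 1.2, -1.0, -0.5)
    mmse_noise_sd: float = 0.8
    # centiloid = c0 + c1*global_uptake + noise, amyloid-positive subset only
    centiloid_coefs: tuple[float, float] = (170.0, -75.0)
    centiloid_noise_sd: float = 8.0
    n_abeta_pos_old: int = 6
    n_abeta_pos_patient: int = 6
    # spatial tau-vs-SV2A anticorrelation per group
    tau_rho: dict = field(default_factory=lambda: {"Y": 0.0, "O": 0.0, "patient": -0.5})

    def schedule(self) -> FrameSchedule:
        return parse_frame_schedule(self.schedule_spec)


#: cortical region set simulated for every subject (the 34 bilateral
#: cortical parcels plus the bilateral amygdala for the temporal meta-ROI)
COHORT_ROI_NAMES: tuple[str, ...] = DK_CORTICAL_NAMES + ("amygdala",)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    age: float
    mmse: float
    meta_volume_norm: float
    abeta_positive: bool
    centiloid: float
    reference_tacs: dict
    cortical_tacs: dict  # "lh_<name>" / "rh_<name>" -> TimeActivityCurve
    k1p: float
    k2p: float


@dataclass
class SyntheticCohort:
    """Simulated TACs plus the ground truth that generated them."""

    config: CohortConfig
    schedule: FrameSchedule
    subjects: list
    ground_truth: pd.DataFrame       # per subject x region kinetics and DVR
    demographics: pd.DataFrame       # per subject covariates and outcomes
    tau: pd.DataFrame                # per subject x cortical ROI tau SUVR
    volumes: pd.DataFrame            # per subject x region volume_mm3

    def subject(self, subject_id: str) -> SyntheticSubject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    # ---- serialization ----------------------------------------------
    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.17g"
        rows = []
        for s in self.subjects:
            for region, tac in {**{f"ref_{k}": v for k, v in s.reference_tacs.items()},
                                **s.cortical_tacs}.items():
                rows.append({"subject_id": s.subject_id, "region": region,
                             **{f"f{j}": v for j, v in enumerate(tac.values)}})
        pd.DataFrame(rows).to_csv(out / "tacs.tsv", sep="\t", index=False,
                                  float_format=fmt)
        self.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                                 float_format=fmt)
        self.demographics.to_csv(out / "demographics.tsv", sep="\t", index=False,
                                 float_format=fmt)
        self.tau.to_csv(out / "tau.tsv", sep="\t", index=False, float_format=fmt)
        self.volumes.to_csv(out / "volumes.tsv", sep="\t", index=False,
                            float_format=fmt)
        self.schedule.to_sidecar(out / "frame_timing.json")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)


def read_cohort_tables(indir) -> dict[str, pd.DataFrame]:
    """Read back the serialized cohort tables losslessly.

    Uses round-trip float parsing so that write -> read reproduces the
    exact binary values.
    """
    import pathlib
    ind = pathlib.Path(indir)
    return {name: pd.read_csv(ind / f"{name}.tsv", sep="\t",
                              float_precision="round_trip")
            for name in ("tacs", "ground_truth", "demographics", "tau", "volumes")}


def _spawn(master_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=keys))


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort with ground truth.

    Per subject: three candidate reference-region TACs (``cereb_gm`` is
    the generating 1TC reference; ``cereb_whole`` and ``wm_eroded`` are
    two-component mixtures with perturbed kinetics), 70 regional target
    TACs (34 bilateral cortical parcels + bilateral amygdala) with
    group-scaled DVR, frame noise, and a demographics row whose MMSE is
    drawn from a linear model with a volume-by-uptake interaction.
    """
    cfg = config or CohortConfig()
    schedule = cfg.schedule()
    plasma = InputFunctionParams(scale=cfg.plasma_scale)
    groups = (["Y"] * cfg.n_young + ["O"] * cfg.n_old + ["patient"] * cfg.n_patient)

    roi_rng = _spawn(cfg.seed, 0)
    n_roi = len(COHORT_ROI_NAMES)
    base_dvr = roi_rng.uniform(*cfg.dvr_range, size=n_roi)
    roi_k2 = roi_rng.uniform(*cfg.k2_range, size=n_roi)

    base_vol = cortical_roi_table()
    vol_lookup = dict(zip(zip(base_vol["hemisphere"], base_vol["roi_name"]),
                          base_vol["volume_mm3"]))
    for hemi in ("lh", "rh"):
        vol_lookup[(hemi, "amygdala")] = 1700.0

    # amyloid positivity assignment (first k of each eligible group)
    old_ids = [i for i, g in enumerate(groups) if g == "O"]
    pat_ids = [i for i, g in enumerate(groups) if g == "patient"]
    abeta_pos = set(old_ids[:cfg.n_abeta_pos_old] + pat_ids[:cfg.n_abeta_pos_patient])

    subjects: list[SyntheticSubject] = []
    truth_rows, demo_rows, tau_rows, vol_rows = [], [], [], []

    for si, group in enumerate(groups):
        rng = _spawn(cfg.seed, 1, si)
        sid = f"sub-{si + 1:03d}"
        k1p = cfg.ref_k1 * np.exp(rng.normal(0, cfg.subject_k1_sd))
        k2p = cfg.ref_k2 * np.exp(rng.normal(0, cfg.subject_k2p_sd))
        dv_ref = k1p / k2p

        # candidate reference regions; only cereb_gm generates the
        # cortical data (1TC, shared input).  The alternates are
        # two-component tissue mixtures — mixing proportions and
        # component kinetics vary more between subjects than the
        # homogeneous gray-matter region does, as heterogeneous regions
        # do anatomically — so they are both worse-fitting under the
        # single-compartment model and less stable across the cohort.
        frac_cw = float(np.clip(rng.normal(0.75, 0.08), 0.5, 0.95))
        wm_k1 = 0.10 * np.exp(rng.normal(0, 0.25))
        wm_k2 = 0.030 * np.exp(rng.normal(0, 0.20))
        frac_wm = float(np.clip(rng.normal(0.55, 0.10), 0.3, 0.8))
        ref_defs = {
            "cereb_gm": [(1.0, k1p, k2p)],
            "cereb_whole": [(frac_cw, k1p, k2p), (1.0 - frac_cw, wm_k1, wm_k2)],
            "wm_eroded": [(frac_wm, 0.085 * np.exp(rng.normal(0, 0.25)), wm_k2),
                          (1.0 - frac_wm, 0.065 * np.exp(rng.normal(0, 0.25)), 0.012)],
        }
        reference_tacs = {}
        for ri, (rname, comps) in enumerate(ref_defs.items()):
            clean = _mixture_tac(comps, plasma, schedule)
            tac = TimeActivityCurve.from_schedule(schedule, clean, name=rname)
            reference_tacs[rname] = add_tac_noise(
                tac, schedule, cfg.sigma0, _spawn(cfg.seed, 2, si, ri))

        gmult = cfg.dvr_multipliers[group]
        subj_scale = np.exp(rng.normal(0, 0.03))
        cortical_tacs = {}
        dvr_true_by_key = {}
        for ni, name in enumerate(COHORT_ROI_NAMES):
            for hi, hemi in enumerate(("lh", "rh")):
                key = f"{hemi}_{name}"
                dvr = base_dvr[ni] * gmult * subj_scale * np.exp(rng.normal(0, 0.02))
                k2 = roi_k2[ni]
                k1 = dvr * dv_ref * k2
                clean = simulate_tissue_tac(k1, k2, plasma, schedule)
                clean.name = key
                gm_frac = float(np.clip(
                    cfg.gm_fraction[group] + rng.normal(0, cfg.gm_fraction_sd), 0.5, 1.0))
                cortical_tacs[key] = add_tac_noise(
                    clean, schedule, cfg.sigma0, _spawn(cfg.seed, 3, si, ni, hi))
                dvr_true_by_key[key] = dvr
                vol = vol_lookup[(hemi, name)] * np.exp(rng.normal(0, 0.08))
                truth_rows.append({"subject_id": sid, "group": group, "region": key,
                                   "roi_name": name, "hemisphere": hemi,
                                   "K1": k1, "k2": k2, "dvr_true": dvr,
                                   "gm_fraction": gm_frac})
                vol_rows.append({"subject_id": sid, "region": key, "roi_name": name,
                                 "hemisphere": hemi, "volume_mm3": vol})

        # demographics and outcomes
        age = rng.normal(*cfg.age_mean_sd[group])
        vol_norm = rng.normal(*cfg.vol_mean_sd[group])
        # standardized covariates use fixed population scales so the
        # generative coefficients are stable across cohort sizes
        uptake = float(np.mean([dvr_true_by_key[f"{h}_{n}"]
                                for n in ("entorhinal", "amygdala", "parahippocampal",
                                          "fusiform", "inferiortemporal", "middletemporal")
                                for h in ("lh", "rh")]))
        zv = (vol_norm - 0.019) / 0.002
        zu = (uptake - 1.7) / 0.25
        za = (age - 60.0) / 20.0
        b0, bv, bu, bint, ba = cfg.mmse_coefs
        mmse = (b0 + bv * zv + bu * zu + bint * zv * zu + ba * za
                + rng.normal(0, cfg.mmse_noise_sd))
        mmse = float(np.clip(mmse, 0.0, 30.0))

        is_pos = si in abeta_pos
        if is_pos:
            c0, c1 = cfg.centiloid_coefs
            global_uptake = float(np.mean(list(dvr_true_by_key.values())))
            centiloid = c0 + c1 * global_uptake + rng.normal(0, cfg.centiloid_noise_sd)
        else:
            centiloid = np.nan

        # tau table: anticorrelated with SV2A in patients, independent in
        # controls, over the 68 cortical ROIs
        rho = cfg.tau_rho[group]
        cort_keys = [f"{h}_{n}" for n in DK_CORTICAL_NAMES for h in ("lh", "rh")]
        sv2a = np.array([dvr_true_by_key[k] for k in cort_keys])
        sv2a_z = (sv2a - sv2a.mean()) / sv2a.std()
        noise_z = rng.normal(0, 1, size=len(cort_keys))
        tau_vals = 1.15 + 0.12 * (rho * sv2a_z + np.sqrt(1 - rho ** 2) * noise_z)
        for k, tv in zip(cort_keys, tau_vals):
            tau_rows.append({"subject_id": sid, "region": k, "tau_suvr": float(tv)})

        demo_rows.append({"subject_id": sid, "group": group, "age": float(age),
                          "mmse": mmse, "meta_volume_norm": float(vol_norm),
                          "abeta_positive": bool(is_pos),
                          "centiloid": float(centiloid),
                          "k1p_true": float(k1p), "k2p_true": float(k2p)})
        subjects.append(SyntheticSubject(
            subject_id=sid, group=group, age=float(age), mmse=mmse,
            meta_volume_norm=float(vol_norm), abeta_positive=bool(is_pos),
            centiloid=float(centiloid), reference_tacs=reference_tacs,
            cortical_tacs=cortical_tacs, k1p=float(k1p), k2p=float(k2p)))

    return SyntheticCohort(config=cfg, schedule=schedule, subjects=subjects,
                           ground_truth=pd.DataFrame(truth_rows),
                           demographics=pd.DataFrame(demo_rows),
                           tau=pd.DataFrame(tau_rows),
                           volumes=pd.DataFrame(vol_rows))


# ---------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------

def generate_phantom(shapes, grid_shape=(40, 40, 40), voxel_sizes=(2.0, 2.0, 2.0),
                     schedule: FrameSchedule | None = None, fwhm_mm: float = 0.0,
                     sigma0: float = 0.0, seed: int = 0):
    """Build a labelled phantom image from simple geometric shapes.

    ``shapes`` is a list of dicts with keys ``label`` (positive int),
    ``kind`` ("box" or "sphere"), ``center`` (voxel coords), ``size``
    (half-widths for boxes, radius for spheres, in voxels) and
    ``value`` — a scalar for a static phantom or a per-frame sequence
    for a dynamic one (then ``schedule`` is required).

    Returns ``(image, label_map, truth)`` where ``image`` is a
    :class:`DynamicImage` or a static 3-D array, ``label_map`` aligns
    with it and ``truth`` tabulates the assigned values.  Overlapping
    labels are an error.  Optional isotropic Gaussian blur (``fwhm_mm``)
    and frame noise are applied after assignment.
    """
    from scipy.ndimage import gaussian_filter

    labels = np.zeros(grid_shape, int)
    idx = np.indices(grid_shape)
    values = {}
    dynamic = schedule is not None
    for sh in shapes:
        c = np.asarray(sh["center"], float).reshape(3, 1, 1, 1)
        if sh["kind"] == "box":
            half = np.asarray(sh["size"], float).reshape(3, 1, 1, 1)
            mask = np.all(np.abs(idx - c) <= half, axis=0)
        elif sh["kind"] == "sphere":
            mask = np.sum((idx - c) ** 2, axis=0) <= float(sh["size"]) ** 2
        else:
            raise ValueError(f"unknown shape kind {sh['kind']!r}")
        if np.any(labels[mask] != 0):
            raise ValueError(f"shape with label {sh['label']} overlaps an earlier shape")
        labels[mask] = int(sh["label"])
        values[int(sh["label"])] = np.atleast_1d(np.asarray(sh["value"], float))

    n_frames = len(schedule) if dynamic else 1
    data = np.zeros(grid_shape + (n_frames,))
    truth_rows = []
    for lab, val in values.items():
        if dynamic and val.size != n_frames:
            raise ValueError(f"label {lab}: value sequence length {val.size} != "
                             f"{n_frames} frames")
        data[labels == lab] = val if dynamic else val[0]
        truth_rows.append({"label": lab, "value_mean": float(val.mean())})

    if fwhm_mm > 0:
        sig_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_sizes)
        for j in range(n_frames):
            data[..., j] = gaussian_filter(data[..., j], sigma=sig_vox, mode="constant")
    if sigma0 > 0:
        rng = np.random.default_rng(seed)
        if dynamic:
            dur_min = schedule.durations / 60.0
            sd = sigma0 * np.sqrt(np.maximum(data, 1e-3) / dur_min)
        else:
            sd = sigma0 * np.sqrt(np.maximum(data, 1e-3))
        data = data + rng.normal(0, 1, size=data.shape) * sd

    truth = pd.DataFrame(truth_rows)
    if dynamic:
        return DynamicImage(data, tuple(voxel_sizes), schedule), labels, truth
    return data[..., 0], labels, truth


def pvc_acceptance_phantom(tissue_value: float = 3.0, fwhm_mm: float = 6.0,
                           grid_shape=(40, 40, 40), voxel_sizes=(2.0, 2.0, 2.0),
                           half_width: int = 14):
    """The standard partial-volume test object: a tissue box of constant
    value surrounded by zero-valued CSF, pre-blurred with the scanner
    PSF.  Returns ``(blurred_image, tissue_mask, tissue_value)``."""
    center = tuple(s // 2 for s in grid_shape)
    shapes = [{"label": 1, "kind": "box", "center": center,
               "size": (half_width,) * 3, "value": tissue_value}]
    img, labels, _ = generate_phantom(shapes, grid_shape=grid_shape,
                                      voxel_sizes=voxel_sizes, fwhm_mm=fwhm_mm)
    return img, labels == 1, tissue_value
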