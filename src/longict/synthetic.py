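"""Phantom-cohort generator: longitudinal multi-lesion CT-like volumes,
tumor-marker series, clinical covariates and right-censored survival, all
driven by a known per-patient latent risk.

Every patient gets one primary (gastric) lesion and 1-5 target lesions with
baseline diameters above 10 mm.  Lesion size follows a multiplicative
log-diameter random walk whose drift sign is tied to the latent risk
(high-risk patients grow, low-risk patients shrink), survival is Weibull with
a proportional-hazards effect of the latent risk, follow-up dropout is
monotone (a missing follow-up truncates all later ones), and markers are a
noisy monotone transform of the latent risk over time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import LesionAnnotation, PatientRecord, MAX_TIMEPOINTS
from .io import assemble_record, write_volume

TARGET_SITES = ("lymph_node", "liver", "lung")
TARGET_SITE_WEIGHTS = (0.50, 0.35, 0.15)
# background HU range per anatomic site; lesion foreground HU per site class
DEFAULT_SITE_PALETTE = {
    "stomach": (0.0, 40.0),
    "lymph_node": (0.0, 40.0),
    "liver": (30.0, 70.0),
    "lung": (-850.0, -750.0),
}
LESION_HU = {"lung": 40.0}
LESION_HU_DEFAULT = 100.0
MARKER_NAMES = ("marker_a", "marker_b", "marker_c")
MARKER_RISK_SLOPES = (0.8, 0.5, -0.6)
MARKER_BASE_LOG = (3.0, 1.5, 4.0)


@dataclass
class PhantomConfig:
    """Study conditions for the phantom cohort.

    ``hazard_coef`` is the log-hazard effect of one unit of latent risk;
    ``growth_scale`` the per-timepoint log-diameter drift per unit latent
    risk; diameters are mm, survival months, HU for intensities.
    """

    n_patients: int = 200
    n_timepoints_max: int = MAX_TIMEPOINTS
    lesion_count_range: tuple = (1, 5)            # target lesions per patient
    baseline_diameter_range: tuple = (12.0, 35.0)
    followup_missing_prob: float = 0.15
    censoring_rate: float = 0.25
    hazard_coef: float = 1.0
    image_size: int = 128
    patch_size: int = 64
    spacing: float = 1.0                          # mm per pixel
    noise_sd: float = 15.0                        # HU
    site_palette: dict = field(default_factory=lambda: dict(DEFAULT_SITE_PALETTE))
    growth_scale: float = 0.12
    growth_lesion_sd: float = 0.04
    walk_sd: float = 0.03
    weibull_shape: float = 1.2
    median_survival_months: float = 16.0          # at latent risk 0
    marker_missing_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        lo, hi = self.lesion_count_range
        if not 1 <= lo <= hi <= 5:
            raise ValueError("lesion_count_range must lie in 1..5 target lesions")
        if not 1 <= self.n_timepoints_max <= MAX_TIMEPOINTS:
            raise ValueError(f"n_timepoints_max must be 1..{MAX_TIMEPOINTS}")
        if self.baseline_diameter_range[0] <= 10.0:
            raise ValueError("baseline diameters must exceed 10 mm")
        for name in ("followup_missing_prob", "censoring_rate", "marker_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for site in self.site_palette:
            if site != "stomach" and site not in TARGET_SITES:
                raise ValueError(f"unknown site {site!r} in palette")


@dataclass
class PhantomTruth:
    """Ground truth behind one phantom patient."""

    patient_id: str
    latent_risk: float
    growth_rates: np.ndarray          # per-lesion log-diameter drift per timepoint
    true_survival_time: float
    censoring_time: float

    @property
    def os_months(self) -> float:
        return min(self.true_survival_time, self.censoring_time)

    @property
    def event(self) -> int:
        return int(self.true_survival_time < self.censoring_time)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_lesion_patch(diameter_mm: float, site: str, noise_sd: float,
                        rng: np.random.Generator, canvas_px: int | None = None,
                        spacing: float = 1.0, background_hu: float | None = None,
                        eccentricity: float = 0.85,
                        orientation: float | None = None) -> np.ndarray:
    """Render a soft-edged elliptical lesion as 3 consecutive HU slices.

    The center slice carries the full cross-section (longest axis =
    ``diameter_mm``); the neighbouring slices a reduced one, mimicking a
    roughly spheroidal lesion.  Returns an (canvas, canvas, 3) HU array.
    """
    if diameter_mm <= 0:
        raise ValueError("lesion diameter must be positive")
    if site not in DEFAULT_SITE_PALETTE:
        raise ValueError(f"unknown site {site!r}")
    if canvas_px is None:
        canvas_px = int(np.ceil(2.2 * diameter_mm / spacing))
    if background_hu is None:
        lo, hi = DEFAULT_SITE_PALETTE[site]
        background_hu = float(rng.uniform(lo, hi))
    fg = LESION_HU.get(site, LESION_HU_DEFAULT)
    a = diameter_mm / 2.0 / spacing                 # semi-major axis, px
    b = a * eccentricity
    theta = rng.uniform(0.0, np.pi) if orientation is None else float(orientation)
    c = (canvas_px - 1) / 2.0
    yy, xx = np.mgrid[0:canvas_px, 0:canvas_px]
    xr = (xx - c) * np.cos(theta) + (yy - c) * np.sin(theta)
    yr = -(xx - c) * np.sin(theta) + (yy - c) * np.cos(theta)
    slices = []
    for scale in (0.75, 1.0, 0.75):                 # through-plane profile
        r = np.sqrt((xr / (a * scale)) ** 2 + (yr / (b * scale)) ** 2)
        blob = 1.0 / (1.0 + np.exp((r - 1.0) / 0.08))
        hu = background_hu + (fg - background_hu) * blob
        hu = hu + rng.normal(0.0, noise_sd, size=hu.shape)
        slices.append(hu)
    return np.stack(slices, axis=-1).astype(np.float32)


def _paint_lesion(volume: np.ndarray, patch3: np.ndarray,
                  x: int, y: int, slice_index: int) -> None:
    h, w, _ = patch3.shape
    volume[y:y + h, x:x + w, slice_index - 1:slice_index + 2] = patch3


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _solve_censoring_rate(hazard_rates: np.ndarray, target: float) -> float:
    """Censoring Weibull rate (same shape as survival) such that the marginal
    probability of censoring-before-death equals ``target``.

    For two Weibulls with a shared shape ``k``, ``P(C < T) = rc / (rc + rt)``
    per patient, with ``r = scale ** -k``; average over patients and solve."""
    if target <= 0.0:
        return 0.0
    if target >= 1.0:
        return np.inf

    def frac(log_rc):
        rc = np.exp(log_rc)
        return float(np.mean(rc / (rc + hazard_rates))) - target

    lo, hi = np.log(hazard_rates.min()) - 20, np.log(hazard_rates.max()) + 20
    return float(np.exp(brentq(frac, lo, hi)))


def simulate_survival(config: PhantomConfig, rng: np.random.Generator,
                      latent_risk: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (death time, censoring time) in months for given latent risks.

    Death is Weibull with log-hazard ``hazard_coef * latent_risk``; censoring
    is an independent Weibull of the same shape, its scale calibrated so the
    marginal censoring fraction matches ``censoring_rate``.
    """
    z = np.asarray(latent_risk, dtype=float)
    n = z.size
    k = config.weibull_shape
    lam0 = config.median_survival_months / np.log(2.0) ** (1.0 / k)
    e_surv = rng.exponential(1.0, size=n)
    t_surv = lam0 * (e_surv / np.exp(config.hazard_coef * z)) ** (1.0 / k)
    rt = np.exp(config.hazard_coef * z) / lam0 ** k        # per-patient Weibull rate
    rc = _solve_censoring_rate(rt, config.censoring_rate)
    e_cens = rng.exponential(1.0, size=n)
    if rc == 0.0:
        t_cens = np.full(n, np.inf)
    elif np.isinf(rc):
        t_cens = np.zeros(n)
    else:
        t_cens = (e_cens / rc) ** (1.0 / k)
    return t_surv, t_cens


def simulate_cohort(config: PhantomConfig, keep_volumes: bool = False
                    ) -> tuple[list[PatientRecord], list[PhantomTruth]]:
    """Generate the phantom cohort.

    Returns assembled patient records (built through the same ROI pipeline as
    :func:`longict.io.load_cohort`) and the per-patient ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    tmax = config.n_timepoints_max

    z = rng.normal(0.0, 1.0, size=n)                       # latent risk
    t_surv, t_cens = simulate_survival(config, rng, z)

    records, truths = [], []
    for i in range(n):
        pid = f"P{i:04d}"
        n_targets = int(rng.integers(config.lesion_count_range[0],
                                     config.lesion_count_range[1] + 1))
        sites = ["stomach"] + list(rng.choice(TARGET_SITES, size=n_targets,
                                              p=TARGET_SITE_WEIGHTS))
        # monotone follow-up dropout
        n_avail = 1
        while n_avail < tmax and rng.uniform() >= config.followup_missing_prob:
            n_avail += 1

        d_lo, d_hi = config.baseline_diameter_range
        diam0 = np.empty(len(sites))
        diam0[0] = rng.uniform(max(20.0, d_lo), max(40.0, d_hi))   # primary
        diam0[1:] = rng.uniform(d_lo, d_hi, size=n_targets)
        growth = config.growth_scale * z[i] + rng.normal(
            0.0, config.growth_lesion_sd, size=len(sites))

        # log-diameter random walk, bounded so lesions stay inside their box
        diam = np.empty((len(sites), tmax))
        diam[:, 0] = diam0
        for t in range(1, tmax):
            step = growth + rng.normal(0.0, config.walk_sd, size=len(sites))
            diam[:, t] = np.clip(diam[:, t - 1] * np.exp(step),
                                 0.5 * diam0, 1.6 * diam0)

        # one volume per available timepoint; lesions in disjoint slice bands
        img = config.image_size
        n_slices = 3 * len(sites) + 2
        # box holds the lesion at its maximum allowed growth (1.6x baseline)
        box_side = np.ceil(1.7 * diam0 / config.spacing).astype(int)
        bg = np.array([rng.uniform(*config.site_palette[s]) for s in sites])
        orient = rng.uniform(0.0, np.pi, size=len(sites))
        pos = np.empty((len(sites), 2), dtype=int)
        for l, side in enumerate(box_side):
            if img - side - 2 <= 2:
                raise ValueError("image_size too small for configured diameters")
            pos[l] = rng.integers(2, img - side - 2, size=2)

        annotations, volumes = [], {}
        for t in range(n_avail):
            vol = np.zeros((img, img, n_slices), dtype=np.float32)
            vol += rng.normal(20.0, config.noise_sd,
                              size=vol.shape).astype(np.float32)
            for l, site in enumerate(sites):
                sl = 3 * l + 1
                canvas = render_lesion_patch(
                    diam[l, t], site, config.noise_sd, rng,
                    canvas_px=int(box_side[l]), spacing=config.spacing,
                    background_hu=float(bg[l]), orientation=float(orient[l]))
                # pad the whole band with this lesion's background
                band = np.full((img, img, 3), bg[l], dtype=np.float32)
                band += rng.normal(0.0, config.noise_sd,
                                   size=band.shape).astype(np.float32)
                vol[:, :, sl - 1:sl + 2] = band
                _paint_lesion(vol, canvas, int(pos[l, 0]), int(pos[l, 1]), sl)
                annotations.append(LesionAnnotation(
                    patient_id=pid, lesion_id=l, site=site, timepoint=t,
                    slice_index=sl, x=int(pos[l, 0]), y=int(pos[l, 1]),
                    width=int(box_side[l]), height=int(box_side[l]),
                    phase="venous"))
            volumes[t] = vol

        # markers: noisy monotone transform of latent risk over time
        markers = np.full((tmax, len(MARKER_NAMES)), np.nan)
        for t in range(n_avail):
            for m, (slope, base) in enumerate(zip(MARKER_RISK_SLOPES, MARKER_BASE_LOG)):
                if rng.uniform() < config.marker_missing_prob:
                    continue
                trend = slope * z[i] * t / max(tmax - 1, 1)
                markers[t, m] = float(np.exp(base + trend + rng.normal(0.0, 0.15)))

        clinical = {
            "sex": "M" if rng.uniform() < 0.77 else "F",
            "her2_status": "3+" if rng.uniform() < 0.75 else "2+/FISH+",
            "therapy_line": int(rng.choice([1, 2, 3], p=[0.8, 0.13, 0.07])),
            "os_months": float(min(t_surv[i], t_cens[i])),
            "event": int(t_surv[i] < t_cens[i]),
        }
        records.append(assemble_record(
            pid, annotations, volumes, markers, MARKER_NAMES, clinical,
            patch_size=config.patch_size, spacing=config.spacing,
            n_timepoints=tmax, keep_volumes=keep_volumes))
        truths.append(PhantomTruth(
            patient_id=pid, latent_risk=float(z[i]), growth_rates=growth,
            true_survival_time=float(t_surv[i]),
            censoring_time=float(t_cens[i])))
    return records, truths


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(records: list[PatientRecord], truths: list[PhantomTruth],
                 out_dir, spacing: float = 1.0) -> dict:
    """Write NIfTI volumes + annotation/marker/clinical CSVs that round-trip
    through :func:`longict.io.load_cohort`.  Records must have been simulated
    with ``keep_volumes=True``."""
    if not records:
        raise ValueError("no records to write")
    os.makedirs(out_dir, exist_ok=True)
    image_dir = os.path.join(out_dir, "images")
    os.makedirs(image_dir, exist_ok=True)

    ann_rows, marker_rows, clin_rows = [], [], []
    for rec in records:
        if rec.volumes is None:
            raise ValueError(
                f"patient {rec.patient_id} carries no volumes; simulate with "
                "keep_volumes=True before writing")
        for t, vol in sorted(rec.volumes.items()):
            write_volume(os.path.join(image_dir, f"{rec.patient_id}_t{t}.nii.gz"),
                         vol, spacing)
        for track in rec.lesions:
            x, y, w, h = track.box
            for t in np.nonzero(track.valid)[0]:
                ann_rows.append(dict(
                    patient_id=rec.patient_id, lesion_id=track.lesion_id,
                    site=track.site, timepoint=int(t),
                    slice_index=track.slice_index, x=x, y=y, width=w, height=h,
                    phase=track.phase))
        for t in range(rec.markers.shape[0]):
            if t not in rec.volumes and np.all(np.isnan(rec.markers[t])):
                continue
            for m, name in enumerate(rec.marker_names):
                v = rec.markers[t, m]
                marker_rows.append(dict(patient_id=rec.patient_id, timepoint=t,
                                        marker_name=name,
                                        value=v if np.isfinite(v) else np.nan))
        clin_rows.append(dict(patient_id=rec.patient_id, sex=rec.sex,
                              her2_status=rec.her2_status,
                              therapy_line=rec.therapy_line,
                              os_months=rec.os_months, event=rec.event))

    paths = {
        "annotation_csv": os.path.join(out_dir, "annotations.csv"),
        "marker_csv": os.path.join(out_dir, "markers.csv"),
        "clinical_csv": os.path.join(out_dir, "clinical.csv"),
        "truth_csv": os.path.join(out_dir, "truth.csv"),
        "image_dir": image_dir,
    }
    pd.DataFrame(ann_rows).to_csv(paths["annotation_csv"], index=False)
    pd.DataFrame(marker_rows).to_csv(paths["marker_csv"], index=False)
    pd.DataFrame(clin_rows).to_csv(paths["clinical_csv"], index=False)
    pd.DataFrame([dict(patient_id=t.patient_id, latent_risk=t.latent_risk,
                       true_survival_time=t.true_survival_time,
                       censoring_time=t.censoring_time,
                       os_months=t.os_months, event=t.event)
                  for t in truths]).to_csv(paths["truth_csv"], index=False)
    return paths
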