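"""Synthetic thoracic-CT-like phantom cohorts.

Real chest-CT datasets with thymoma labels are essentially never public, so
every downstream stage of this package is exercised on procedurally
generated phantoms.  A phantom slice is not an anatomically realistic CT
image; it reproduces the *geometry that matters for the pipeline*: a body
ellipse, two dark lung fields, a brighter mediastinal band between them,
and — for thymoma patients — a bright lesion confined to the anterior
mediastinal region, i.e. inside the central-column/upper-two-rows cells of
the 3x3 grid the cropping stage selects.  Benign lesions are smooth
ellipsoids with homogeneous interior; malignant lesions get an irregular
(harmonically perturbed) boundary and heterogeneous internal texture, so
the benign/malignant task carries a morphological rather than purely
intensity-based signal.

Healthy scans are full-length stacks while thymoma scans contain only the
lesion-bearing slab plus nothing else, emulating the strong healthy:thymoma
slice imbalance that lesion-neighborhood slice selection produces in the
clinical dataset this mirrors (tens of healthy slices per scan against a
handful of tumor slices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ct_io import CTVolume, save_image_stack
from .errors import EmptyCohortError, ParameterError

__all__ = ["PhantomParams", "PhantomPatient", "PhantomCohort",
           "generate_cohort", "cohort_to_disk", "load_cohort",
           "HEALTHY", "BENIGN", "MALIGNANT"]

HEALTHY, BENIGN, MALIGNANT = "healthy", "benign", "malignant"


@dataclass
class PhantomParams:
    """Generator settings.

    Defaults mirror the cohort structure of a single-institution thymoma
    study: 120 healthy / 46 benign / 32 malignant patients, with healthy
    scans an order of magnitude richer in slices than tumor slabs.
    Intensities live in [0, 1]; there is no Hounsfield calibration.
    """

    n_healthy: int = 120
    n_benign: int = 46
    n_malignant: int = 32
    slices_per_scan: tuple[int, int] = (36, 48)   # healthy stack length
    lesion_slices: tuple[int, int] = (3, 6)       # thymoma slab length
    slice_shape: tuple[int, int] = (96, 96)
    lesion_contrast: float = 0.35   # intensity offset of lesion over the band
    lesion_radius: tuple[int, int] = (4, 7)       # pixels
    malignant_irregularity: float = 0.35          # boundary perturbation amplitude
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.n_healthy, self.n_benign, self.n_malignant) < 0:
            raise ParameterError("patient counts must be >= 0")
        h, w = self.slice_shape
        if h % 3 or w % 3:
            raise ParameterError(
                f"slice_shape must be divisible by 3 in both axes for an exact "
                f"3x3 grid, got {self.slice_shape}")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ParameterError("lesion_contrast must lie in [0, 1]")
        if self.noise_sd < 0 or self.malignant_irregularity < 0:
            raise ParameterError("noise_sd and malignant_irregularity must be >= 0")
        for name, (lo, hi) in (("slices_per_scan", self.slices_per_scan),
                               ("lesion_slices", self.lesion_slices),
                               ("lesion_radius", self.lesion_radius)):
            if lo < 1 or hi < lo:
                raise ParameterError(f"{name} must be a range with 1 <= lo <= hi")

    @property
    def n_total(self) -> int:
        return self.n_healthy + self.n_benign + self.n_malignant


@dataclass
class PhantomPatient:
    patient_id: str
    label: str
    volume: CTVolume
    lesion_mask: np.ndarray | None = None  # boolean, same shape as the volume


@dataclass
class PhantomCohort:
    patients: list[PhantomPatient]
    params: PhantomParams | None = None

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.patient_id, p.label, p.volume.n_slices) for p in self.patients],
            columns=["patient_id", "label", "n_slices"])

    @property
    def labels(self) -> dict[str, str]:
        return {p.patient_id: p.label for p in self.patients}


# -- slice rendering ---------------------------------------------------------
def _background(shape: tuple[int, int]) -> np.ndarray:
    """Body ellipse with two dark lung fields and a brighter mediastinal band.

    The band is drawn last and coincides exactly with the 3x3-grid crop
    region (upper two cells of the middle column), so lesions placed in it
    always sit on a uniform 0.45 background — which is what makes the
    pixel-level lesion/band intensity oracle exact.
    """
    h, w = shape
    r = np.arange(h)[:, None] / h
    c = np.arange(w)[None, :] / w
    img = np.full(shape, 0.05)

    def ellipse(cr, cc, ar, ac):
        return ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0

    img[ellipse(0.50, 0.50, 0.48, 0.46)] = 0.30
    img[ellipse(0.52, 0.27, 0.30, 0.16)] = 0.08
    img[ellipse(0.52, 0.73, 0.30, 0.16)] = 0.08
    img[band_mask(shape)] = 0.45
    return img


def band_mask(shape: tuple[int, int]) -> np.ndarray:
    """The mediastinal-band pixels: rows [0, 2H/3), cols [W/3, 2W/3)."""
    h, w = shape
    m = np.zeros(shape, dtype=bool)
    m[0:2 * (h // 3), w // 3:2 * (w // 3)] = True
    return m


def _lesion_slice_mask(shape, center, radius, aspect, theta_coeffs, irregularity):
    h, w = shape
    rr = np.arange(h)[:, None] - center[0]
    cc = np.arange(w)[None, :] - center[1]
    rho = np.sqrt((rr / aspect) ** 2 + cc ** 2)
    limit = np.full(shape, float(radius))
    if irregularity > 0 and theta_coeffs:
        theta = np.arctan2(rr * np.ones_like(cc), cc * np.ones_like(rr))
        bump = np.zeros(shape)
        for k, (a, phi) in theta_coeffs.items():
            bump += a * np.cos(k * theta + phi)
        limit = radius * (1.0 + irregularity * bump)
    return rho <= limit


def _render_patient(params: PhantomParams, label: str, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    h, w = params.slice_shape
    base = _background(params.slice_shape)
    if label == HEALTHY:
        n = int(rng.integers(params.slices_per_scan[0], params.slices_per_scan[1] + 1))
        vol = np.repeat(base[None], n, axis=0)
        vol = np.clip(vol + rng.normal(0.0, params.noise_sd, vol.shape), 0.0, 1.0)
        return vol, None

    n = int(rng.integers(params.lesion_slices[0], params.lesion_slices[1] + 1))
    r_lo, r_hi = params.lesion_radius
    radius = float(rng.uniform(r_lo, r_hi))
    irr = params.malignant_irregularity if label == MALIGNANT else 0.0
    # keep the lesion (including boundary perturbation) strictly inside the
    # crop region rows [0, 2H/3), cols [W/3, 2W/3)
    margin = radius * (1.0 + irr) + 2.0
    row_lo, row_hi = margin, 2 * (h // 3) - margin
    col_lo, col_hi = w // 3 + margin, 2 * (w // 3) - margin
    if row_lo >= row_hi or col_lo >= col_hi:
        raise ParameterError(
            f"lesion_radius {params.lesion_radius} too large for slice_shape "
            f"{params.slice_shape}: the lesion cannot fit inside the crop region")
    center = (float(rng.uniform(max(row_lo, 0.22 * h), min(row_hi, 0.55 * h))),
              float(rng.uniform(col_lo, col_hi)))
    aspect = float(rng.uniform(0.8, 1.2))
    coeffs = {}
    if irr > 0:
        ks = (2, 3, 5)
        amps = rng.uniform(0.3, 1.0, len(ks))
        amps = amps / amps.sum()
        coeffs = {k: (float(a), float(rng.uniform(0, 2 * np.pi)))
                  for k, a in zip(ks, amps)}
    vol = np.repeat(base[None], n, axis=0)
    mask = np.zeros((n, h, w), dtype=bool)
    z0 = (n - 1) / 2.0
    half = max(n / 2.0, 1.0)
    for z in range(n):
        # ellipsoidal through-slice profile
        frac = 1.0 - ((z - z0) / half) ** 2
        r_z = radius * np.sqrt(max(frac, 0.0))
        if r_z < 1.0:
            r_z = 1.0
        m = _lesion_slice_mask(params.slice_shape, center, r_z, aspect, coeffs, irr)
        lesion = np.full(params.slice_shape, params.lesion_contrast)
        if label == MALIGNANT:
            # heterogeneous interior: smooth zero-mean modulation
            tex = rng.normal(0.0, 1.0, params.slice_shape)
            from scipy.ndimage import gaussian_filter
            tex = gaussian_filter(tex, 1.5)
            sd = tex.std()
            if sd > 0:
                tex = np.clip(tex / (3 * sd), -1.0, 1.0)
            lesion *= 1.0 + 0.25 * tex
        vol[z][m] = np.clip(vol[z][m] + lesion[m], 0.0, 1.0)
        mask[z] = m
    vol = np.clip(vol + rng.normal(0.0, params.noise_sd, vol.shape), 0.0, 1.0)
    return vol, mask


def generate_cohort(params: PhantomParams | None = None, **kwargs) -> PhantomCohort:
    """Generate a deterministic phantom cohort.

    Accepts either a :class:`PhantomParams` or keyword overrides of its
    fields.  Identical parameters (including ``seed``) give bit-identical
    cohorts.
    """
    if params is None:
        params = PhantomParams(**kwargs)
    elif kwargs:
        raise ParameterError("pass either PhantomParams or keyword overrides, not both")
    if params.n_total == 0:
        raise EmptyCohortError("cohort must contain at least one patient")
    rng = np.random.default_rng(params.seed)
    patients = []
    plan = [(HEALTHY, params.n_healthy), (BENIGN, params.n_benign),
            (MALIGNANT, params.n_malignant)]
    for label, count in plan:
        for i in range(count):
            pid = f"{label}_{i + 1:03d}"
            vol, mask = _render_patient(params, label, rng)
            patients.append(PhantomPatient(
                patient_id=pid, label=label,
                volume=CTVolume(slices=vol, patient_id=pid, scan_id=pid,
                                source_format="array"),
                lesion_mask=mask))
    return PhantomCohort(patients=patients, params=params)


def cohort_to_disk(cohort: PhantomCohort, directory: str | Path) -> Path:
    """Write each volume as an ordered 8-bit PNG stack plus one manifest CSV.

    The manifest has columns ``patient_id,label,n_slices,path`` with paths
    relative to ``directory``; the written stacks round-trip through
    :func:`thymixer.ct_io.load_volume` up to the 1/255 quantization step.
    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        sub = directory / p.patient_id
        save_image_stack(p.volume, sub)
        rows.append((p.patient_id, p.label, p.volume.n_slices, p.patient_id))
    manifest = pd.DataFrame(rows, columns=["patient_id", "label", "n_slices", "path"])
    out = directory / "manifest.csv"
    manifest.to_csv(out, index=False)
    return out


def load_cohort(directory: str | Path) -> PhantomCohort:
    """Load a cohort previously written by :func:`cohort_to_disk`.

    Lesion masks are not persisted; loaded patients carry ``lesion_mask=None``.
    Intensities are rescaled from 8-bit back to [0, 1].
    """
    from .ct_io import load_volume

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    patients = []
    for row in manifest.itertuples(index=False):
        v = load_volume(directory / row.path, format="image_stack",
                        patient_id=row.patient_id, scan_id=row.patient_id)
        v.slices = v.slices / 255.0
        patients.append(PhantomPatient(patient_id=row.patient_id, label=row.label,
                                       volume=v))
    return PhantomCohort(patients=patients)
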