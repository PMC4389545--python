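"""Seeded synthetic head/brain volumes with age-parameterized tissue geometry.

The phantom is a set of concentric smooth shells defined in world mm
(scalp, skull, subarachnoid CSF, GM ribbon, WM core, central ventricle),
with compartment radii chosen so the ground-truth tissue fractions follow
simple aging trends: GM fraction declines linearly with age, WM fraction is
quadratic with a vertex near mid-life, and the remaining "other matter"
(OM: ventricles plus CSF-like tissue) takes up the slack.  Intracranial
(inner skull) volume does not change with age.

All geometry lives in world coordinates, so the same spec rendered on a
different grid/voxel size produces the same shapes.  Identical spec + seed
reproduces identical volumes bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._seeds import derive_seed
from .volume import CLASSES, PVEMap, Volume, center_affine

AGE_MIN, AGE_MAX = 20.0, 89.0

#: Pure-class mean intensities (arbitrary units, T1-like ordering WM>GM>CSF).
PURE_INTENSITY: dict[str, float] = {"om": 30.0, "gm": 70.0, "wm": 110.0}
SKULL_INTENSITY = 20.0
SCALP_INTENSITY = 55.0

# Baseline tissue fractions of the brain compartment at the anchor age /
# the WM vertex.  Synthetic conventions, not estimates.
GM_FRACTION_AT_20 = 0.50
WM_FRACTION_PEAK = 0.35


class PhantomGeometryError(ValueError):
    """Raised when the requested grid cannot contain all phantom shells."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head volume."""

    age: float
    gm_slope: float = -0.0011          # GM fraction change per year (< 0)
    wm_peak_age: float = 50.0          # vertex of the quadratic WM trend
    wm_curv: float = 2.0e-5            # downward curvature of WM fraction
    noise_sigma: float = 0.0           # additive Gaussian noise, intensity units
    bias_amplitude: float = 0.0        # multiplicative field dynamic range
    shape_jitter: float = 0.0          # RMS boundary perturbation, mm
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    # shell radii in mm (outer edges); brain_radius is fixed across age
    scalp_radius: float = 42.0
    skull_outer_radius: float = 39.0
    inner_skull_radius: float = 37.0
    brain_radius: float = 35.0

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise ValueError(f"age must be in [{AGE_MIN}, {AGE_MAX}], got {self.age}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if not (
            self.brain_radius
            < self.inner_skull_radius
            < self.skull_outer_radius
            < self.scalp_radius
        ):
            raise ValueError("shell radii must be strictly nested")


@dataclass
class PhantomCase:
    """One generated phantom with its ground truth."""

    head: Volume
    brain: Volume
    truth_pve: PVEMap
    brain_mask: np.ndarray
    inner_skull_mask: np.ndarray
    spec: PhantomSpec
    bias: Volume | None = None
    subject_id: str = "phantom"

    @property
    def age(self) -> float:
        return self.spec.age

    def truth_labels(self) -> np.ndarray:
        """Hard ground-truth labels (0 bg, 1 OM, 2 GM, 3 WM)."""
        from .segment import classify_hard

        return classify_hard(self.truth_pve)


def expected_class_fractions(age: float, spec: PhantomSpec | None = None) -> dict[str, float]:
    """Generator target GM/WM/OM fractions of the brain compartment at ``age``."""
    if spec is None:
        spec = PhantomSpec(age=age)
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age must be in [{AGE_MIN}, {AGE_MAX}]")
    f_gm = GM_FRACTION_AT_20 + spec.gm_slope * (age - AGE_MIN)
    f_wm = WM_FRACTION_PEAK - spec.wm_curv * (age - spec.wm_peak_age) ** 2
    f_om = 1.0 - f_gm - f_wm
    if min(f_gm, f_wm, f_om) <= 0:
        raise ValueError("trend parameters drive a class fraction below zero")
    return {"om": f_om, "gm": f_gm, "wm": f_wm}


def compartment_radii(spec: PhantomSpec) -> dict[str, float]:
    """Radii (mm) realizing the target fractions inside a fixed brain sphere.

    The GM ribbon is the outermost brain shell, WM sits underneath, and a
    central sphere of OM models the ventricles; sphere-volume algebra turns
    the target fractions into boundary radii.
    """
    f = expected_class_fractions(spec.age, spec)
    rb = spec.brain_radius
    r_gw = rb * (1.0 - f["gm"]) ** (1.0 / 3.0)      # GM/WM boundary
    r_vent = rb * f["om"] ** (1.0 / 3.0)            # ventricle radius
    return {
        "scalp": spec.scalp_radius,
        "skull_outer": spec.skull_outer_radius,
        "inner_skull": spec.inner_skull_radius,
        "brain": rb,
        "gm_wm": r_gw,
        "ventricle": r_vent,
    }


def analytic_compartment_volumes(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form mm^3 volumes of the generating shells (zero jitter)."""
    r = compartment_radii(spec)
    sph = lambda radius: 4.0 / 3.0 * np.pi * radius**3
    return {
        "gm": sph(r["brain"]) - sph(r["gm_wm"]),
        "wm": sph(r["gm_wm"]) - sph(r["ventricle"]),
        "om": sph(r["ventricle"]),
        "brain": sph(r["brain"]),
        "inner_skull": sph(r["inner_skull"]),
    }


def _smooth_unit_field(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth random field with ~unit RMS (for boundary jitter)."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=4.0, mode="nearest")
    rms = float(np.sqrt(np.mean(raw**2)))
    return raw / max(rms, 1e-12)


def _bias_field(shape, coords_norm, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """exp(random quadratic polynomial) scaled to the requested dynamic range."""
    if amplitude <= 0:
        return np.ones(shape)
    x, y, z = coords_norm
    basis = [x, y, z, x * y, x * z, y * z, x**2, y**2, z**2]
    coeffs = rng.standard_normal(len(basis))
    logb = sum(c * b for c, b in zip(coeffs, basis))
    span = float(logb.max() - logb.min())
    if span > 0:
        logb *= np.log1p(amplitude) / span
    logb -= logb.mean()
    return np.exp(logb)


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case with ground-truth PVE maps.

    Raises :class:`PhantomGeometryError` if the grid is too small to contain
    the scalp shell (with jitter margin).
    """
    shape = tuple(spec.grid_shape)
    affine = center_affine(shape, spec.voxel_size)
    vol_proto = Volume(np.zeros(shape), affine)
    world = vol_proto.world_coordinates()
    half_extent = float(np.min((np.asarray(shape) - 1) / 2.0) * spec.voxel_size)
    margin = spec.scalp_radius + 2.0 * spec.shape_jitter + spec.voxel_size
    if margin > half_extent:
        raise PhantomGeometryError(
            f"grid half-extent {half_extent:.1f} mm cannot contain the scalp "
            f"shell ({margin:.1f} mm needed)"
        )

    rng = np.random.default_rng(spec.seed)
    r = np.sqrt((world**2).sum(axis=0))
    if spec.shape_jitter > 0:
        r = r + spec.shape_jitter * _smooth_unit_field(shape, rng)
    else:
        rng.standard_normal(shape)  # keep stream alignment across jitter settings

    radii = compartment_radii(spec)
    w = spec.voxel_size  # partial-volume transition width

    def inside_frac(radius: float) -> np.ndarray:
        return np.clip((radius - r) / w + 0.5, 0.0, 1.0)

    f_brain = inside_frac(radii["brain"])
    f_gw = inside_frac(radii["gm_wm"])
    f_vent = inside_frac(radii["ventricle"])
    brain_mask = f_brain >= 0.5
    inner_skull_mask = inside_frac(radii["inner_skull"]) >= 0.5

    raw = np.stack([f_vent, f_brain - f_gw, f_gw - f_vent])  # om, gm, wm
    raw_mix = np.tensordot(
        np.array([PURE_INTENSITY[k] for k in CLASSES]), raw, axes=1
    )  # unnormalized brain intensity contribution
    denom = np.where(brain_mask, np.maximum(f_brain, 1e-12), 1.0)
    pve = raw / denom
    pve[:, ~brain_mask] = 0.0
    truth_pve = PVEMap({k: pve[i] for i, k in enumerate(CLASSES)}, brain_mask, affine)

    # intensities: normalized mixture inside the brain, shell mixture outside
    brain_intensity = sum(PURE_INTENSITY[k] * truth_pve.maps[k] for k in CLASSES)
    f_inner = inside_frac(radii["inner_skull"])
    f_sk = inside_frac(radii["skull_outer"])
    f_scalp = inside_frac(radii["scalp"])
    outside_intensity = (
        (f_inner - f_brain) * PURE_INTENSITY["om"]
        + (f_sk - f_inner) * SKULL_INTENSITY
        + (f_scalp - f_sk) * SCALP_INTENSITY
        + raw_mix  # boundary voxels keep their (unnormalized) brain share
    )
    head_data = np.where(brain_mask, brain_intensity, outside_intensity)

    coords_norm = world / half_extent
    bias = _bias_field(shape, coords_norm, spec.bias_amplitude, rng)
    head_data = head_data * bias
    if spec.noise_sigma > 0:
        head_data = head_data + rng.normal(0.0, spec.noise_sigma, size=shape)

    head = Volume(head_data, affine)
    brain = Volume(np.where(brain_mask, head_data, 0.0), affine)
    return PhantomCase(
        head=head,
        brain=brain,
        truth_pve=truth_pve,
        brain_mask=brain_mask,
        inner_skull_mask=inner_skull_mask,
        spec=spec,
        bias=Volume(bias, affine),
        subject_id=f"phantom-age{spec.age:.1f}-seed{spec.seed}",
    )


def parse_age_groups(text: str) -> list[tuple[float, float]]:
    """Parse ``"20-24,25-29"`` into [(20, 24), (25, 29)]."""
    groups = []
    for chunk in text.split(","):
        lo, hi = chunk.strip().split("-")
        groups.append((float(lo), float(hi)))
    return groups


def make_cohort(
    age_groups: list[tuple[float, float]],
    n_per_group: int,
    seed: int,
    **spec_overrides: object,
) -> list[PhantomCase]:
    """Deterministic cohort: ``n_per_group`` phantoms per age group.

    Ages are sampled uniformly within each group; per-case seeds derive from
    the root seed, so identical arguments reproduce the identical cohort.
    Extra keyword arguments override :class:`PhantomSpec` fields.
    """
    if not age_groups:
        raise ValueError("age_groups must not be empty")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    cases = []
    for gi, (lo, hi) in enumerate(age_groups):
        for ci in range(n_per_group):
            case_seed = derive_seed(seed, "phantom", gi, ci)
            age_rng = np.random.default_rng(derive_seed(seed, "age", gi, ci))
            age = float(age_rng.uniform(lo, hi))
            spec = PhantomSpec(age=age, seed=case_seed, **spec_overrides)  # type: ignore[arg-type]
            case = make_phantom(spec)
            case.subject_id = f"g{gi:02d}s{ci:02d}-age{age:.1f}"
            cases.append(case)
    return cases


def write_case(case: PhantomCase, out_dir) -> None:
    """Write a PhantomCase as NIfTI files plus a JSON spec sidecar."""
    from pathlib import Path

    from .io import write_mask, write_pve, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.head, out / "head.nii.gz")
    write_volume(case.brain, out / "brain.nii.gz")
    write_pve(case.truth_pve, out, prefix="pve")
    write_mask(case.brain_mask, case.head.affine, out / "brain_mask.nii.gz")
    write_mask(case.inner_skull_mask, case.head.affine, out / "inner_skull_mask.nii.gz")
    if case.bias is not None:
        write_volume(case.bias, out / "bias.nii.gz")
    spec_dict = asdict(case.spec)
    spec_dict["grid_shape"] = list(spec_dict["grid_shape"])
    (out / "spec.json").write_text(json.dumps(spec_dict, indent=2, sort_keys=True))
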