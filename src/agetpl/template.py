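"""Iterative average-template construction and age-specific tissue priors.

The builder rigidly aligns every input to an initial reference and averages
(A0), then repeats {deformably register every input to the current average,
warp, re-average} with a coarse -> medium -> fine resolution plan, stopping
when the RMS difference between successive averages levels off (relative
change below ``rms_tol``) or ``max_iter`` is reached.

Tissue priors for an age group are the per-class arithmetic means of the
subjects' PVE maps forward-warped into template space by the final-iteration
transforms.  A prior *library* spans grouping schemes (five-year, ten-year,
multi-year) and both base references: ``image`` priors come from prior-free
segmentations and ``reference`` priors from segmentations guided by the
young-adult (20-24) reference set, the internal stand-in for an external
young-adult atlas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .register import (
    AffineTransform,
    DeformationField,
    ResolutionSchedule,
    SCHEDULE_COARSE,
    SCHEDULE_FINE,
    SCHEDULE_MEDIUM,
    apply_transform,
    register_deformable,
    register_rigid,
)
from .segment import SegConfig, segment_em
from .volume import CLASSES, GeometryError, PVEMap, Volume

logger = logging.getLogger(__name__)

SCHEMES = ("five_year", "ten_year", "multi_year")
YOUNG_ADULT_LABEL = "20-24"

DEFAULT_SCHEDULE_PLAN = [SCHEDULE_COARSE, SCHEDULE_MEDIUM, SCHEDULE_FINE]


class TemplateError(RuntimeError):
    pass


@dataclass(frozen=True)
class AgeGroup:
    label: str
    low: float
    high: float
    scheme: str

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("age group low must be <= high")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")

    def contains(self, age: float) -> bool:
        return self.low <= age <= self.high


def scheme_groups(scheme: str) -> list[AgeGroup]:
    """Age-group tilings of 20-89: 14 five-year, 7 ten-year, 3 multi-year."""
    if scheme == "five_year":
        bounds = [(lo, lo + 4) for lo in range(20, 90, 5)]
    elif scheme == "ten_year":
        bounds = [(lo, lo + 9) for lo in range(20, 90, 10)]
    elif scheme == "multi_year":
        bounds = [(25, 39), (40, 59), (60, 89)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return [
        AgeGroup(label=f"{lo}-{hi}", low=lo, high=hi, scheme=scheme)
        for lo, hi in bounds
    ]


def group_for_age(age: float, scheme: str) -> AgeGroup:
    for g in scheme_groups(scheme):
        if g.contains(age):
            return g
    raise ValueError(f"age {age} falls in no {scheme} group")


@dataclass
class TemplateResult:
    template: Volume
    subject_transforms: list[DeformationField]
    iterations: list[tuple[int, float]]
    converged: bool


@dataclass
class TissuePriors:
    """Per-class probability volumes in a template space."""

    maps: dict[str, np.ndarray]
    affine: np.ndarray
    age_group: AgeGroup | None = None
    base_reference: str = "image"   # {image, reference}

    def __post_init__(self) -> None:
        if set(self.maps) != set(CLASSES):
            raise ValueError(f"priors require classes {CLASSES}")
        stacked = self.stacked()
        if stacked.min() < -1e-9 or stacked.max() > 1 + 1e-6:
            raise ValueError("prior values outside [0, 1]")
        if stacked.sum(axis=0).max() > 1 + 1e-6:
            raise ValueError("per-voxel prior sum exceeds 1")

    def stacked(self) -> np.ndarray:
        return np.stack([self.maps[k] for k in CLASSES])


def compute_rms(a: Volume, b: Volume, mask: np.ndarray) -> float:
    """sqrt(mean over mask of squared intensity difference)."""
    if a.shape != b.shape:
        raise GeometryError("volumes must share a grid")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    d = a.data[mask] - b.data[mask]
    return float(np.sqrt(np.mean(d * d)))


def build_template(
    volumes: list[Volume],
    init_reference: Volume,
    schedule_plan: list[ResolutionSchedule] | None = None,
    rms_tol: float = 0.05,
    max_iter: int = 6,
) -> TemplateResult:
    """Iterative register/transform/average template construction."""
    if not volumes:
        raise TemplateError("no input volumes")
    plan = schedule_plan or DEFAULT_SCHEDULE_PLAN

    rigids: list[AffineTransform] = []
    aligned: list[Volume] = []
    for i, vol in enumerate(volumes):
        try:
            xf = register_rigid(vol, init_reference)
        except Exception as exc:  # pragma: no cover - error path
            raise TemplateError(f"rigid registration failed for subject {i}: {exc}")
        rigids.append(xf)
        aligned.append(apply_transform(vol, xf, target_grid=init_reference))
    a_prev = Volume(np.mean([v.data for v in aligned], axis=0), init_reference.affine)

    if len(volumes) == 1:
        # single input: the template is its rigidly aligned self
        f = DeformationField.identity(a_prev.shape, a_prev.affine)
        f.pre_affine = rigids[0]
        return TemplateResult(a_prev, [f], [(0, 0.0)], converged=True)

    span = float(np.ptp(a_prev.data))
    iterations: list[tuple[int, float]] = []
    transforms: list[DeformationField] = []
    rms_prev: float | None = None
    converged = False
    for n in range(1, max_iter + 1):
        schedule = plan[min(n - 1, len(plan) - 1)]
        warped: list[Volume] = []
        transforms = []
        for i, vol in enumerate(volumes):
            try:
                fld = register_deformable(vol, a_prev, schedule=schedule,
                                          pre_affine=rigids[i])
            except Exception as exc:
                raise TemplateError(
                    f"deformable registration failed for subject {i}: {exc}"
                )
            transforms.append(fld)
            warped.append(apply_transform(vol, fld))
        a_new = Volume(np.mean([v.data for v in warped], axis=0), a_prev.affine)
        support = (a_new.data != 0) | (a_prev.data != 0)
        rms = compute_rms(a_new, a_prev, support)
        iterations.append((n, rms))
        a_prev = a_new
        if rms < 1e-6 * max(span, 1e-12):
            converged = True
            break
        if rms_prev is not None and abs(rms - rms_prev) < rms_tol * rms_prev:
            converged = True
            break
        rms_prev = rms
    return TemplateResult(a_prev, transforms, iterations, converged)


def build_priors(
    pves: list[PVEMap],
    transforms: list[DeformationField],
    template_grid,
    age_group: AgeGroup | None = None,
    base_reference: str = "image",
) -> TissuePriors:
    """Average forward-warped per-subject PVEs into template-space priors."""
    if len(pves) != len(transforms):
        raise TemplateError(
            f"{len(pves)} PVE maps but {len(transforms)} transforms"
        )
    if isinstance(template_grid, Volume):
        shape, affine = template_grid.shape, template_grid.affine
    else:
        shape, affine = template_grid
        shape = tuple(shape)
    acc = np.zeros((len(CLASSES),) + shape)
    for pve, xf in zip(pves, transforms):
        warped = apply_transform(pve, xf, target_grid=(shape, affine))
        acc += warped.stacked()
    acc /= len(pves)
    acc = np.clip(acc, 0.0, 1.0)
    total = acc.sum(axis=0)
    over = total > 1.0
    if over.any():
        acc[:, over] /= total[over]
    return TissuePriors(
        maps={k: acc[i] for i, k in enumerate(CLASSES)},
        affine=affine,
        age_group=age_group,
        base_reference=base_reference,
    )


# ---------------------------------------------------------------------------
# prior library

@dataclass
class LibraryEntry:
    group: AgeGroup
    template: Volume
    priors: dict[str, TissuePriors]          # keyed by base reference
    result: TemplateResult | None = None


@dataclass
class PriorLibrary:
    entries: dict[tuple[str, str], LibraryEntry] = field(default_factory=dict)

    def add(self, entry: LibraryEntry) -> None:
        self.entries[(entry.group.scheme, entry.group.label)] = entry

    def get(self, scheme: str, label: str) -> LibraryEntry:
        key = (scheme, label)
        if key not in self.entries:
            raise KeyError(f"prior library has no entry for {scheme}/{label}")
        return self.entries[key]

    @property
    def young_adult(self) -> LibraryEntry:
        """The 20-24 five-year entry, used as the young-adult comparator."""
        return self.get("five_year", YOUNG_ADULT_LABEL)

    def entry_for_age(self, age: float, scheme: str) -> LibraryEntry:
        return self.get(scheme, group_for_age(age, scheme).label)


def warp_priors_to_subject(
    priors: TissuePriors,
    template: Volume,
    subject: Volume,
    subject_mask: np.ndarray,
    xf: AffineTransform | None = None,
) -> dict[str, np.ndarray]:
    """Resample template-space priors onto a subject grid (rigid transfer).

    Registers the subject to the template (rigid) and pulls the prior maps
    back through the inverse map; values are renormalized later by
    :func:`agetpl.segment.segment_em`.  A precomputed subject-to-template
    transform may be passed when all library templates share one frame.
    """
    if xf is None:
        xf = register_rigid(subject, template)
    inv = AffineTransform(np.linalg.inv(xf.matrix), dof_tag=xf.dof_tag)
    out = {}
    for k in CLASSES:
        vol = Volume(priors.maps[k], priors.affine)
        out[k] = apply_transform(vol, inv, target_grid=subject).data
    return out


@dataclass
class PreparedCase:
    """Preprocessed subject ready for template/prior construction."""

    subject_id: str
    age: float
    brain: Volume
    mask: np.ndarray
    pve_image: PVEMap               # prior-free segmentation
    pve_reference: PVEMap | None = None  # reference-prior segmentation


def build_prior_library(
    cases: list[PreparedCase],
    schemes: list[str] = list(SCHEMES),
    schedule_plan: list[ResolutionSchedule] | None = None,
    rms_tol: float = 0.05,
    max_iter: int = 3,
    seg_config: SegConfig | None = None,
    include_reference_base: bool = True,
) -> PriorLibrary:
    """Templates + image/reference priors per scheme x age group.

    The young-adult (20-24) five-year set is built first from prior-free
    PVEs; its image priors then play the external-reference role when
    producing every group's ``reference``-base PVE maps.  Groups with no
    cases are skipped with a warning.
    """
    for c in cases:
        if not (20 <= c.age <= 89):
            raise TemplateError(f"case {c.subject_id} age {c.age} outside [20, 89]")
    lib = PriorLibrary()
    seg_config = seg_config or SegConfig(prior_usage="a_posteriori")

    young_group = AgeGroup(YOUNG_ADULT_LABEL, 20, 24, "five_year")
    young_cases = [c for c in cases if young_group.contains(c.age)]
    if not young_cases:
        raise TemplateError("no 20-24 cases: cannot build the reference set")

    def template_for(group_cases, init_reference=None):
        vols = [c.brain for c in group_cases]
        init = init_reference if init_reference is not None else vols[0]
        result = build_template(vols, init, schedule_plan=schedule_plan,
                                rms_tol=rms_tol, max_iter=max_iter)
        return result

    # --- reference (young adult) set ----------------------------------
    young_result = template_for(young_cases)
    ref_priors = build_priors(
        [c.pve_image for c in young_cases], young_result.subject_transforms,
        young_result.template, age_group=young_group, base_reference="image",
    )
    reference_template = young_result.template
    reference_priors = ref_priors

    # segment every case with the reference priors (a posteriori)
    if include_reference_base:
        for c in cases:
            if c.pve_reference is None:
                warped = warp_priors_to_subject(reference_priors, reference_template,
                                                c.brain, c.mask)
                seg = segment_em(c.brain, c.mask, priors=warped, config=seg_config)
                c.pve_reference = seg.pve

    # --- per scheme x group entries ------------------------------------
    for scheme in schemes:
        for group in scheme_groups(scheme):
            group_cases = [c for c in cases if group.contains(c.age)]
            if not group_cases:
                logger.warning("skipping %s/%s: no cases", scheme, group.label)
                continue
            if scheme == "five_year" and group.label == YOUNG_ADULT_LABEL:
                result = young_result
            else:
                # orient every group template to the internal young-adult
                # reference so all library entries share one rough frame
                result = template_for(group_cases, init_reference=reference_template)
            entry_priors = {}
            bases = (("image", "pve_image"), ("reference", "pve_reference"))
            if not include_reference_base:
                bases = (("image", "pve_image"),)
            for base, attr in bases:
                entry_priors[base] = build_priors(
                    [getattr(c, attr) for c in group_cases],
                    result.subject_transforms,
                    result.template,
                    age_group=group,
                    base_reference=base,
                )
            lib.add(LibraryEntry(group=group, template=result.template,
                                 priors=entry_priors, result=result))
    return lib
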