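"""Synthetic inputs with known ground truth for every pipeline stage.

Geometric phantoms, not realistic histology: trichrome images are
non-overlapping nuclear disks with a programmed per-compartment PGR+
fraction; estrous series are stage-blocked multinomial smears; qPCR
tables carry programmed fold changes against two reference genes; and
the packaged cohort fixtures reconstruct the study's printed proportions
from the smallest integer cohorts consistent with them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from ._rounding import round_half_up
from .cytology import STAGES, SmearObservation
from .fluoro import CompartmentMasks, CompartmentROIs, TrichromeImage, rasterize_polygons
from .grading import UterusSectionGeometry
from .stats import ADENOMYOSIS, CONTROL, BreedingRecord, LitterEvent


class ReconstructionError(ValueError):
    """No integer cohort consistent with the printed percentages."""


# ---------------------------------------------------------------------------
# Percentage reconstruction
# ---------------------------------------------------------------------------


def _rounds_to(count: int, n: int, printed: float, ndigits: int = 2) -> bool:
    q = Decimal(1).scaleb(-ndigits)
    exact = (Decimal(count) * 100) / Decimal(n)
    return exact.quantize(q, rounding=ROUND_HALF_UP) == Decimal(repr(printed)).quantize(q)


def counts_for_n(
    percentages: Sequence[float], n: int, ndigits: int = 2
) -> tuple[int, ...] | None:
    """Integer counts summing to n that re-round (half-up, ``ndigits``
    decimals) to the printed percentages, or None if none exist."""
    candidate_sets: list[list[int]] = []
    for p in percentages:
        center = p * n / 100.0
        cands = [
            c for c in range(max(0, math.floor(center) - 1),
                             min(n, math.ceil(center) + 1) + 1)
            if _rounds_to(c, n, p, ndigits)
        ]
        if not cands:
            return None
        candidate_sets.append(cands)

    def search(i: int, remaining: int, acc: list[int]) -> tuple[int, ...] | None:
        if i == len(candidate_sets):
            return tuple(acc) if remaining == 0 else None
        for c in candidate_sets[i]:
            if c <= remaining:
                found = search(i + 1, remaining - c, acc + [c])
                if found is not None:
                    return found
        return None

    return search(0, n, [])


def reconstruct_counts_from_percentages(
    percentages: Sequence[float], n_max: int = 500
) -> tuple[int, tuple[int, ...]]:
    """Smallest cohort size n <= n_max, with integer counts, whose exact
    percentages round half-up (2 decimals) to the printed values.

    Printed percentage tables lose the underlying counts; because the
    rounding map is many-to-one only for large n, the smallest consistent
    n recovers the unique original cohort for the tables handled here.
    """
    percentages = list(percentages)
    if any(not (0 < p < 100) for p in percentages):
        raise ValueError("percentages must lie strictly between 0 and 100")
    if not math.isclose(sum(percentages), 100.0, abs_tol=0.5):
        raise ValueError(f"percentages must sum to ~100, got {sum(percentages)}")
    for n in range(1, n_max + 1):
        counts = counts_for_n(percentages, n)
        if counts is not None:
            return n, counts
    raise ReconstructionError(
        f"no integer cohort of size <= {n_max} re-rounds to {percentages}"
    )


# ---------------------------------------------------------------------------
# Trichrome image phantoms
# ---------------------------------------------------------------------------


@dataclass
class ImageSimParams:
    """Phantom design: disks of radius ``nucleus_radius`` placed without
    overlap inside each compartment; a programmed fraction of them also
    carries red (PGR+) signal. ``noise`` is additive Gaussian, as a
    fraction of the 8-bit range."""

    size: int = 256
    pixel_size_um: float | None = 0.5
    nucleus_radius: int = 4
    nuclei_per_compartment: dict[str, int] = field(
        default_factory=lambda: {"epithelium": 25, "glands": 10, "stroma": 80}
    )
    pgr_positive_fraction: dict[str, float] = field(
        default_factory=lambda: {"epithelium": 0.6, "glands": 0.5, "stroma": 0.4}
    )
    noise: float = 0.0
    signal_intensity: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.size:
            raise ValueError("nucleus radius must be smaller than the image")
        if self.nucleus_radius < 1 or self.size < 16:
            raise ValueError("radius >= 1 and size >= 16 required")
        for comp, frac in self.pgr_positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{comp}: fraction must lie in [0, 1]")
        for comp, n in self.nuclei_per_compartment.items():
            if n < 0:
                raise ValueError(f"{comp}: nucleus count must be >= 0")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError("noise must lie in [0, 1)")


@dataclass
class ImageGroundTruth:
    nuclei_mask: np.ndarray  # all nuclear disks (blue signal support)
    positive_mask: np.ndarray  # the PGR+ subset (red signal support)
    true_fraction: dict[str, float]  # realised positive/total disk count ratio
    n_nuclei: dict[str, int]
    n_positive: dict[str, int]


def _phantom_rois(size: int) -> CompartmentROIs:
    """Fixed phantom layout: studied region is a central square; the
    epithelium is a left band inside it and the glands two inner boxes.
    Half-integer vertices keep pixel centers off polygon boundaries."""
    m = size // 8  # margin for the myometrial band outside the studied region
    s0, s1 = m + 0.5, size - m - 0.5
    epi_x1 = m + (size - 2 * m) * 0.25 - 0.5
    gx0 = m + (size - 2 * m) * 0.45
    gw = (size - 2 * m) * 0.2
    gy0a, gy0b = m + (size - 2 * m) * 0.1, m + (size - 2 * m) * 0.6

    def rect(x0, y0, x1, y1):
        return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]

    return CompartmentROIs(
        total_region=rect(s0, s0, s1, s1),
        luminal_epithelium=[rect(s0, s0, epi_x1, s1)],
        glands=[
            rect(gx0, gy0a, gx0 + gw, gy0a + gw),
            rect(gx0, gy0b, gx0 + gw, gy0b + gw),
        ],
    )


def _place_disks(
    allowed: np.ndarray, n: int, radius: int, occupied: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Rejection-sample n non-overlapping integer disk centers such that
    each disk lies wholly inside ``allowed`` and clear of ``occupied``."""
    from scipy.ndimage import distance_transform_edt

    interior = distance_transform_edt(allowed) > radius + 1
    rr, cc = np.nonzero(interior)
    if rr.size == 0 and n > 0:
        raise ValueError("compartment too small for any nucleus")
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError("cannot place nuclei without overlap; reduce density")
        i = int(rng.integers(0, rr.size))
        r, c = int(rr[i]), int(cc[i])
        dr, dc = _disk((r, c), radius, shape=occupied.shape)
        if occupied[dr, dc].any():
            continue
        # keep a 1-px moat so disks never touch
        dr2, dc2 = _disk((r, c), radius + 1, shape=occupied.shape)
        occupied[dr2, dc2] = True
        centers.append((r, c))
    return centers


def simulate_trichrome_image(
    params: ImageSimParams,
) -> tuple[TrichromeImage, CompartmentROIs, CompartmentMasks, ImageGroundTruth]:
    """Generate a trichrome phantom with exact area ground truth.

    All nuclei appear as identical disks in the blue channel; a chosen
    subset (round-half-up of fraction x count per compartment) is also
    painted red, so the red support is a subset of the blue support and
    the red/blue area ratio inside each compartment equals the positive
    disk-count fraction exactly at zero noise. The green channel marks a
    muscle band outside the studied region.
    """
    size = params.size
    rng = np.random.default_rng(params.seed)
    rois = _phantom_rois(size)
    shape = (size, size)
    studied = rasterize_polygons([rois.total_region], shape)
    epithelium = rasterize_polygons(rois.luminal_epithelium, shape) & studied
    glands = rasterize_polygons(rois.glands, shape) & studied & ~epithelium
    stroma = studied & ~epithelium & ~glands
    masks = CompartmentMasks(
        epithelium=epithelium, glands=glands, stroma=stroma, studied_region=studied
    )

    nuclei = np.zeros(shape, dtype=bool)
    positive = np.zeros(shape, dtype=bool)
    occupied = np.zeros(shape, dtype=bool)
    true_fraction: dict[str, float] = {}
    n_nuclei: dict[str, int] = {}
    n_positive: dict[str, int] = {}
    for comp, comp_mask in masks.as_dict().items():
        n = params.nuclei_per_compartment.get(comp, 0)
        frac = params.pgr_positive_fraction.get(comp, 0.0)
        centers = _place_disks(comp_mask, n, params.nucleus_radius, occupied, rng)
        n_pos = int(round_half_up(frac * n, 0)) if n else 0
        pos_idx = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()
        for i, (r, c) in enumerate(centers):
            dr, dc = _disk((r, c), params.nucleus_radius, shape=shape)
            nuclei[dr, dc] = True
            if i in pos_idx:
                positive[dr, dc] = True
        n_nuclei[comp] = n
        n_positive[comp] = n_pos
        true_fraction[comp] = n_pos / n if n else math.nan

    intensity = params.signal_intensity
    red = np.where(positive, intensity, 0).astype(float)
    blue = np.where(nuclei, intensity, 0).astype(float)
    green = np.zeros(shape, dtype=float)
    band = max(2, size // 16)
    green[:band, :] = intensity  # myometrial band outside the studied region
    if params.noise > 0:
        sd = params.noise * 255.0
        red += rng.normal(0.0, sd, shape)
        blue += rng.normal(0.0, sd, shape)
        green += rng.normal(0.0, sd, shape)
    image = TrichromeImage(
        red=np.clip(red, 0, 255).astype(np.uint8),
        green=np.clip(green, 0, 255).astype(np.uint8),
        blue=np.clip(blue, 0, 255).astype(np.uint8),
        pixel_size_um=params.pixel_size_um,
    )
    truth = ImageGroundTruth(
        nuclei_mask=nuclei, positive_mask=positive, true_fraction=true_fraction,
        n_nuclei=n_nuclei, n_positive=n_positive,
    )
    return image, rois, masks, truth


# ---------------------------------------------------------------------------
# Estrous cycle series
# ---------------------------------------------------------------------------


@dataclass
class CycleSimParams:
    """Stage-blocked cycle simulator.

    Default durations (P1 E2 M1 D2 days, a 6-day cycle, ~2.3 cycles per
    14-day window) sit in the normal range for cycling mice; the
    adenomyosis condition is modelled as a multiplicative prolongation
    of the estrus block. Compositions are expected fractions of
    (nucleated, cornified, leukocyte) cells per stage.
    """

    stage_durations: dict[str, int] = field(
        default_factory=lambda: {"proestrus": 1, "estrus": 2, "metestrus": 1, "diestrus": 2}
    )
    estrus_prolongation: float = 1.0
    compositions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "proestrus": (0.80, 0.15, 0.05),
            "estrus": (0.05, 0.90, 0.05),
            "metestrus": (0.05, 0.45, 0.50),
            "diestrus": (0.10, 0.15, 0.75),
        }
    )
    cells_per_smear: int = 100
    n_days: int = 14
    duration_jitter: bool = False  # optional geometric jitter on block lengths
    seed: int = 0

    def __post_init__(self) -> None:
        for stage, dur in self.stage_durations.items():
            if dur <= 0:
                raise ValueError(f"{stage}: duration must be > 0")
        for stage, comp in self.compositions.items():
            if not math.isclose(sum(comp), 1.0, abs_tol=1e-9):
                raise ValueError(f"{stage}: composition must sum to 1")
        if self.estrus_prolongation <= 0:
            raise ValueError("estrus prolongation must be > 0")


def simulate_cycles(
    params: CycleSimParams,
) -> tuple[list[SmearObservation], list[str]]:
    """Daily smears over the observation window plus true stage labels.

    Stages repeat in the fixed order P -> E -> M -> D with block lengths
    from ``stage_durations`` (estrus scaled by the prolongation factor,
    rounded half-up, minimum 1 day); per-day cell counts are multinomial
    draws from that stage's composition.
    """
    rng = np.random.default_rng(params.seed)
    labels: list[str] = []
    while len(labels) < params.n_days:
        for stage in STAGES:
            dur = params.stage_durations[stage]
            if stage == "estrus":
                dur = max(1, int(round_half_up(dur * params.estrus_prolongation, 0)))
            if params.duration_jitter:
                dur = max(1, dur + int(rng.geometric(0.7)) - 1)
            labels.extend([stage] * dur)
    labels = labels[: params.n_days]
    observations = []
    for day, stage in enumerate(labels, start=1):
        counts = rng.multinomial(params.cells_per_smear, params.compositions[stage])
        observations.append(
            SmearObservation(
                day=day, nucleated=int(counts[0]), cornified=int(counts[1]),
                leukocyte=int(counts[2]),
            )
        )
    return observations, labels


DEGENERATE_COMPOSITIONS = {
    "proestrus": (1.0, 0.0, 0.0),
    "estrus": (0.0, 1.0, 0.0),
    "metestrus": (0.0, 0.5, 0.5),
    "diestrus": (0.0, 0.0, 1.0),
}
"""Pure/near-pure per-stage compositions under which the rule cascade
must recover every true label."""


# ---------------------------------------------------------------------------
# qPCR and follicle tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    fold_changes: dict[str, float],
    n_per_group: int = 8,
    reference_genes: Sequence[str] = ("Rplp0", "Gapdh"),
    reference_cts: Sequence[float] = (17.0, 19.0),
    target_base_ct: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Well-level Ct table with programmed fold changes per target gene.

    Adenomyosis-group target Cts are shifted by -log2(fold) relative to
    control, so the 2^-ddCt analysis recovers ``fold_changes`` exactly
    at zero noise. ``noise_sd`` adds Gaussian cycles per well.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in ((CONTROL, n_per_group), (ADENOMYOSIS, n_per_group)):
        for i in range(n):
            sample = f"{group}_{i+1}"
            for gene, base in zip(reference_genes, reference_cts):
                for well in (1, 2):
                    rows.append(
                        {"sample_id": sample, "group": group, "gene": gene,
                         "well": well,
                         "ct": base + float(rng.normal(0, noise_sd)) if noise_sd else base}
                    )
            for gene, fold in fold_changes.items():
                ct = target_base_ct
                if group == ADENOMYOSIS:
                    ct -= math.log2(fold)
                for well in (1, 2):
                    rows.append(
                        {"sample_id": sample, "group": group, "gene": gene,
                         "well": well,
                         "ct": ct + float(rng.normal(0, noise_sd)) if noise_sd else ct}
                    )
    return pd.DataFrame(rows)


def simulate_follicle_table(
    densities: dict[str, float],
    n_sections: int = 6,
    area_mm2: float = 2.0,
    ovary_id: str = "ov1",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-section annotation table with Poisson counts at the programmed
    per-type densities (n/mm²)."""
    rng = np.random.default_rng(seed)
    rows = []
    fid = 0
    for idx in range(n_sections):
        any_row = False
        for ftype, dens in densities.items():
            k = int(rng.poisson(dens * area_mm2))
            for _ in range(k):
                fid += 1
                rows.append(
                    {"ovary_id": ovary_id, "section_index": idx,
                     "surface_area_mm2": area_mm2,
                     "follicle_id": f"f{fid}", "type": ftype}
                )
                any_row = True
        if not any_row:
            rows.append(
                {"ovary_id": ovary_id, "section_index": idx,
                 "surface_area_mm2": area_mm2, "follicle_id": None, "type": None}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wall-geometry phantoms
# ---------------------------------------------------------------------------


def make_annulus_geometry(
    r_inner: float = 40.0,
    r_outer: float = 120.0,
    center: tuple[float, float] | None = None,
    focus_depths: Sequence[float] = (),
    focus_radius: float = 3.0,
    n_vertices: int = 256,
) -> UterusSectionGeometry:
    """Concentric-circle wall phantom with foci at chosen normalised depths.

    A focus at depth d is a small disk centred at radius
    r_inner + d * (r_outer - r_inner); its own extent makes the realised
    maximum depth slightly larger than d, which callers account for by
    keeping foci away from tertile boundaries or shrinking the radius.
    """
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    if center is None:
        c = r_outer + 8.0
        center = (c, c)
    cx, cy = center

    def circle(radius: float, n: int = n_vertices) -> list[tuple[float, float]]:
        return [(cx + radius * math.cos(t), cy + radius * math.sin(t))
                for t in np.linspace(0, 2 * np.pi, n, endpoint=False)]

    foci = []
    for i, d in enumerate(focus_depths):
        if not 0.0 <= d <= 1.0:
            raise ValueError("focus depth must lie in [0, 1]")
        rad = r_inner + d * (r_outer - r_inner)
        angle = 2 * np.pi * i / max(1, len(focus_depths))
        fx, fy = cx + rad * math.cos(angle), cy + rad * math.sin(angle)
        foci.append(
            [(fx + focus_radius * math.cos(t), fy + focus_radius * math.sin(t))
             for t in np.linspace(0, 2 * np.pi, 32, endpoint=False)]
        )
    return UterusSectionGeometry(
        inner_boundary=circle(r_inner), outer_boundary=circle(r_outer), foci=foci
    )


# ---------------------------------------------------------------------------
# Packaged cohort fixtures (printed-proportion reconstructions)
# ---------------------------------------------------------------------------

GRADE_COHORT_PERCENTAGES = {"0": 1.47, "I": 2.94, "II": 4.41, "III": 91.18}
ADENOMYOSIS_DELIVERING_PERCENT = 33.33
BREEDING_GROUP_SIZE = 6
ENROLMENT = {ADENOMYOSIS: 69, CONTROL: 78}
EUTHANASIA_GROUPS = {ADENOMYOSIS: (14, 55), CONTROL: (12, 66)}


@dataclass
class CohortFixture:
    grades: list[str]
    breeding: list[BreedingRecord]


def make_grade_fixture() -> list[str]:
    """Grade labels of the smallest cohort consistent with the printed
    3-month grade distribution (n = 68: counts 1, 2, 3, 62)."""
    order = list(GRADE_COHORT_PERCENTAGES)
    n, counts = reconstruct_counts_from_percentages(
        [GRADE_COHORT_PERCENTAGES[g] for g in order]
    )
    labels: list[str] = []
    for grade, count in zip(order, counts):
        labels.extend([grade] * count)
    assert len(labels) == n
    return labels


def make_breeding_fixture() -> list[BreedingRecord]:
    """Deterministic 12-dam breeding fixture (6 per arm).

    Every control dam delivers (three litters of about 13 pups at
    weaning each); the number of delivering adenomyosis dams is the
    unique count of 6 whose percentage re-rounds to the printed value
    (2 of 6 -> 33.33%), each with one small litter.
    """
    delivering = None
    for k in range(BREEDING_GROUP_SIZE + 1):
        if k > 0 and _rounds_to(k, BREEDING_GROUP_SIZE, ADENOMYOSIS_DELIVERING_PERCENT):
            delivering = k
            break
    if delivering is None:
        raise ReconstructionError(
            "no delivering count matches the printed group percentage"
        )
    records: list[BreedingRecord] = []
    control_sizes = [(14, 13), (13, 13), (14, 12)]
    for i in range(BREEDING_GROUP_SIZE):
        litters = [
            LitterEvent(month=m, pups_born=born, pups_at_weaning=wean)
            for m, (born, wean) in enumerate(control_sizes, start=1)
        ]
        records.append(BreedingRecord(f"ctl_{i+1}", CONTROL, litters))
    adm_litters = [(7, 6), (7, 7)]
    for i in range(BREEDING_GROUP_SIZE):
        litters = []
        if i < delivering:
            born, wean = adm_litters[i % len(adm_litters)]
            litters = [LitterEvent(month=2, pups_born=born, pups_at_weaning=wean)]
        records.append(BreedingRecord(f"adm_{i+1}", ADENOMYOSIS, litters))
    return records


def make_cohort_fixture() -> CohortFixture:
    return CohortFixture(grades=make_grade_fixture(), breeding=make_breeding_fixture())


def _fixture_path(name: str):
    from importlib import resources

    return resources.files("adenoquant").joinpath(f"data/{name}")


def load_grade_fixture() -> list[str]:
    """Grade labels of the packaged 3-month cohort fixture CSV."""
    with _fixture_path("grade_cohort.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", dtype={"grade": str})
    return df["grade"].tolist()


def load_breeding_fixture() -> list[BreedingRecord]:
    """Breeding records of the packaged 12-dam trial fixture CSV."""
    from .stats import read_breeding_csv

    with _fixture_path("breeding_trial.csv").open() as fh:
        return read_breeding_csv(fh)


def write_fixture_csvs(directory) -> None:
    """Regenerate the packaged fixture CSVs from the reconstruction code."""
    from pathlib import Path

    from .stats import breeding_records_to_frame

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grades = make_grade_fixture()
    gdf = pd.DataFrame(
        {"mouse_id": [f"adm3m_{i+1}" for i in range(len(grades))], "grade": grades}
    )
    with open(directory / "grade_cohort.csv", "w") as fh:
        fh.write("# 3-month cohort grades reconstructed from printed percentages "
                 "(smallest consistent n)\n")
        gdf.to_csv(fh, index=False)
    bdf = breeding_records_to_frame(make_breeding_fixture())
    with open(directory / "breeding_trial.csv", "w") as fh:
        fh.write("# 12-dam breeding-trial fixture; delivering counts reconstructed "
                 "from printed group percentages\n")
        bdf.to_csv(fh, index=False)
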