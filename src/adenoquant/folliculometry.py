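"""Ovarian follicle densitometry from per-section annotation tables.

Ovaries are serially sectioned at 5 µm and one in every ten sections is
stained (Lhx8) for differential follicle counts. Follicles arrive here
already typed (primordial / primary / secondary-or-more-growing /
corpus luteum) by upstream morphological classification; this module
turns the annotation tables into per-type densities (n/mm², pooled over
sections) and deduplicated corpora-lutea counts over a fixed span of
stained sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

FOLLICLE_TYPES = ("primordial", "primary", "secondary_plus", "corpus_luteum")
MIN_SECTIONS = 6  # quantification design: at least six sections per ovary


@dataclass
class OvarySection:
    """One stained section: position in the stained series, its outlined
    surface area, and the follicle annotations found on it."""

    ovary_id: str
    section_index: int
    surface_area_mm2: float
    # (follicle_id, type); follicle_id may be None (fallback: every
    # annotation distinct, reproducing unadjusted raw counting)
    annotations: list[tuple[str | None, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.surface_area_mm2 <= 0:
            raise ValueError("surface_area_mm2 must be positive")
        if self.section_index < 0:
            raise ValueError("section_index must be >= 0")
        for fid, ftype in self.annotations:
            if ftype not in FOLLICLE_TYPES:
                raise ValueError(f"unknown follicle type {ftype!r}")


@dataclass
class DensityResult:
    ovary_id: str
    counts: dict[str, int]
    densities: dict[str, float]  # n/mm2, pooled
    total_area_mm2: float
    n_sections: int
    qc_flags: list[str]


def follicle_density(sections: Sequence[OvarySection]) -> DensityResult:
    """Per-type follicle density for one ovary: pooled counts / pooled area.

    The pooled estimator (sum of counts across sections divided by the
    summed outlined surface) matches a per-mm² definition over the whole
    quantified series and is invariant to how annotations are split
    across sections of equal combined area. Fewer than six sections is
    flagged, not rejected.
    """
    if not sections:
        raise ValueError("no sections supplied")
    ids = {s.ovary_id for s in sections}
    if len(ids) != 1:
        raise ValueError(f"sections from multiple ovaries: {sorted(ids)}")
    flags: list[str] = []
    if len(sections) < MIN_SECTIONS:
        flags.append(f"fewer_than_{MIN_SECTIONS}_sections")
        warnings.warn(
            f"ovary {sections[0].ovary_id}: only {len(sections)} sections "
            f"(design calls for >= {MIN_SECTIONS})",
            stacklevel=2,
        )
    total_area = sum(s.surface_area_mm2 for s in sections)
    if total_area <= 0:
        raise ValueError("zero total surface area")
    counts = {t: 0 for t in FOLLICLE_TYPES}
    for s in sections:
        for _, ftype in s.annotations:
            counts[ftype] += 1
    densities = {t: counts[t] / total_area for t in FOLLICLE_TYPES}
    return DensityResult(
        ovary_id=sections[0].ovary_id,
        counts=counts,
        densities=densities,
        total_area_mm2=total_area,
        n_sections=len(sections),
        qc_flags=flags,
    )


def corpora_lutea_count(
    sections: Sequence[OvarySection], span_sections: int = 8
) -> tuple[int, list[str]]:
    """Distinct corpora lutea over a span of consecutive stained sections.

    The same corpus luteum crosses adjacent sections, so identity is
    carried by the follicle_id column: equal ids within the span count
    once (raw count, no volumetric adjustment). Annotations without an
    id are each counted as distinct. Returns (count, qc_flags).
    """
    if not sections:
        raise ValueError("no sections supplied")
    flags: list[str] = []
    ordered = sorted(sections, key=lambda s: s.section_index)
    if len(ordered) < span_sections:
        flags.append("span_exceeds_available_sections")
    window = ordered[:span_sections]
    seen_ids: set[str] = set()
    anonymous = 0
    for s in window:
        for fid, ftype in s.annotations:
            if ftype != "corpus_luteum":
                continue
            if fid is None:
                anonymous += 1
            else:
                seen_ids.add(fid)
    return len(seen_ids) + anonymous, flags


def sections_for_span(
    span_um: float, section_thickness_um: float, sampling_interval: int
) -> int:
    """Stained sections covering a tissue span.

    With 5 µm sections and one-in-ten staining, consecutive stained
    sections are 50 µm apart, so a 400 µm span covers 8 of them.
    """
    if span_um <= 0 or section_thickness_um <= 0 or sampling_interval <= 0:
        raise ValueError("all arguments must be positive")
    return int(span_um // (section_thickness_um * sampling_interval))


def read_sections_csv(path) -> dict[str, list[OvarySection]]:
    """Read ovary_id, section_index, surface_area_mm2, follicle_id, type.

    One row per annotation; sections without annotations appear with an
    empty follicle_id/type. Returns sections grouped by ovary.
    """
    df = pd.read_csv(path, comment="#")
    out: dict[str, dict[int, OvarySection]] = {}
    for _, row in df.iterrows():
        oid = str(row["ovary_id"])
        idx = int(row["section_index"])
        per = out.setdefault(oid, {})
        if idx not in per:
            per[idx] = OvarySection(
                ovary_id=oid, section_index=idx,
                surface_area_mm2=float(row["surface_area_mm2"]),
            )
        if pd.notna(row.get("type")):
            fid = row.get("follicle_id")
            fid = None if pd.isna(fid) else str(fid)
            per[idx].annotations.append((fid, str(row["type"])))
    return {oid: sorted(per.values(), key=lambda s: s.section_index)
            for oid, per in out.items()}


def summarize_ovaries(
    sections_by_ovary: dict[str, list[OvarySection]], span_sections: int = 8
) -> pd.DataFrame:
    """Per-ovary output table: counts, densities, CL count, QC flags."""
    rows = []
    for oid, sections in sections_by_ovary.items():
        dens = follicle_density(sections)
        cl, cl_flags = corpora_lutea_count(sections, span_sections)
        for t in FOLLICLE_TYPES:
            rows.append(
                {
                    "ovary_id": oid,
                    "type": t,
                    "count": dens.counts[t],
                    "density_per_mm2": dens.densities[t],
                    "n_sections": dens.n_sections,
                    "cl_count_in_span": cl,
                    "qc_flags": ";".join(dens.qc_flags + cl_flags),
                }
            )
    return pd.DataFrame(rows)
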