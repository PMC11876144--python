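"""Geometric descriptors of KASP plate morphology.

These quantify the verbal clauses of the 0-100 typing rubric — cluster
independence, heterozygote midpoint placement, axis shifts, trailing tails,
diffusion and NTC specificity — so that simulated morphologies can be checked
numerically.  They require known genotype assignments, i.e. simulator output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plate import DNA, NTC, PlateRecord
from .synth import BACKGROUND_LEVEL

#: An NTC farther from background than half the mean signal-cluster distance
#: is called "markedly specific" (nonspecific amplification in the control).
NTC_SPECIFICITY_THRESHOLD = 0.5


@dataclass
class GeometryReport:
    """Morphology descriptors for one plate (genotype-resolved)."""

    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    within_spread: dict[str, float] = field(default_factory=dict)
    #: het centroid minus homozygote midpoint, as (parallel, perpendicular)
    #: components along/about the hom_A -> hom_B axis; None if a cluster is absent.
    het_midpoint_deviation: tuple[float, float] | None = None
    tailing_index: dict[str, float] = field(default_factory=dict)
    separation_index: float | None = None
    ntc_specificity_index: float | None = None

    @property
    def ntc_specific(self) -> bool:
        return (
            self.ntc_specificity_index is not None
            and self.ntc_specificity_index > NTC_SPECIFICITY_THRESHOLD
        )


def _points_by_genotype(plate: PlateRecord) -> dict[str, np.ndarray]:
    groups: dict[str, list] = {}
    for w in plate.wells:
        if w.role == DNA and w.genotype != "unknown":
            groups.setdefault(w.genotype, []).append((w.x, w.y))
    return {g: np.asarray(pts, dtype=float) for g, pts in groups.items()}


def morphology_descriptors(
    plate: PlateRecord, background: tuple[float, float] = (BACKGROUND_LEVEL, BACKGROUND_LEVEL)
) -> GeometryReport:
    """Compute the full geometry report for a genotype-resolved plate.

    * ``within_spread``: RMS distance of a cluster's points to its centroid.
    * ``het_midpoint_deviation``: het centroid minus homozygote midpoint,
      decomposed parallel/perpendicular to the homozygote line; exactly (0, 0)
      when the het cloud sits on the midpoint.
    * ``tailing_index``: skewness of homozygote point projections onto the
      centroid-to-origin direction (positive = trailing toward the origin).
    * ``separation_index``: min inter-centroid distance over mean within-cluster
      spread (scale-covariant cluster-independence measure).
    * ``ntc_specificity_index``: max NTC distance from the background point over
      mean signal-cluster distance from background; large values mean the
      control amplified.

    A genotype class with no wells simply has its fields absent.
    """
    groups = _points_by_genotype(plate)
    report = GeometryReport()

    for g, pts in groups.items():
        c = pts.mean(axis=0)
        report.centroids[g] = c
        report.within_spread[g] = float(
            np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1)))
        )

    for g in ("AA", "BB"):
        if g in groups and len(groups[g]) >= 3:
            c = report.centroids[g]
            to_origin = -c
            norm = np.linalg.norm(to_origin)
            if norm > 0:
                proj = (groups[g] - c) @ (to_origin / norm)
                # a degenerate (zero-spread) cluster has no tail by definition
                report.tailing_index[g] = (
                    float(stats.skew(proj)) if np.std(proj) > 1e-12 else 0.0
                )

    if "AA" in report.centroids and "BB" in report.centroids:
        a, b = report.centroids["AA"], report.centroids["BB"]
        if "AB" in report.centroids:
            line = b - a
            norm = np.linalg.norm(line)
            if norm > 0:
                u = line / norm
                perp = np.array([-u[1], u[0]])
                d = report.centroids["AB"] - 0.5 * (a + b)
                report.het_midpoint_deviation = (float(d @ u), float(d @ perp))

    if len(report.centroids) >= 2:
        genos = sorted(report.centroids)
        dists = [
            np.linalg.norm(report.centroids[g1] - report.centroids[g2])
            for i, g1 in enumerate(genos)
            for g2 in genos[i + 1:]
        ]
        mean_spread = np.mean([report.within_spread[g] for g in genos])
        report.separation_index = (
            float(min(dists) / mean_spread) if mean_spread > 0 else float("inf")
        )

    ntc = np.asarray([(w.x, w.y) for w in plate.wells if w.role == NTC], dtype=float)
    if len(ntc) and report.centroids:
        bg = np.asarray(background, dtype=float)
        ntc_dist = float(np.max(np.linalg.norm(ntc - bg, axis=1)))
        cluster_dist = float(
            np.mean([np.linalg.norm(c - bg) for c in report.centroids.values()])
        )
        if cluster_dist > 0:
            report.ntc_specificity_index = ntc_dist / cluster_dist

    return report


def descriptor_features(plate: PlateRecord) -> np.ndarray:
    """Fixed-length numeric summary of a geometry report (for sanity-check
    classifiers on simulated plates)."""
    rep = morphology_descriptors(plate)
    dev = rep.het_midpoint_deviation or (0.0, 0.0)
    return np.array(
        [
            rep.separation_index if rep.separation_index is not None else 0.0,
            np.mean(list(rep.within_spread.values())) if rep.within_spread else 0.0,
            abs(dev[0]),
            abs(dev[1]),
            max(rep.tailing_index.values(), default=0.0),
            rep.ntc_specificity_index or 0.0,
        ]
    )
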